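"""Isoform coexpression network construction and cross-dataset merging.

The pipeline computes Pearson correlations rho_ij = cov(E_i, E_j) / (sigma_i
sigma_j) between the expression profiles of protein-coding isoforms within
each dataset, removes intra-gene pairs, thresholds on |rho| >= s (default
0.5), checks that the two datasets yield topologically consistent networks
(degree correlation > 0.5), and merges the two correlation estimates per
pair by inverse-variance-weighted Fisher z meta-analysis (weights n-3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CombineConfig",
    "StabilityReport",
    "filter_expressed_isoforms",
    "compute_coexpression",
    "threshold_network",
    "degree_stability",
    "combine_networks",
]


@dataclass(frozen=True)
class CombineConfig:
    """How the per-dataset correlation tables are merged into one network.

    edge_rule
        ``"intersection"`` keeps a pair only if |rho| >= ``s`` in BOTH
        datasets (robust connections); ``"union"`` requires it in either.
    s
        Per-dataset correlation threshold applied by the edge rule.
    threshold
        Cut applied to the combined coefficient after the z-transform merge.
    """

    edge_rule: str = "intersection"
    s: float = 0.5
    threshold: float = 0.5

    def __post_init__(self):
        if self.edge_rule not in ("intersection", "union"):
            raise ValidationError(f"edge_rule must be intersection/union, got {self.edge_rule!r}")
        if not 0 < self.threshold <= 1:
            raise ValidationError(f"combine threshold must be in (0,1], got {self.threshold}")


@dataclass(frozen=True)
class StabilityReport:
    """Degree-correlation check between the two per-dataset networks."""

    cor: float
    passed: bool
    n_nodes: int
    degrees: pd.DataFrame = field(repr=False)  # columns: degree_a, degree_b


def filter_expressed_isoforms(
    expr: pd.DataFrame, min_value: float = 1.0, min_samples: int = 30
) -> pd.DataFrame:
    """Keep isoforms whose expression is >= ``min_value`` in >= ``min_samples`` samples.

    Both bounds are inclusive. Column order is preserved.
    """
    if min_samples > expr.shape[1]:
        raise ValidationError(
            f"min_samples={min_samples} exceeds the {expr.shape[1]} available samples"
        )
    keep = (expr.values >= min_value).sum(axis=1) >= min_samples
    out = expr.loc[keep]
    logger.info("expression filter kept %d/%d isoforms", out.shape[0], expr.shape[0])
    return out


def _canonical_pairs(isoforms: list[str], gene_model: GeneModel) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i<j by lexicographic isoform ID) excluding intra-gene pairs."""
    order = np.argsort(np.asarray(isoforms, dtype=object))
    sorted_isos = [isoforms[k] for k in order]
    genes = np.asarray([gene_model.gene_of(i) or f"\x00{i}" for i in sorted_isos], dtype=object)
    ii, jj = np.triu_indices(len(sorted_isos), k=1)
    keep = genes[ii] != genes[jj]
    return order[ii[keep]], order[jj[keep]]


def compute_coexpression(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    gene_model: GeneModel,
    min_overlap: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation tables for the isoforms common to both datasets.

    Returns one table per dataset over the identical pair universe, each with
    columns ``isoform_a < isoform_b`` (lexicographic), ``rho`` and ``n`` (the
    dataset's sample count). Pairs of isoforms from the same gene are removed,
    as are pairs touching a zero-variance expression vector in either dataset.
    """
    common = sorted(set(expr_a.index) & set(expr_b.index))
    if len(common) < min_overlap:
        raise ValidationError(
            f"only {len(common)} isoforms shared between datasets (min_overlap={min_overlap})"
        )
    a = expr_a.loc[common]
    b = expr_b.loc[common]

    var_ok = (a.values.std(axis=1) > 0) & (b.values.std(axis=1) > 0)
    n_zero = int((~var_ok).sum())
    if n_zero:
        logger.info("dropping %d isoforms with zero variance in at least one dataset", n_zero)
    common = [iso for iso, ok in zip(common, var_ok) if ok]
    a, b = a.loc[common], b.loc[common]

    ii, jj = _canonical_pairs(common, gene_model)
    isos = np.asarray(common, dtype=object)

    tables = []
    for mat in (a, b):
        corr = np.corrcoef(mat.values)
        tables.append(
            pd.DataFrame(
                {
                    "isoform_a": isos[ii],
                    "isoform_b": isos[jj],
                    "rho": corr[ii, jj],
                    "n": mat.shape[1],
                }
            )
        )
    return tables[0], tables[1]


def threshold_network(corr: pd.DataFrame, s: float = 0.5) -> nx.Graph:
    """Build a coexpression network keeping pairs with |rho| >= s (inclusive).

    Isolated nodes are dropped: the node set is exactly the set of endpoint
    isoforms of retained edges. Edge weights are the signed correlations.
    """
    if not 0 < s <= 1:
        raise ValidationError(f"threshold s must be in (0,1], got {s}")
    net = nx.Graph(threshold=s)
    if len(corr):
        kept = corr[np.abs(corr["rho"].values) >= s]
        net.add_weighted_edges_from(
            zip(kept["isoform_a"], kept["isoform_b"], kept["rho"].astype(float))
        )
    return net


def degree_stability(net_a: nx.Graph, net_b: nx.Graph, cut: float = 0.5) -> StabilityReport:
    """Pearson correlation of per-isoform degrees between the two networks.

    Degrees are taken over the union of node sets (a node absent from one
    network contributes degree 0 there). Networks with ``cor > cut`` are
    considered stable enough to merge.
    """
    nodes = sorted(set(net_a) | set(net_b))
    n_common = len(set(net_a) & set(net_b))
    if n_common < 3:
        raise ValidationError(f"only {n_common} common nodes; need >=3 for a degree correlation")
    deg = pd.DataFrame(
        {
            "degree_a": [net_a.degree(v) if v in net_a else 0 for v in nodes],
            "degree_b": [net_b.degree(v) if v in net_b else 0 for v in nodes],
        },
        index=pd.Index(nodes, name="isoform_id"),
    )
    cor = float(stats.pearsonr(deg["degree_a"], deg["degree_b"]).statistic)
    return StabilityReport(cor=cor, passed=cor > cut, n_nodes=len(nodes), degrees=deg)


def _fisher_z(rho: np.ndarray) -> np.ndarray:
    clipped = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
    if np.any(np.abs(rho) >= 1):
        logger.warning("|rho| = 1 encountered; clamped before the z transform")
    return np.arctanh(clipped)


def combine_networks(
    corr_a: pd.DataFrame,
    corr_b: pd.DataFrame,
    n_a: int | None = None,
    n_b: int | None = None,
    cfg: CombineConfig | None = None,
) -> nx.Graph:
    """Merge two correlation tables into the combined (Comb) network.

    For each pair the two coefficients are Fisher z-transformed, averaged
    with inverse-variance weights ``n_k - 3``, and back-transformed:
    ``rho_comb = tanh((w_a z_a + w_b z_b) / (w_a + w_b))``.  A pair becomes an
    edge when it satisfies ``cfg.edge_rule`` at the per-dataset threshold
    ``cfg.s`` and the combined coefficient passes ``cfg.threshold``.
    """
    cfg = cfg or CombineConfig()
    n_a = int(n_a if n_a is not None else corr_a["n"].iloc[0])
    n_b = int(n_b if n_b is not None else corr_b["n"].iloc[0])
    if n_a < 4 or n_b < 4:
        raise ValidationError(f"need >=4 samples per dataset for z weights (got {n_a}, {n_b})")

    merged = corr_a.merge(
        corr_b, on=["isoform_a", "isoform_b"], suffixes=("_a", "_b"), how="inner"
    )
    rho_a = merged["rho_a"].values
    rho_b = merged["rho_b"].values
    pass_a = np.abs(rho_a) >= cfg.s
    pass_b = np.abs(rho_b) >= cfg.s
    eligible = (pass_a & pass_b) if cfg.edge_rule == "intersection" else (pass_a | pass_b)

    w_a, w_b = n_a - 3, n_b - 3
    z = (w_a * _fisher_z(rho_a) + w_b * _fisher_z(rho_b)) / (w_a + w_b)
    rho_comb = np.tanh(z)
    keep = eligible & (np.abs(rho_comb) >= cfg.threshold)

    net = nx.Graph(threshold=cfg.threshold, edge_rule=cfg.edge_rule, n_a=n_a, n_b=n_b)
    net.add_weighted_edges_from(
        zip(merged["isoform_a"].values[keep], merged["isoform_b"].values[keep], rho_comb[keep])
    )
    logger.info(
        "combined network: %d nodes, %d edges (%s rule)",
        net.number_of_nodes(), net.number_of_edges(), cfg.edge_rule,
    )
    return net
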