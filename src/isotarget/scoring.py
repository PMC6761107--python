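"""Shortest-path proximity scoring of candidate target isoforms.

An isoform n is scored against a drug's perturbed isoform set DI by its
shortest-path distances in the coexpression network:

    S(n) = sum_{Pr in DI} sp(n, Pr, N)      (sum mode)

or the mean of the same distances (default), restricted to reachable
perturbed isoforms.  Distances are unweighted hop counts; an optional
weighted mode uses 1 - |rho| edge lengths.  Within each target gene,
isoforms are ranked by ascending score; the rank-1 isoform is the drug's
predicted target major isoform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneModel, ValidationError
from .signatures import PerturbedIsoformSet
from . import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineDistribution",
    "shortest_path_score",
    "score_all_nodes",
    "build_score_table",
    "rank_target_isoforms",
    "random_baseline",
    "compare_to_baseline",
]


def _distance_rows(
    net: nx.Graph, perturbed: frozenset[str], weighted: bool
) -> tuple[list[str], np.ndarray]:
    """Distances from every perturbed isoform to every network node.

    Returns (sorted node list, |DI| x |N| matrix with inf for unreachable).
    One BFS/Dijkstra per perturbed node — cheaper than per-candidate searches.
    """
    nodes = sorted(net)
    index = {v: k for k, v in enumerate(nodes)}
    rows = np.full((len(perturbed), len(nodes)), np.inf)
    for r, src in enumerate(sorted(perturbed)):
        if weighted:
            lengths = nx.single_source_dijkstra_path_length(
                net, src, weight=lambda u, v, d: 1.0 - abs(d.get("weight", 1.0))
            )
        else:
            lengths = nx.single_source_shortest_path_length(net, src)
        for node, dist in lengths.items():
            rows[r, index[node]] = dist
    return nodes, rows


def shortest_path_score(
    net: nx.Graph,
    node: str,
    perturbed: PerturbedIsoformSet,
    mode: str = "mean",
    min_coverage: float = 0.5,
    weighted: bool = False,
) -> tuple[float | None, float]:
    """Proximity of one node to the perturbed set; returns (score, coverage).

    coverage is the fraction of perturbed isoforms reachable from ``node``;
    when it falls below ``min_coverage`` the score is undefined (None), not
    zero.  A node that is itself perturbed contributes its self-distance 0.
    """
    if node not in net:
        raise ValidationError(f"node {node!r} is not in the network")
    if len(perturbed) == 0:
        raise ValidationError("perturbed set is empty")
    if mode not in ("mean", "sum"):
        raise ValidationError(f"mode must be mean/sum, got {mode!r}")
    if weighted:
        lengths = nx.single_source_dijkstra_path_length(
            net, node, weight=lambda u, v, d: 1.0 - abs(d.get("weight", 1.0))
        )
    else:
        lengths = nx.single_source_shortest_path_length(net, node)
    dists = [lengths[p] for p in perturbed.isoforms if p in lengths]
    coverage = len(dists) / len(perturbed)
    if coverage < min_coverage or not dists:
        return None, coverage
    score = float(np.sum(dists)) if mode == "sum" else float(np.mean(dists))
    return score, coverage


def score_all_nodes(
    net: nx.Graph,
    perturbed: PerturbedIsoformSet,
    mode: str = "mean",
    min_coverage: float = 0.5,
    weighted: bool = False,
) -> pd.DataFrame:
    """Score every network node at once (columns: score, n_reachable, coverage).

    Nodes below the coverage guard get a missing (NaN) score.  Equivalent to
    calling :func:`shortest_path_score` per node but runs one search per
    perturbed isoform instead.
    """
    if len(perturbed) == 0:
        raise ValidationError("perturbed set is empty")
    if mode not in ("mean", "sum"):
        raise ValidationError(f"mode must be mean/sum, got {mode!r}")
    nodes, rows = _distance_rows(net, perturbed.isoforms, weighted)
    finite = np.isfinite(rows)
    n_reach = finite.sum(axis=0)
    coverage = n_reach / rows.shape[0]
    with np.errstate(invalid="ignore"):
        total = np.where(finite, rows, 0.0).sum(axis=0)
        score = total if mode == "sum" else np.divide(
            total, n_reach, out=np.full(len(nodes), np.nan), where=n_reach > 0
        )
    score = np.where(coverage >= min_coverage, score, np.nan)
    return pd.DataFrame(
        {"score": score, "n_reachable": n_reach, "coverage": coverage},
        index=pd.Index(nodes, name="isoform_id"),
    )


def build_score_table(
    net: nx.Graph,
    perturbed: PerturbedIsoformSet,
    gene_model: GeneModel,
    mode: str = "mean",
    min_coverage: float = 0.5,
    weighted: bool = False,
) -> pd.DataFrame:
    """Full per-drug score table over all network nodes.

    Adds the source gene, the network-wide rank of every scored isoform
    (ascending score, ties broken by isoform ID), and the within-gene rank.
    Unscored isoforms (coverage below guard) carry NaN score and no rank.
    """
    table = score_all_nodes(net, perturbed, mode, min_coverage, weighted).reset_index()
    table.insert(0, "drug", perturbed.drug)
    table["gene_id"] = [gene_model.gene_of(i) or "" for i in table["isoform_id"]]

    scored = table["score"].notna()
    order = table.loc[scored].sort_values(["score", "isoform_id"], kind="mergesort")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    table["network_rank"] = ranks.reindex(table.index)

    table["gene_rank"] = (
        table.loc[scored]
        .sort_values(["score", "isoform_id"], kind="mergesort")
        .groupby("gene_id")
        .cumcount()
        .add(1)
        .reindex(table.index)
    )
    return table


def rank_target_isoforms(
    score_table: pd.DataFrame, target_gene: str, gene_model: GeneModel
) -> tuple[list[str], str | None]:
    """Rank a target gene's isoforms by score; first is the target major isoform.

    Returns ``(ranked_isoforms, major)``.  ``major`` is None when no isoform
    of the gene has a defined score in the network (gene unpredictable);
    SIT genes trivially return their sole isoform when scored.
    """
    isos = set(gene_model.isoforms_of(target_gene))
    sub = score_table[score_table["isoform_id"].isin(isos) & score_table["score"].notna()]
    if sub.empty:
        logger.info("gene %s: no scored isoform in the network; unpredictable", target_gene)
        return [], None
    ranked = list(sub.sort_values(["score", "isoform_id"], kind="mergesort")["isoform_id"])
    return ranked, ranked[0]


@dataclass(frozen=True)
class BaselineDistribution:
    """Scores of randomly sampled nontarget isoforms for one drug."""

    drug: str
    nodes: tuple[str, ...]
    scores: tuple[float, ...]  # defined scores only
    seed: int


def random_baseline(
    net: nx.Graph,
    perturbed: PerturbedIsoformSet,
    excluded_target_isoforms: set[str],
    k: int = 1000,
    seed: int = 0,
    mode: str = "mean",
    min_coverage: float = 0.5,
    weighted: bool = False,
) -> BaselineDistribution:
    """Score ``k`` random distinct nontarget isoforms.

    Only the drug's own target isoforms are excluded from eligibility;
    perturbed isoforms remain eligible.  Sampling is uniform without
    replacement from the sorted node list, so a seed fully determines the
    draw.  If fewer than ``k`` nodes are eligible, all of them are used.
    """
    eligible = sorted(set(net) - set(excluded_target_isoforms))
    if not eligible:
        raise ValidationError("no eligible nontarget nodes for the baseline")
    rng = np.random.default_rng(seed)
    if len(eligible) < k:
        logger.info("only %d eligible nodes for a baseline of %d; using all", len(eligible), k)
        chosen = eligible
    else:
        chosen = sorted(rng.choice(np.asarray(eligible, dtype=object), size=k, replace=False))
    scores_frame = score_all_nodes(net, perturbed, mode, min_coverage, weighted)
    vals = scores_frame.loc[chosen, "score"]
    defined = vals.dropna()
    return BaselineDistribution(
        drug=perturbed.drug,
        nodes=tuple(chosen),
        scores=tuple(float(v) for v in defined),
        seed=seed,
    )


def compare_to_baseline(
    target_scores: list[float], baseline: BaselineDistribution
) -> "_stats.MannWhitneyResult":
    """Two-sided Mann-Whitney test: target scores vs the random baseline."""
    if not target_scores or not baseline.scores:
        raise ValidationError("both score lists must be nonempty")
    return _stats.mann_whitney_u(list(target_scores), list(baseline.scores))
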