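"""Evaluation statistics: SIT-gene ROC, Mann-Whitney, permutation overlap
tests, drug-sensitivity association, hypergeometric enrichment with BH FDR,
and the neighbor-perturbation ratio statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import AnnotationSet, GeneModel, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MannWhitneyResult",
    "RocResult",
    "OverlapTestResult",
    "mann_whitney_u",
    "roc_sit_evaluation",
    "permutation_overlap_test",
    "overlap_percentage",
    "sensitivity_association",
    "hypergeometric_enrichment",
    "neighbor_perturbation_ratio",
]


# ---------------------------------------------------------------------------
# Mann-Whitney


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" | "normal"
    n_x: int
    n_y: int


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: #{x_i > y_j} + 0.5 * #{x_i == y_j}."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_max: int = 8
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Uses full enumeration of all C(n+m, n) group assignments (an exact,
    distribution-free p) when both samples are small (max(n, m) <=
    ``exact_max``) and tie-free; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("Mann-Whitney requires two nonempty samples")
    n, m = x.size, y.size
    u = _u_statistic(x, y)

    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n + m
    if max(n, m) <= exact_max and not has_ties:
        ranks = sps.rankdata(pooled)  # integers, no ties
        center = n * m / 2.0
        dev = abs(u - center)
        count = total = 0
        for combo in combinations(range(n + m), n):
            u_perm = ranks[list(combo)].sum() - n * (n + 1) / 2.0
            total += 1
            if abs(u_perm - center) >= dev - 1e-9:
                count += 1
        return MannWhitneyResult(u, count / total, "exact", n, m)

    if np.array_equal(np.sort(x), np.sort(y)):
        # identical samples: U is central, the test is uninformative
        return MannWhitneyResult(u, 1.0, "normal", n, m)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), "normal", n, m)


# ---------------------------------------------------------------------------
# ROC over SIT-gene rankings


@dataclass(frozen=True)
class RocResult:
    """Pooled ROC over per-drug rankings; ``frame`` holds one row per cutoff."""

    frame: pd.DataFrame  # cutoff, TP, FP, FN, TN, TPR, FPR
    auc: float


def roc_sit_evaluation(
    rankings: Iterable[tuple[Sequence[str], Iterable[str]]],
    n_nodes: int | None = None,
) -> RocResult:
    """ROC/AUC from ranked isoform lists and known positives.

    ``rankings`` yields per drug an ordered isoform list (rank 1 first) and
    the known target isoforms.  At each rank cutoff c (inclusive: ranked at
    or above c counts as predicted positive), confusion counts are pooled by
    summation across drugs; TPR = TP/(TP+FN), FPR = FP/(FP+TN), and AUC is
    the trapezoidal area under the (FPR, TPR) curve with (0,0) and (1,1)
    endpoints.
    """
    per_drug = []
    max_len = 0
    for ranking, positives in rankings:
        ranking = list(ranking)
        positives = set(positives)
        pos_ranks = np.sort([ranking.index(p) + 1 for p in positives if p in ranking])
        # positives missing from the ranking (e.g. unscored under the
        # coverage guard) are known targets never ranked above any cutoff:
        # permanent false negatives
        per_drug.append((len(ranking), len(positives), len(pos_ranks), pos_ranks))
        max_len = max(max_len, len(ranking))
    if not per_drug or all(p[2] == 0 for p in per_drug):
        raise ValidationError("no known target isoform appears in any ranking")

    n_cut = int(n_nodes) if n_nodes else max_len
    cutoffs = np.arange(1, n_cut + 1)
    tp = np.zeros(n_cut, dtype=int)
    fp = np.zeros(n_cut, dtype=int)
    fn = np.zeros(n_cut, dtype=int)
    tn = np.zeros(n_cut, dtype=int)
    for r_d, n_pos, n_pos_ranked, pos_ranks in per_drug:
        ranked = np.minimum(cutoffs, r_d)
        tp_d = np.searchsorted(pos_ranks, cutoffs, side="right")
        tp += tp_d
        fp += ranked - tp_d
        fn += n_pos - tp_d
        tn += r_d - n_pos_ranked - (ranked - tp_d)

    tpr = tp / np.maximum(tp + fn, 1)
    fpr = fp / np.maximum(fp + tn, 1)
    frame = pd.DataFrame(
        {"cutoff": cutoffs, "TP": tp, "FP": fp, "FN": fn, "TN": tn, "TPR": tpr, "FPR": fpr}
    )
    xs = np.concatenate([[0.0], fpr, [1.0]])
    ys = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(ys, xs))
    return RocResult(frame, auc)


# ---------------------------------------------------------------------------
# permutation overlap test against annotation sets


@dataclass(frozen=True)
class OverlapTestResult:
    observed: int
    n_genes: int
    percentage: float
    null_mean: float
    null_sd: float
    p_value: float
    n_permutations: int
    seed: int


def overlap_percentage(observed: int, total: int) -> float:
    """Percentage truncated (floored) to one decimal, e.g. 75/118 -> 63.5."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= observed <= total:
        raise ValidationError("observed must lie in [0, total]")
    return (1000 * observed // total) / 10


def permutation_overlap_test(
    predicted: dict[str, str],
    reference: AnnotationSet,
    gene_model: GeneModel,
    n_perm: int = 1000,
    seed: int = 0,
) -> OverlapTestResult:
    """Does the predicted major isoform agree with a reference annotation
    more often than chance?

    Restricted to MIT genes present in both maps whose reference isoform
    belongs to the gene.  The null redraws one isoform uniformly per gene
    ``n_perm`` times; the empirical p-value is
    ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    common = []
    for gene in sorted(set(predicted) & set(reference.gene_to_isoform)):
        isos = gene_model.isoforms_of(gene)
        if len(isos) < 2:
            continue  # SIT genes carry no information here
        if reference.gene_to_isoform[gene] not in isos:
            logger.info("gene %s: reference isoform not in gene model; excluded", gene)
            continue
        common.append(gene)
    if not common:
        raise ValidationError("no common MIT genes between prediction and reference")

    observed = sum(
        1 for g in common if predicted[g] == reference.gene_to_isoform[g]
    )
    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm, dtype=int)
    for gene in common:
        isos = gene_model.isoforms_of(gene)
        ref_idx = isos.index(reference.gene_to_isoform[gene])
        null += rng.integers(0, len(isos), size=n_perm) == ref_idx
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return OverlapTestResult(
        observed=observed,
        n_genes=len(common),
        percentage=overlap_percentage(observed, len(common)),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# drug sensitivity association


def sensitivity_association(
    expr: pd.DataFrame,
    sens: pd.DataFrame,
    drug: str,
    isoforms: Sequence[str],
) -> pd.Series:
    """Pearson r between isoform expression and drug sensitivity (AAC).

    ``sens`` is tidy with columns ``cell_line``, ``drug`` and either ``aac``
    or ``auc`` (dose-response area under the curve; converted as
    AAC = 1 - AUC).  Correlations run over the >= 3 cell lines shared with
    the expression matrix; constant expression yields a missing value.
    """
    sub = sens[sens["drug"] == drug]
    if "aac" in sub.columns:
        aac = sub.set_index("cell_line")["aac"].astype(float)
    elif "auc" in sub.columns:
        aac = 1.0 - sub.set_index("cell_line")["auc"].astype(float)
    else:
        raise ValidationError("sensitivity table needs an 'aac' or 'auc' column")
    shared = [c for c in expr.columns if c in aac.index]
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} cell lines shared for drug {drug!r}; need >=3")
    out = {}
    for iso in isoforms:
        if iso not in expr.index:
            out[iso] = math.nan
            continue
        vec = expr.loc[iso, shared].astype(float)
        if vec.std() == 0 or aac[shared].std() == 0:
            out[iso] = math.nan
        else:
            out[iso] = float(sps.pearsonr(vec, aac[shared]).statistic)
    return pd.Series(out, name="pearson_r")


# ---------------------------------------------------------------------------
# hypergeometric enrichment


def hypergeometric_enrichment(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list in each term.

    Returns a frame with per-term overlap, raw p-value, Benjamini-Hochberg
    FDR, and a ``significant`` flag (FDR strictly below ``fdr_cut``).
    """
    uni = frozenset(universe) if universe is not None else collection.universe
    if not uni:
        raise ValidationError("empty gene universe")
    query = set(query_genes)
    dropped = query - uni
    if dropped:
        logger.info("%d query genes outside the universe dropped", len(dropped))
        query &= uni

    terms = sorted(collection.sets)
    rows = []
    for term in terms:
        members = collection.sets[term] & uni
        if not members:
            continue
        k = len(query & members)
        p = float(sps.hypergeom.sf(k - 1, len(uni), len(members), len(query)))
        rows.append((term, collection.names.get(term, term), len(members), k, p))
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "term_size", "overlap", "p_value", "fdr", "significant"]
        )
    frame = pd.DataFrame(rows, columns=["term", "name", "term_size", "overlap", "p_value"])
    frame["fdr"] = multipletests(frame["p_value"].values, method="fdr_bh")[1]
    frame["significant"] = frame["fdr"] < fdr_cut
    return frame


# ---------------------------------------------------------------------------
# neighbor-perturbation ratio


def neighbor_perturbation_ratio(
    net: nx.Graph,
    isoform: str,
    perturbed_genes: Iterable[str],
    collection: GeneSetCollection,
    gene_model: GeneModel,
    fdr_cut: float = 0.05,
    denominator: str = "union",
) -> pd.Series:
    """Per-term overlap ratios between an isoform's neighbor genes and a
    drug's perturbed genes.

    The genes of the isoform's direct network neighbors (N) and the
    perturbed gene set (P) are enriched separately; for every term g
    significant in both, the ratio is |N∩g| / |(N∪P)∩g| (``denominator=
    "union"``, bounded in (0,1]) or |N∩g| / |P∩g| (``"perturbed"``).  Ratio
    lists of two isoforms are compared with :func:`mann_whitney_u`.
    """
    if isoform not in net:
        raise ValidationError(f"isoform {isoform!r} is not in the network")
    if denominator not in ("union", "perturbed"):
        raise ValidationError(f"denominator must be union/perturbed, got {denominator!r}")
    neighbor_genes = {
        g for g in (gene_model.gene_of(v) for v in net.neighbors(isoform)) if g
    }
    if not neighbor_genes:
        logger.info("isoform %s has no annotated neighbors; empty ratio list", isoform)
        return pd.Series(dtype=float, name="ratio")
    perturbed = set(perturbed_genes)

    enr_n = hypergeometric_enrichment(neighbor_genes, collection, fdr_cut=fdr_cut)
    enr_p = hypergeometric_enrichment(perturbed, collection, fdr_cut=fdr_cut)
    sig_n = set(enr_n.loc[enr_n["significant"], "term"])
    sig_p = set(enr_p.loc[enr_p["significant"], "term"])
    ratios = {}
    for term in sorted(sig_n & sig_p):
        members = collection.sets[term]
        num = len(neighbor_genes & members)
        if denominator == "union":
            den = len((neighbor_genes | perturbed) & members)
        else:
            den = len(perturbed & members)
        if den:
            ratios[term] = num / den
    return pd.Series(ratios, name="ratio")
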