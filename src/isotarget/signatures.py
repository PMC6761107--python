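"""Per-gene drug perturbation signatures from dose-structured experiments.

For one drug, every gene's expression G across treated samples is fit by
ordinary least squares to

    G = beta0 + beta_i * C_i + beta_t * T + beta_d * D + beta_b * B

where C_i is the compound concentration (numeric) and T (cell-line type),
D (duration) and B (batch) are dummy-coded categorical covariates.  The
concentration effect is assessed by the 1-df F-test comparing the full model
against the model without the C_i term; genes with F p-value < 0.01 are
called dysregulated and carry |t| of beta_i as their effect magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneModel, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationDesign",
    "DrugSignature",
    "PerturbedIsoformSet",
    "fit_drug_signature",
    "dysregulated_genes",
    "map_genes_to_perturbed_isoforms",
]

_COVARIATES = ("cell_line", "duration", "batch")


@dataclass(frozen=True)
class PerturbationDesign:
    """Sample sheet for perturbation experiments.

    ``frame`` columns: sample_id, drug, concentration, cell_line, duration,
    batch. Concentration is numeric in whatever units the experiments used;
    the remaining covariates are categorical.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"sample_id", "drug", "concentration", *_COVARIATES}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"design is missing columns: {sorted(missing)}")
        if self.frame[list(required)].isna().any().any():
            raise ValidationError("design contains missing covariate values")
        if self.frame["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample IDs in design")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.frame["drug"].unique())

    def samples_for(self, drug: str) -> pd.DataFrame:
        sub = self.frame[self.frame["drug"] == drug]
        if sub.empty:
            raise ValidationError(f"no samples for drug {drug!r}")
        return sub.reset_index(drop=True)


def read_design(path) -> PerturbationDesign:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["concentration"] = df["concentration"].astype(float)
    for col in _COVARIATES:
        if col in df.columns:
            df[col] = df[col].astype(str)
    return PerturbationDesign(df)


@dataclass(frozen=True)
class DrugSignature:
    """Fitted concentration-effect statistics for one drug.

    ``frame`` is indexed by gene_id with columns beta_i, t_stat, F_pvalue.
    """

    drug: str
    frame: pd.DataFrame
    n_samples: int
    model_terms: tuple[str, ...] = ()


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + concentration + dummy-coded covariates (first level reference).

    Covariates with a single observed level are dropped automatically.
    """
    cols: list[np.ndarray] = [np.ones(len(design))]
    names = ["intercept"]
    cols.append(design["concentration"].to_numpy(float))
    names.append("concentration")
    for cov in _COVARIATES:
        levels = sorted(design[cov].unique())
        if len(levels) == 1:
            continue
        for lev in levels[1:]:
            cols.append((design[cov] == lev).to_numpy(float))
            names.append(f"{cov}[{lev}]")
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValidationError(f"design matrix is rank-deficient; collinear columns: {collinear}")


def fit_drug_signature(
    expr_genes: pd.DataFrame, design: PerturbationDesign, drug: str
) -> DrugSignature:
    """OLS fit of the concentration model for every gene, for one drug.

    ``expr_genes`` is a gene x sample matrix covering (at least) the drug's
    samples.  Returns per-gene beta_i, its t statistic, and the F-test
    p-value for dropping the concentration term (numerator df = 1, so
    F = t^2 and the two tests agree exactly).
    """
    sub = design.samples_for(drug)
    if sub["concentration"].nunique() < 2:
        raise ValidationError(f"drug {drug!r} has a single concentration value; beta_i inestimable")
    missing = [s for s in sub["sample_id"] if s not in expr_genes.columns]
    if missing:
        raise ValidationError(f"expression matrix lacks samples {missing[:5]}")
    Y = expr_genes[list(sub["sample_id"])].to_numpy(float).T  # samples x genes
    X, names = _design_matrix(sub)
    n, p = X.shape
    if n < p + 2:
        raise ValidationError(f"need >= {p + 2} samples to fit {p} parameters, got {n}")
    _check_full_rank(X, names)

    c_idx = names.index("concentration")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    rss_full = np.einsum("ij,ij->j", resid, resid)

    X0 = np.delete(X, c_idx, axis=1)
    beta0 = np.linalg.lstsq(X0, Y, rcond=None)[0]
    resid0 = Y - X0 @ beta0
    rss_red = np.einsum("ij,ij->j", resid0, resid0)

    df_resid = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss_full / df_resid
        f_stat = (rss_red - rss_full) / sigma2
        se = np.sqrt(sigma2 * xtx_inv[c_idx, c_idx])
        t_stat = beta[c_idx] / se
    # perfect fits (residuals at floating-point noise level): t infinite,
    # p-value underflows to 0
    perfect = rss_full <= 1e-12 * np.maximum(rss_red, 1.0)
    f_stat = np.where(perfect, np.inf, f_stat)
    t_stat = np.where(perfect, np.sign(beta[c_idx]) * np.inf, t_stat)
    pvals = sps.f.sf(f_stat, 1, df_resid)

    frame = pd.DataFrame(
        {"beta_i": beta[c_idx], "t_stat": t_stat, "F_pvalue": pvals},
        index=pd.Index(expr_genes.index, name="gene_id"),
    )
    return DrugSignature(drug=drug, frame=frame, n_samples=n, model_terms=tuple(names))


def dysregulated_genes(
    sig: DrugSignature, p_cut: float = 0.01, fdr: bool = False
) -> pd.Series:
    """Genes with concentration-effect p-value strictly below ``p_cut``.

    Returns a Series mapping gene_id -> |t| magnitude.  With ``fdr=True``
    the cut is applied to Benjamini-Hochberg adjusted p-values instead of
    raw ones.
    """
    pvals = sig.frame["F_pvalue"]
    if fdr:
        from statsmodels.stats.multitest import multipletests

        pvals = pd.Series(
            multipletests(pvals.values, method="fdr_bh")[1], index=pvals.index
        )
    mask = pvals < p_cut
    if not mask.any():
        logger.warning("drug %s: no dysregulated genes at p<%g", sig.drug, p_cut)
    return sig.frame.loc[mask, "t_stat"].abs().rename("magnitude")


@dataclass(frozen=True)
class PerturbedIsoformSet:
    """Network-resident isoforms of a drug's dysregulated genes."""

    drug: str
    isoforms: frozenset[str]
    source_gene: dict[str, str] = field(default_factory=dict)
    magnitude: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.isoforms)


def map_genes_to_perturbed_isoforms(
    genes: pd.Series | dict[str, float],
    gene_model: GeneModel,
    net: nx.Graph,
    drug: str,
) -> PerturbedIsoformSet:
    """Expand dysregulated genes to all of their network-resident isoforms.

    Because perturbation data is gene-level, every isoform of a dysregulated
    gene is treated as perturbed; isoforms absent from the network (and genes
    absent from the gene model) are dropped and logged.
    """
    if isinstance(genes, pd.Series):
        genes = genes.to_dict()
    isoforms: set[str] = set()
    source: dict[str, str] = {}
    magnitude: dict[str, float] = {}
    n_skipped_genes = n_dropped_isoforms = 0
    for gene in sorted(genes):
        isos = gene_model.isoforms_of(gene)
        if not isos:
            n_skipped_genes += 1
            continue
        for iso in isos:
            if iso in net:
                isoforms.add(iso)
                source[iso] = gene
                magnitude[iso] = abs(float(genes[gene]))
            else:
                n_dropped_isoforms += 1
    if n_skipped_genes or n_dropped_isoforms:
        logger.info(
            "drug %s: skipped %d genes missing from the model, dropped %d isoforms not in the network",
            drug, n_skipped_genes, n_dropped_isoforms,
        )
    if not isoforms:
        raise ValidationError(f"drug {drug!r}: no perturbed isoforms are network nodes; cannot score")
    return PerturbedIsoformSet(drug, frozenset(isoforms), source, magnitude)
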