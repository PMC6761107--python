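"""Synthetic datasets with planted ground truth for the full pipeline.

The generator emulates the statistical structure the method assumes:

* a gene model mixing single-isoform (SIT) and multi-isoform (MIT) genes;
* two replicate expression datasets over a shared cell-line panel, driven
  by per-module latent factors (Gaussian factor model) plus dataset-specific
  noise, so the two coexpression networks share module structure;
* per-drug perturbation experiments in which the genes of the planted
  target isoform's network neighborhood respond linearly to concentration
  (slope ``effect_beta``) on top of batch and duration effects, while the
  target gene itself stays unperturbed — mirroring the premise that drug
  targets are expression-stable but their network neighborhoods are not.

Everything is deterministic given ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import DrugTargetTable, GeneModel, ValidationError, write_edge_list, write_expression_matrix, write_gene_model
from .network import CombineConfig, combine_networks, compute_coexpression, filter_expressed_isoforms, threshold_network
from .signatures import PerturbationDesign

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_gene_model",
    "generate_expression_pair",
    "generate_perturbation_experiments",
    "simulate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the documented study conditions."""

    seed: int
    n_genes: int = 150
    sit_fraction: float = 0.4
    mit_isoform_range: tuple[int, int] = (2, 8)
    n_modules: int = 8
    module_coherence: float = 0.8  # P(isoform joins its gene's primary module)
    n_samples_a: int = 60
    n_samples_b: int = 60
    loading_range: tuple[float, float] = (0.62, 0.72)
    noise_sd_a: float = 0.6
    noise_sd_b: float = 0.6
    baseline_mean: float = 4.0
    baseline_sd: float = 0.75
    # perturbation experiments
    n_drugs_mit: int = 3
    n_drugs_sit: int = 3
    radius: int = 1
    n_perturbed_genes: int = 12
    perturb_coherence: float = 1.0  # min fraction of a responder gene's network isoforms within radius
    concentrations: tuple[float, ...] = (0.1, 0.5, 1.0, 5.0, 10.0)
    n_samples_per_drug: int = 40
    n_batches: int = 2
    n_durations: int = 2
    n_cell_types: int = 1
    effect_beta: float = 0.25
    covariate_effect_sd: float = 0.3
    perturb_baseline: float = 6.0
    perturb_noise_sd: float = 0.5
    min_target_degree: int = 20

    def __post_init__(self):
        for name in ("n_genes", "n_modules", "n_samples_a", "n_samples_b",
                     "n_samples_per_drug", "n_perturbed_genes", "radius"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >=1")
        if self.noise_sd_a <= 0 or self.noise_sd_b <= 0 or self.perturb_noise_sd <= 0:
            raise ValidationError("noise standard deviations must be positive")
        if len(self.concentrations) < 2:
            raise ValidationError("need >=2 concentration levels")
        if not 0 <= self.sit_fraction <= 1:
            raise ValidationError("sit_fraction must be in [0,1]")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, per drug: the target gene, its target major isoform,
    and the genes whose expression was made concentration-responsive."""

    drugs: dict[str, dict]  # drug -> {target_gene, planted_isoform, perturbed_genes, kind}
    module_map: dict[str, int]  # isoform -> module

    def to_json(self) -> str:
        return json.dumps(
            {"drugs": self.drugs, "module_map": self.module_map}, indent=2, sort_keys=True
        )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    gene_model: GeneModel
    expr_a: pd.DataFrame
    expr_b: pd.DataFrame
    net_a: nx.Graph
    net_b: nx.Graph
    comb: nx.Graph
    design: PerturbationDesign
    gene_expr: pd.DataFrame
    drug_targets: DrugTargetTable
    truth: GroundTruth


def generate_gene_model(cfg: SyntheticConfig, rng: np.random.Generator | None = None) -> GeneModel:
    """Genes G0001.. with isoforms G0001T1..; SIT/MIT mix per config."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lo, hi = cfg.mit_isoform_range
    records = []
    for g in range(1, cfg.n_genes + 1):
        gene = f"G{g:04d}"
        if rng.random() < cfg.sit_fraction:
            k = 1
        else:
            k = int(rng.integers(lo, hi + 1))
        for t in range(1, k + 1):
            records.append((gene, f"{gene}T{t}"))
    return GeneModel.from_records(records)


def generate_expression_pair(
    gene_model: GeneModel, cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Two expression matrices over a shared cell-line panel plus module map.

    Each gene gets a primary module; each isoform joins it with probability
    ``module_coherence`` or a uniformly chosen other module — so isoforms of
    one gene can live in different network neighborhoods.  Expression is
    ``baseline + loading * factor(module, cell line) + noise`` clipped to
    the non-negative log2(FPKM+1) scale; the latent factors are shared
    between datasets (same biology), the noise is dataset-specific.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    isoforms = gene_model.isoforms
    n_lines = max(cfg.n_samples_a, cfg.n_samples_b)
    lines = [f"CL{i:03d}" for i in range(1, n_lines + 1)]

    primary = {g: int(rng.integers(cfg.n_modules)) for g in gene_model.genes}
    module_map: dict[str, int] = {}
    for iso in isoforms:
        gene = gene_model.gene_of(iso)
        if rng.random() < cfg.module_coherence or cfg.n_modules == 1:
            module_map[iso] = primary[gene]
        else:
            others = [m for m in range(cfg.n_modules) if m != primary[gene]]
            module_map[iso] = int(others[rng.integers(len(others))])

    lo, hi = cfg.loading_range
    loading = {iso: float(rng.uniform(lo, hi)) for iso in isoforms}
    baseline = {iso: float(rng.normal(cfg.baseline_mean, cfg.baseline_sd)) for iso in isoforms}
    factors = rng.standard_normal((cfg.n_modules, n_lines))

    def _one(n_samples: int, noise_sd: float) -> pd.DataFrame:
        cols = lines[:n_samples]
        signal = np.array(
            [baseline[iso] + loading[iso] * factors[module_map[iso], :n_samples] for iso in isoforms]
        )
        values = signal + rng.normal(0.0, noise_sd, size=signal.shape)
        return pd.DataFrame(
            np.clip(values, 0.0, None),
            index=pd.Index(isoforms, name="isoform_id"),
            columns=cols,
        )

    expr_a = _one(cfg.n_samples_a, cfg.noise_sd_a)
    expr_b = _one(cfg.n_samples_b, cfg.noise_sd_b)
    return expr_a, expr_b, module_map


def _coherent_responders(
    gene_model: GeneModel, comb: nx.Graph, planted: str, target_gene: str, radius: int,
    coherence: float,
) -> list[str]:
    """Neighbor genes that make coherent responders for a planted isoform.

    A responder gene must keep >=50% of its network transcripts in the
    planted component (so the target stays scoreable after the gene-level
    perturbation is expanded to all isoforms) and have all of its
    in-component transcripts within the perturbation radius (so network
    proximity carries the signal).
    """
    ego = set(nx.single_source_shortest_path_length(comb, planted, cutoff=radius))
    comp = nx.node_connected_component(comb, planted)
    neighbor_genes = sorted(
        {gene_model.gene_of(v) for v in ego if v != planted} - {target_gene, None}
    )

    def _net_isos(g: str) -> list[str]:
        return [i for i in gene_model.isoforms_of(g) if i in comb]

    out = []
    for g in neighbor_genes:
        net_isos = _net_isos(g)
        in_comp = [i for i in net_isos if i in comp]
        if not in_comp or len(in_comp) / len(net_isos) < 0.5:
            continue
        if sum(1 for i in in_comp if i in ego) / len(in_comp) >= coherence:
            out.append(g)
    return out


def _plant_targets(
    gene_model: GeneModel, comb: nx.Graph, cfg: SyntheticConfig, rng: np.random.Generator
) -> dict[str, dict]:
    """Choose target genes and the isoform to plant as target major.

    MIT targets need >=2 network-resident isoforms; the planted isoform is
    the best-connected one.  A target qualifies only if its planted isoform
    has enough coherent responder genes in its neighborhood — the generator
    emulates exactly the regime the method assumes, where a drug
    dysregulates genes co-expressed with its target isoform.  The target
    gene itself is never perturbed (target expression is assumed stable
    under treatment).
    """
    degree = dict(comb.degree())

    def _net_isos(gene: str) -> list[str]:
        return [i for i in gene_model.isoforms_of(gene) if i in comb]

    def _planted_for(gene: str) -> str:
        return max(_net_isos(gene), key=lambda i: (degree[i], i))

    candidates: dict[str, tuple[str, list[str]]] = {}

    def _pool_of(gene: str) -> tuple[str, list[str]]:
        if gene not in candidates:
            planted = _planted_for(gene)
            candidates[gene] = (
                planted,
                _coherent_responders(
                    gene_model, comb, planted, gene, cfg.radius, cfg.perturb_coherence
                ),
            )
        return candidates[gene]

    def _choose(genes: list[str], n_drugs: int, kind: str) -> list[str]:
        eligible = [g for g in genes if len(_pool_of(g)[1]) >= 1]
        if not eligible:
            raise ValidationError(f"no {kind} target gene has any coherent responder")
        qualified = [
            g for g in eligible
            if degree[_pool_of(g)[0]] >= cfg.min_target_degree
            and len(_pool_of(g)[1]) >= cfg.n_perturbed_genes
        ]
        if len(qualified) >= n_drugs:
            return [str(g) for g in rng.choice(qualified, n_drugs, replace=False)]
        backup = sorted(
            (g for g in eligible if g not in qualified),
            key=lambda g: (-len(_pool_of(g)[1]), -degree[_pool_of(g)[0]], g),
        )
        logger.info(
            "only %d qualifying %s target genes (< %d); falling back to best available",
            len(qualified), kind, n_drugs,
        )
        return qualified + backup[: n_drugs - len(qualified)]

    mit_genes = [g for g in gene_model.mit_genes if len(_net_isos(g)) >= 2]
    sit_genes = [g for g in gene_model.sit_genes if len(_net_isos(g)) == 1]
    chosen_mit = _choose(mit_genes, cfg.n_drugs_mit, "MIT")
    chosen_sit = _choose(sit_genes, cfg.n_drugs_sit, "SIT")

    drugs: dict[str, dict] = {}
    for idx, (gene, kind) in enumerate(
        [(g, "MIT") for g in chosen_mit] + [(g, "SIT") for g in chosen_sit], start=1
    ):
        planted, pool = candidates[gene]
        n_take = min(cfg.n_perturbed_genes, len(pool))
        if n_take < cfg.n_perturbed_genes:
            logger.info(
                "drug D%02d: coherent neighborhood has %d genes (< %d requested); using all",
                idx, len(pool), cfg.n_perturbed_genes,
            )
        perturbed = sorted(str(g) for g in rng.choice(pool, n_take, replace=False))
        drugs[f"D{idx:02d}"] = {
            "target_gene": gene,
            "planted_isoform": planted,
            "perturbed_genes": perturbed,
            "kind": kind,
        }
    return drugs


def generate_perturbation_experiments(
    gene_model: GeneModel,
    truth: GroundTruth,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PerturbationDesign, pd.DataFrame]:
    """Balanced dose/batch/duration design plus the gene expression it yields.

    Perturbed genes respond to concentration with slope ``effect_beta``;
    all other genes have slope zero.  Batch and duration shift every gene by
    gene-specific coefficients so the signature model has real nuisance
    terms to absorb.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genes = gene_model.genes
    levels = list(cfg.concentrations)
    batches = [f"B{i}" for i in range(1, cfg.n_batches + 1)]
    durations = [f"{h}h" for h in (6, 24, 48, 96)[: cfg.n_durations]]
    cell_types = [f"CT{i}" for i in range(1, cfg.n_cell_types + 1)]

    rows = []
    for drug in sorted(truth.drugs):
        for i in range(cfg.n_samples_per_drug):
            rows.append(
                {
                    "sample_id": f"{drug}_S{i + 1:03d}",
                    "drug": drug,
                    "concentration": levels[i % len(levels)],
                    "cell_line": cell_types[i % len(cell_types)],
                    "duration": durations[(i // len(levels)) % len(durations)],
                    "batch": batches[i % len(batches)],
                }
            )
    design = PerturbationDesign(pd.DataFrame(rows))

    batch_coef = rng.normal(0.0, cfg.covariate_effect_sd, size=(len(genes), len(batches)))
    batch_coef[:, 0] = 0.0
    dur_coef = rng.normal(0.0, cfg.covariate_effect_sd, size=(len(genes), len(durations)))
    dur_coef[:, 0] = 0.0

    frame = design.frame
    mat = np.full((len(genes), len(frame)), cfg.perturb_baseline)
    conc = frame["concentration"].to_numpy(float)
    batch_idx = frame["batch"].map({b: i for i, b in enumerate(batches)}).to_numpy()
    dur_idx = frame["duration"].map({d: i for i, d in enumerate(durations)}).to_numpy()
    gene_index = {g: i for i, g in enumerate(genes)}
    for drug, info in sorted(truth.drugs.items()):
        cols = (frame["drug"] == drug).to_numpy()
        for g in info["perturbed_genes"]:
            mat[gene_index[g], cols] += cfg.effect_beta * conc[cols]
    mat += batch_coef[:, batch_idx] + dur_coef[:, dur_idx]
    mat += rng.normal(0.0, cfg.perturb_noise_sd, size=mat.shape)
    gene_expr = pd.DataFrame(
        np.clip(mat, 0.0, None),
        index=pd.Index(genes, name="gene_id"),
        columns=list(frame["sample_id"]),
    )
    return design, gene_expr


def simulate_dataset(
    cfg: SyntheticConfig,
    min_samples: int = 30,
    combine_cfg: CombineConfig | None = None,
) -> SyntheticDataset:
    """Run the whole generator: model, expression, networks, perturbations."""
    rng = np.random.default_rng(cfg.seed)
    gene_model = generate_gene_model(cfg, rng)
    expr_a, expr_b, module_map = generate_expression_pair(gene_model, cfg, rng)

    filt_a = filter_expressed_isoforms(expr_a, 1.0, min(min_samples, cfg.n_samples_a))
    filt_b = filter_expressed_isoforms(expr_b, 1.0, min(min_samples, cfg.n_samples_b))
    corr_a, corr_b = compute_coexpression(filt_a, filt_b, gene_model)
    combine_cfg = combine_cfg or CombineConfig()
    net_a = threshold_network(corr_a, combine_cfg.s)
    net_b = threshold_network(corr_b, combine_cfg.s)
    comb = combine_networks(corr_a, corr_b, cfg.n_samples_a, cfg.n_samples_b, combine_cfg)

    drugs = _plant_targets(gene_model, comb, cfg, rng)
    truth = GroundTruth(drugs=drugs, module_map=module_map)
    design, gene_expr = generate_perturbation_experiments(gene_model, truth, cfg, rng)
    targets = DrugTargetTable(
        pd.DataFrame(
            [(d, info["target_gene"], "inhibitor") for d, info in sorted(drugs.items())],
            columns=["drug_id", "target_gene_id", "action"],
        )
    )
    return SyntheticDataset(
        config=cfg,
        gene_model=gene_model,
        expr_a=expr_a,
        expr_b=expr_b,
        net_a=net_a,
        net_b=net_b,
        comb=comb,
        design=design,
        gene_expr=gene_expr,
        drug_targets=targets,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write every artifact in the exact formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(ds.expr_a, out / "expression_a.tsv")
    write_expression_matrix(ds.expr_b, out / "expression_b.tsv")
    write_gene_model(ds.gene_model, out / "gene_model.tsv")
    ds.design.frame.to_csv(out / "design.tsv", sep="\t", index=False)
    ds.gene_expr.to_csv(out / "gene_expression.tsv", sep="\t", index_label="gene_id")
    ds.drug_targets.frame.to_csv(out / "drug_targets.tsv", sep="\t", index=False)
    write_edge_list(ds.comb, out / "network_comb.tsv")
    (out / "ground_truth.json").write_text(ds.truth.to_json(), encoding="utf-8")
    (out / "config.json").write_text(
        json.dumps(asdict(ds.config), indent=2, sort_keys=True), encoding="utf-8"
    )
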