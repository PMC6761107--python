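"""End-to-end orchestration: filter -> correlate -> threshold -> stability
gate -> combine -> cluster -> signatures -> perturbed isoforms -> score ->
rank -> evaluate, with every stage's output written as plain TSV/JSON under
a config-hash-named directory so reruns with the same inputs, config and
seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    ValidationError,
    read_drug_targets,
    read_expression_matrix,
    read_gene_model,
    write_edge_list,
)
from .network import (
    CombineConfig,
    combine_networks,
    compute_coexpression,
    degree_stability,
    filter_expressed_isoforms,
    threshold_network,
)
from .community import cluster_size_summary, walktrap_clusters
from .signatures import dysregulated_genes, fit_drug_signature, map_genes_to_perturbed_isoforms, read_design
from .scoring import build_score_table, compare_to_baseline, random_baseline, rank_target_isoforms
from .stats import roc_sit_evaluation

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StabilityGateError", "run_pipeline"]


class StabilityGateError(RuntimeError):
    """The two per-dataset networks were too dissimilar to merge (Cor <= cut)."""


@dataclass(frozen=True)
class PipelineConfig:
    """All inputs and thresholds of a pipeline run.

    Defaults equal the method's published operating point: expression filter
    log2(FPKM+1) >= 1 in >= 30 samples, correlation threshold s = 0.5,
    degree-correlation stability gate 0.5, signature p < 0.01, FDR < 0.05,
    coverage guard 0.5, 1,000 baseline isoforms, 1,000 permutations.
    """

    expression_a: str
    expression_b: str
    gene_model: str
    design: str
    gene_expression: str
    drug_targets: str
    out_dir: str
    min_value: float = 1.0
    min_samples: int = 30
    s: float = 0.5
    stability_cut: float = 0.5
    p_cut: float = 0.01
    fdr_cut: float = 0.05
    min_coverage: float = 0.5
    edge_rule: str = "intersection"
    score_mode: str = "mean"
    walktrap_steps: int = 4
    baseline_k: int = 1000
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.s <= 1:
            raise ValidationError(f"s must be in (0,1], got {self.s}")
        if not 0 < self.p_cut < 1:
            raise ValidationError(f"p_cut must be in (0,1), got {self.p_cut}")
        if not 0 < self.fdr_cut < 1:
            raise ValidationError(f"fdr_cut must be in (0,1), got {self.fdr_cut}")
        if not 0 <= self.min_coverage <= 1:
            raise ValidationError(f"min_coverage must be in [0,1], got {self.min_coverage}")
        if self.score_mode not in ("mean", "sum"):
            raise ValidationError(f"score_mode must be mean/sum, got {self.score_mode!r}")
        if self.edge_rule not in ("intersection", "union"):
            raise ValidationError(f"edge_rule must be intersection/union, got {self.edge_rule!r}")
        if self.walktrap_steps < 1 or self.baseline_k < 1 or self.n_perm < 1:
            raise ValidationError("walktrap_steps, baseline_k and n_perm must be >=1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    The run directory is named by the config hash (no timestamps), and a
    manifest with the package version, seed and config is written first so
    partial runs are identifiable.  A failed stability gate raises
    :class:`StabilityGateError` after writing the report.
    """
    run_dir = Path(cfg.out_dir) / f"run-{cfg.config_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    _write_json(
        {"version": __version__, "seed": cfg.seed, "config": dataclasses.asdict(cfg),
         "config_hash": cfg.config_hash()},
        run_dir / "manifest.json",
    )

    # --- load & filter
    expr_a = read_expression_matrix(cfg.expression_a)
    expr_b = read_expression_matrix(cfg.expression_b)
    gene_model = read_gene_model(cfg.gene_model)
    design = read_design(cfg.design)
    gene_expr = read_expression_matrix(cfg.gene_expression)
    targets = read_drug_targets(cfg.drug_targets)

    filt_a = filter_expressed_isoforms(expr_a, cfg.min_value, cfg.min_samples)
    filt_b = filter_expressed_isoforms(expr_b, cfg.min_value, cfg.min_samples)

    # --- correlate, threshold, stability gate, combine
    corr_a, corr_b = compute_coexpression(filt_a, filt_b, gene_model)
    net_a = threshold_network(corr_a, cfg.s)
    net_b = threshold_network(corr_b, cfg.s)
    write_edge_list(net_a, run_dir / "network_a.tsv")
    write_edge_list(net_b, run_dir / "network_b.tsv")

    stability = degree_stability(net_a, net_b, cfg.stability_cut)
    _write_json(
        {"cor": stability.cor, "passed": bool(stability.passed), "n_nodes": stability.n_nodes},
        run_dir / "stability.json",
    )
    if not stability.passed:
        raise StabilityGateError(
            f"degree correlation {stability.cor:.3f} <= {cfg.stability_cut}; networks not merged"
        )

    comb = combine_networks(
        corr_a, corr_b, expr_a.shape[1], expr_b.shape[1],
        CombineConfig(edge_rule=cfg.edge_rule, s=cfg.s, threshold=cfg.s),
    )
    write_edge_list(comb, run_dir / "network_comb.tsv")

    # --- clusters
    clusters = walktrap_clusters(comb, steps=cfg.walktrap_steps)
    pd.DataFrame(
        sorted(clusters.membership.items()), columns=["isoform_id", "cluster_id"]
    ).to_csv(run_dir / "clusters.tsv", sep="\t", index=False)
    n_clusters, n_small, n_large, sizes = cluster_size_summary(clusters)
    _write_json(
        {"n_clusters": n_clusters, "n_small": n_small, "n_large": n_large,
         "sizes": sorted(sizes, reverse=True), "modularity": clusters.modularity},
        run_dir / "cluster_summary.json",
    )

    # --- per-drug signatures, scoring, ranking
    rng = np.random.default_rng(cfg.seed)
    all_scores = []
    predictions = []
    rankings = []
    baseline_rows = []
    for drug in targets.drugs:
        if drug not in design.drugs:
            logger.warning("drug %s has no perturbation samples; skipped", drug)
            continue
        sig = fit_drug_signature(gene_expr, design, drug)
        sig.frame.assign(dysregulated=sig.frame["F_pvalue"] < cfg.p_cut).to_csv(
            run_dir / f"signature_{drug}.tsv", sep="\t"
        )
        dys = dysregulated_genes(sig, cfg.p_cut)
        if dys.empty:
            logger.warning("drug %s: nothing dysregulated; skipped", drug)
            continue
        pset = map_genes_to_perturbed_isoforms(dys, gene_model, comb, drug)
        table = build_score_table(comb, pset, gene_model, cfg.score_mode, cfg.min_coverage)
        all_scores.append(table)

        target_isoforms: set[str] = set()
        for gene in targets.targets_of(drug):
            target_isoforms.update(gene_model.isoforms_of(gene))
            ranked, major = rank_target_isoforms(table, gene, gene_model)
            predictions.append(
                {
                    "drug": drug,
                    "gene_id": gene,
                    "n_isoforms": len(gene_model.isoforms_of(gene)),
                    "sit": gene_model.is_sit(gene),
                    "ranked_isoforms": ",".join(ranked),
                    "target_major_isoform": major if major else "",
                }
            )
            if gene_model.is_sit(gene):
                scored = table[table["score"].notna()].sort_values(
                    ["score", "isoform_id"], kind="mergesort"
                )
                rankings.append(
                    (list(scored["isoform_id"]), set(gene_model.isoforms_of(gene)))
                )
        baseline = random_baseline(
            comb, pset, target_isoforms, cfg.baseline_k,
            seed=int(rng.integers(2**31 - 1)), mode=cfg.score_mode,
            min_coverage=cfg.min_coverage,
        )
        target_scores = [
            float(s)
            for s in table.loc[
                table["isoform_id"].isin(target_isoforms) & table["score"].notna(), "score"
            ]
        ]
        if target_scores and baseline.scores:
            mw = compare_to_baseline(target_scores, baseline)
            baseline_rows.append(
                {"drug": drug, "n_target_scores": len(target_scores),
                 "n_baseline": len(baseline.scores), "U": mw.u, "p_value": mw.p_value}
            )

    if all_scores:
        pd.concat(all_scores, ignore_index=True).to_csv(
            run_dir / "scores.tsv", sep="\t", index=False, float_format="%.10g"
        )
    pd.DataFrame(predictions).to_csv(run_dir / "predictions.tsv", sep="\t", index=False)
    pd.DataFrame(baseline_rows).to_csv(run_dir / "baseline_tests.tsv", sep="\t", index=False)

    # --- SIT-gene ROC
    evaluation: dict = {"n_drugs_scored": len(all_scores)}
    try:
        roc = roc_sit_evaluation(rankings)
        roc.frame.to_csv(run_dir / "roc.tsv", sep="\t", index=False, float_format="%.10g")
        evaluation["sit_roc_auc"] = roc.auc
        evaluation["n_sit_rankings"] = len(rankings)
    except ValidationError as exc:
        evaluation["sit_roc_auc"] = None
        evaluation["roc_note"] = str(exc)
    _write_json(evaluation, run_dir / "evaluation.json")
    return run_dir
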