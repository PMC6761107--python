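"""Readers, writers and validated data containers for pipeline artifacts.

All tabular formats are plain UTF-8 TSV with ``#``-prefixed comment lines
skipped and no quoting; gene sets use the standard GMT layout.  Identifiers
are opaque strings — no Ensembl-style prefix is parsed or required.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "GeneModel",
    "DrugTargetTable",
    "AnnotationSet",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_model",
    "read_drug_targets",
    "read_annotation_set",
    "read_gmt",
    "read_edge_list",
    "write_edge_list",
]


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicate IDs, bad mapping...)."""


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path: str | Path, impute_missing: bool = False) -> pd.DataFrame:
    """Load an isoform (or gene) expression matrix.

    Layout: header row of sample IDs, first column of feature IDs, numeric
    cells on the log2(FPKM+1) scale.  Returns a float DataFrame indexed by
    feature ID.

    Parameters
    ----------
    path:
        TSV file to read.
    impute_missing:
        If true, missing cells are replaced by the row mean; by default any
        missing value is rejected.
    """
    path = Path(path)
    try:
        raw = _read_tsv(path, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty expression file") from exc
    if raw.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")
    if raw.index.duplicated().any():
        dupes = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicated row IDs: {dupes[:5]}")
    if raw.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicated sample columns")

    try:
        mat = raw.astype(float)
    except ValueError:
        # locate the offending cell for a useful error message
        for col in raw.columns:
            bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad][0]
                raise ValidationError(
                    f"{path}: non-numeric value {raw.at[row, col]!r} at row {row!r}, column {col!r}"
                ) from None
        raise
    if mat.isna().any().any():
        if impute_missing:
            mat = mat.apply(lambda r: r.fillna(r.mean()), axis=1)
        else:
            row = mat.index[mat.isna().any(axis=1)][0]
            raise ValidationError(f"{path}: missing value in row {row!r} (pass impute_missing=True to mean-impute)")
    mat.index = mat.index.astype(str)
    mat.index.name = "isoform_id"
    return mat


def write_expression_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t", index_label="isoform_id")


# ---------------------------------------------------------------------------
# gene model


@dataclass(frozen=True)
class GeneModel:
    """Mapping between genes and their transcript/protein isoforms.

    A gene with a single isoform is a SIT (single-isoform target) gene;
    one with two or more is a MIT (multi-isoform target) gene.
    """

    gene_to_isoforms: dict[str, tuple[str, ...]]
    isoform_to_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.isoform_to_gene:
            i2g: dict[str, str] = {}
            for gene, isos in self.gene_to_isoforms.items():
                for iso in isos:
                    i2g[iso] = gene
            object.__setattr__(self, "isoform_to_gene", i2g)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "GeneModel":
        g2i: dict[str, list[str]] = {}
        i2g: dict[str, str] = {}
        for gene, iso in records:
            if not gene or not iso:
                raise ValidationError("empty gene or isoform ID in gene model")
            if iso in i2g:
                if i2g[iso] != gene:
                    raise ValidationError(f"isoform {iso!r} mapped to two genes ({i2g[iso]!r}, {gene!r})")
                continue
            i2g[iso] = gene
            g2i.setdefault(gene, []).append(iso)
        if not g2i:
            logger.warning("gene model is empty")
        return cls({g: tuple(sorted(isos)) for g, isos in g2i.items()})

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_to_isoforms)

    @property
    def isoforms(self) -> list[str]:
        return sorted(self.isoform_to_gene)

    def isoforms_of(self, gene: str) -> tuple[str, ...]:
        return self.gene_to_isoforms.get(gene, ())

    def gene_of(self, isoform: str) -> str | None:
        return self.isoform_to_gene.get(isoform)

    def is_sit(self, gene: str) -> bool:
        return len(self.gene_to_isoforms.get(gene, ())) == 1

    def is_mit(self, gene: str) -> bool:
        return len(self.gene_to_isoforms.get(gene, ())) >= 2

    @property
    def sit_genes(self) -> list[str]:
        return sorted(g for g, isos in self.gene_to_isoforms.items() if len(isos) == 1)

    @property
    def mit_genes(self) -> list[str]:
        return sorted(g for g, isos in self.gene_to_isoforms.items() if len(isos) >= 2)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, i) for g in self.genes for i in self.gene_to_isoforms[g]]
        return pd.DataFrame(rows, columns=["gene_id", "isoform_id"])


def read_gene_model(path: str | Path) -> GeneModel:
    """Read a two-column (gene_id, isoform_id) TSV into a :class:`GeneModel`."""
    path = Path(path)
    try:
        df = _read_tsv(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty gene model file", path)
        return GeneModel({})
    cols = list(df.columns[:2])
    if len(cols) < 2:
        raise ValidationError(f"{path}: gene model needs two columns (gene_id, isoform_id)")
    return GeneModel.from_records(df[cols].itertuples(index=False, name=None))


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    model.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# drug targets


@dataclass(frozen=True)
class DrugTargetTable:
    """Known drug → target-gene relations with an optional action label."""

    frame: pd.DataFrame  # columns: drug_id, target_gene_id, action

    def __post_init__(self):
        f = self.frame
        if f.duplicated(subset=["drug_id", "target_gene_id"]).any():
            raise ValidationError("duplicate (drug, gene) pair in drug target table")

    @property
    def drugs(self) -> list[str]:
        return sorted(self.frame["drug_id"].unique())

    def targets_of(self, drug: str) -> list[str]:
        sub = self.frame[self.frame["drug_id"] == drug]
        return sorted(sub["target_gene_id"])


def read_drug_targets(path: str | Path) -> DrugTargetTable:
    df = _read_tsv(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValidationError(f"{path}: drug target table needs ≥2 columns")
    out = pd.DataFrame(
        {
            "drug_id": df[cols[0]],
            "target_gene_id": df[cols[1]],
            "action": df[cols[2]] if len(cols) > 2 else "unknown",
        }
    )
    out["action"] = out["action"].fillna("unknown")
    return DrugTargetTable(out)


# ---------------------------------------------------------------------------
# annotation sets (principal / longest / proteomic isoform per gene)


@dataclass(frozen=True)
class AnnotationSet:
    """One designated isoform per gene, e.g. APPRIS-style principal isoforms."""

    label: str
    gene_to_isoform: dict[str, str]

    def restrict_to(self, model: GeneModel) -> "AnnotationSet":
        """Drop genes whose annotated isoform is not in the gene model; log them."""
        kept, dropped = {}, []
        for gene, iso in self.gene_to_isoform.items():
            if iso in model.isoforms_of(gene):
                kept[gene] = iso
            else:
                dropped.append(gene)
        if dropped:
            logger.info("annotation %s: %d genes dropped (isoform not in gene model)", self.label, len(dropped))
        return AnnotationSet(self.label, kept)


def read_annotation_set(path: str | Path, label: str) -> AnnotationSet:
    df = _read_tsv(path)
    cols = list(df.columns[:2])
    if len(cols) < 2:
        raise ValidationError(f"{path}: annotation set needs two columns (gene_id, isoform_id)")
    mapping: dict[str, str] = {}
    for gene, iso in df[cols].itertuples(index=False, name=None):
        if gene in mapping and mapping[gene] != iso:
            raise ValidationError(f"{path}: gene {gene!r} annotated with two isoforms")
        mapping[gene] = iso
    return AnnotationSet(label, mapping)


def write_annotation_set(ann: AnnotationSet, path: str | Path) -> None:
    pd.DataFrame(sorted(ann.gene_to_isoform.items()), columns=["gene_id", "isoform_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GO terms etc.) plus the gene universe they live in."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str]
    universe: frozenset[str]

    @classmethod
    def from_dict(cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str] | None = None) -> "GeneSetCollection":
        frozen = {t: frozenset(m) for t, m in sets.items()}
        uni = frozenset(universe) if universe is not None else frozenset().union(*frozen.values()) if frozen else frozenset()
        return cls(frozen, {t: t for t in frozen}, uni)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        uni = frozenset(universe)
        return GeneSetCollection(
            {t: m & uni for t, m in self.sets.items()}, dict(self.names), uni
        )

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line ``term<TAB>description<TAB>member...``."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need ≥3")
            term, desc, *members = fields
            sets[term] = frozenset(m for m in members if m)
            names[term] = desc
    universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets, names, universe)


# ---------------------------------------------------------------------------
# network edge lists


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Serialize an undirected weighted network as a three-column TSV.

    Each unordered pair appears once with the smaller node first; weights are
    written with ``repr`` so a re-read is bit-identical.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{a}\t{b}\t{float(net[a][b]['weight'])!r}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    path = Path(path)
    net = nx.Graph()
    seen: dict[tuple[str, str], float] = {}
    with open(path, encoding="utf-8") as fh:
        header_skipped = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            a, b, w = fields
            if not header_skipped:
                header_skipped = True
                try:
                    float(w)
                except ValueError:
                    continue  # header row
            if a == b:
                raise ValidationError(f"{path}:{lineno}: self-loop on node {a!r}")
            try:
                weight = float(w)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: bad weight {w!r}") from exc
            if not math.isfinite(weight):
                raise ValidationError(f"{path}:{lineno}: non-finite weight")
            key = tuple(sorted((a, b)))
            if key in seen:
                if seen[key] != weight:
                    raise ValidationError(f"{path}:{lineno}: pair {key} repeated with conflicting weights")
                continue
            seen[key] = weight
            net.add_edge(a, b, weight=weight)
    return net
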