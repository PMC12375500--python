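"""Shared domain types and readers/writers for the pipeline's file formats.

The pipeline exchanges plain-text formats only: BED6 peak intervals, TSV
count matrices and sample design tables, a simplified gene-annotation TSV,
GMT gene-set collections, and CSV melt-curve tables.  Every tabular output
is TSV with ``#``-prefixed comment lines so files stay diffable and
language-neutral.  All genomic coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "ClusterRecord",
    "SampleDesign",
    "CountMatrix",
    "GeneFeature",
    "GeneAnnotation",
    "GeneSet",
    "REGIONS",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_count_matrix",
    "write_count_matrix",
    "read_design",
    "write_design",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
    "read_melt_csv",
    "write_melt_csv",
    "to_zero_based",
    "write_tsv",
    "read_tsv",
]

#: Region labels a cluster may be assigned to.
REGIONS = ("5UTR", "CDS", "3UTR", "intron", "intergenic", "other")

_STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A malformed line in an input file (message names the line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval.

    Strand ``"."`` means unknown and matches either strand in overlap
    queries.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of overlap in bp, respecting strands ('.' matches both)."""
        if self.chrom != other.chrom:
            return 0
        if "." not in (self.strand, other.strand) and self.strand != other.strand:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def to_zero_based(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """Convert 1-based closed coordinates to the 0-based half-open convention."""
    return start_1based - 1, end_inclusive


@dataclass
class ClusterRecord:
    """An eCLIP cluster (peak) with optional gene/region assignment.

    ``region == "intergenic"`` if and only if ``gene_id`` is empty; freshly
    parsed, unannotated clusters therefore start as intergenic.
    """

    interval: GenomicInterval
    cluster_id: str
    gene_id: str = ""
    region: str = "intergenic"
    score: float = 0.0
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region label {self.region!r}")
        if (self.region == "intergenic") != (self.gene_id == ""):
            raise ValueError(
                "region 'intergenic' requires an empty gene_id (and vice versa); "
                f"got region={self.region!r} gene_id={self.gene_id!r}"
            )


@dataclass(frozen=True)
class SampleDesign:
    """Metadata for one sequencing library in the 2x2 eCLIP design."""

    sample_id: str
    assay: str  # "IP" or "input"
    treatment: str  # "treated" or "untreated"
    replicate: int
    library_size: int

    def __post_init__(self) -> None:
        if self.assay not in ("IP", "input"):
            raise ValueError(f"assay must be IP or input, got {self.assay!r}")
        if self.treatment not in ("treated", "untreated"):
            raise ValueError(f"invalid treatment {self.treatment!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")


def _check_design_unique(designs: Sequence[SampleDesign]) -> None:
    keys = [(d.assay, d.treatment, d.replicate) for d in designs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (assay, treatment, replicate) in design")
    ids = [d.sample_id for d in designs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in design")


@dataclass
class CountMatrix:
    """Integer reads per feature (row) per sample (column)."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} cols"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("row_ids must be unique")
        if np.issubdtype(self.values.dtype, np.integer):
            if (self.values < 0).any():
                raise ValueError("negative counts")
        # float matrices (RPM) are allowed but must still be non-negative
        elif (self.values < 0).any():
            raise ValueError("negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset_cols(self, cols: Sequence[str]) -> "CountMatrix":
        idx = [self.col_ids.index(c) for c in cols]
        return CountMatrix(list(self.row_ids), list(cols), self.values[:, idx])

    def subset_rows(self, rows: Sequence[str]) -> "CountMatrix":
        pos = {r: i for i, r in enumerate(self.row_ids)}
        idx = [pos[r] for r in rows]
        return CountMatrix(list(rows), list(self.col_ids), self.values[idx, :])


@dataclass(frozen=True)
class GeneFeature:
    interval: GenomicInterval
    region: str  # one of REGIONS (normally 5UTR/CDS/3UTR/intron)

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region label {self.region!r}")


@dataclass
class GeneAnnotation:
    """A gene with its labelled region features (all on one chrom/strand)."""

    gene_id: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        chroms = {f.interval.chrom for f in self.features}
        strands = {f.interval.strand for f in self.features}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"features of gene {self.gene_id} must share chrom and strand"
            )


@dataclass
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[ClusterRecord]:
    """Parse a BED(6+) file into cluster records.

    Columns beyond the sixth are preserved opaquely in ``extra``.  A missing
    name column yields an auto-generated cluster id; a missing strand is
    recorded as ``"."``.
    """
    records: list[ClusterRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            try:
                interval = GenomicInterval(
                    chrom, start, end,
                    fields[5] if len(fields) > 5 and fields[5] in _STRANDS else ".",
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 and fields[3] else f"peak_{lineno}"
            if name in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate cluster id {name!r}")
            seen.add(name)
            score = 0.0
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: bad score") from exc
            records.append(
                ClusterRecord(
                    interval=interval,
                    cluster_id=name,
                    score=score,
                    extra=tuple(fields[6:]),
                )
            )
    return records


def write_bed(records: Iterable[ClusterRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            cols = [
                iv.chrom,
                str(iv.start),
                str(iv.end),
                rec.cluster_id,
                format(rec.score, "g"),
                iv.strand,
                *rec.extra,
            ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# TSV helpers (commented-header convention)


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    descriptions: dict[str, str] | None = None,
    index: bool = False,
    index_label: str | None = None,
) -> None:
    """Write a TSV with ``#`` comment lines describing each column."""
    with open(path, "w") as fh:
        if descriptions:
            for col, desc in descriptions.items():
                fh.write(f"# {col}: {desc}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# Count matrices and design tables


def read_design(path: str | Path) -> list[SampleDesign]:
    df = read_tsv(path, dtype={"sample_id": str})
    required = {"sample_id", "assay", "treatment", "replicate", "library_size"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: design table missing columns {sorted(missing)}")
    designs = [
        SampleDesign(
            sample_id=row.sample_id,
            assay=row.assay,
            treatment=row.treatment,
            replicate=int(row.replicate),
            library_size=int(row.library_size),
        )
        for row in df.itertuples()
    ]
    _check_design_unique(designs)
    return designs


def write_design(designs: Sequence[SampleDesign], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in designs],
            "assay": [d.assay for d in designs],
            "treatment": [d.treatment for d in designs],
            "replicate": [d.replicate for d in designs],
            "library_size": [d.library_size for d in designs],
        }
    )
    write_tsv(df, path, {"sample_id": "library identifier",
                         "assay": "IP or input (SMInput)",
                         "treatment": "treated or untreated",
                         "replicate": "biological replicate number",
                         "library_size": "mapped reads in the library"})


def read_count_matrix(
    path: str | Path, design_path: str | Path
) -> tuple[CountMatrix, list[SampleDesign]]:
    """Read a feature-by-sample count TSV plus its sample design table.

    Every matrix column must have a design row; counts must be non-negative
    integers.
    """
    df = read_tsv(path, index_col=0)
    designs = read_design(design_path)
    by_id = {d.sample_id: d for d in designs}
    absent = [c for c in df.columns if c not in by_id]
    if absent:
        raise ValueError(f"samples missing from design table: {absent}")
    arr = df.to_numpy()
    as_int = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(as_int)):
        raise ValueError("non-numeric count in matrix")
    if (as_int < 0).any():
        raise ValueError("negative count in matrix")
    if not np.allclose(as_int, np.round(as_int)):
        raise ValueError("non-integer count in matrix")
    cm = CountMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns],
        as_int.astype(np.int64),
    )
    return cm, [by_id[c] for c in cm.col_ids]


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    write_tsv(cm.to_frame(), path, index=True, index_label="feature_id")


# ---------------------------------------------------------------------------
# Gene annotation (simplified GTF-lite TSV)

_ANNOT_COLS = ("gene_id", "chrom", "start", "end", "strand", "region")


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    df = read_tsv(path)
    missing = set(_ANNOT_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: annotation missing columns {sorted(missing)}")
    genes: dict[str, GeneAnnotation] = {}
    for row in df.itertuples():
        feat = GeneFeature(
            GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
            row.region,
        )
        gene = genes.setdefault(row.gene_id, GeneAnnotation(row.gene_id, []))
        gene.features.append(feat)
    for gene in genes.values():
        GeneAnnotation(gene.gene_id, gene.features)  # re-validate shared chrom/strand
    return list(genes.values())


def write_annotation(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    rows = []
    for gene in genes:
        for feat in gene.features:
            iv = feat.interval
            rows.append((gene.gene_id, iv.chrom, iv.start, iv.end, iv.strand,
                         feat.region))
    df = pd.DataFrame(rows, columns=list(_ANNOT_COLS))
    write_tsv(df, path, {"region": "feature label (5UTR/CDS/3UTR/intron)"})


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Members are deduplicated; a line with fewer than three fields is a parse
    error (a set must have at least one member).
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected name, description and members"
                )
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ParseError(f"{path}: line {lineno}: gene set has no members")
            sets.append(GeneSet(fields[0], fields[1], members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# Melt-curve CSV

_MELT_COLS = ("temperature", "fraction", "condition", "replicate")


def read_melt_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(_MELT_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: melt table missing columns {sorted(missing)}")
    return df[list(_MELT_COLS)]


def write_melt_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[list(_MELT_COLS)].to_csv(path, index=False)
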