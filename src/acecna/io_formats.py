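"""Readers and writers for the pipeline's external representations.

All genomic coordinates held in memory are 1-based inclusive.  BED files on
disk follow the usual 0-based half-open convention; the conversion happens
exactly once, inside :func:`read_segments` / :func:`write_segments`.
Strand information in annotation files is accepted and discarded — copy-number
dosage is strand-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMPLIFICATION = "amplification"
DELETION = "deletion"
DIRECTIONS = (AMPLIFICATION, DELETION)

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "midpoint"]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def _annotation_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a gene annotation table.

    Expects columns gene_id/chrom/start/end; adds the derived midpoint
    ((start+end)//2) and sorts by (chrom, midpoint, gene_id).
    """
    df = df.copy()
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate gene id in annotation: {dup.iloc[0]!r}")
    if (df["start"] < 1).any():
        bad = df.loc[df["start"] < 1, "gene_id"].iloc[0]
        raise FormatError(
            f"annotation start < 1 for gene {bad!r}; coordinates must be "
            "1-based inclusive"
        )
    if (df["end"] < df["start"]).any():
        bad = df.loc[df["end"] < df["start"], "gene_id"].iloc[0]
        raise FormatError(f"annotation end < start for gene {bad!r}")
    df["midpoint"] = (df["start"] + df["end"]) // 2
    df = df.sort_values(
        ["chrom", "midpoint", "gene_id"], kind="stable"
    ).reset_index(drop=True)
    return df[ANNOTATION_COLUMNS]


@dataclass
class ExpressionCohort:
    """Paired tumor/non-tumor log2 expression with genome-ordered genes.

    Attributes
    ----------
    genes : pd.DataFrame
        Columns gene_id, chrom, start, end, midpoint; sorted by
        (chrom, midpoint, gene_id); row order matches ``values`` rows.
    values : pd.DataFrame
        genes x samples table of log2 expression, index = gene_id.
    pairing : dict
        tumor sample id -> matched non-tumor sample id.
    """

    genes: pd.DataFrame
    values: pd.DataFrame
    pairing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.genes["gene_id"]) != list(self.values.index):
            raise ValueError("gene order of annotation and values disagree")
        tumors = set(self.pairing)
        normals = set(self.pairing.values())
        if len(normals) != len(tumors):
            raise ValueError("pairing is not one-to-one")
        missing = (tumors | normals) - set(self.values.columns)
        if missing:
            raise ValueError(f"paired samples absent from expression table: {sorted(missing)}")

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.pairing)

    @property
    def non_tumor_samples(self) -> list[str]:
        return list(self.pairing.values())

    def group_of(self, sample: str) -> str:
        if sample in self.pairing:
            return "tumor"
        if sample in set(self.pairing.values()):
            return "non_tumor"
        raise KeyError(f"unknown sample id {sample!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    def paired_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(tumor, non_tumor) arrays of shape (n_genes, n_pairs), pair-aligned."""
        t = self.values[self.tumor_samples].to_numpy(float)
        n = self.values[self.non_tumor_samples].to_numpy(float)
        return t, n

    def with_values(self, values: pd.DataFrame) -> "ExpressionCohort":
        return replace(self, values=values)


@dataclass(frozen=True)
class CnaSegmentRecord:
    """A called run of aberrant neighborhood scores."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    direction: str
    n_genes: int
    mean_ns: float
    cohort_id: str

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"bad direction {self.direction!r}")
        if self.end < self.start:
            raise ValueError("segment end < start")
        if self.n_genes < 1:
            raise ValueError("segment must span at least one gene")

    @property
    def width_bp(self) -> int:
        """Interval width in base pairs (1-based inclusive span)."""
        return self.end - self.start + 1


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED4(+strand) gene annotation with 1-based inclusive starts."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {lineno}: expected >=4 columns")
            chrom, start, end, gene_id = parts[:4]
            try:
                rows.append((gene_id, chrom, int(start), int(end)))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    return _annotation_frame(df)


def read_pairing(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping tumor sample id -> non-tumor sample id."""
    pairing: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            tumor, normal = parts
            if tumor in pairing:
                raise FormatError(f"{path}: tumor sample {tumor!r} paired twice")
            pairing[tumor] = normal
    if len(set(pairing.values())) != len(pairing):
        raise FormatError(f"{path}: a non-tumor sample is paired with several tumors")
    return pairing


def read_expression(
    path: str | Path,
    annotation_path: str | Path,
    pairing_path: str | Path,
) -> ExpressionCohort:
    """Assemble an :class:`ExpressionCohort` from the three on-disk tables.

    Genes present in the expression table but missing from the annotation are
    dropped (the count is logged); the returned cohort is restricted to genes
    present in both and sorted by genomic position.
    """
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.index.duplicated().any():
        dup = expr.index[expr.index.duplicated()][0]
        raise FormatError(f"duplicate gene id in expression table: {dup!r}")
    non_numeric = expr.columns[
        [not pd.api.types.is_numeric_dtype(expr[c]) for c in expr.columns]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        coerced = pd.to_numeric(expr[col], errors="coerce")
        bad_row = expr.index[coerced.isna() & expr[col].notna()][0]
        raise FormatError(
            f"non-numeric expression value at gene {bad_row!r}, sample {col!r}"
        )
    expr.index = expr.index.astype(str)

    anno = read_annotation(annotation_path)
    pairing = read_pairing(pairing_path)

    unpaired = set(expr.columns) - set(pairing) - set(pairing.values())
    if unpaired:
        raise FormatError(f"samples without a pair: {sorted(unpaired)}")
    missing_samples = (set(pairing) | set(pairing.values())) - set(expr.columns)
    if missing_samples:
        raise FormatError(
            f"paired samples absent from expression table: {sorted(missing_samples)}"
        )

    keep = anno["gene_id"].isin(expr.index)
    dropped = int((~keep).sum()) + int((~expr.index.isin(anno["gene_id"])).sum())
    n_unannotated = int((~expr.index.isin(anno["gene_id"])).sum())
    if n_unannotated:
        logger.info("dropped %d genes lacking annotation", n_unannotated)
    anno = anno[keep].reset_index(drop=True)
    values = expr.loc[anno["gene_id"]]
    return ExpressionCohort(genes=anno, values=values, pairing=pairing)


_BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tn_genes\tmean_ns"


def write_segments(segments: Sequence[CnaSegmentRecord], path: str | Path) -> None:
    """Write segments as BED6+2 (0-based half-open on disk).

    name = direction:cohort_id, score = round(|mean_ns|); the two extra
    columns (n_genes, mean_ns) make the record round-trippable.
    """
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for seg in segments:
            fh.write(
                "\t".join(
                    [
                        seg.chrom,
                        str(seg.start - 1),
                        str(seg.end),
                        f"{seg.direction}:{seg.cohort_id}",
                        str(int(round(abs(seg.mean_ns)))),
                        ".",
                        str(seg.n_genes),
                        repr(float(seg.mean_ns)),
                    ]
                )
                + "\n"
            )


def read_segments(path: str | Path) -> list[CnaSegmentRecord]:
    """Inverse of :func:`write_segments`; skips comment lines."""
    out: list[CnaSegmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}: line {lineno}: expected 8 columns")
            try:
                chrom, bed_start, bed_end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                n_genes, mean_ns = int(parts[6]), float(parts[7])
                direction, _, cohort_id = name.partition(":")
                out.append(
                    CnaSegmentRecord(
                        chrom=chrom,
                        start=bed_start + 1,
                        end=bed_end,
                        direction=direction,
                        n_genes=n_genes,
                        mean_ns=mean_ns,
                        cohort_id=cohort_id,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return out


def write_expression(cohort: ExpressionCohort, prefix: str | Path) -> None:
    """Write <prefix>.expr.tsv / .anno.bed / .pairs.tsv readable by read_expression."""
    prefix = Path(prefix)
    cohort.values.to_csv(prefix.with_suffix(".expr.tsv"), sep="\t")
    with open(prefix.with_suffix(".anno.bed"), "w") as fh:
        for row in cohort.genes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\n")
    with open(prefix.with_suffix(".pairs.tsv"), "w") as fh:
        for t, n in cohort.pairing.items():
            fh.write(f"{t}\t{n}\n")
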