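"""Readers and writers for the formats the pipeline touches.

The internal data model is deliberately small: bi-allelic
:class:`VariantRecord` rows (multi-allelic VCF sites are split into one
record per alternate allele at read time), a dense
:class:`GenotypeMatrix` of alternate-allele dosages, half-open
:class:`GeneRegion` intervals, and two keyed tables for population
allele frequencies and functional annotations.

VCF parsing and writing go through :mod:`pysam`; this module owns the
dialect rules layered on top (diploid-only genotypes, per-allele
recoding, missing-call semantics).
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "MISSING",
    "VariantRecord",
    "GenotypeMatrix",
    "GeneRegion",
    "AFTable",
    "AnnotationTable",
    "Annotation",
    "VCFParseError",
    "read_vcf",
    "write_vcf",
    "read_regions_bed",
    "write_regions_bed",
    "read_af_table",
    "write_af_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_covariates",
    "write_covariates",
]

#: Sentinel dosage for a missing diploid call.
MISSING: int = -1

CONSEQUENCES = ("nonsynonymous", "synonymous", "other")
SIFT_CATEGORIES = ("damaging", "tolerated", "missing")
POLYPHEN_CATEGORIES = ("probably_damaging", "possibly_damaging", "benign", "missing")


class VCFParseError(ValueError):
    """Raised when a VCF stream violates the dialect this package accepts."""


@dataclass(frozen=True)
class VariantRecord:
    """A single bi-allelic variant site (1-based position)."""

    chrom: str
    pos: int
    id: str | None
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        """Stable identifier: the VCF ID if present, else chrom:pos:ref:alt."""
        return self.id if self.id else f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


class GenotypeMatrix:
    """Alternate-allele dosages, variants x samples.

    Calls are restricted to {0, 1, 2, MISSING}.
    """

    def __init__(self, samples: Sequence[str], calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2:
            raise ValueError("calls must be a 2-D matrix (variants x samples)")
        if calls.shape[1] != len(samples):
            raise ValueError(
                f"matrix has {calls.shape[1]} columns but {len(samples)} sample ids"
            )
        bad = ~np.isin(calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype call value(s): {np.unique(calls[bad])}")
        self.samples = list(samples)
        self.calls = calls

    @property
    def n_variants(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample!r}") from None

    def column(self, sample: str) -> np.ndarray:
        return self.calls[:, self.sample_index(sample)]

    def row(self, i: int) -> np.ndarray:
        return self.calls[i]

    def subset_variants(self, indices: Sequence[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples, self.calls[list(indices)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return self.samples == other.samples and np.array_equal(self.calls, other.calls)


@dataclass(frozen=True)
class GeneRegion:
    """Half-open genomic interval (BED convention: 0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int
    gene: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"region start must be < end, got [{self.start}, {self.end}) for {self.gene}"
            )

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """Membership of a 1-based position; chromosome labels compared exactly."""
        return chrom == self.chrom and self.start < pos_1based <= self.end


@dataclass
class AFTable:
    """(variant key, population) -> allele frequency, with an explicit missing state."""

    frequencies: dict[tuple[str, str], float] = field(default_factory=dict)

    def add(self, variant_key: str, population: str, af: float) -> None:
        if not (0.0 <= af <= 1.0):
            raise ValueError(f"allele frequency out of [0,1]: {af} for {variant_key}")
        key = (variant_key, population)
        if key in self.frequencies:
            raise ValueError(f"duplicate AF row for {variant_key} in {population}")
        self.frequencies[key] = af

    def lookup(self, variant_key: str, population: str) -> float | None:
        """Return the AF, or None when the variant is absent from the table."""
        return self.frequencies.get((variant_key, population))

    @property
    def populations(self) -> set[str]:
        return {pop for _, pop in self.frequencies}


@dataclass(frozen=True)
class Annotation:
    gene: str
    consequence: str
    sift_category: str = "missing"
    polyphen_category: str = "missing"

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence class: {self.consequence!r}")
        if self.sift_category not in SIFT_CATEGORIES:
            raise ValueError(f"unknown SIFT category: {self.sift_category!r}")
        if self.polyphen_category not in POLYPHEN_CATEGORIES:
            raise ValueError(f"unknown PolyPhen category: {self.polyphen_category!r}")


@dataclass
class AnnotationTable:
    """variant key -> functional annotation; one row per variant."""

    annotations: dict[str, Annotation] = field(default_factory=dict)

    def add(self, variant_key: str, annotation: Annotation) -> None:
        if variant_key in self.annotations:
            raise ValueError(f"duplicate annotation row for {variant_key}")
        self.annotations[variant_key] = annotation

    def lookup(self, variant_key: str) -> Annotation | None:
        return self.annotations.get(variant_key)


# ---------------------------------------------------------------------------
# path/stream plumbing


def _as_input_path(source: str | os.PathLike | IO[str], suffix: str) -> tuple[str, bool]:
    """Return (path, is_temporary). File-like inputs are spooled to a temp file
    because htslib readers require a path."""
    if hasattr(source, "read"):
        fd, path = tempfile.mkstemp(suffix=suffix)
        with os.fdopen(fd, "w") as fh:
            fh.write(source.read())  # type: ignore[union-attr]
        return path, True
    return os.fspath(source), False


def _strip_chr(label: str) -> str:
    return label[3:] if label.lower().startswith("chr") else label


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    source: str | os.PathLike | IO[str],
    normalize_chrom: bool = False,
) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read a VCF 4.x text file into variant records and a dosage matrix.

    Multi-allelic sites are split into one record per alternate allele; each
    sample's call on a split record counts copies of that allele only.
    Phased separators are treated as unphased; any missing allele makes the
    whole call missing.

    Parameters
    ----------
    source
        Path or text stream of an uncompressed VCF with a GT FORMAT field.
    normalize_chrom
        If True, strip a leading ``chr`` from contig labels.
    """
    path, is_tmp = _as_input_path(source, ".vcf")
    try:
        try:
            vf = pysam.VariantFile(path)
        except (ValueError, OSError) as exc:
            raise VCFParseError(f"cannot parse VCF: {exc}") from exc
        with vf:
            samples = list(vf.header.samples)
            variants: list[VariantRecord] = []
            rows: list[list[int]] = []
            for rec in vf:
                chrom = _strip_chr(rec.chrom) if normalize_chrom else rec.chrom
                alts = rec.alts or ()
                calls_per_alt: list[list[int]] = [[] for _ in alts]
                for sample in samples:
                    gt = rec.samples[sample].get("GT")
                    if gt is None or len(gt) == 0:
                        raise VCFParseError(
                            f"missing GT at {rec.chrom}:{rec.pos} for sample {sample}"
                        )
                    if len(gt) != 2:
                        raise VCFParseError(
                            f"non-diploid GT ({len(gt)} alleles) at "
                            f"{rec.chrom}:{rec.pos} for sample {sample}"
                        )
                    for j in range(len(alts)):
                        if any(allele is None for allele in gt):
                            calls_per_alt[j].append(MISSING)
                        else:
                            calls_per_alt[j].append(sum(a == j + 1 for a in gt))
                for j, alt in enumerate(alts):
                    variants.append(
                        VariantRecord(
                            chrom=chrom,
                            pos=rec.pos,
                            id=rec.id,
                            ref=rec.ref,
                            alt=alt,
                        )
                    )
                    rows.append(calls_per_alt[j])
            calls = (
                np.array(rows, dtype=np.int8)
                if rows
                else np.empty((0, len(samples)), dtype=np.int8)
            )
            return variants, GenotypeMatrix(samples, calls)
    finally:
        if is_tmp:
            os.unlink(path)


_GT_BY_CALL = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_vcf(
    variants: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    dest: str | os.PathLike | IO[str],
) -> None:
    """Write bi-allelic records and dosages as an uncompressed VCF 4.2 file."""
    if len(variants) != genotypes.n_variants:
        raise ValueError(
            f"{len(variants)} variant records but matrix has "
            f"{genotypes.n_variants} rows"
        )
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")])
    seen: list[str] = []
    for v in variants:
        if v.chrom not in seen:
            seen.append(v.chrom)
    for chrom in seen:
        header.contigs.add(chrom, length=2**29)
    for sample in genotypes.samples:
        header.add_sample(sample)

    stream_out = hasattr(dest, "write")
    if stream_out:
        fd, path = tempfile.mkstemp(suffix=".vcf")
        os.close(fd)
    else:
        path = os.fspath(dest)
    try:
        with pysam.VariantFile(path, "w", header=header) as vf:
            for i, v in enumerate(variants):
                rec = vf.new_record(
                    contig=v.chrom,
                    start=v.pos - 1,
                    stop=v.pos - 1 + len(v.ref),
                    alleles=(v.ref, v.alt),
                    id=v.id,
                )
                for j, sample in enumerate(genotypes.samples):
                    rec.samples[sample]["GT"] = _GT_BY_CALL[int(genotypes.calls[i, j])]
                vf.write(rec)
        if stream_out:
            with open(path) as fh:
                dest.write(fh.read())  # type: ignore[union-attr]
    finally:
        if stream_out:
            os.unlink(path)


# ---------------------------------------------------------------------------
# BED


def read_regions_bed(
    source: str | os.PathLike | IO[str],
    normalize_chrom: bool = False,
) -> list[GeneRegion]:
    """Read a BED4+ file of gene regions (0-based half-open, preserved exactly).

    Overlapping regions are kept as-is; no merging.
    """
    regions: list[GeneRegion] = []
    close = False
    if hasattr(source, "read"):
        fh = source
    else:
        fh = open(source)
        close = True
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"BED line {lineno}: expected >= 4 columns, got {len(fields)}")
            chrom, start_s, end_s, gene = fields[0], fields[1], fields[2], fields[3]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(f"BED line {lineno}: start {start} >= end {end}")
            if normalize_chrom:
                chrom = _strip_chr(chrom)
            regions.append(GeneRegion(chrom=chrom, start=start, end=end, gene=gene))
        return regions
    finally:
        if close:
            fh.close()


def write_regions_bed(regions: Iterable[GeneRegion], dest: str | os.PathLike | IO[str]) -> None:
    df = pd.DataFrame(
        [(r.chrom, r.start, r.end, r.gene) for r in regions],
        columns=["chrom", "start", "end", "gene"],
    )
    df.to_csv(dest, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# TSV tables (headers mandatory)

_AF_COLUMNS = ["variant_id", "population", "af"]
_ANN_COLUMNS = ["variant_id", "gene", "consequence", "sift_category", "polyphen_category"]


def read_af_table(source: str | os.PathLike | IO[str]) -> AFTable:
    """Read the population allele-frequency TSV (columns: variant_id, population, af)."""
    df = pd.read_csv(source, sep="\t", dtype={"variant_id": str, "population": str})
    missing = [c for c in _AF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"AF table missing required column(s): {missing}")
    table = AFTable()
    for row in df.itertuples(index=False):
        af = float(row.af)
        if math.isnan(af):
            raise ValueError(f"non-numeric AF for {row.variant_id}")
        table.add(str(row.variant_id), str(row.population), af)
    return table


def write_af_table(table: AFTable, dest: str | os.PathLike | IO[str]) -> None:
    rows = [
        {"variant_id": vid, "population": pop, "af": af}
        for (vid, pop), af in table.frequencies.items()
    ]
    pd.DataFrame(rows, columns=_AF_COLUMNS).to_csv(dest, sep="\t", index=False)


def read_annotation_table(source: str | os.PathLike | IO[str]) -> AnnotationTable:
    """Read the annotation TSV (gene, consequence class, SIFT/PolyPhen categories)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing required column(s): {missing}")
    table = AnnotationTable()
    for row in df.itertuples(index=False):
        table.add(
            str(row.variant_id),
            Annotation(
                gene=row.gene,
                consequence=row.consequence,
                sift_category=row.sift_category or "missing",
                polyphen_category=row.polyphen_category or "missing",
            ),
        )
    return table


def write_annotation_table(table: AnnotationTable, dest: str | os.PathLike | IO[str]) -> None:
    rows = [
        {
            "variant_id": vid,
            "gene": ann.gene,
            "consequence": ann.consequence,
            "sift_category": ann.sift_category,
            "polyphen_category": ann.polyphen_category,
        }
        for vid, ann in table.annotations.items()
    ]
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(dest, sep="\t", index=False)


_COV_REQUIRED = ["subject_id", "status"]


def read_covariates(source: str | os.PathLike | IO[str]) -> pd.DataFrame:
    """Read the per-subject covariate TSV (must carry subject_id and status columns)."""
    df = pd.read_csv(source, sep="\t")
    missing = [c for c in _COV_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table missing required column(s): {missing}")
    bad = set(df["status"].unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown status value(s): {sorted(bad)}")
    return df


def write_covariates(df: pd.DataFrame, dest: str | os.PathLike | IO[str]) -> None:
    df.to_csv(dest, sep="\t", index=False)
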