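"""Family-based discovery cascade for a shared rare thrombophilia variant.

The cascade reduces the exome of a set of affected relatives to candidate
variants by applying, in order:

1. shared heterozygosity — the variant is carried as exactly one copy by
   every affected member (a dominant-acting, shared-by-descent pattern);
2. candidate-gene regions — coagulation-pathway genes previously
   implicated in venous thromboembolism;
3. nonsynonymous consequence — the change must alter the protein;
4. population rarity — reference minor allele frequency strictly below a
   threshold (default 2%, double the conventional 1% rare-variant cutoff
   so borderline-rare variants are kept);
5. deleteriousness — SIFT/PolyPhen categories are attached; by default
   this stage annotates without removing, an optional strict mode drops
   variants called benign/tolerated by both predictors.

Stages 2-5 are pure per-variant predicates and therefore commute; stage
order only affects the intermediate counts recorded in the
:class:`FilterTrace`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .io import AFTable, Annotation, AnnotationTable, GeneRegion, GenotypeMatrix, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FilterTrace",
    "Candidate",
    "CandidateSet",
    "CascadeConfig",
    "filter_shared_heterozygous",
    "filter_by_regions",
    "filter_nonsynonymous",
    "filter_rare",
    "classify_deleteriousness",
    "run_cascade",
]


@dataclass(frozen=True)
class StageRecord:
    name: str
    n_in: int
    n_out: int
    retained: tuple[str, ...]


@dataclass
class FilterTrace:
    """Ordered per-stage record of the cascade (the survivor counts)."""

    stages: list[StageRecord] = field(default_factory=list)

    def record(self, name: str, before: Sequence[VariantRecord], after: Sequence[VariantRecord]) -> None:
        if len(after) > len(before):
            raise ValueError(f"stage {name!r} produced more variants than it received")
        self.stages.append(
            StageRecord(name, len(before), len(after), tuple(v.key for v in after))
        )

    def counts(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.n_in, s.n_out) for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "n_in": s.n_in, "n_out": s.n_out, "retained": list(s.retained)}
                for s in self.stages
            ]
        }


@dataclass(frozen=True)
class Candidate:
    variant: VariantRecord
    annotation: Annotation | None
    af_missing: bool = False

    @property
    def deleterious(self) -> bool:
        """Flagged by at least one predictor (damaging / probably or possibly damaging)."""
        if self.annotation is None:
            return False
        return (
            self.annotation.sift_category == "damaging"
            or self.annotation.polyphen_category in ("probably_damaging", "possibly_damaging")
        )


@dataclass
class CandidateSet:
    candidates: list[Candidate] = field(default_factory=list)

    @property
    def keys(self) -> set[str]:
        return {c.variant.key for c in self.candidates}

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass(frozen=True)
class CascadeConfig:
    population: str = "AA"
    af_threshold: float = 0.02
    strict_deleterious: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.af_threshold < 1.0):
            raise ValueError(f"AF threshold must be in (0,1), got {self.af_threshold}")


# ---------------------------------------------------------------------------
# stages


def filter_shared_heterozygous(
    variants: Sequence[VariantRecord],
    genotypes: GenotypeMatrix,
    member_ids: Sequence[str],
) -> list[VariantRecord]:
    """Keep variants heterozygous (dosage exactly 1) in every listed member.

    A missing call in any member excludes the variant: sharing cannot be
    established.
    """
    if not member_ids:
        raise ValueError("member_ids must be non-empty")
    cols = [genotypes.sample_index(m) for m in member_ids]
    kept = []
    for i, v in enumerate(variants):
        if all(genotypes.calls[i, j] == 1 for j in cols):
            kept.append(v)
    return kept


def filter_by_regions(
    variants: Sequence[VariantRecord],
    regions: Sequence[GeneRegion],
) -> list[VariantRecord]:
    """Keep variants whose 1-based position falls in at least one region
    (BED half-open semantics, exact chromosome-label match)."""
    if not regions:
        raise ValueError("regions must be non-empty")
    return [
        v for v in variants
        if any(r.contains(v.chrom, v.pos) for r in regions)
    ]


def filter_nonsynonymous(
    variants: Sequence[VariantRecord],
    annotations: AnnotationTable,
) -> list[VariantRecord]:
    """Keep amino-acid-changing variants; unannotated variants are dropped
    with a warning."""
    kept = []
    for v in variants:
        ann = annotations.lookup(v.key)
        if ann is None:
            logger.warning("variant %s has no annotation row; excluded", v.key)
            continue
        if ann.consequence == "nonsynonymous":
            kept.append(v)
    return kept


def filter_rare(
    variants: Sequence[VariantRecord],
    af_table: AFTable,
    population: str,
    threshold: float = 0.02,
) -> tuple[list[VariantRecord], set[str]]:
    """Keep variants with reference AF strictly below ``threshold`` in the
    named population.

    A variant absent from the reference is retained and flagged: absence
    from a population panel is evidence of rarity, not of frequency.
    Returns (retained variants, keys of retained-but-unlooked-up variants).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    if population not in af_table.populations:
        raise ValueError(f"unknown population label: {population!r}")
    kept: list[VariantRecord] = []
    flagged: set[str] = set()
    for v in variants:
        af = af_table.lookup(v.key, population)
        if af is None:
            kept.append(v)
            flagged.add(v.key)
        elif af < threshold:
            kept.append(v)
    return kept, flagged


def classify_deleteriousness(
    candidates: Sequence[VariantRecord],
    annotations: AnnotationTable,
    strict: bool = False,
    af_flagged: set[str] | None = None,
) -> CandidateSet:
    """Attach SIFT/PolyPhen categories to the surviving candidates.

    By default this annotates without removing anything.  In ``strict``
    mode, variants called tolerated by SIFT *and* benign by PolyPhen are
    removed; variants with both predictions missing are retained with a
    warning (no evidence either way).
    """
    af_flagged = af_flagged or set()
    out = CandidateSet()
    for v in candidates:
        ann = annotations.lookup(v.key)
        if strict and ann is not None:
            sift, poly = ann.sift_category, ann.polyphen_category
            if sift == "missing" and poly == "missing":
                logger.warning("variant %s has no predictor calls; retained", v.key)
            elif (sift in ("tolerated", "missing")) and (poly in ("benign", "missing")):
                continue
        out.candidates.append(
            Candidate(variant=v, annotation=ann, af_missing=v.key in af_flagged)
        )
    return out


def run_cascade(
    dataset,
    config: CascadeConfig = CascadeConfig(),
    member_ids: Sequence[str] | None = None,
) -> tuple[CandidateSet, FilterTrace]:
    """Apply the full discovery cascade to a family dataset.

    ``dataset`` needs attributes ``variants``, ``genotypes``,
    ``candidate_regions``, ``annotations`` and ``af_table`` (as produced
    by :func:`vtescan.simulate.generate_family_exomes` or assembled from
    files).  Stage order: shared-het, regions, nonsynonymous, rare,
    deleteriousness.
    """
    members = list(member_ids) if member_ids is not None else list(dataset.genotypes.samples)
    trace = FilterTrace()

    current = list(dataset.variants)
    step = filter_shared_heterozygous(current, dataset.genotypes, members)
    trace.record("shared_heterozygous", current, step)
    current = step

    step = filter_by_regions(current, dataset.candidate_regions) if current else []
    trace.record("candidate_genes", current, step)
    current = step

    step = filter_nonsynonymous(current, dataset.annotations)
    trace.record("nonsynonymous", current, step)
    current = step

    if current:
        step, flagged = filter_rare(current, dataset.af_table, config.population, config.af_threshold)
    else:
        step, flagged = [], set()
    trace.record("rare_in_reference", current, step)
    current = step

    candidates = classify_deleteriousness(
        current, dataset.annotations, strict=config.strict_deleterious, af_flagged=flagged
    )
    trace.record("deleteriousness", current, [c.variant for c in candidates.candidates])
    return candidates, trace
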