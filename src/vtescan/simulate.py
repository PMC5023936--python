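"""Synthetic inputs with the statistical structure the analysis assumes.

Nothing here is derived from real genomes.  The generators plant one
causal rare nonsynonymous variant shared heterozygously by the affected
relatives among decoy variants engineered to fail at least one cascade
stage, and draw case/control/background cohorts whose carrier counts
match the configured frequencies in expectation.  All randomness flows
through a single :class:`numpy.random.Generator` seeded from the config,
so identical configs give identical datasets.

Default parameters encode the study conditions of the motivating
analysis: three affected family members; 306 cases versus 370 controls
with 15 and 4 expected heterozygote carriers respectively; a background
population of 2203 subjects with 48 carriers (reference minor allele
frequency 1.09%); an eight-gene coagulation-pathway candidate panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    AFTable,
    Annotation,
    AnnotationTable,
    GeneRegion,
    GenotypeMatrix,
    VariantRecord,
    write_af_table,
    write_annotation_table,
    write_covariates,
    write_regions_bed,
    write_vcf,
)

__all__ = [
    "CANDIDATE_GENE_PANEL",
    "SimulationConfig",
    "FamilyDataset",
    "CohortDataset",
    "generate_family_exomes",
    "generate_af_reference",
    "generate_case_control_cohort",
    "write_family_dataset",
    "write_cohort_dataset",
]

#: Coagulation-pathway candidate panel: synthetic intervals on the genes'
#: real chromosomes (coordinates are round-number stand-ins, not real
#: gene boundaries).
CANDIDATE_GENE_PANEL: tuple[GeneRegion, ...] = (
    GeneRegion("chr1", 169_480_000, 169_560_000, "F5"),
    GeneRegion("chr2", 128_175_000, 128_190_000, "PROC"),
    GeneRegion("chr3", 93_590_000, 93_700_000, "PROS1"),
    GeneRegion("chr11", 46_740_000, 46_765_000, "F2"),
    GeneRegion("chr1", 173_870_000, 173_890_000, "SERPINC1"),
    GeneRegion("chr21", 44_470_000, 44_500_000, "CBS"),
    GeneRegion("chr1", 207_104_000, 207_145_000, "C4BPA"),
    GeneRegion("chr1", 207_084_000, 207_104_000, "C4BPB"),
)

_OFF_PANEL_CHROMS = ("chr5", "chr7", "chr12", "chr17", "chr19")
_BASES = ("A", "C", "G", "T")

#: Number of decoy variants entering the family cascade.  The raw input
#: size of a real candidate-panel exome filter is not pinned down by the
#: study design, so this is a configurable order-of-magnitude choice.
DEFAULT_N_DECOYS = 60


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of the synthetic family/cohort/reference generators."""

    n_family_members: int = 3
    n_decoy_variants: int = DEFAULT_N_DECOYS
    candidate_regions: tuple[GeneRegion, ...] = CANDIDATE_GENE_PANEL
    causal_af_reference: float = 0.0109
    extra_truth_populations: Mapping[str, float] = field(default_factory=dict)
    reference_population: str = "AA"
    case_n: int = 306
    control_n: int = 370
    case_carrier_freq: float = 15 / 306
    control_carrier_freq: float = 4 / 370
    background_n: int = 2203
    background_carriers: int = 48
    hwe_genotypes: bool = False
    # warfarin/biovu subcohort splits (fractions of each arm)
    case_subcohort_fracs: Mapping[str, float] = field(
        default_factory=lambda: {"warfarin": 173 / 306, "biovu": 133 / 306}
    )
    control_subcohort_fracs: Mapping[str, float] = field(
        default_factory=lambda: {"warfarin": 134 / 370, "biovu": 236 / 370}
    )
    sex_female_prob: float = 0.5
    covariate_means_cases: Mapping[str, float] = field(
        default_factory=lambda: {"age": 48.0, "height": 167.0, "weight": 95.0}
    )
    covariate_means_controls: Mapping[str, float] = field(
        default_factory=lambda: {"age": 64.0, "height": 170.0, "weight": 86.0}
    )
    covariate_sds: Mapping[str, float] = field(
        default_factory=lambda: {"age": 12.0, "height": 9.0, "weight": 20.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_family_members", "n_decoy_variants", "case_n", "control_n",
                     "background_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("causal_af_reference", "case_carrier_freq", "control_carrier_freq",
                     "sex_female_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if not (0 <= self.background_carriers <= self.background_n):
            raise ValueError("background_carriers must lie in [0, background_n]")
        for pop, af in self.extra_truth_populations.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"AF for population {pop!r} out of [0,1]: {af}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class FamilyDataset:
    """Planted-truth family exome: variants, genotypes, annotations, AF table."""

    variants: list[VariantRecord]
    genotypes: GenotypeMatrix
    annotations: AnnotationTable
    af_table: AFTable
    candidate_regions: tuple[GeneRegion, ...]
    truth: str  # key of the planted causal variant


@dataclass
class CohortDataset:
    """Case-control cohort genotyped at the tested variant, with covariates."""

    variant: VariantRecord
    genotypes: np.ndarray  # dosage per subject, aligned with covariates rows
    covariates: pd.DataFrame  # subject_id, status, sex, age, height, weight, subcohort

    @property
    def case_calls(self) -> np.ndarray:
        return self.genotypes[(self.covariates["status"] == "case").to_numpy()]

    @property
    def control_calls(self) -> np.ndarray:
        return self.genotypes[(self.covariates["status"] == "control").to_numpy()]


# ---------------------------------------------------------------------------
# family generator

# decoy failure classes: each decoy is engineered to fail >= 1 stage
_DECOY_CLASSES = ("not_shared_het", "off_panel", "synonymous", "common")


def _random_position(rng: np.random.Generator, region: GeneRegion, used: set) -> tuple[str, int]:
    while True:
        pos = int(rng.integers(region.start + 1, region.end + 1))
        if (region.chrom, pos) not in used:
            used.add((region.chrom, pos))
            return region.chrom, pos


def _random_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return _BASES[ref], _BASES[alt]


def _offpanel_position(rng: np.random.Generator, used: set) -> tuple[str, int]:
    while True:
        chrom = _OFF_PANEL_CHROMS[int(rng.integers(len(_OFF_PANEL_CHROMS)))]
        pos = int(rng.integers(1_000_000, 50_000_000))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos


def _non_shared_het_calls(rng: np.random.Generator, n_members: int) -> np.ndarray:
    """A genotype vector over the members that is not all-heterozygous."""
    while True:
        calls = rng.choice([0, 1, 2, MISSING], size=n_members, p=[0.35, 0.35, 0.2, 0.1])
        if not np.all(calls == 1):
            return calls.astype(np.int8)


def generate_family_exomes(config: SimulationConfig) -> FamilyDataset:
    """Generate the affected-family exome with one planted causal variant.

    The truth variant is heterozygous in every member, sits in a
    candidate-panel gene, is nonsynonymous, and has reference AF
    ``config.causal_af_reference``; it passes the default cascade exactly
    when that AF is below the rarity threshold.  Decoys cover all four
    single-stage failure classes, so every stage removes something.
    """
    if config.n_decoy_variants < len(_DECOY_CLASSES):
        raise ValueError(
            f"n_decoy_variants must be >= {len(_DECOY_CLASSES)} to plant "
            "one decoy per failure class"
        )
    rng = np.random.default_rng(config.seed)
    n_mem = config.n_family_members
    samples = [f"subject{i + 1}" for i in range(n_mem)]
    used_pos: set = set()
    panel = config.candidate_regions
    pros1 = next((r for r in panel if r.gene == "PROS1"), panel[0])

    records: list[tuple[VariantRecord, np.ndarray, Annotation, float | None]] = []

    # planted causal variant
    chrom, pos = _random_position(rng, pros1, used_pos)
    ref, alt = _random_alleles(rng)
    truth_rec = VariantRecord(chrom, pos, "rs_causal", ref, alt)
    records.append(
        (
            truth_rec,
            np.ones(n_mem, dtype=np.int8),
            Annotation(pros1.gene, "nonsynonymous", "damaging", "possibly_damaging"),
            config.causal_af_reference,
        )
    )

    # decoys: first one of each class, the rest drawn uniformly over classes
    classes = list(_DECOY_CLASSES) + [
        _DECOY_CLASSES[int(rng.integers(len(_DECOY_CLASSES)))]
        for _ in range(config.n_decoy_variants - len(_DECOY_CLASSES))
    ]
    sift_choices = ("damaging", "tolerated", "missing")
    poly_choices = ("probably_damaging", "possibly_damaging", "benign", "missing")
    for i, cls in enumerate(classes):
        region = panel[int(rng.integers(len(panel)))]
        if cls == "off_panel":
            chrom, pos = _offpanel_position(rng, used_pos)
            gene = "intergenic"
        else:
            chrom, pos = _random_position(rng, region, used_pos)
            gene = region.gene
        ref, alt = _random_alleles(rng)
        calls = (
            _non_shared_het_calls(rng, n_mem)
            if cls == "not_shared_het"
            else np.ones(n_mem, dtype=np.int8)
        )
        consequence = "synonymous" if cls == "synonymous" else "nonsynonymous"
        af = (
            float(rng.uniform(0.02, 0.5))
            if cls == "common"
            else float(rng.uniform(0.0005, 0.015))
        )
        ann = Annotation(
            gene,
            consequence,
            sift_choices[int(rng.integers(3))],
            poly_choices[int(rng.integers(4))],
        )
        records.append((VariantRecord(chrom, pos, f"decoy{i:04d}", ref, alt), calls, ann, af))

    # sort by genomic coordinate for a tidy VCF
    records.sort(key=lambda r: (r[0].chrom, r[0].pos))
    variants = [r[0] for r in records]
    calls = np.vstack([r[1] for r in records])
    annotations = AnnotationTable()
    for rec, _, ann, _ in records:
        annotations.add(rec.key, ann)
    assigned = {rec.key: af for rec, _, _, af in records}
    af_table = generate_af_reference(
        config, variants, truth_rec.key, rng=rng, assigned_afs=assigned
    )
    return FamilyDataset(
        variants=variants,
        genotypes=GenotypeMatrix(samples, calls),
        annotations=annotations,
        af_table=af_table,
        candidate_regions=panel,
        truth=truth_rec.key,
    )


def generate_af_reference(
    config: SimulationConfig,
    variants: Sequence[VariantRecord],
    truth_key: str,
    rng: np.random.Generator | None = None,
    assigned_afs: Mapping[str, float] | None = None,
) -> AFTable:
    """Population AF reference: one row per variant per population label.

    The truth variant's AF in the reference population equals
    ``config.causal_af_reference`` exactly; in any configured extra
    population it takes the configured value.  Other variants use their
    ``assigned_afs`` entry in the reference population when provided
    (this is how the family generator pins each decoy's rarity class),
    and draw rare AFs otherwise.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    assigned_afs = assigned_afs or {}
    table = AFTable()
    pops = [config.reference_population] + list(config.extra_truth_populations)
    for v in variants:
        for pop in pops:
            if v.key == truth_key:
                af = (
                    config.causal_af_reference
                    if pop == config.reference_population
                    else float(config.extra_truth_populations[pop])
                )
            elif pop == config.reference_population and v.key in assigned_afs:
                af = float(assigned_afs[v.key])
            else:
                af = float(rng.uniform(0.0005, 0.015))
            table.add(v.key, pop, af)
    return table


# ---------------------------------------------------------------------------
# cohort generator


def _subcohort_labels(n: int, fracs: Mapping[str, float]) -> list[str]:
    names = list(fracs)
    counts = [int(round(n * fracs[name])) for name in names]
    counts[-1] = n - sum(counts[:-1])
    labels: list[str] = []
    for name, cnt in zip(names, counts):
        labels.extend([name] * cnt)
    return labels


def generate_case_control_cohort(config: SimulationConfig) -> CohortDataset:
    """Draw the case-control cohort genotyped at the tested variant.

    Carriers are heterozygotes drawn per subject as
    Bernoulli(carrier frequency); with ``hwe_genotypes`` the dosage is
    instead Binomial(2, q) under Hardy-Weinberg equilibrium, with allele
    frequency q = carrier_freq / 2 (the frequency the heterozygote
    parameterization implies).  Covariates: sex ~ Bernoulli, age, height
    and weight ~ normal with per-arm means.
    """
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from the family
    pros1 = next(
        (r for r in config.candidate_regions if r.gene == "PROS1"),
        config.candidate_regions[0],
    )
    pos = int(rng.integers(pros1.start + 1, pros1.end + 1))
    ref, alt = _random_alleles(rng)
    variant = VariantRecord(pros1.chrom, pos, "rs_tested", ref, alt)

    frames = []
    genos = []
    for status, n, freq, fracs, means in (
        ("case", config.case_n, config.case_carrier_freq,
         config.case_subcohort_fracs, config.covariate_means_cases),
        ("control", config.control_n, config.control_carrier_freq,
         config.control_subcohort_fracs, config.covariate_means_controls),
    ):
        if config.hwe_genotypes:
            g = rng.binomial(2, freq / 2.0, size=n)
        else:
            g = (rng.random(n) < freq).astype(int)
        genos.append(g.astype(np.int8))
        cols = {
            "subject_id": [f"{status}{i + 1:04d}" for i in range(n)],
            "status": status,
            "subcohort": _subcohort_labels(n, fracs),
            "sex": np.where(rng.random(n) < config.sex_female_prob, "F", "M"),
        }
        for cov, mean in means.items():
            cols[cov] = np.round(rng.normal(mean, config.covariate_sds[cov], size=n), 2)
        frames.append(pd.DataFrame(cols))
    covariates = pd.concat(frames, ignore_index=True)
    return CohortDataset(
        variant=variant,
        genotypes=np.concatenate(genos),
        covariates=covariates,
    )


# ---------------------------------------------------------------------------
# artifact writers


def write_family_dataset(ds: FamilyDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the family dataset as VCF + BED + TSV artifacts; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "family.vcf",
        "regions": outdir / "candidate_genes.bed",
        "annotations": outdir / "annotations.tsv",
        "af_table": outdir / "af_reference.tsv",
    }
    write_vcf(ds.variants, ds.genotypes, paths["vcf"])
    write_regions_bed(ds.candidate_regions, paths["regions"])
    write_annotation_table(ds.annotations, paths["annotations"])
    write_af_table(ds.af_table, paths["af_table"])
    return paths


def write_cohort_dataset(ds: CohortDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as one VCF over all subjects plus the covariate TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "covariates": outdir / "covariates.tsv",
    }
    samples = ds.covariates["subject_id"].tolist()
    matrix = GenotypeMatrix(samples, ds.genotypes[None, :])
    write_vcf([ds.variant], matrix, paths["vcf"])
    write_covariates(ds.covariates, paths["covariates"])
    return paths
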