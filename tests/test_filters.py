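"""Discovery-cascade stages: contracts, boundary semantics, commutativity."""

import itertools

import numpy as np
import pytest

from vtescan.filters import (
    CascadeConfig,
    classify_deleteriousness,
    filter_by_regions,
    filter_nonsynonymous,
    filter_rare,
    filter_shared_heterozygous,
    run_cascade,
)
from vtescan.io import (
    MISSING,
    AFTable,
    Annotation,
    AnnotationTable,
    GeneRegion,
    GenotypeMatrix,
    VariantRecord,
)
from vtescan.simulate import SimulationConfig, generate_family_exomes


def make_variant(i, chrom="chr3", pos=None):
    return VariantRecord(chrom, pos if pos is not None else i + 1, f"v{i}", "A", "G")


class TestSharedHeterozygous:
    def test_all_call_patterns_over_three_members(self):
        # exhaustively: only the (1,1,1) pattern survives
        patterns = list(itertools.product([0, 1, 2, MISSING], repeat=3))
        variants = [make_variant(i) for i in range(len(patterns))]
        mat = GenotypeMatrix(["m1", "m2", "m3"], np.array(patterns, dtype=np.int8))
        kept = filter_shared_heterozygous(variants, mat, ["m1", "m2", "m3"])
        expected = [variants[patterns.index((1, 1, 1))]]
        assert kept == expected

    def test_unknown_member_is_error(self):
        mat = GenotypeMatrix(["m1"], np.array([[1]], dtype=np.int8))
        with pytest.raises(KeyError, match="m2"):
            filter_shared_heterozygous([make_variant(0)], mat, ["m2"])

    def test_empty_member_list_is_error(self):
        mat = GenotypeMatrix(["m1"], np.array([[1]], dtype=np.int8))
        with pytest.raises(ValueError, match="non-empty"):
            filter_shared_heterozygous([make_variant(0)], mat, [])

    def test_subset_of_samples_considered(self):
        # variant het in m1/m2 but hom in m3 passes when only m1,m2 listed
        mat = GenotypeMatrix(["m1", "m2", "m3"], np.array([[1, 1, 2]], dtype=np.int8))
        assert len(filter_shared_heterozygous([make_variant(0)], mat, ["m1", "m2"])) == 1
        assert filter_shared_heterozygous([make_variant(0)], mat, ["m1", "m2", "m3"]) == []


class TestRegionFilter:
    def test_half_open_boundaries(self):
        region = [GeneRegion("chr3", 0, 10, "PROS1")]
        inside = make_variant(0, pos=10)
        outside = make_variant(1, pos=11)
        assert filter_by_regions([inside, outside], region) == [inside]

    def test_chromosome_labels_exact_match(self):
        region = [GeneRegion("chr3", 0, 100, "PROS1")]
        assert filter_by_regions([make_variant(0, chrom="3", pos=5)], region) == []

    def test_matches_quadratic_oracle(self, rng):
        chroms = ["chr1", "chr2", "chr3"]
        regions = [
            GeneRegion(chroms[int(rng.integers(3))], s, s + int(rng.integers(1, 50)), f"g{i}")
            for i, s in enumerate(rng.integers(0, 500, size=20))
        ]
        variants = [
            make_variant(i, chrom=chroms[int(rng.integers(3))], pos=int(p))
            for i, p in enumerate(rng.integers(1, 600, size=100))
        ]
        got = filter_by_regions(variants, regions)
        oracle = [
            v for v in variants
            if any(r.chrom == v.chrom and r.start + 1 <= v.pos <= r.end for r in regions)
        ]
        assert got == oracle

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            filter_by_regions([make_variant(0)], [])


class TestConsequenceFilter:
    def test_keeps_nonsynonymous_drops_rest(self, caplog):
        variants = [make_variant(i) for i in range(3)]
        ann = AnnotationTable()
        ann.add("v0", Annotation("PROS1", "nonsynonymous"))
        ann.add("v1", Annotation("PROS1", "synonymous"))
        # v2 unannotated
        with caplog.at_level("WARNING"):
            kept = filter_nonsynonymous(variants, ann)
        assert kept == [variants[0]]
        assert "v2" in caplog.text


class TestRarityFilter:
    def make_table(self, **afs):
        table = AFTable()
        for key, af in afs.items():
            table.add(key, "AA", af)
        return table

    def test_threshold_is_strict(self):
        variants = [make_variant(0), make_variant(1)]
        table = self.make_table(v0=0.0109, v1=0.02)
        kept, flagged = filter_rare(variants, table, "AA", 0.02)
        assert kept == [variants[0]] and not flagged

    def test_missing_af_retained_and_flagged(self):
        variants = [make_variant(0), make_variant(1)]
        table = self.make_table(v0=0.001)
        kept, flagged = filter_rare(variants, table, "AA")
        assert kept == variants and flagged == {"v1"}

    def test_unknown_population_is_error(self):
        with pytest.raises(ValueError, match="population"):
            filter_rare([make_variant(0)], self.make_table(v0=0.001), "EU")

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.5])
    def test_threshold_domain(self, threshold):
        with pytest.raises(ValueError, match="threshold"):
            filter_rare([make_variant(0)], self.make_table(v0=0.001), "AA", threshold)


class TestDeleteriousness:
    def make_ann(self, sift, poly):
        ann = AnnotationTable()
        ann.add("v0", Annotation("PROS1", "nonsynonymous", sift, poly))
        return ann

    def test_default_mode_annotates_without_removal(self):
        cs = classify_deleteriousness([make_variant(0)], self.make_ann("tolerated", "benign"))
        assert len(cs) == 1 and not cs.candidates[0].deleterious

    def test_damaging_variant_flagged(self):
        cs = classify_deleteriousness(
            [make_variant(0)], self.make_ann("damaging", "possibly_damaging")
        )
        assert cs.candidates[0].deleterious

    def test_strict_mode_removes_doubly_benign(self):
        cs = classify_deleteriousness(
            [make_variant(0)], self.make_ann("tolerated", "benign"), strict=True
        )
        assert len(cs) == 0

    def test_strict_mode_keeps_missing_predictions(self, caplog):
        with caplog.at_level("WARNING"):
            cs = classify_deleteriousness(
                [make_variant(0)], self.make_ann("missing", "missing"), strict=True
            )
        assert len(cs) == 1 and "v0" in caplog.text


def _random_dataset(rng, n_variants=50):
    """A dataset-like object with random per-variant stage attributes."""
    from dataclasses import dataclass, field

    regions = (GeneRegion("chr3", 0, 500, "PROS1"), GeneRegion("chr1", 100, 400, "F5"))
    variants, calls = [], []
    ann, af = AnnotationTable(), AFTable()
    positions = rng.choice(np.arange(1, 2000), size=n_variants, replace=False)
    for i, pos in enumerate(positions):
        chrom = ["chr1", "chr3", "chr9"][int(rng.integers(3))]
        variants.append(VariantRecord(chrom, int(pos), f"v{i}", "A", "G"))
        calls.append(rng.choice([0, 1, 2, MISSING], size=3, p=[0.2, 0.5, 0.2, 0.1]))
        ann.add(f"v{i}", Annotation(
            "PROS1",
            ["nonsynonymous", "synonymous"][int(rng.integers(2))],
            ["damaging", "tolerated", "missing"][int(rng.integers(3))],
            ["possibly_damaging", "benign", "missing"][int(rng.integers(3))],
        ))
        if rng.random() > 0.15:  # some variants stay absent from the reference
            af.add(f"v{i}", "AA", float(rng.uniform(0, 0.1)))

    @dataclass
    class DS:
        variants: list
        genotypes: GenotypeMatrix
        candidate_regions: tuple
        annotations: AnnotationTable
        af_table: AFTable

    return DS(variants, GenotypeMatrix(["m1", "m2", "m3"], np.array(calls, dtype=np.int8)),
              regions, ann, af)


class TestCascade:
    def test_monotone_and_trace_consistent(self, family):
        _, trace = run_cascade(family)
        for s in trace.stages:
            assert s.n_out <= s.n_in
            assert len(s.retained) == s.n_out

    def test_zero_variant_dataset(self, rng):
        ds = _random_dataset(rng, n_variants=5)
        ds.variants, ds.genotypes = [], GenotypeMatrix(["m1", "m2", "m3"],
                                                       np.empty((0, 3), dtype=np.int8))
        candidates, trace = run_cascade(ds)
        assert len(candidates) == 0
        assert all(s.n_in == 0 and s.n_out == 0 for s in trace.stages)

    def test_equals_single_pass_predicate_oracle(self, rng):
        ds = _random_dataset(rng)
        config = CascadeConfig(strict_deleterious=True)
        candidates, _ = run_cascade(ds, config)

        def passes(i, v):
            ann = ds.annotations.lookup(v.key)
            af = ds.af_table.lookup(v.key, "AA")
            sift = ann.sift_category
            poly = ann.polyphen_category
            strict_ok = (sift == "missing" and poly == "missing") or not (
                sift in ("tolerated", "missing") and poly in ("benign", "missing")
            )
            return (
                (ds.genotypes.calls[i] == 1).all()
                and any(r.contains(v.chrom, v.pos) for r in ds.candidate_regions)
                and ann.consequence == "nonsynonymous"
                and (af is None or af < 0.02)
                and strict_ok
            )

        oracle = {v.key for i, v in enumerate(ds.variants) if passes(i, v)}
        assert candidates.keys == oracle

    def test_stage_order_does_not_change_final_set(self, rng):
        # the five stages are pure per-variant predicates, so every ordering
        # of the cascade yields the same survivors
        ds = _random_dataset(rng)
        members = ["m1", "m2", "m3"]

        def s_het(vs):
            return filter_shared_heterozygous(vs, ds.genotypes_by_key, members)

        # rebuild a lookup-based genotype filter so subsets keep alignment
        key_to_row = {v.key: i for i, v in enumerate(ds.variants)}

        stages = {
            "het": lambda vs: [
                v for v in vs if (ds.genotypes.calls[key_to_row[v.key]] == 1).all()
            ],
            "region": lambda vs: filter_by_regions(vs, ds.candidate_regions) if vs else [],
            "nonsyn": lambda vs: filter_nonsynonymous(vs, ds.annotations),
            "rare": lambda vs: filter_rare(vs, ds.af_table, "AA")[0] if vs else [],
            "delet": lambda vs: [
                c.variant
                for c in classify_deleteriousness(vs, ds.annotations, strict=True).candidates
            ],
        }
        results = set()
        for order in itertools.permutations(stages):
            vs = list(ds.variants)
            for name in order:
                vs = stages[name](vs)
            results.add(frozenset(v.key for v in vs))
        assert len(results) == 1

    def test_strict_mode_can_only_shrink(self, family):
        default, _ = run_cascade(family, CascadeConfig(strict_deleterious=False))
        strict, _ = run_cascade(family, CascadeConfig(strict_deleterious=True))
        assert strict.keys <= default.keys
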