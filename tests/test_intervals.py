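import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_intervals
from oracles import brute_force_overlap_pairs
from serpeak.intervals import (
    GeneModel,
    GenomicInterval,
    RegionClass,
    assign_peak_to_gene,
    classify_genomic_location,
    enrichment_score,
    intersect_interval_sets,
    merge_intervals,
    overlap_peak_sets,
    overlaps_reciprocal,
    peak_overlaps_region,
    subtract_interval_sets,
    total_length,
)

iv = GenomicInterval


class TestGenomicInterval:
    def test_validation(self):
        with pytest.raises(ValueError):
            iv("chr1", 100, 100)
        with pytest.raises(ValueError):
            iv("chr1", -1, 5)
        with pytest.raises(ValueError):
            iv("", 0, 5)

    def test_overlap_length(self):
        assert iv("chr1", 0, 100).overlap_length(iv("chr1", 50, 150)) == 50
        assert iv("chr1", 0, 100).overlap_length(iv("chr2", 0, 100)) == 0
        assert iv("chr1", 0, 10).overlap_length(iv("chr1", 10, 20)) == 0


class TestReciprocalOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 100), (70, 170), True),  # overlap 30 = 30% of each
            ((0, 100), (90, 200), False),  # overlap 10 < 30
            ((0, 10), (0, 100), False),  # 10 >= 3 but 10 < 30: both sides required
            ((0, 100), (0, 100), True),
        ],
    )
    def test_rule(self, a, b, expected):
        assert overlaps_reciprocal(iv("chr1", *a), iv("chr1", *b)) is expected

    def test_different_chrom_false(self):
        assert not overlaps_reciprocal(iv("chr1", 0, 100), iv("chr2", 0, 100))

    def test_symmetric_on_random_pairs(self, rng):
        ivs = random_intervals(rng, 200)
        for a, b in zip(ivs[:100], ivs[100:]):
            assert overlaps_reciprocal(a, b) == overlaps_reciprocal(b, a)

    def test_one_sided_rule_is_not_symmetric(self):
        peak, region = iv("chr1", 0, 100), iv("chr1", 50, 5000)
        assert peak_overlaps_region(peak, region)
        assert not peak_overlaps_region(region, peak)


class TestPeakOverlapsRegion:
    @pytest.mark.parametrize(
        "peak,region,expected",
        [
            ((0, 100), (50, 5000), True),  # 50 >= 30
            ((0, 100), (80, 5000), False),  # 20 < 30
            ((200, 300), (0, 5000), True),  # fully inside
        ],
    )
    def test_rule(self, peak, region, expected):
        assert peak_overlaps_region(iv("chr1", *peak), iv("chr1", *region)) is expected


class TestOverlapPeakSets:
    def test_identity(self):
        res = overlap_peak_sets([iv("chr1", 0, 100)], [iv("chr1", 0, 100)])
        assert res.n_a_overlap == 1 and res.n_a_only == 0

    def test_disjoint_chromosomes(self):
        res = overlap_peak_sets([iv("chr1", 0, 100)], [iv("chr2", 0, 100)])
        assert res.n_a_overlap == 0 and res.n_b_overlap == 0
        assert res.n_a_only == 1 and res.n_b_only == 1

    def test_matches_brute_force_on_random_sets(self, rng):
        a = random_intervals(rng, 1000)
        b = random_intervals(rng, 1000)
        res = overlap_peak_sets(a, b)
        assert res.pairs == brute_force_overlap_pairs(a, b)

    def test_invariant_under_reordering(self, rng):
        a = random_intervals(rng, 100)
        b = random_intervals(rng, 100)
        res1 = overlap_peak_sets(a, b)
        perm = rng.permutation(len(a))
        res2 = overlap_peak_sets([a[i] for i in perm], b)
        assert res1.n_a_overlap == res2.n_a_overlap
        assert res1.n_b_only == res2.n_b_only


def make_gene(tss=10_000, strand="+", length=5_000, chrom="chr1", gene_id="g1"):
    tts = tss + length if strand == "+" else tss - length
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss, tts=tts)


class TestClassifyGenomicLocation:
    def test_promoter_upstream_plus_strand(self):
        gene = make_gene()
        assert classify_genomic_location("chr1", 9_500, [gene]) is RegionClass.PROMOTER

    def test_enhancer_window(self):
        gene = make_gene()
        assert (
            classify_genomic_location("chr1", 5_000, [gene])
            is RegionClass.PUTATIVE_ENHANCER
        )

    def test_far_summit_is_distal(self):
        gene = make_gene()
        assert (
            classify_genomic_location("chr1", 500_000, [gene])
            is RegionClass.DISTAL_INTERGENIC
        )

    def test_minus_strand_windows_mirror(self):
        # - strand gene: promoter covers [tss-500, tss+1000) genomically
        gene = make_gene(tss=50_000, strand="-")
        assert classify_genomic_location("chr1", 50_800, [gene]) is RegionClass.PROMOTER
        assert (
            classify_genomic_location("chr1", 55_000, [gene])
            is RegionClass.PUTATIVE_ENHANCER
        )

    def test_gene_body_and_tts(self):
        gene = make_gene(tss=10_000, length=5_000)
        assert classify_genomic_location("chr1", 12_000, [gene]) is RegionClass.GENE_BODY
        assert classify_genomic_location("chr1", 15_200, [gene]) is RegionClass.TTS

    def test_promoter_precedence_over_other_classes(self):
        # summit in g1's promoter and inside g2's gene body: promoter wins
        g1 = make_gene(tss=10_000, gene_id="g1")
        g2 = make_gene(tss=5_000, length=20_000, gene_id="g2")
        assert classify_genomic_location("chr1", 9_500, [g1, g2]) is RegionClass.PROMOTER

    def test_total_function_over_random_summits(self, rng):
        genes = [make_gene(tss=int(t)) for t in rng.integers(30_000, 300_000, 20)]
        labels = [
            classify_genomic_location("chr1", int(p), genes)
            for p in rng.integers(0, 400_000, 300)
        ]
        assert len(labels) == 300
        assert all(isinstance(l, RegionClass) for l in labels)

    def test_empty_gene_list_warns_distal(self):
        with pytest.warns(UserWarning):
            assert (
                classify_genomic_location("chr1", 100, [])
                is RegionClass.DISTAL_INTERGENIC
            )


class TestAssignPeakToGene:
    def test_fully_inside_promoter(self):
        gene = make_gene(tss=10_000)
        peak = iv("chr1", 9_700, 10_100)
        assert assign_peak_to_gene(peak, [gene]) == ["g1"]

    def test_insufficient_coverage(self):
        gene = make_gene(tss=10_000)
        # promoter is [9000, 10500); 200 of 1000 bp inside = 20% < 30%
        peak = iv("chr1", 10_300, 11_300)
        assert assign_peak_to_gene(peak, [gene]) == []

    def test_two_overlapping_promoters(self):
        g1 = make_gene(tss=10_000, gene_id="g1")
        g2 = make_gene(tss=10_200, gene_id="g2")
        peak = iv("chr1", 9_800, 10_200)
        assert assign_peak_to_gene(peak, [g1, g2]) == ["g1", "g2"]


class TestEnrichmentScore:
    def test_formula(self):
        assert enrichment_score(100, 50, 10) == pytest.approx(20.0)

    def test_zero_overlap(self):
        assert enrichment_score(10, 10, 0) == 0.0

    @given(
        n_a=st.integers(1, 10_000),
        n_b=st.integers(1, 10_000),
        frac=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, n_a, n_b, frac):
        k = int(frac * min(n_a, n_b))
        assert enrichment_score(n_a, n_b, k) == enrichment_score(n_b, n_a, k)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            enrichment_score(0, 10, 0)


class TestIntervalAlgebra:
    def test_merge_bookended(self):
        merged = merge_intervals([iv("chr1", 0, 100), iv("chr1", 100, 200)])
        assert merged == [iv("chr1", 0, 200)]

    def test_intersect_and_subtract_roundtrip(self, rng):
        a = random_intervals(rng, 300, chroms=("chr1",))
        b = random_intervals(rng, 300, chroms=("chr1",))
        inter = intersect_interval_sets(a, b)
        minus = subtract_interval_sets(a, b)
        # intersection and difference partition a's covered bases
        assert total_length(inter) + total_length(minus) == total_length(a)
        # subtraction output never touches b
        assert total_length(intersect_interval_sets(minus, b)) == 0
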