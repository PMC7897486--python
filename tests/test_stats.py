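import numpy as np
import pytest

from serpeak.intervals import GeneModel, GenomicInterval
from serpeak.io import BedRecord
from serpeak.stats import (
    boxplot_summary,
    cluster_order,
    cohens_d,
    correlation_matrix,
    expression_by_binding,
    make_genome_bins,
)

iv = GenomicInterval


class TestMakeGenomeBins:
    def test_no_exclusions(self):
        bins = make_genome_bins({"chr1": 10_000})
        assert len(bins.bins) == 10

    def test_blacklist_spanning_boundary_removes_both_tiles(self):
        bins = make_genome_bins({"chr1": 10_000}, blacklist=[iv("chr1", 900, 1_100)])
        starts = {b.start for b in bins.bins}
        assert 0 not in starts and 1_000 not in starts and len(bins.bins) == 8

    def test_mappability_boundary_excludes_at_0_2(self):
        low = [BedRecord(iv("chr1", 2_000, 2_500), value=0.2)]
        ok = [BedRecord(iv("chr1", 2_000, 2_500), value=0.21)]
        assert len(make_genome_bins({"chr1": 10_000}, mappability=low).bins) == 9
        assert len(make_genome_bins({"chr1": 10_000}, mappability=ok).bins) == 10

    def test_bins_never_intersect_excluded_regions(self, rng):
        blacklist = [iv("chr1", int(s), int(s) + 700) for s in rng.integers(0, 95_000, 20)]
        low = [BedRecord(iv("chr1", int(s), int(s) + 300), value=0.1) for s in rng.integers(0, 95_000, 20)]
        bins = make_genome_bins({"chr1": 100_000}, blacklist, low)
        for b in bins.bins:
            assert all(b.overlap_length(x) == 0 for x in blacklist)
            assert all(b.overlap_length(x.interval) == 0 for x in low)


def poisson_reads(rng, rate_per_kb, size=100_000, chrom="chr1"):
    n = rng.poisson(rate_per_kb * size / 1_000)
    starts = rng.integers(0, size - 100, n)
    return [iv(chrom, int(s), int(s) + 100) for s in starts]


class TestCorrelationMatrix:
    def test_self_and_duplicate_correlation_is_one(self, rng):
        reads = poisson_reads(rng, 5)
        bins = make_genome_bins({"chr1": 100_000})
        corr = correlation_matrix(
            {"a": reads, "b": list(reads)}, bins, {"chr1": 100_000}
        )
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_tracks_near_zero(self, rng):
        a = poisson_reads(rng, 5, size=10_000_000)
        b = poisson_reads(rng, 5, size=10_000_000)
        bins = make_genome_bins({"chr1": 10_000_000})
        corr = correlation_matrix({"a": a, "b": b}, bins, {"chr1": 10_000_000})
        assert abs(corr.loc["a", "b"]) < 0.05

    def test_symmetry_and_scale_invariance(self, rng):
        a = poisson_reads(rng, 5)
        b = poisson_reads(rng, 8)
        doubled = b + b  # duplicate every read: counts scale by 2
        bins = make_genome_bins({"chr1": 100_000})
        c1 = correlation_matrix({"a": a, "b": b}, bins, {"chr1": 100_000})
        c2 = correlation_matrix({"a": a, "b": doubled}, bins, {"chr1": 100_000})
        assert c1.loc["a", "b"] == pytest.approx(c1.loc["b", "a"])
        assert c1.loc["a", "b"] == pytest.approx(c2.loc["a", "b"])

    def test_zero_variance_sample_reported_missing(self, rng):
        a = poisson_reads(rng, 5)
        bins = make_genome_bins({"chr1": 100_000})
        corr = correlation_matrix({"a": a, "empty": []}, bins, {"chr1": 100_000})
        assert np.isnan(corr.loc["a", "empty"])


class TestClusterOrder:
    def test_identical_samples_become_siblings(self, rng):
        import pandas as pd

        r = np.array(
            [
                [1.0, 0.2, 0.95, 0.1],
                [0.2, 1.0, 0.2, 0.15],
                [0.95, 0.2, 1.0, 0.1],
                [0.1, 0.15, 0.1, 1.0],
            ]
        )
        corr = pd.DataFrame(r, index=list("abcd"), columns=list("abcd"))
        order = cluster_order(corr)
        assert abs(order.index("a") - order.index("c")) == 1

    def test_block_structure_groups_leaves(self):
        import pandas as pd

        block = np.full((4, 4), 0.1)
        block[:2, :2] = 0.9
        block[2:, 2:] = 0.9
        np.fill_diagonal(block, 1.0)
        corr = pd.DataFrame(block, index=list("wxyz"), columns=list("wxyz"))
        order = cluster_order(corr)
        assert {order.index("w"), order.index("x")} in ({0, 1}, {2, 3})

    def test_missing_entries_raise(self):
        import pandas as pd

        corr = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            cluster_order(corr)


class TestCohensD:
    def test_identical_samples(self, rng):
        x = rng.normal(size=50)
        es = cohens_d(x, x.copy())
        assert es.d == 0.0 and es.category == "no_difference"

    def test_unit_shift_is_large(self, rng):
        # sample with unit ddof-1 variance shifted by exactly one sd: d = 1
        x = np.array([1.0, 0.0, -1.0])
        es = cohens_d(x + 1.0, x)
        assert es.d == pytest.approx(1.0)
        assert es.category == "large"

    def test_matches_direct_formula(self, rng):
        x, y = rng.normal(2, 1.5, 37), rng.normal(1.2, 0.8, 53)
        es = cohens_d(x, y)
        nx, ny = len(x), len(y)
        pooled = np.sqrt(
            ((nx - 1) * x.std(ddof=1) ** 2 + (ny - 1) * y.std(ddof=1) ** 2)
            / (nx + ny - 2)
        )
        assert es.d == pytest.approx((x.mean() - y.mean()) / pooled, abs=1e-12)

    @pytest.mark.parametrize(
        "d,category",
        [(0.1, "no_difference"), (0.25, "small"), (0.5, "medium"), (1.0, "large")],
    )
    def test_categories(self, d, category, rng):
        x = np.array([1.0, 0.0, -1.0])  # unit pooled sd, so the shift is d
        es = cohens_d(x + d, x)
        assert es.d == pytest.approx(d)
        assert es.category == category

    def test_antisymmetry(self, rng):
        x, y = rng.normal(0, 1, 30), rng.normal(1, 2, 30)
        assert cohens_d(x, y).d == pytest.approx(-cohens_d(y, x).d)
        assert cohens_d(x, y).category == cohens_d(y, x).category

    def test_zero_pooled_sd_raises(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestBoxplotSummary:
    def test_constant_values(self):
        box = boxplot_summary([4.0] * 10)
        assert box.q1 == box.median == box.q3 == box.whisker_low == box.whisker_high == 4.0

    def test_one_to_nine(self):
        box = boxplot_summary(np.arange(1, 10))
        assert box.median == 5.0
        assert box.whisker_low == 1.0 and box.whisker_high == 9.0

    def test_far_outlier_excluded_from_whisker(self):
        values = list(np.arange(1, 10)) + [100.0]
        box = boxplot_summary(values)
        iqr = box.q3 - box.q1
        assert box.whisker_high <= box.q3 + 1.5 * iqr
        assert box.whisker_high < 100.0


class TestExpressionByBinding:
    def genes(self, expressions):
        return [
            GeneModel(f"g{i}", "chr1", "+", 10_000 + 50_000 * i, 20_000 + 50_000 * i, expression=e)
            for i, e in enumerate(expressions)
        ]

    def test_no_peaks_single_unbound_group(self):
        genes = self.genes([1.0, 2.0, 3.0])
        groups = expression_by_binding(genes, {"A": []})
        assert set(groups) == {"unbound"} and len(groups["unbound"]) == 3

    def test_partition_sums_to_gene_count(self):
        genes = self.genes([1.0, 2.0, 3.0, 4.0])
        peaks_a = [iv("chr1", 9_500, 9_900)]  # in g0's promoter
        peaks_b = [iv("chr1", 9_600, 9_950), iv("chr1", 59_500, 59_900)]  # g0 and g1
        groups = expression_by_binding(genes, {"A": peaks_a, "B": peaks_b})
        assert sum(len(v) for v in groups.values()) == 4
        assert set(groups) == {"A+B", "B", "unbound"}

    def test_planted_effect_orders_group_medians(self, rng):
        from serpeak.simulate import simulate_expression

        genes = self.genes([None] * 60)
        binding = {g.gene_id: ("cobound" if i < 20 else "single" if i < 40 else "unbound")
                   for i, g in enumerate(genes)}
        table = simulate_expression(
            genes,
            binding,
            effect={"cobound": 2.0, "single": 1.0, "unbound": 0.0},
            noise_sd=0.1,
            seed=5,
        )
        med = table.groupby("category")["expression"].median()
        assert med["cobound"] > med["single"] > med["unbound"]
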