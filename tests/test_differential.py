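import numpy as np
import pytest

from serpeak.coverage import Pileup
from serpeak.differential import (
    ScoredDataset,
    classify_subpeak,
    compare_datasets,
    height_in_other,
    presence_matrix,
    unique_score,
)
from serpeak.intervals import GenomicInterval
from serpeak.subpeaks import Subpeak


def sp(pos, height, width=200):
    return Subpeak(
        region=GenomicInterval("chr1", pos - width // 2, pos + width // 2),
        summit=pos,
        height_norm=height,
    )


def make_dataset(name, subpeaks, depth_at, total_mapped=10_000_000, size=50_000):
    """Dataset whose pileup has the given integer depths at given positions."""
    depth = np.zeros(size, dtype=np.int64)
    for pos, d in depth_at.items():
        depth[pos] = d
    return ScoredDataset(
        name=name,
        subpeaks=subpeaks,
        pileup=Pileup(depth={"chr1": depth}, total_mapped=total_mapped),
        total_mapped=total_mapped,
    )


class TestUniqueScore:
    @pytest.mark.parametrize(
        "h_a,h_b,expected",
        [
            (10, 2, 4.0),
            (5, 0.5, 4.5),  # denominator floored at 1
            (3, 3, 0.0),
            (0, 4, -1.0),
        ],
    )
    def test_formula(self, h_a, h_b, expected):
        assert unique_score(h_a, h_b) == pytest.approx(expected)

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            unique_score(-1, 0)


class TestHeightInOther:
    def test_zero_depth(self):
        b = make_dataset("B", [], {})
        assert height_in_other(sp(1_000, 5.0), b.pileup, b.total_mapped) == 0.0

    def test_normalization(self):
        # depth 3 at the summit, library 1.5e7 -> height 2.0
        b = make_dataset("B", [], {1_000: 3}, total_mapped=15_000_000)
        assert height_in_other(sp(1_000, 5.0), b.pileup, b.total_mapped) == pytest.approx(2.0)

    def test_missing_chromosome_warns_zero(self):
        b = make_dataset("B", [], {})
        probe = Subpeak(region=GenomicInterval("chrX", 0, 100), summit=50, height_norm=1.0)
        with pytest.warns(UserWarning):
            assert height_in_other(probe, b.pileup, b.total_mapped) == 0.0


class TestClassificationTruthTable:
    """Constructed fixture covering every branch of the unique/shared rules.

    Dataset B uses total_mapped 2e7, so a pileup depth of d corresponds to a
    normalized height of d/2; every expected label below is hand-derived
    from the rules: unique iff score > 2 (strict) and no B summit within
    100 bp (<= 100 counts as within); shared iff a B summit is within 100 bp
    and the matched summit heights differ by < 1 (strict).
    """

    # (A summit, height_A, B depth at summit, B summit offset or None,
    #  B subpeak height, expected label, reason)
    CASES = [
        (1_000, 10.0, 4, None, None, "unique", "score (10-2)/2=4 > 2, no B summit"),
        (4_000, 5.0, 1, None, None, "unique", "floor: (5-0.5)/max(0.5,1)=4.5 > 2"),
        (8_000, 6.0, 8, None, None, "ambiguous", "score (6-4)/4=0.5, no B summit"),
        (12_000, 6.0, 4, None, None, "ambiguous", "score exactly 2, not > 2"),
        (16_000, 4.0, 6, 40, 3.5, "shared", "|4-3.5| < 1 within 40 bp"),
        (20_000, 4.0, 5, 40, 2.5, "ambiguous", "score 0.6, |4-2.5| >= 1"),
        (24_000, 3.0, 4, 100, 2.8, "shared", "100 bp counts as within"),
        (28_000, 10.0, 2, 101, 9.5, "unique", "101 bp is outside; score 9 > 2"),
        (32_000, 3.0, 4, 50, 2.0, "ambiguous", "|3-2| not < 1 (strict)"),
    ]

    @pytest.mark.parametrize(
        "a_pos,h_a,b_depth,b_offset,b_height,expected,reason",
        CASES,
        ids=[c[6] for c in CASES],
    )
    def test_branch(self, a_pos, h_a, b_depth, b_offset, b_height, expected, reason):
        b_subpeaks = []
        if b_offset is not None:
            b_subpeaks.append(sp(a_pos + b_offset, b_height))
        b = make_dataset("B", b_subpeaks, {a_pos: b_depth}, total_mapped=20_000_000)
        result = classify_subpeak(sp(a_pos, h_a), b)
        assert result.label == expected, reason

    def test_whole_fixture_at_once(self):
        """All branches classified together (summits interact only locally)."""
        a_subpeaks = [sp(c[0], c[1]) for c in self.CASES]
        b_subpeaks = [
            sp(c[0] + c[3], c[4]) for c in self.CASES if c[3] is not None
        ]
        depth_at = {c[0]: c[2] for c in self.CASES}
        b = make_dataset("B", b_subpeaks, depth_at, total_mapped=20_000_000)
        labels = [classify_subpeak(s, b).label for s in a_subpeaks]
        assert labels == [c[5] for c in self.CASES]


class TestCompareDatasets:
    def test_identical_datasets_all_shared(self):
        peaks = [sp(1_000, 5.0), sp(3_000, 8.0)]
        a = make_dataset("A", peaks, {1_000: 5, 3_000: 8})
        b = make_dataset("B", list(peaks), {1_000: 5, 3_000: 8})
        result = compare_datasets(a, b)
        assert result.counts["shared"] == 2
        assert result.counts["unique_a"] == result.counts["unique_b"] == 0
        assert result.shared_pairs == [(0, 0), (1, 1)]

    def test_different_chromosomes_all_unique(self):
        a = make_dataset("A", [sp(1_000, 50.0)], {1_000: 50})
        b_peak = Subpeak(
            region=GenomicInterval("chr2", 900, 1_100), summit=1_000, height_norm=40.0
        )
        b = ScoredDataset(
            name="B",
            subpeaks=[b_peak],
            pileup=Pileup(
                depth={"chr2": np.zeros(50_000, dtype=np.int64)}, total_mapped=10_000_000
            ),
            total_mapped=10_000_000,
        )
        with pytest.warns(UserWarning):  # chromosomes missing from either pileup
            result = compare_datasets(a, b)
        assert result.counts["unique_a"] == 1 and result.counts["unique_b"] == 1

    def test_unique_rule_is_antisymmetric(self):
        # a B summit within 100 bp of an A summit forbids unique on both sides
        a = make_dataset("A", [sp(1_000, 50.0)], {1_000: 50, 1_050: 10})
        b = make_dataset("B", [sp(1_050, 10.0)], {1_000: 10, 1_050: 10})
        result = compare_datasets(a, b)
        assert result.counts["unique_a"] == 0 and result.counts["unique_b"] == 0

    def test_labels_invariant_under_equal_library_scaling(self):
        # duplicating every read k times and scaling total_mapped by k leaves
        # all normalized heights, hence all labels, unchanged
        a = make_dataset("A", [sp(1_000, 10.0), sp(5_000, 4.0)], {1_000: 10, 5_000: 4})
        b = make_dataset("B", [sp(5_040, 3.5)], {1_000: 2, 5_000: 7})
        base = compare_datasets(a, b)
        k = 3
        a2 = make_dataset(
            "A",
            list(a.subpeaks),
            {1_000: 10 * k, 5_000: 4 * k},
            total_mapped=10_000_000 * k,
        )
        b2 = make_dataset(
            "B",
            list(b.subpeaks),
            {1_000: 2 * k, 5_000: 7 * k},
            total_mapped=10_000_000 * k,
        )
        scaled = compare_datasets(a2, b2)
        assert [c.label for c in base.classified_a] == [
            c.label for c in scaled.classified_a
        ]
        assert base.counts == scaled.counts


class TestPresenceMatrix:
    def test_threshold_boundary_and_conservation(self):
        peaks = [sp(1_000, 5.0), sp(3_000, 5.0)]
        ds = {
            # depth 2 at 10M reads -> height exactly 2.0: present
            "ESC": (Pileup(depth={"chr1": _depth({1_000: 2})}, total_mapped=10_000_000), 10_000_000),
            "NPC": (Pileup(depth={"chr1": _depth({3_000: 1})}, total_mapped=10_000_000), 10_000_000),
        }
        m = presence_matrix(peaks, ds)
        assert bool(m.loc[0, "ESC"]) is True  # boundary: height 2.0 counts
        assert bool(m.loc[1, "ESC"]) is False
        assert bool(m.loc[1, "NPC"]) is False  # height 1.0 < 2
        # Venn-region totals partition the subpeaks
        patterns = m.apply(lambda row: tuple(row), axis=1).value_counts()
        assert patterns.sum() == len(peaks)

    def test_requires_two_cell_types(self):
        with pytest.raises(ValueError):
            presence_matrix([sp(1_000, 5.0)], {"only": (Pileup(depth={}, total_mapped=1), 1)})


def _depth(depth_at, size=50_000):
    d = np.zeros(size, dtype=np.int64)
    for pos, v in depth_at.items():
        d[pos] = v
    return d
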