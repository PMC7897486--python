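"""Genomic interval arithmetic, overlap conventions and summit annotation.

All coordinates are 0-based half-open (BED convention). Two overlap rules are
used throughout the pipeline:

* **reciprocal 30%** — two peaks overlap if the shared span covers at least
  30% of *each* peak's length; used for peak-set comparisons.
* **one-sided 30%** — a peak overlaps a (typically much larger) annotation
  segment if the shared span covers at least 30% of the *peak's* length; used
  for chromatin-state assignment.

Summits are annotated against gene models with strand-aware windows:
promoter [-1 kb, +0.5 kb] and putative enhancer [-20 kb, -1 kb] relative to
the TSS, TTS window [-0.5 kb, +1 kb] relative to the TTS, and gene body
[TSS + 0.5 kb, TTS - 0.5 kb]; everything else is distal intergenic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "RegionClass",
    "PeakSetOverlap",
    "overlaps_reciprocal",
    "peak_overlaps_region",
    "overlap_peak_sets",
    "classify_genomic_location",
    "assign_peak_to_gene",
    "enrichment_score",
    "merge_intervals",
    "intersect_interval_sets",
    "subtract_interval_sets",
    "total_length",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Length of the shared span; 0 for different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end)


class RegionClass(str, Enum):
    """Five-way genomic location classes for a peak summit."""

    PROMOTER = "promoter"
    PUTATIVE_ENHANCER = "putative_enhancer"
    TTS = "tts"
    GENE_BODY = "gene_body"
    DISTAL_INTERGENIC = "distal_intergenic"


@dataclass(frozen=True)
class GeneModel:
    """One gene (or transcript) record with TSS/TTS as genomic positions.

    ``tss`` and ``tts`` are stored as genomic coordinates; orientation is
    carried by ``strand``, so on the minus strand ``tss > tts``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    expression: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"{self.gene_id}: + strand gene requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"{self.gene_id}: - strand gene requires tss > tts")
        if self.expression is not None and self.expression < 0:
            raise ValueError(f"{self.gene_id}: expression must be non-negative")


# offsets in bp, expressed along the direction of transcription
_PROMOTER_UP, _PROMOTER_DOWN = 1_000, 500
_ENHANCER_UP, _ENHANCER_DOWN = 20_000, 1_000
_TTS_UP, _TTS_DOWN = 500, 1_000
_BODY_MARGIN = 500


def _window(anchor: int, strand: str, up: int, down: int) -> tuple[int, int]:
    # strand-aware [-up, +down) window around an anchor, in genomic coords
    if strand == "+":
        lo, hi = anchor - up, anchor + down
    else:
        lo, hi = anchor - down, anchor + up
    return max(0, lo), hi


def promoter_window(gene: GeneModel) -> GenomicInterval:
    lo, hi = _window(gene.tss, gene.strand, _PROMOTER_UP, _PROMOTER_DOWN)
    return GenomicInterval(gene.chrom, lo, hi)


def enhancer_window(gene: GeneModel) -> GenomicInterval:
    if gene.strand == "+":
        lo, hi = gene.tss - _ENHANCER_UP, gene.tss - _ENHANCER_DOWN
    else:
        lo, hi = gene.tss + _ENHANCER_DOWN, gene.tss + _ENHANCER_UP
    return GenomicInterval(gene.chrom, max(0, lo), hi)


def tts_window(gene: GeneModel) -> GenomicInterval:
    lo, hi = _window(gene.tts, gene.strand, _TTS_UP, _TTS_DOWN)
    return GenomicInterval(gene.chrom, lo, hi)


def gene_body_window(gene: GeneModel) -> Optional[GenomicInterval]:
    """Gene body minus 500 bp margins at both ends; None for short genes."""
    if gene.strand == "+":
        lo, hi = gene.tss + _BODY_MARGIN, gene.tts - _BODY_MARGIN
    else:
        lo, hi = gene.tts + _BODY_MARGIN, gene.tss - _BODY_MARGIN
    if lo >= hi:
        return None
    return GenomicInterval(gene.chrom, max(0, lo), hi)


def overlaps_reciprocal(a: GenomicInterval, b: GenomicInterval, frac: float = 0.3) -> bool:
    """True iff the overlap covers >= ``frac`` of the length of *each* interval."""
    ov = a.overlap_length(b)
    return ov >= frac * a.length and ov >= frac * b.length


def peak_overlaps_region(peak: GenomicInterval, region: GenomicInterval, frac: float = 0.3) -> bool:
    """One-sided rule: overlap covers >= ``frac`` of the *peak's* length."""
    return peak.overlap_length(region) >= frac * peak.length


@dataclass
class PeakSetOverlap:
    """Result of a reciprocal-overlap comparison of two peak sets."""

    n_a: int
    n_b: int
    pairs: list = field(default_factory=list)  # (index in A, index in B)
    a_hit: frozenset = frozenset()
    b_hit: frozenset = frozenset()

    @property
    def n_a_overlap(self) -> int:
        return len(self.a_hit)

    @property
    def n_b_overlap(self) -> int:
        return len(self.b_hit)

    @property
    def n_a_only(self) -> int:
        return self.n_a - len(self.a_hit)

    @property
    def n_b_only(self) -> int:
        return self.n_b - len(self.b_hit)


def overlap_peak_sets(
    peaks_a: Sequence[GenomicInterval],
    peaks_b: Sequence[GenomicInterval],
    frac: float = 0.3,
) -> PeakSetOverlap:
    """All reciprocal-``frac`` overlapping pairs between two peak sets.

    A peak counts as overlapping if at least one peak on the other side
    satisfies the reciprocal rule. Order of the inputs within each set does
    not affect the counts.
    """
    trees: dict[str, IntervalTree] = {}
    for j, b in enumerate(peaks_b):
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, j)
    pairs = []
    for i, a in enumerate(peaks_a):
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(a.start, a.end):
            j = hit.data
            if overlaps_reciprocal(a, peaks_b[j], frac):
                pairs.append((i, j))
    pairs.sort()
    return PeakSetOverlap(
        n_a=len(peaks_a),
        n_b=len(peaks_b),
        pairs=pairs,
        a_hit=frozenset(i for i, _ in pairs),
        b_hit=frozenset(j for _, j in pairs),
    )


def classify_genomic_location(
    chrom: str, summit: int, genes: Sequence[GeneModel]
) -> RegionClass:
    """Assign a summit to one of the five genomic region classes.

    When the summit falls inside windows of several genes or classes the more
    proximal class wins: promoter > TTS > gene body > putative enhancer >
    distal intergenic.
    """
    if not genes:
        warnings.warn("empty gene list: all summits classified distal_intergenic")
        return RegionClass.DISTAL_INTERGENIC
    in_tts = in_body = in_enh = False
    for g in genes:
        if g.chrom != chrom:
            continue
        if promoter_window(g).contains(summit):
            return RegionClass.PROMOTER
        if not in_tts and tts_window(g).contains(summit):
            in_tts = True
        if not in_body:
            body = gene_body_window(g)
            if body is not None and body.contains(summit):
                in_body = True
        if not in_enh and enhancer_window(g).contains(summit):
            in_enh = True
    if in_tts:
        return RegionClass.TTS
    if in_body:
        return RegionClass.GENE_BODY
    if in_enh:
        return RegionClass.PUTATIVE_ENHANCER
    return RegionClass.DISTAL_INTERGENIC


def assign_peak_to_gene(
    peak: GenomicInterval, genes: Sequence[GeneModel], frac: float = 0.3
) -> list[str]:
    """Gene ids whose promoter window covers >= ``frac`` of the peak length."""
    out = []
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        if peak.overlap_length(promoter_window(g)) >= frac * peak.length:
            out.append(g.gene_id)
    return out


def enrichment_score(n_a: int, n_b: int, n_overlap: int) -> float:
    """Overlap enrichment ``n_overlap / (n_a * n_b) * 10_000``.

    The x10 000 rescaling keeps the score on a readable magnitude; the score
    is symmetric in the two peak sets.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("enrichment_score undefined for empty peak sets")
    if not (0 <= n_overlap <= min(n_a, n_b)):
        raise ValueError("n_overlap must lie in [0, min(n_a, n_b)]")
    return n_overlap / (n_a * n_b) * 10_000.0


# ---------------------------------------------------------------------------
# interval-set algebra (sorted-sweep; inputs need not be sorted)

def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    groups: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        groups.setdefault(iv.chrom, []).append(iv)
    for ivs in groups.values():
        ivs.sort(key=lambda x: (x.start, x.end))
    return groups


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge overlapping or near-adjacent intervals (within ``gap`` bp).

    ``gap=0`` merges book-ended intervals ([0,100) + [100,200) -> [0,200)).
    """
    out: list[GenomicInterval] = []
    groups = _by_chrom(intervals)
    for chrom in sorted(groups):
        cur_s = cur_e = None
        for iv in groups[chrom]:
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start <= cur_e + gap:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def intersect_interval_sets(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-level intersection of two interval sets, as maximal intervals."""
    a_m, b_m = merge_intervals(a), merge_intervals(b)
    ga, gb = _by_chrom(a_m), _by_chrom(b_m)
    out: list[GenomicInterval] = []
    for chrom in sorted(set(ga) & set(gb)):
        xs, ys = ga[chrom], gb[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return out


def subtract_interval_sets(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases of ``a`` not covered by ``b``, as maximal intervals."""
    a_m, b_m = merge_intervals(a), merge_intervals(b)
    gb = _by_chrom(b_m)
    out: list[GenomicInterval] = []
    for iv in a_m:
        cuts = gb.get(iv.chrom, [])
        pos = iv.start
        for c in cuts:
            if c.end <= pos or c.start >= iv.end:
                continue
            if c.start > pos:
                out.append(GenomicInterval(iv.chrom, pos, c.start))
            pos = max(pos, c.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    out.sort(key=GenomicInterval.sort_key)
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered (intervals merged first)."""
    return sum(iv.length for iv in merge_intervals(intervals))
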