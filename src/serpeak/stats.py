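"""Genome-binned sample correlation, effect sizes and summary statistics.

The correlation convention: tile the genome with non-overlapping 1 kb bins,
drop every bin touching a blacklist interval or a low-mappability
(score <= 0.2) region, count reads per surviving bin for each sample and
compute pairwise Pearson correlations of the raw counts. Effect sizes use
Cohen's d with the pooled standard deviation and the conventional verbal
categories; boxplot summaries use linearly interpolated quartiles and
1.5 x IQR whiskers clamped to observed data points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .coverage import WindowGrid, count_reads_in_windows
from .intervals import GeneModel, GenomicInterval, assign_peak_to_gene, merge_intervals

__all__ = [
    "GenomeBins",
    "EffectSize",
    "BoxplotSummary",
    "make_genome_bins",
    "correlation_matrix",
    "cluster_order",
    "cohens_d",
    "boxplot_summary",
    "expression_by_binding",
]

MAPPABILITY_MAX_EXCLUDED = 0.2
DEFAULT_BIN_SIZE = 1_000


@dataclass
class GenomeBins:
    """Kept 1 kb tiles after blacklist / low-mappability exclusion."""

    bin_size: int
    bins: List[GenomicInterval]


def make_genome_bins(
    chrom_sizes: Dict[str, int],
    blacklist: Sequence[GenomicInterval] = (),
    mappability: Sequence = (),
    bin_size: int = DEFAULT_BIN_SIZE,
) -> GenomeBins:
    """Tile each chromosome with ``bin_size`` windows and drop excluded tiles.

    ``mappability`` is a sequence of bedGraph-like records (interval +
    ``value``); stretches with value <= 0.2 are excluded. A tile is dropped
    if it overlaps any excluded region by at least one base. Positions with
    no mappability record are treated as fully mappable. Only full-size
    tiles are produced (a trailing partial tile is ignored).
    """
    low_map = [
        GenomicInterval(r.chrom, r.start, r.end)
        for r in mappability
        if getattr(r, "value", None) is not None and r.value <= MAPPABILITY_MAX_EXCLUDED
    ]
    excluded = merge_intervals(list(blacklist) + low_map)
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in excluded:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    bins: List[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        bad = by_chrom.get(chrom, [])
        for start in range(0, chrom_sizes[chrom] - bin_size + 1, bin_size):
            tile = GenomicInterval(chrom, start, start + bin_size)
            if not any(tile.overlap_length(b) > 0 for b in bad):
                bins.append(tile)
    return GenomeBins(bin_size=bin_size, bins=bins)


def _counts_in_bins(reads, bins: Sequence[GenomicInterval], chrom_sizes) -> np.ndarray:
    """Per-bin read counts (any-overlap counting) via the window counter."""
    grid = WindowGrid(chrom_sizes, bin_size=bins[0].length, phase=0)
    track = count_reads_in_windows(reads, grid)
    out = np.empty(len(bins), dtype=np.int64)
    for k, b in enumerate(bins):
        out[k] = track.counts[b.chrom][b.start // grid.bin_size]
    return out


def correlation_matrix(
    samples: Dict[str, Iterable], bins: GenomeBins, chrom_sizes: Dict[str, int]
) -> pd.DataFrame:
    """Pairwise Pearson correlation of raw per-bin read counts.

    Symmetric with unit diagonal; pairs involving a zero-variance sample are
    reported as NaN.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if not bins.bins:
        raise ValueError("no genome bins to correlate over")
    names = list(samples)
    counts = np.vstack(
        [_counts_in_bins(samples[n], bins.bins, chrom_sizes) for n in names]
    ).astype(np.float64)
    sd = counts.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(counts)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def cluster_order(corr: pd.DataFrame) -> List[str]:
    """Leaf order of average-linkage clustering on distance 1 - r."""
    if corr.isna().any().any():
        raise ValueError("correlation matrix contains missing entries")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = average(squareform(dist, checks=False))
    return [corr.index[i] for i in leaves_list(linkage)]


_CATEGORY_EDGES = [(0.2, "no_difference"), (0.3, "small"), (0.8, "medium")]


@dataclass(frozen=True)
class EffectSize:
    d: float
    category: str


def cohens_d(x: Sequence[float], y: Sequence[float]) -> EffectSize:
    """Cohen's d with the pooled standard deviation, plus its verbal category.

    d = (mean(x) - mean(y)) / s_pooled with
    s_pooled^2 = ((n_x - 1) s_x^2 + (n_y - 1) s_y^2) / (n_x + n_y - 2).
    Categories by |d|: [0, 0.2) no difference, [0.2, 0.3) small,
    [0.3, 0.8) medium, [0.8, inf) large.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("cohens_d needs at least two values per sample")
    nx, ny = len(x), len(y)
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var <= 0:
        raise ValueError("pooled standard deviation is zero")
    d = float((x.mean() - y.mean()) / np.sqrt(pooled_var))
    category = "large"
    for edge, name in _CATEGORY_EDGES:
        if abs(d) < edge:
            category = name
            break
    return EffectSize(d=d, category=category)


@dataclass(frozen=True)
class BoxplotSummary:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    """Quartiles (linear interpolation) and 1.5 x IQR whiskers.

    Whiskers extend to the most extreme data points lying within
    ``[q1 - 1.5 IQR, q3 + 1.5 IQR]``.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("boxplot_summary needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotSummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
    )


def expression_by_binding(
    genes: Sequence[GeneModel],
    peak_sets: Dict[str, Sequence[GenomicInterval]],
    frac: float = 0.3,
) -> Dict[str, np.ndarray]:
    """Partition gene expression values by which peak sets bind the promoter.

    A peak set binds a gene when at least one of its peaks is promoter-
    assigned to that gene (promoter window covers >= ``frac`` of the peak).
    Group names are '+'-joined sorted set names (e.g. ``"A+B"``); genes hit
    by no set fall into ``"unbound"``. Genes without an expression value are
    skipped. The groups partition the genes, so group sizes sum to the
    number of expressed genes.
    """
    bound: Dict[str, set] = {g.gene_id: set() for g in genes}
    for name, peaks in peak_sets.items():
        for peak in peaks:
            for gid in assign_peak_to_gene(peak, genes, frac):
                bound[gid].add(name)
    groups: Dict[str, List[float]] = {}
    for g in genes:
        if g.expression is None:
            continue
        label = "+".join(sorted(bound[g.gene_id])) or "unbound"
        groups.setdefault(label, []).append(g.expression)
    return {k: np.asarray(v) for k, v in groups.items()}
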