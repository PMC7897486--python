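"""Subpeak decomposition of signal-enriched regions.

An SER frequently covers several binding events. The profile over the SER is
smoothed with a short moving average, local maxima become candidate summits,
and two adjacent candidates are split into separate subpeaks when the valley
between them drops below ``valley_frac`` times the lower of the two maxima
(a scale-free ratio rule). Each subpeak is scored by the raw read depth at
its summit, normalized to reads per 10 million mapped reads, and subpeaks
with normalized height below 2 are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Sequence

import numpy as np

from .coverage import Pileup, normalize_per_10M
from .intervals import GenomicInterval
from .sercall import SER

__all__ = [
    "Subpeak",
    "smooth_profile",
    "split_subpeaks",
    "score_subpeaks",
    "filter_subpeaks",
]

DEFAULT_VALLEY_FRAC = 0.5
DEFAULT_SMOOTH_WINDOW = 51
DEFAULT_MIN_WIDTH = 50
DEFAULT_MIN_HEIGHT = 2.0


@dataclass(frozen=True)
class Subpeak:
    """A subdivision of an SER with its summit and normalized summit height."""

    region: GenomicInterval
    summit: int
    height_norm: float = 0.0

    def __post_init__(self) -> None:
        if not self.region.contains(self.summit):
            raise ValueError("summit must lie inside the subpeak region")


def smooth_profile(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    values = np.asarray(values, dtype=np.float64)
    if window == 1 or len(values) == 0:
        return values.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _local_maxima(s: np.ndarray) -> List[int]:
    """Leftmost indices of local-maximum plateaus (endpoints included)."""
    n = len(s)
    maxima: List[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        left_ok = i == 0 or s[i - 1] < s[i]
        right_ok = j == n - 1 or s[j + 1] < s[i]
        if left_ok and right_ok and s[i] > 0:
            maxima.append(i)
        i = j + 1
    return maxima


def split_subpeaks(
    ser: SER,
    pileup: Pileup,
    valley_frac: float = DEFAULT_VALLEY_FRAC,
    min_width: int = DEFAULT_MIN_WIDTH,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> List[Subpeak]:
    """Split one SER into subpeaks at sufficiently deep valleys.

    Two adjacent candidate summits separate iff the minimum of the smoothed
    profile between them is below ``valley_frac`` times the lower of the two
    smoothed maxima; the boundary sits at the leftmost base of the minimal
    run. Subpeaks narrower than ``min_width`` are merged into their taller
    neighbour. Summits are the leftmost base of maximal *unsmoothed* depth
    within each subpeak. Heights are not set here (see
    :func:`score_subpeaks`).
    """
    if not (0.0 < valley_frac < 1.0):
        raise ValueError("valley_frac must be in (0, 1)")
    region = ser.region
    raw = np.asarray(
        pileup.segment(region.chrom, region.start, region.end), dtype=np.float64
    )
    if raw.max(initial=0.0) <= 0:
        warnings.warn(f"flat-zero SER at {region.chrom}:{region.start}-{region.end}")
        return [Subpeak(region=region, summit=region.start)]
    s = smooth_profile(raw, smooth_window)
    candidates = _local_maxima(s)
    if len(candidates) <= 1:
        summit = region.start + int(np.argmax(raw))
        return [Subpeak(region=region, summit=summit)]

    # decide a split boundary between each pair of adjacent candidates
    bounds = [0]
    for c1, c2 in zip(candidates[:-1], candidates[1:]):
        between = s[c1 : c2 + 1]
        valley = between.min()
        if valley < valley_frac * min(s[c1], s[c2]):
            bounds.append(c1 + int(np.argmin(between)))
    bounds.append(len(raw))
    spans = [(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]

    # absorb too-narrow subpeaks into the taller adjacent neighbour
    while len(spans) > 1:
        widths = [b - a for a, b in spans]
        narrow = [k for k, w in enumerate(widths) if w < min_width]
        if not narrow:
            break
        k = min(narrow, key=lambda i: (widths[i], i))
        peak_height = lambda span: s[span[0] : span[1]].max()
        if k == 0:
            j = 1
        elif k == len(spans) - 1:
            j = k - 1
        else:
            j = k - 1 if peak_height(spans[k - 1]) >= peak_height(spans[k + 1]) else k + 1
        lo, hi = min(k, j), max(k, j)
        spans[lo : hi + 1] = [(spans[lo][0], spans[hi][1])]

    out = []
    for a, b in spans:
        summit = region.start + a + int(np.argmax(raw[a:b]))
        out.append(
            Subpeak(
                region=GenomicInterval(region.chrom, region.start + a, region.start + b),
                summit=summit,
            )
        )
    return out


def score_subpeaks(
    subpeaks: Sequence[Subpeak], pileup: Pileup, total_mapped: int
) -> List[Subpeak]:
    """Attach the normalized summit height (reads per 10 M) to each subpeak."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return [
        replace(
            sp,
            height_norm=float(
                normalize_per_10M(pileup.depth_at(sp.region.chrom, sp.summit), total_mapped)
            ),
        )
        for sp in subpeaks
    ]


def filter_subpeaks(
    subpeaks: Sequence[Subpeak], min_height: float = DEFAULT_MIN_HEIGHT
) -> List[Subpeak]:
    """Keep subpeaks whose normalized height is at least ``min_height``."""
    return [sp for sp in subpeaks if sp.height_norm >= min_height]
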