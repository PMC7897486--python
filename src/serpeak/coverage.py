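"""Window counting, per-10M normalization, base-pair pileups and tag-density profiles.

The genome is tiled by a :class:`WindowGrid` (200 bp bins by default, with an
optional half-bin phase shift). Reads are counted into every window they
overlap by at least one base — a read straddling a window boundary therefore
increments both windows of the same grid. Depth-style quantities are rescaled
to a library of 10 million mapped reads (``value * 1e7 / total_mapped``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval

__all__ = [
    "WindowGrid",
    "CountTrack",
    "Pileup",
    "count_reads_in_windows",
    "normalize_per_10M",
    "build_pileup",
    "tag_density_profile",
]


def _read_arrays(reads, chrom_sizes: Dict[str, int]):
    """Group interval-like reads into per-chrom (starts, ends) int arrays."""
    groups: Dict[str, Tuple[list, list]] = {c: ([], []) for c in chrom_sizes}
    n_outside = 0
    for r in reads:
        if r.chrom not in groups:
            n_outside += 1
            continue
        groups[r.chrom][0].append(r.start)
        groups[r.chrom][1].append(r.end)
    if n_outside:
        warnings.warn(f"{n_outside} reads on chromosomes absent from the grid; skipped")
    return {
        c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
        for c, (s, e) in groups.items()
    }


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping tiling of each chromosome with ``bin_size`` bp windows.

    With ``phase > 0`` the first window is the partial ``[0, phase)`` stretch
    and subsequent windows start at ``phase, phase + bin_size, ...``; the last
    window is clipped to the chromosome end. Windows of one grid never
    overlap, and the two phases of the standard 200/100 setup are offset by
    half a bin.
    """

    chrom_sizes: Dict[str, int]
    bin_size: int = 200
    phase: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not (0 <= self.phase < self.bin_size):
            raise ValueError("phase must lie in [0, bin_size)")

    def edges(self, chrom: str) -> np.ndarray:
        size = self.chrom_sizes[chrom]
        inner = np.arange(self.phase, size, self.bin_size)
        if self.phase > 0:
            inner = np.concatenate(([0], inner))
        elif inner.size == 0 or inner[0] != 0:
            inner = np.concatenate(([0], inner))
        if inner[-1] != size:
            inner = np.concatenate((inner, [size]))
        return inner.astype(np.int64)

    def n_windows(self, chrom: str) -> int:
        return len(self.edges(chrom)) - 1

    def windows(self, chrom: str) -> list[GenomicInterval]:
        e = self.edges(chrom)
        return [GenomicInterval(chrom, int(a), int(b)) for a, b in zip(e[:-1], e[1:])]

    def window_interval(self, chrom: str, index: int) -> GenomicInterval:
        e = self.edges(chrom)
        return GenomicInterval(chrom, int(e[index]), int(e[index + 1]))


@dataclass
class CountTrack:
    """Per-window read counts on one grid, plus the library size."""

    grid: WindowGrid
    counts: Dict[str, np.ndarray]
    total_mapped: int

    def __post_init__(self) -> None:
        for chrom, c in self.counts.items():
            if len(c) != self.grid.n_windows(chrom):
                raise ValueError(f"{chrom}: counts length does not match grid")


def count_reads_in_windows(reads, grid: WindowGrid) -> CountTrack:
    """Count reads into windows; a read increments every window it overlaps.

    Reads extending past a chromosome end are clipped (with a warning); reads
    on chromosomes unknown to the grid are skipped (with a warning).
    """
    arrays = _read_arrays(reads, grid.chrom_sizes)
    counts: Dict[str, np.ndarray] = {}
    total = 0
    clipped = 0
    for chrom, (starts, ends) in arrays.items():
        n = grid.n_windows(chrom)
        c = np.zeros(n, dtype=np.int64)
        if len(starts):
            size = grid.chrom_sizes[chrom]
            bad = (starts < 0) | (ends > size)
            clipped += int(bad.sum())
            starts = np.clip(starts, 0, size - 1)
            ends = np.clip(ends, 1, size)
            edges = grid.edges(chrom)
            i0 = np.searchsorted(edges, starts, side="right") - 1
            i1 = np.searchsorted(edges, ends - 1, side="right") - 1
            span = int((i1 - i0).max()) + 1
            for k in range(span):
                idx = i0 + k
                mask = idx <= i1
                np.add.at(c, idx[mask], 1)
            total += len(starts)
        counts[chrom] = c
    if clipped:
        warnings.warn(f"{clipped} reads extended past chromosome bounds; clipped")
    return CountTrack(grid=grid, counts=counts, total_mapped=total)


def normalize_per_10M(value, total_mapped: int):
    """Rescale a count-like value to a library of 10 million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return value * 1e7 / total_mapped


@dataclass
class Pileup:
    """Per-base read depth, one dense array per chromosome."""

    depth: Dict[str, np.ndarray]
    total_mapped: int

    def depth_at(self, chrom: str, pos: int) -> int:
        arr = self.depth.get(chrom)
        if arr is None or not (0 <= pos < len(arr)):
            return 0
        return int(arr[pos])

    def segment(self, chrom: str, start: int, end: int) -> np.ndarray:
        arr = self.depth.get(chrom)
        if arr is None:
            return np.zeros(end - start, dtype=np.int64)
        return arr[start:end]

    def integral(self) -> int:
        return int(sum(arr.sum() for arr in self.depth.values()))


def build_pileup(reads, chrom_sizes: Dict[str, int]) -> Pileup:
    """Depth(x) = number of reads covering base x; built by difference arrays."""
    arrays = _read_arrays(reads, chrom_sizes)
    depth: Dict[str, np.ndarray] = {}
    total = 0
    for chrom, (starts, ends) in arrays.items():
        size = chrom_sizes[chrom]
        d = np.zeros(size + 1, dtype=np.int64)
        if len(starts):
            starts = np.clip(starts, 0, size)
            ends = np.clip(ends, 0, size)
            np.add.at(d, starts, 1)
            np.add.at(d, ends, -1)
            total += len(starts)
        depth[chrom] = np.cumsum(d[:-1])
    return Pileup(depth=depth, total_mapped=total)


def tag_density_profile(
    pileup: Pileup,
    anchors: Sequence[Tuple[str, int]],
    half_width: int,
    total_mapped: int | None = None,
) -> Tuple[np.ndarray, int]:
    """Average per-10M read depth around a set of anchor positions.

    The returned profile has ``2 * half_width + 1`` entries; ``profile[p]``
    is the mean normalized depth at offset ``p - half_width`` from the
    anchors. Anchors closer than ``half_width`` to a chromosome edge are
    skipped (their number is reported via the second return value as
    ``n_used``). Raises if no anchor is usable.
    """
    if total_mapped is None:
        total_mapped = pileup.total_mapped
    width = 2 * half_width + 1
    acc = np.zeros(width, dtype=np.float64)
    n_used = 0
    for chrom, pos in anchors:
        arr = pileup.depth.get(chrom)
        if arr is None:
            continue
        lo, hi = pos - half_width, pos + half_width + 1
        if lo < 0 or hi > len(arr):
            continue
        acc += arr[lo:hi]
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable anchors for the tag-density profile")
    return normalize_per_10M(acc / n_used, total_mapped), n_used
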