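"""Chromatin-state segmentation from binarized histone-mark tracks.

Mark counts in 200 bp bins are binarized against a Poisson background (a bin
is "marked" when the upper-tail probability of its count drops below 1e-4).
A single multivariate-Bernoulli HMM (6 states by default) is learned jointly
from the binarized tracks of *all* cell types — concatenated as independent
chains — and then applied per cell type to obtain a genome segmentation by
posterior-argmax decoding. Downstream summaries: the distribution of peaks
over states (one-sided 30% overlap with a maximal same-state segment) and
state-fate transition matrices between two cell types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.stats import poisson

from .hmm import BernoulliHMM
from .intervals import GenomicInterval, peak_overlaps_region

__all__ = [
    "Segmentation",
    "binarize_marks",
    "fit_chromstate",
    "segment",
    "peak_state_distribution",
    "state_fate",
]

BINARIZE_P = 1e-4


def binarize_marks(
    counts: np.ndarray, background_rate: float, p_threshold: float = BINARIZE_P
) -> np.ndarray:
    """Poisson upper-tail binarization of per-bin mark counts.

    A bin is called marked (1) when ``P(X >= count)`` under
    ``X ~ Poisson(background_rate)`` is below ``p_threshold``.
    """
    if background_rate <= 0:
        raise ValueError("background_rate must be positive")
    counts = np.asarray(counts)
    tail = poisson.sf(counts - 1, background_rate)  # P(X >= count)
    return (tail < p_threshold).astype(np.uint8)


# cell-type data: dict chrom -> (n_bins, n_marks) binary matrix
CellTracks = Dict[str, np.ndarray]


def _chain_list(tracks_by_cell: Dict[str, CellTracks]) -> List[np.ndarray]:
    chains = []
    n_marks = None
    for cell in sorted(tracks_by_cell):
        for chrom in sorted(tracks_by_cell[cell]):
            m = np.asarray(tracks_by_cell[cell][chrom])
            if m.ndim != 2:
                raise ValueError("each track must be a (n_bins, n_marks) matrix")
            if n_marks is None:
                n_marks = m.shape[1]
            elif m.shape[1] != n_marks:
                raise ValueError("all cell types must carry the same marks")
            chains.append(m)
    if not chains:
        raise ValueError("no tracks supplied")
    return chains


def fit_chromstate(
    tracks_by_cell: Dict[str, CellTracks],
    n_states: int = 6,
    seed: int = 0,
    n_restarts: int = 3,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> BernoulliHMM:
    """Learn one shared chromatin-state model across all cell types.

    ``n_restarts`` random initializations (seeded) are fitted and the model
    with the best final log-likelihood kept; states are relabelled by
    descending total emission probability.
    """
    chains = _chain_list(tracks_by_cell)
    n_marks = chains[0].shape[1]
    best: BernoulliHMM | None = None
    best_ll = -np.inf
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        model = BernoulliHMM.random_init(n_states, n_marks, rng)
        model.fit(chains, max_iter=max_iter, tol=tol)
        ll = model.history_[-1] if model.history_ else model.loglikelihood(chains)
        if ll > best_ll:
            best, best_ll = model, ll
    assert best is not None
    return best


@dataclass
class Segmentation:
    """Per-bin chromatin-state labels (1-based) for one cell type."""

    cell_type: str
    bin_size: int
    states: Dict[str, np.ndarray]  # chrom -> 1-based state per bin

    def n_states(self) -> int:
        return int(max(s.max() for s in self.states.values()))

    def to_segments(self) -> List[Tuple[GenomicInterval, int]]:
        """Maximal same-state runs as (interval, state) records, sorted."""
        out: List[Tuple[GenomicInterval, int]] = []
        for chrom in sorted(self.states):
            s = self.states[chrom]
            if len(s) == 0:
                continue
            change = np.flatnonzero(np.diff(s)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(s)]))
            for a, b in zip(starts, ends):
                out.append(
                    (
                        GenomicInterval(chrom, int(a) * self.bin_size, int(b) * self.bin_size),
                        int(s[a]),
                    )
                )
        return out

    def state_coverage_in(self, peak: GenomicInterval, n_states: int) -> np.ndarray:
        """Bases of the peak covered by each state (index 0 = state 1)."""
        cov = np.zeros(n_states)
        s = self.states.get(peak.chrom)
        if s is None:
            return cov
        lo_bin = peak.start // self.bin_size
        hi_bin = (peak.end - 1) // self.bin_size
        for b in range(lo_bin, min(hi_bin, len(s) - 1) + 1):
            bin_start, bin_end = b * self.bin_size, (b + 1) * self.bin_size
            ov = min(peak.end, bin_end) - max(peak.start, bin_start)
            if ov > 0:
                cov[s[b] - 1] += ov
        return cov


def segment(
    model: BernoulliHMM, tracks: CellTracks, cell_type: str, bin_size: int = 200
) -> Segmentation:
    """Posterior-argmax state labels per bin for one cell type."""
    states = {}
    for chrom in sorted(tracks):
        gamma = model.posterior(np.asarray(tracks[chrom]))
        states[chrom] = (np.argmax(gamma, axis=1) + 1).astype(np.int64)
    return Segmentation(cell_type=cell_type, bin_size=bin_size, states=states)


def peak_state_distribution(
    peaks: Sequence[GenomicInterval],
    segmentation: Segmentation,
    n_states: int | None = None,
    min_frac: float = 0.3,
) -> np.ndarray:
    """Count peaks overlapping each state by the one-sided 30% rule.

    A peak counts for a state when some maximal same-state segment covers at
    least ``min_frac`` of the peak's length; a peak straddling a state
    boundary can therefore count for more than one state, so the counts need
    not sum to the number of peaks.
    """
    K = n_states or segmentation.n_states()
    counts = np.zeros(K, dtype=np.int64)
    segments = segmentation.to_segments()
    by_chrom: Dict[str, List[Tuple[GenomicInterval, int]]] = {}
    for iv, st in segments:
        by_chrom.setdefault(iv.chrom, []).append((iv, st))
    for peak in peaks:
        hit_states = set()
        for iv, st in by_chrom.get(peak.chrom, ()):
            if iv.end <= peak.start or iv.start >= peak.end:
                continue
            if st not in hit_states and peak_overlaps_region(peak, iv, min_frac):
                hit_states.add(st)
        for st in hit_states:
            counts[st - 1] += 1
    return counts


def state_fate(
    peaks: Sequence[GenomicInterval],
    segmentation_a: Segmentation,
    segmentation_b: Segmentation,
    n_states: int | None = None,
) -> np.ndarray:
    """State-transition counts of fixed regions between two cell types.

    Each peak contributes one count at (dominant state in A, dominant state
    in B), where the dominant state covers the largest fraction of the peak
    (ties resolved toward the lower state index). Row sums equal the number
    of peaks.
    """
    K = n_states or max(segmentation_a.n_states(), segmentation_b.n_states())
    matrix = np.zeros((K, K), dtype=np.int64)
    for peak in peaks:
        sa = int(np.argmax(segmentation_a.state_coverage_in(peak, K)))
        sb = int(np.argmax(segmentation_b.state_coverage_in(peak, K)))
        matrix[sa, sb] += 1
    return matrix
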