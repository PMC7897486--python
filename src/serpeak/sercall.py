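"""Signal-enriched-region (SER) calling from ChIP and input read intervals.

The caller tiles the genome with 200 bp windows in two phases (offset by
100 bp), counts reads per window, learns a 4-state Gaussian HMM on
log2(count + 1) per phase, and takes windows decoded into the two
highest-mean states as enriched. Bases enriched in *both* phase grids
survive; bases that are input-enriched under the same (ChIP-learned) models
are subtracted; regions touching a blacklist interval are dropped; the
remainder is merged (gap 0) into the final SER set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .coverage import CountTrack, WindowGrid, build_pileup, count_reads_in_windows, normalize_per_10M
from .hmm import GaussianHMM
from .intervals import (
    GenomicInterval,
    intersect_interval_sets,
    merge_intervals,
    subtract_interval_sets,
)

__all__ = [
    "SerCallConfig",
    "SER",
    "SerCallResult",
    "transform_counts",
    "fit_hmm4",
    "assign_states",
    "enriched_windows",
    "intersect_phases",
    "subtract_input",
    "filter_blacklist",
    "call_sers",
]

log = logging.getLogger(__name__)


@dataclass
class SerCallConfig:
    """Tunable parameters of the SER caller (defaults are the pipeline's)."""

    bin_size: int = 200
    phase_shift: int = 100
    n_states: int = 4
    n_enriched_states: int = 2  # the top-mean states counted as enriched
    max_iter: int = 200
    tol: float = 1e-6
    sd_floor: float = 0.4
    self_transition: float = 0.9
    min_self_transition: float = 0.999


@dataclass(frozen=True)
class SER:
    """A signal-enriched region with its mean per-10M ChIP coverage."""

    region: GenomicInterval
    mean_normalized_coverage: float


@dataclass
class SerCallResult:
    sers: List[SER]
    models: Dict[int, GaussianHMM]  # keyed by grid phase
    chip_enriched: Dict[int, List[GenomicInterval]] = field(default_factory=dict)
    input_enriched: Dict[int, List[GenomicInterval]] = field(default_factory=dict)

    @property
    def regions(self) -> List[GenomicInterval]:
        return [s.region for s in self.sers]


def transform_counts(counts: np.ndarray) -> np.ndarray:
    """Variance-stabilizing transform log2(count + 1) used as emission scale."""
    return np.log2(np.asarray(counts, dtype=np.float64) + 1.0)


def fit_hmm4(
    tracks: Dict[str, np.ndarray],
    n_states: int = 4,
    max_iter: int = 200,
    tol: float = 1e-6,
    sd_floor: float = 0.4,
    self_transition: float = 0.9,
    min_self_transition: float = 0.999,
) -> GaussianHMM:
    """Learn the enrichment HMM from per-chromosome transformed count tracks.

    Chromosomes are modelled as independent chains sharing one parameter set.
    Initialization is the deterministic percentile scheme; after training
    states are ordered by ascending emission mean, so states with the two
    highest indices are the signal states.
    """
    seqs = [np.asarray(tracks[c], dtype=np.float64) for c in sorted(tracks)]
    if not seqs or min(len(s) for s in seqs) < 10:
        raise ValueError("need at least one sequence of length >= 10")
    data = np.concatenate(seqs)
    model = GaussianHMM.from_percentile_init(
        data, n_states=n_states, self_transition=self_transition, sd_floor=sd_floor
    )
    model.fit(seqs, max_iter=max_iter, tol=tol, min_self_transition=min_self_transition)
    return model


def assign_states(model: GaussianHMM, track: np.ndarray) -> np.ndarray:
    """Viterbi state labels (1-based, ascending emission mean) per window."""
    return model.viterbi(np.asarray(track, dtype=np.float64)) + 1


def enriched_windows(
    states: np.ndarray,
    grid: WindowGrid,
    chrom: str,
    n_enriched_states: int = 2,
    n_states: int = 4,
) -> List[GenomicInterval]:
    """Windows whose 1-based state is among the top ``n_enriched_states``."""
    states = np.asarray(states)
    if len(states) != grid.n_windows(chrom):
        raise ValueError("state vector does not match the grid")
    cut = n_states - n_enriched_states  # keep states > cut (e.g. 3 and 4)
    edges = grid.edges(chrom)
    idx = np.flatnonzero(states > cut)
    return [GenomicInterval(chrom, int(edges[i]), int(edges[i + 1])) for i in idx]


def intersect_phases(
    enriched_phase0: Sequence[GenomicInterval],
    enriched_phase1: Sequence[GenomicInterval],
) -> List[GenomicInterval]:
    """Bases enriched in both phase grids, as maximal disjoint intervals."""
    return intersect_interval_sets(enriched_phase0, enriched_phase1)


def subtract_input(
    chip_regions: Sequence[GenomicInterval],
    input_enriched: Sequence[GenomicInterval],
) -> List[GenomicInterval]:
    """Remove bases covered by input-enriched windows (either phase)."""
    if not input_enriched:
        return merge_intervals(chip_regions)
    return subtract_interval_sets(chip_regions, input_enriched)


def filter_blacklist(
    regions: Sequence[GenomicInterval], blacklist: Sequence[GenomicInterval]
) -> List[GenomicInterval]:
    """Drop any region overlapping a blacklist interval by >= 1 bp."""
    if not blacklist:
        return list(regions)
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for b in blacklist:
        by_chrom.setdefault(b.chrom, []).append(b)
    out = []
    for r in regions:
        hits = by_chrom.get(r.chrom, ())
        if not any(r.overlap_length(b) > 0 for b in hits):
            out.append(r)
    return out


def _enriched_for_phase(
    counts: CountTrack, model: GaussianHMM, cfg: SerCallConfig
) -> List[GenomicInterval]:
    out: List[GenomicInterval] = []
    for chrom in sorted(counts.counts):
        states = assign_states(model, transform_counts(counts.counts[chrom]))
        out.extend(
            enriched_windows(
                states, counts.grid, chrom, cfg.n_enriched_states, cfg.n_states
            )
        )
    return out


def call_sers(
    chip_reads,
    input_reads,
    blacklist: Sequence[GenomicInterval],
    chrom_sizes: Dict[str, int],
    config: SerCallConfig | None = None,
) -> SerCallResult:
    """Run the full SER-calling pipeline on ChIP and matched input reads.

    Per phase grid: count ChIP reads, fit the 4-state model on the ChIP
    counts, Viterbi-decode ChIP *and* input counts with that same model, and
    collect windows in the two top states. Then intersect the two ChIP
    phases at base level, subtract bases that are input-enriched in either
    phase, drop blacklist-touching regions, and merge what remains.
    """
    cfg = config or SerCallConfig()
    chip_enr: Dict[int, List[GenomicInterval]] = {}
    input_enr: Dict[int, List[GenomicInterval]] = {}
    models: Dict[int, GaussianHMM] = {}
    for phase in (0, cfg.phase_shift):
        grid = WindowGrid(chrom_sizes, bin_size=cfg.bin_size, phase=phase)
        chip_counts = count_reads_in_windows(chip_reads, grid)
        model = fit_hmm4(
            {c: transform_counts(v) for c, v in chip_counts.counts.items()},
            n_states=cfg.n_states,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            sd_floor=cfg.sd_floor,
            self_transition=cfg.self_transition,
            min_self_transition=cfg.min_self_transition,
        )
        models[phase] = model
        chip_enr[phase] = _enriched_for_phase(chip_counts, model, cfg)
        input_counts = count_reads_in_windows(input_reads, grid)
        input_enr[phase] = _enriched_for_phase(input_counts, model, cfg)
        log.info(
            "phase %d: %d chip-enriched, %d input-enriched windows",
            phase,
            len(chip_enr[phase]),
            len(input_enr[phase]),
        )
    regions = intersect_phases(chip_enr[0], chip_enr[cfg.phase_shift])
    regions = subtract_input(regions, input_enr[0] + input_enr[cfg.phase_shift])
    regions = filter_blacklist(regions, blacklist)
    regions = merge_intervals(regions, gap=0)

    pileup = build_pileup(chip_reads, chrom_sizes)
    sers = []
    for r in regions:
        mean_depth = float(pileup.segment(r.chrom, r.start, r.end).mean())
        sers.append(
            SER(
                region=r,
                mean_normalized_coverage=float(
                    normalize_per_10M(mean_depth, max(pileup.total_mapped, 1))
                ),
            )
        )
    return SerCallResult(
        sers=sers, models=models, chip_enriched=chip_enr, input_enriched=input_enr
    )
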