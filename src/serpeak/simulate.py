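"""Synthetic ChIP-seq data with known ground truth.

The generator emulates the inputs the pipeline consumes, with everything a
pure function of ``(config, seed)``:

* a genome of one or more chromosomes carrying planted enriched regions,
  blacklist stretches, low-mappability stretches and gene models;
* ChIP and input read sets: background read starts follow a homogeneous
  Poisson process (``background_rate`` expected reads per 200 bp window);
  inside a planted region the start intensity is multiplied by a triangular
  bump per summit whose *average* multiplier equals the configured fold, so
  the mode of each bump sits exactly on a truth summit;
* histone-mark tracks drawn from a known 6-state Bernoulli chromatin model,
  for parameter-recovery exercises;
* an expression table with log-normal expression tied to binding category.

Planted regions carry one of three labels: ``chip_only`` (true binding,
enriched in ChIP only), ``input_artifact`` (enriched in input only) and
``both`` (artefactual signal present in ChIP *and* input — the case input
subtraction must remove).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval
from .io import BedRecord

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "Genome",
    "make_genome",
    "simulate_reads",
    "simulate_state_paths",
    "sample_mark_presence",
    "simulate_marks",
    "simulate_expression",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome and read sets."""

    chrom_sizes: Dict[str, int] = field(default_factory=lambda: {"chr1": 2_000_000})
    n_regions: int = 50  # chip_only planted regions
    n_input_regions: int = 5  # input_artifact regions
    n_shared_artifacts: int = 5  # regions enriched in both chip and input
    region_width: int = 2_000
    fold: float = 8.0  # mean enrichment over background inside a bump
    background_rate: float = 0.5  # expected reads per 200 bp window
    frag_len: int = 200
    summits_per_region: int = 3  # 1..this many summits per region
    n_reads_chip: Optional[int] = None  # None -> rate-determined totals
    n_reads_input: Optional[int] = None
    blacklist_fraction: float = 0.01
    low_mappability_fraction: float = 0.02
    n_genes: int = 40
    seed: int = 1

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("fold must be >= 1 (1 means no enrichment)")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        if not (1 <= self.summits_per_region <= 3):
            raise ValueError("summits_per_region must be 1..3")
        if self.blacklist_fraction + self.low_mappability_fraction >= 0.5:
            raise ValueError("excluded fractions must sum below 0.5")
        for name, val in (
            ("n_regions", self.n_regions),
            ("region_width", self.region_width),
            ("frag_len", self.frag_len),
            ("n_genes", self.n_genes),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """One planted region with its summits and enrichment label."""

    region: GenomicInterval
    summit_positions: Tuple[int, ...]
    planted_fold: float
    label: str  # chip_only | input_artifact | both

    def __post_init__(self) -> None:
        for s in self.summit_positions:
            if not self.region.contains(s):
                raise ValueError("summits must lie inside the region")

    def to_dict(self) -> dict:
        return {
            "chrom": self.region.chrom,
            "start": self.region.start,
            "end": self.region.end,
            "summits": list(self.summit_positions),
            "fold": self.planted_fold,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(
            region=GenomicInterval(d["chrom"], d["start"], d["end"]),
            summit_positions=tuple(d["summits"]),
            planted_fold=d["fold"],
            label=d["label"],
        )


@dataclass
class Genome:
    """Everything make_genome places: features plus the truth records."""

    chrom_sizes: Dict[str, int]
    truth: List[TruthRecord]
    blacklist: List[GenomicInterval]
    mappability: List[BedRecord]  # low-mappability stretches, value 0.1
    genes: List[GeneModel]

    def truth_regions(self, labels: Sequence[str] = ("chip_only",)) -> List[GenomicInterval]:
        return [t.region for t in self.truth if t.label in labels]

    def write_truth_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([t.to_dict() for t in self.truth], fh, indent=1, sort_keys=True)
            fh.write("\n")


def _place_disjoint(
    rng: np.random.Generator,
    chrom_sizes: Dict[str, int],
    widths: Sequence[int],
    occupied: Dict[str, List[Tuple[int, int]]],
    min_gap: int,
    max_tries: int = 10_000,
) -> List[GenomicInterval]:
    """Place intervals uniformly without touching existing occupied spans."""
    chroms = sorted(chrom_sizes)
    lens = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    probs = lens / lens.sum()
    placed = []
    for w in widths:
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            size = chrom_sizes[chrom]
            if size <= w:
                continue
            start = int(rng.integers(0, size - w))
            span = (start - min_gap, start + w + min_gap)
            if any(a < span[1] and span[0] < b for a, b in occupied.get(chrom, ())):
                continue
            occupied.setdefault(chrom, []).append((start, start + w))
            placed.append(GenomicInterval(chrom, start, start + w))
            break
        else:
            raise ValueError("genome too small to place all requested features")
    return placed


def make_genome(config: SimulationConfig) -> Genome:
    """Build the synthetic genome: truth regions, blacklist, mappability, genes.

    Blacklist and low-mappability stretches never overlap planted regions,
    and all placements are deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 101])
    occupied: Dict[str, List[Tuple[int, int]]] = {}

    labels = (
        ["chip_only"] * config.n_regions
        + ["input_artifact"] * config.n_input_regions
        + ["both"] * config.n_shared_artifacts
    )
    regions = _place_disjoint(
        rng,
        config.chrom_sizes,
        [config.region_width] * len(labels),
        occupied,
        min_gap=2_000,
    )
    truth = []
    for region, label in zip(regions, labels):
        k = int(rng.integers(1, config.summits_per_region + 1))
        # summits centred in equal-width slots so bumps never collide
        slot = region.length // k
        summits = tuple(region.start + i * slot + slot // 2 for i in range(k))
        truth.append(
            TruthRecord(
                region=region,
                summit_positions=summits,
                planted_fold=config.fold,
                label=label,
            )
        )

    total_len = sum(config.chrom_sizes.values())
    piece = 2_000

    def pieces(fraction: float) -> List[int]:
        n = int(round(fraction * total_len / piece))
        return [piece] * n

    blacklist = _place_disjoint(
        rng, config.chrom_sizes, pieces(config.blacklist_fraction), occupied, min_gap=500
    )
    low_map = _place_disjoint(
        rng,
        config.chrom_sizes,
        pieces(config.low_mappability_fraction),
        occupied,
        min_gap=500,
    )
    mappability = [BedRecord(iv, value=0.1) for iv in sorted(low_map, key=GenomicInterval.sort_key)]

    gene_lengths = rng.integers(2_000, 10_001, size=config.n_genes)
    gene_spans = _place_disjoint(
        rng, config.chrom_sizes, list(gene_lengths), occupied={}, min_gap=5_000
    )
    genes = []
    for i, span in enumerate(sorted(gene_spans, key=GenomicInterval.sort_key)):
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tts = (span.start, span.end) if strand == "+" else (span.end, span.start)
        genes.append(
            GeneModel(gene_id=f"gene{i:04d}", chrom=span.chrom, strand=strand, tss=tss, tts=tts)
        )
    return Genome(
        chrom_sizes=dict(config.chrom_sizes),
        truth=truth,
        blacklist=sorted(blacklist, key=GenomicInterval.sort_key),
        mappability=mappability,
        genes=genes,
    )


_ENRICHED_LABELS = {"chip": ("chip_only", "both"), "input": ("input_artifact", "both")}


def _intensity(
    config: SimulationConfig, truth: Sequence[TruthRecord], chrom: str, sample: str
) -> np.ndarray:
    """Per-base read-start intensity for one chromosome and sample."""
    size = config.chrom_sizes[chrom]
    base_rate = config.background_rate / 200.0  # expected starts per bp
    lam = np.full(size, base_rate, dtype=np.float64)
    wanted = _ENRICHED_LABELS[sample]
    for t in truth:
        if t.region.chrom != chrom or t.label not in wanted:
            continue
        k = len(t.summit_positions)
        slot = t.region.length // k
        peak_mult = 2.0 * t.planted_fold - 1.0  # triangle averaging to `fold`
        for i, summit in enumerate(t.summit_positions):
            lo = t.region.start + i * slot
            hi = lo + slot if i < k - 1 else t.region.end
            x = np.arange(lo, hi)
            half = np.maximum(np.maximum(summit - lo, hi - 1 - summit), 1)
            tri = 1.0 + (peak_mult - 1.0) * np.maximum(
                0.0, 1.0 - np.abs(x - summit) / half
            )
            lam[lo:hi] *= tri
    return lam


def simulate_reads(
    config: SimulationConfig,
    truth: Sequence[TruthRecord],
    sample: str,
    seed: Optional[int] = None,
) -> List[BedRecord]:
    """Draw fixed-length single-end reads for the ChIP or the input sample.

    Background starts form a homogeneous Poisson process; planted regions
    multiply the local intensity by the triangular bump mixture. When the
    configured read total is None the library size is Poisson with the
    intensity integral as mean; an explicit total draws exactly that many
    starts from the same profile. Reads are ``frag_len`` long and clipped to
    the chromosome end.
    """
    if sample not in ("chip", "input"):
        raise ValueError("sample must be 'chip' or 'input'")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 7 if sample == "chip" else 11])
    n_target = config.n_reads_chip if sample == "chip" else config.n_reads_input

    per_chrom_lam = {
        c: _intensity(config, truth, c, sample) for c in sorted(config.chrom_sizes)
    }
    totals = {c: lam.sum() for c, lam in per_chrom_lam.items()}
    grand = sum(totals.values())

    reads: List[BedRecord] = []
    if n_target is not None:
        chrom_counts = rng.multinomial(
            n_target, [totals[c] / grand for c in sorted(totals)]
        )
        counts = dict(zip(sorted(totals), chrom_counts))
    else:
        counts = {c: rng.poisson(totals[c]) for c in sorted(totals)}

    for chrom in sorted(per_chrom_lam):
        n = int(counts[chrom])
        if n == 0:
            continue
        lam = per_chrom_lam[chrom]
        cdf = np.cumsum(lam)
        cdf /= cdf[-1]
        starts = np.searchsorted(cdf, rng.random(n), side="right")
        starts.sort()
        size = config.chrom_sizes[chrom]
        for s in starts:
            s = int(min(s, size - 1))
            reads.append(
                BedRecord(
                    GenomicInterval(chrom, s, min(s + config.frag_len, size)),
                    name=sample,
                    strand="+",
                )
            )
    return reads


def simulate_state_paths(
    chrom_sizes: Dict[str, int],
    transition: np.ndarray,
    startprob: np.ndarray,
    seed: int,
    bin_size: int = 200,
) -> Dict[str, np.ndarray]:
    """Sample a Markov state path (0-based states) per chromosome."""
    transition = np.asarray(transition, dtype=np.float64)
    startprob = np.asarray(startprob, dtype=np.float64)
    rng = np.random.default_rng([seed, 23])
    K = len(startprob)
    paths = {}
    cum_t = np.cumsum(transition, axis=1)
    for chrom in sorted(chrom_sizes):
        n = chrom_sizes[chrom] // bin_size
        u = rng.random(n)
        path = np.empty(n, dtype=np.int64)
        path[0] = np.searchsorted(np.cumsum(startprob), u[0], side="right")
        for t in range(1, n):
            path[t] = np.searchsorted(cum_t[path[t - 1]], u[t], side="right")
        paths[chrom] = np.minimum(path, K - 1)
    return paths


def sample_mark_presence(
    states: Dict[str, np.ndarray],
    emission: np.ndarray,
    seed: int,
) -> Dict[str, np.ndarray]:
    """Per-bin Bernoulli mark presence given a state path and emission matrix."""
    emission = np.asarray(emission, dtype=np.float64)
    rng = np.random.default_rng([seed, 29])
    out = {}
    for chrom in sorted(states):
        p = emission[states[chrom]]  # (T, M)
        out[chrom] = (rng.random(p.shape) < p).astype(np.uint8)
    return out


def simulate_marks(
    config: SimulationConfig,
    states: Dict[str, np.ndarray],
    emission: np.ndarray,
    seed: Optional[int] = None,
    bin_size: int = 200,
    reads_per_marked_bin: float = 10.0,
    reads_per_unmarked_bin: float = 0.1,
) -> Tuple[Dict[int, List[BedRecord]], Dict[str, np.ndarray]]:
    """Reads per histone mark given a known state path.

    Marked bins (drawn Bernoulli from the emission row of the bin's state)
    receive Poisson(``reads_per_marked_bin``) read starts placed uniformly in
    the bin, unmarked bins Poisson(``reads_per_unmarked_bin``). Returns the
    per-mark read lists and the underlying presence matrices.
    """
    seed = config.seed if seed is None else seed
    presence = sample_mark_presence(states, np.asarray(emission), seed)
    rng = np.random.default_rng([seed, 31])
    n_marks = np.asarray(emission).shape[1]
    reads: Dict[int, List[BedRecord]] = {m: [] for m in range(n_marks)}
    for chrom in sorted(presence):
        pres = presence[chrom]
        size = config.chrom_sizes[chrom]
        for m in range(n_marks):
            rates = np.where(pres[:, m] == 1, reads_per_marked_bin, reads_per_unmarked_bin)
            counts = rng.poisson(rates)
            for b in np.flatnonzero(counts):
                lo = b * bin_size
                starts = lo + rng.integers(0, bin_size, size=int(counts[b]))
                for s in np.sort(starts):
                    s = int(min(s, size - 1))
                    reads[m].append(
                        BedRecord(
                            GenomicInterval(chrom, s, min(s + config.frag_len, size)),
                            name=f"mark{m}",
                            strand="+",
                        )
                    )
    return reads, presence


def simulate_expression(
    genes: Sequence[GeneModel],
    binding_truth: Dict[str, str],
    effect: Dict[str, float],
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Expression table: exp(Normal(effect[category], noise_sd)) per gene."""
    missing = [g.gene_id for g in genes if g.gene_id not in binding_truth]
    if missing:
        raise ValueError(f"genes without a binding category: {missing[:3]}...")
    rng = np.random.default_rng([seed, 37])
    rows = []
    for g in genes:
        cat = binding_truth[g.gene_id]
        log_expr = effect[cat] + (noise_sd * rng.standard_normal() if noise_sd > 0 else 0.0)
        rows.append((g.gene_id, cat, float(np.exp(log_expr))))
    return pd.DataFrame(rows, columns=["gene_id", "category", "expression"])
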