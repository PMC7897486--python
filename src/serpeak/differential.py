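"""Differential occupancy classification of subpeaks between two datasets.

For a subpeak called in dataset A, its normalized height is re-measured in
dataset B's pileup at the same summit coordinate. The uniqueness score is

    (height_A - height_in_B) / max(height_in_B, 1)

where the denominator floor of 1 damps fold changes on near-zero background.
A subpeak is **unique to A** when the score exceeds 2 and no B subpeak summit
lies within 100 bp of its summit; it is **shared** when a B summit lies
within 100 bp and the two matched summit heights differ by less than 1;
anything else is **ambiguous** and excluded from set comparisons. Presence
of a subpeak in any dataset uses a normalized-height threshold of 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coverage import Pileup, normalize_per_10M
from .subpeaks import Subpeak

__all__ = [
    "ScoredDataset",
    "ClassifiedSubpeak",
    "ComparisonResult",
    "height_in_other",
    "unique_score",
    "classify_subpeak",
    "compare_datasets",
    "presence_matrix",
]

SUMMIT_DISTANCE_BP = 100
UNIQUE_MIN_SCORE = 2.0
SHARED_MAX_HEIGHT_DIFF = 1.0
PRESENCE_MIN_HEIGHT = 2.0


@dataclass
class ScoredDataset:
    """One dataset's evidence: scored subpeaks plus the pileup they came from."""

    name: str
    subpeaks: List[Subpeak]
    pileup: Pileup
    total_mapped: int


@dataclass(frozen=True)
class ClassifiedSubpeak:
    subpeak: Subpeak
    height_in_other: float
    unique_score: float
    nearest_other_summit_distance: float  # bp, inf when none on the chrom
    label: str  # "unique", "shared" or "ambiguous", relative to the other set


def height_in_other(subpeak: Subpeak, pileup: Pileup, total_mapped: int) -> float:
    """Normalized depth of the other dataset's pileup at this summit."""
    chrom = subpeak.region.chrom
    if chrom not in pileup.depth:
        warnings.warn(f"chromosome {chrom} absent from the other dataset's pileup")
        return 0.0
    return float(normalize_per_10M(pileup.depth_at(chrom, subpeak.summit), total_mapped))


def unique_score(height_a: float, height_b: float) -> float:
    """Height difference normalized by the other height, floored at 1."""
    if height_a < 0 or height_b < 0:
        raise ValueError("heights must be non-negative")
    return (height_a - height_b) / max(height_b, 1.0)


def _nearest_summit(
    subpeak: Subpeak, others: Sequence[Subpeak]
) -> Tuple[float, Optional[Subpeak]]:
    """Closest other-dataset summit on the same chromosome (ties leftmost)."""
    best_d, best = math.inf, None
    for o in others:
        if o.region.chrom != subpeak.region.chrom:
            continue
        d = abs(o.summit - subpeak.summit)
        if d < best_d or (d == best_d and best is not None and o.summit < best.summit):
            best_d, best = d, o
    return best_d, best


def classify_subpeak(
    subpeak: Subpeak,
    other: ScoredDataset,
    max_distance: int = SUMMIT_DISTANCE_BP,
    unique_min_score: float = UNIQUE_MIN_SCORE,
    shared_max_diff: float = SHARED_MAX_HEIGHT_DIFF,
) -> ClassifiedSubpeak:
    """Label one subpeak of dataset A relative to dataset B."""
    h_other = height_in_other(subpeak, other.pileup, other.total_mapped)
    score = unique_score(subpeak.height_norm, h_other)
    dist, nearest = _nearest_summit(subpeak, other.subpeaks)
    if score > unique_min_score and dist > max_distance:
        label = "unique"
    elif (
        nearest is not None
        and dist <= max_distance
        and abs(subpeak.height_norm - nearest.height_norm) < shared_max_diff
    ):
        label = "shared"
    else:
        label = "ambiguous"
    return ClassifiedSubpeak(
        subpeak=subpeak,
        height_in_other=h_other,
        unique_score=score,
        nearest_other_summit_distance=dist,
        label=label,
    )


@dataclass
class ComparisonResult:
    """Two-way partition of subpeaks into unique/shared/ambiguous."""

    classified_a: List[ClassifiedSubpeak]
    classified_b: List[ClassifiedSubpeak]
    shared_pairs: List[Tuple[int, int]]  # (index in A, index in B)

    @property
    def counts(self) -> Dict[str, int]:
        return {
            "unique_a": sum(c.label == "unique" for c in self.classified_a),
            "unique_b": sum(c.label == "unique" for c in self.classified_b),
            "shared": len(self.shared_pairs),
            "ambiguous": (
                sum(c.label == "ambiguous" for c in self.classified_a)
                + sum(c.label == "ambiguous" for c in self.classified_b)
            ),
        }


def compare_datasets(
    a: ScoredDataset, b: ScoredDataset, max_distance: int = SUMMIT_DISTANCE_BP
) -> ComparisonResult:
    """Classify every subpeak of both datasets and pair the shared ones 1:1.

    Shared-labelled subpeaks are matched greedily by summit distance (ties
    broken by the leftmost A then B summit); each subpeak joins at most one
    pair.
    """
    ca = [classify_subpeak(sp, b, max_distance) for sp in a.subpeaks]
    cb = [classify_subpeak(sp, a, max_distance) for sp in b.subpeaks]
    shared_a = [i for i, c in enumerate(ca) if c.label == "shared"]
    shared_b = [j for j, c in enumerate(cb) if c.label == "shared"]
    candidates = []
    for i in shared_a:
        sa = a.subpeaks[i]
        for j in shared_b:
            sb = b.subpeaks[j]
            if sa.region.chrom != sb.region.chrom:
                continue
            d = abs(sa.summit - sb.summit)
            if d <= max_distance:
                candidates.append((d, sa.summit, sb.summit, i, j))
    candidates.sort()
    used_a: set = set()
    used_b: set = set()
    pairs = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    pairs.sort()
    return ComparisonResult(classified_a=ca, classified_b=cb, shared_pairs=pairs)


def presence_matrix(
    subpeaks: Sequence[Subpeak],
    datasets: Dict[str, Tuple[Pileup, int]],
    min_height: float = PRESENCE_MIN_HEIGHT,
) -> pd.DataFrame:
    """Boolean presence of each subpeak in each cell type.

    A subpeak is present in a cell type when that cell type's normalized
    depth at the subpeak summit is at least ``min_height``. Rows follow the
    subpeak order, columns the dataset names; feeds multi-way (e.g. 3-way)
    occupancy category counts.
    """
    if len(datasets) < 2:
        raise ValueError("presence_matrix needs at least two cell types")
    data = {}
    for name, (pileup, total) in datasets.items():
        data[name] = [
            height_in_other(sp, pileup, total) >= min_height for sp in subpeaks
        ]
    return pd.DataFrame(data, index=np.arange(len(subpeaks)))
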