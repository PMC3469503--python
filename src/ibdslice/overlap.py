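"""Length-weighted segment-overlap evaluation between two segment sets.

Array-derived segments are treated as ground truth.  For a segment
interval pi from one set and the list of intervals the other set reports
for the same sample pair, alpha(pi, IBD') is the genetic length of pi
intersected with the union of the other intervals.  Pooling over all
pairs:

    specificity = sum alpha(pi, IBD_array) over pi in IBD_exome
                  / sum length(pi) over pi in IBD_exome

    sensitivity = sum alpha(pi, IBD_exome) over pi in IBD_array
                  / sum length(pi) over pi in IBD_array

i.e. the proportion of exome-reported segment mass consistent with the
array, and the proportion of array segment mass recovered by the exome.
Lengths are genetic (cM) by default since the filtering thresholds of
interest are in cM; a bp mode exists for diagnostics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import pandas as pd

from .cohort import Cohort
from .detect import DetectParams, detect_ibd
from .segments import IBDSegment, SegmentSet

log = logging.getLogger("ibdslice")

__all__ = [
    "OverlapResult",
    "overlap_alpha",
    "specificity",
    "sensitivity",
    "overlap_result",
    "filter_segments",
    "grid_search",
]


@dataclass(frozen=True)
class OverlapResult:
    """Specificity/sensitivity of one segment-set comparison.

    Undefined ratios (zero total length in the denominator set) are
    reported as NaN, never as 0.
    """

    specificity: float
    sensitivity: float
    total_exome_len_cm: float
    total_array_len_cm: float
    n_pairs_with_segments: int


def _union(intervals: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def overlap_alpha(
    pi: tuple[float, float], others: Sequence[tuple[float, float]]
) -> float:
    """Length of ``pi`` intersected with the union of ``others``.

    Intervals are (start, end) on a common chromosome and coordinate
    scale; overlapping ``others`` are unioned first so shared mass is
    never double-counted.
    """
    a, b = pi
    if b < a:
        raise ValueError("interval end before start")
    total = 0.0
    for x, y in _union(others):
        lo, hi = max(a, x), min(b, y)
        if hi > lo:
            total += hi - lo
    return total


def _seg_interval(seg: IBDSegment, scale: str) -> tuple[float, float]:
    if scale == "cm":
        return (seg.a_cm, seg.b_cm)
    return (float(seg.a_bp), float(seg.b_bp))


def _check_universes(a: SegmentSet, b: SegmentSet) -> None:
    sa, sb = a.samples(), b.samples()
    if sa and sb and not (sa & sb):
        raise ValueError("segment sets share no samples; different cohorts?")


def _pooled_overlap(
    numer_set: SegmentSet, denom_set: SegmentSet, scale: str, per_pair: bool
) -> float:
    """Overlap mass of ``denom_set`` covered by ``numer_set``, as a fraction."""
    total = 0.0
    covered = 0.0
    ratios = []
    for pair in denom_set.pairs():
        segs = denom_set.get(*pair)
        by_chrom: dict[str, list] = {}
        for s in numer_set.get(*pair):
            by_chrom.setdefault(s.chrom, []).append(_seg_interval(s, scale))
        pair_total = pair_covered = 0.0
        for seg in segs:
            iv = _seg_interval(seg, scale)
            pair_total += iv[1] - iv[0]
            pair_covered += overlap_alpha(iv, by_chrom.get(seg.chrom, []))
        total += pair_total
        covered += pair_covered
        if per_pair and pair_total > 0:
            ratios.append(pair_covered / pair_total)
    if per_pair:
        return float(sum(ratios) / len(ratios)) if ratios else math.nan
    if total == 0:
        return math.nan
    return covered / total


def specificity(
    exome: SegmentSet, array: SegmentSet, scale: str = "cm", per_pair: bool = False
) -> float:
    """Fraction of exome segment mass overlapping the array set.

    Pooled across pairs by default; ``per_pair=True`` averages per-pair
    ratios instead.  NaN when the exome set is empty.
    """
    _check_universes(exome, array)
    return _pooled_overlap(array, exome, scale, per_pair)


def sensitivity(
    exome: SegmentSet, array: SegmentSet, scale: str = "cm", per_pair: bool = False
) -> float:
    """Fraction of array segment mass recovered by the exome set."""
    _check_universes(exome, array)
    return _pooled_overlap(exome, array, scale, per_pair)


def overlap_result(exome: SegmentSet, array: SegmentSet, scale: str = "cm") -> OverlapResult:
    pairs = set(exome.pairs()) | set(array.pairs())
    return OverlapResult(
        specificity=specificity(exome, array, scale),
        sensitivity=sensitivity(exome, array, scale),
        total_exome_len_cm=exome.total_len_cm(),
        total_array_len_cm=array.total_len_cm(),
        n_pairs_with_segments=len(pairs),
    )


def filter_segments(
    segments: SegmentSet,
    min_len_cm: float | None = None,
    min_density: float | None = None,
) -> SegmentSet:
    """Keep segments by genetic length and marker density.

    ``min_density`` is in sites/cM.  Zero-cM segments have infinite
    density and always pass the density filter (logged).  The two filters
    commute and are idempotent.
    """
    n_zero = sum(1 for s in segments if s.len_cm == 0)
    if n_zero and min_density:
        log.info("density filter: %d zero-cM segment(s) kept as infinite density", n_zero)

    def keep(s: IBDSegment) -> bool:
        if min_len_cm is not None and s.len_cm < min_len_cm:
            return False
        if min_density is not None and s.density < min_density:
            return False
        return True

    return segments.filter(keep)


def grid_search(
    exome_cohort: Cohort,
    array_segments: SegmentSet,
    bit_sizes: Sequence[int],
    mismatches: Sequence[int],
    metrics: Sequence[str],
    length_thresholds: Sequence[float] = (0.0,),
    density_thresholds: Sequence[float] = (0.0,),
    min_len_cm: float = 3.0,
    min_seeds: int = 1,
) -> pd.DataFrame:
    """Sweep detection and filtering parameters against a reference set.

    Runs detection on ``exome_cohort`` once per (bit_size, m, metric)
    combination, then evaluates every (length, density) filter cell,
    producing one row per parameter combination with the pooled
    specificity and sensitivity versus ``array_segments``.
    """
    for name, vals in (
        ("bit_sizes", bit_sizes),
        ("mismatches", mismatches),
        ("metrics", metrics),
        ("length_thresholds", length_thresholds),
        ("density_thresholds", density_thresholds),
    ):
        if len(list(vals)) == 0:
            raise ValueError(f"empty parameter list: {name}")

    rows = []
    for bit, m, metric in product(bit_sizes, mismatches, metrics):
        params = DetectParams(
            bit_size=bit, m=m, metric=metric,
            min_len_cm=min_len_cm, min_seeds=min_seeds,
        )
        detected = detect_ibd(exome_cohort, params)
        for min_len, min_dens in product(length_thresholds, density_thresholds):
            kept = filter_segments(detected, min_len_cm=min_len, min_density=min_dens)
            res = overlap_result(kept, array_segments)
            rows.append(
                {
                    "bit_size": bit,
                    "mismatch": m,
                    "metric": metric,
                    "min_len_cm": min_len,
                    "min_density": min_dens,
                    "n_segments": len(kept),
                    "specificity": res.specificity,
                    "sensitivity": res.sensitivity,
                    "total_exome_len_cm": res.total_exome_len_cm,
                    "total_array_len_cm": res.total_array_len_cm,
                }
            )
    return pd.DataFrame(rows)
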