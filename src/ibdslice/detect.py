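"""Seed-and-extend IBD detection by dictionary hashing of haplotype slices.

Each chromosome is tiled into non-overlapping slices of ``bit_size``
consecutive markers.  Exact allele-string matches between haplotypes of
different samples within a slice ("seeds") are found by hashing the slice
words, then extended outward slice by slice under one of three mismatch
metrics with per-slice budget ``m``:

``genotype``
    A slice passes if the sites where both samples are homozygous
    (non-missing) disagree at most ``m`` times.  Heterozygotes are ignored,
    so the rule is phase-agnostic.
``haplotype``
    A slice passes if the best of the four phased haplotype pairings has
    at most ``m`` allele mismatches; the best pairing may switch between
    slices (tolerates phase switch errors).
``haploid``
    Like ``haplotype`` but the seed's haplotype pairing is kept fixed for
    the whole segment; no phase switching.

The three rules are increasingly restrictive: for any seed the extended
marker span nests as haploid <= haplotype <= genotype, because a mutually
homozygous opposite-allele site mismatches all four pairings and the fixed
pairing is one of the four.

The budget comparator is ``<= m``, so ``m = 0`` means exact matching.
Missing calls never count as mismatches during extension, but a haplotype
with a missing call inside a slice is excluded from that slice's seed
dictionary (exact identity cannot be asserted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import MISSING, Cohort, Slice
from .segments import IBDSegment, SegmentSet

__all__ = [
    "DetectParams",
    "SeedMatch",
    "build_dictionary",
    "find_seeds",
    "extend_slice_ok",
    "extend_seed",
    "detect_ibd",
]

_PAIRINGS = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class DetectParams:
    """Detection parameters.

    bit_size
        Markers per slice (seed length); 10 and 50 are the usual
        working points.
    m
        Per-slice mismatch budget; a slice passes with at most ``m``
        mismatches under the active metric (0 = exact).
    metric
        One of ``genotype``, ``haplotype``, ``haploid``.
    min_len_cm
        Minimum genetic length of a reported segment.
    min_seeds
        Minimum number of consecutive exactly-matching slices required
        before a seed run is extended.
    """

    bit_size: int = 50
    m: int = 0
    metric: str = "haplotype"
    min_len_cm: float = 3.0
    min_seeds: int = 1

    def __post_init__(self) -> None:
        if self.bit_size < 2:
            raise ValueError("bit_size must be >= 2")
        if self.m < 0:
            raise ValueError("mismatch budget m must be >= 0")
        if self.min_len_cm < 0:
            raise ValueError("min_len_cm must be >= 0")
        if self.metric not in ("genotype", "haplotype", "haploid"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.min_seeds < 1:
            raise ValueError("min_seeds must be >= 1")


@dataclass(frozen=True, order=True)
class SeedMatch:
    """An exact haplotype-word match between two samples in one slice."""

    sample_i: str
    sample_j: str
    hap_i: int
    hap_j: int
    chrom: str
    slice_index: int


def build_dictionary(cohort: Cohort, slc: Slice) -> dict[bytes, list[tuple[int, int]]]:
    """Hash every complete haplotype word over a slice.

    Returns a multimap from allele word (bytes) to ``(sample_index,
    haplotype_index)`` entries.  Haplotypes with a missing call inside the
    slice are omitted.
    """
    cohort.require_phased("seed dictionary construction")
    lo, hi = cohort.chrom_range(slc.chrom)
    a, b = lo + slc.start_idx, lo + slc.end_idx
    if b > hi:
        raise ValueError("slice extends past chromosome end")
    words: dict[bytes, list[tuple[int, int]]] = {}
    H = cohort.haplotypes
    for s in range(cohort.n_samples):
        for h in (0, 1):
            w = H[s, h, a:b]
            if np.any(w == MISSING):
                continue
            words.setdefault(w.tobytes(), []).append((s, h))
    return words


def find_seeds(cohort: Cohort, params: DetectParams) -> list[SeedMatch]:
    """All exact slice matches between haplotypes of different samples.

    One :class:`SeedMatch` per (unordered sample pair, haplotype pair,
    full slice) with identical words; equivalent to a brute-force
    all-pairs comparison of every slice.
    """
    cohort.require_phased("seed finding")
    bit = params.bit_size
    seeds: list[SeedMatch] = []
    for chrom in cohort.chroms:
        lo, hi = cohort.chrom_range(chrom)
        n_full = (hi - lo) // bit
        for k in range(n_full):
            slc = Slice(chrom, k * bit, (k + 1) * bit)
            for entries in build_dictionary(cohort, slc).values():
                if len(entries) < 2:
                    continue
                for x in range(len(entries)):
                    si, hi_ = entries[x]
                    for y in range(x + 1, len(entries)):
                        sj, hj = entries[y]
                        if si == sj:
                            continue
                        if si > sj:
                            (si2, hi2), (sj2, hj2) = (sj, hj), (si, hi_)
                        else:
                            (si2, hi2), (sj2, hj2) = (si, hi_), (sj, hj)
                        seeds.append(
                            SeedMatch(
                                sample_i=cohort.samples[si2],
                                sample_j=cohort.samples[sj2],
                                hap_i=hi2,
                                hap_j=hj2,
                                chrom=chrom,
                                slice_index=k,
                            )
                        )
    seeds.sort()
    return seeds


# -- mismatch machinery -----------------------------------------------------


def _genotype_mismatches(cohort: Cohort, si: int, sj: int, a: int, b: int) -> np.ndarray:
    """Mask of mutually homozygous, opposite-allele sites over [a, b)."""
    gi = cohort.genotypes[si, a:b]
    gj = cohort.genotypes[sj, a:b]
    hom_i = (gi == 0) | (gi == 2)
    hom_j = (gj == 0) | (gj == 2)
    return hom_i & hom_j & (gi != gj)


def _haploid_mismatches(
    cohort: Cohort, si: int, sj: int, pairing: tuple[int, int], a: int, b: int
) -> np.ndarray:
    hi = cohort.haplotypes[si, pairing[0], a:b]
    hj = cohort.haplotypes[sj, pairing[1], a:b]
    return (hi != MISSING) & (hj != MISSING) & (hi != hj)


def _slice_mismatch_count(
    cohort: Cohort,
    si: int,
    sj: int,
    metric: str,
    pairing: tuple[int, int] | None,
    a: int,
    b: int,
) -> tuple[int, tuple[int, int] | None]:
    """Mismatch count over global index range [a, b) under one metric.

    For the haplotype metric the count is the minimum over the four
    pairings and the best pairing is returned alongside.
    """
    if metric == "genotype":
        return int(_genotype_mismatches(cohort, si, sj, a, b).sum()), None
    if metric == "haploid":
        if pairing is None:
            raise ValueError("haploid metric requires a fixed haplotype pairing")
        return int(_haploid_mismatches(cohort, si, sj, pairing, a, b).sum()), pairing
    best_count, best_pairing = None, None
    for p in _PAIRINGS:
        c = int(_haploid_mismatches(cohort, si, sj, p, a, b).sum())
        if best_count is None or c < best_count:
            best_count, best_pairing = c, p
    return best_count, best_pairing


def extend_slice_ok(
    cohort: Cohort,
    pair: tuple[str, str],
    hap_pair: tuple[int, int] | None,
    slc: Slice,
    metric: str,
    m: int,
) -> tuple[bool, tuple[int, int] | None]:
    """Whether a slice is compatible with IBD under a metric and budget.

    Returns ``(ok, pairing)`` where ``pairing`` is the best haplotype
    pairing for the haplotype metric (``None`` for genotype).
    """
    si = cohort.samples.index(pair[0])
    sj = cohort.samples.index(pair[1])
    lo, _ = cohort.chrom_range(slc.chrom)
    count, pairing = _slice_mismatch_count(
        cohort, si, sj, metric, hap_pair if metric == "haploid" else None,
        lo + slc.start_idx, lo + slc.end_idx,
    )
    return count <= m, pairing


def _refine_boundary(
    cohort: Cohort,
    si: int,
    sj: int,
    metric: str,
    pairing: tuple[int, int] | None,
    a: int,
    b: int,
    m: int,
    direction: int,
    start_boundary: int,
) -> int:
    """Marker-by-marker walk into a failing region [a, b).

    Walks outward (direction +1 = rightward from ``a``, -1 = leftward from
    ``b - 1``), stops before the (m+1)-th mismatch, and returns the global
    index of the last *compatible* marker reached (or ``start_boundary``
    if no marker could be added).  For the haplotype metric all four
    pairings are tried and the farthest boundary wins.
    """
    if a >= b:
        return start_boundary
    if metric == "genotype":
        masks = [_genotype_mismatches(cohort, si, sj, a, b)]
    elif metric == "haploid":
        masks = [_haploid_mismatches(cohort, si, sj, pairing, a, b)]
    else:
        masks = [_haploid_mismatches(cohort, si, sj, p, a, b) for p in _PAIRINGS]

    best = start_boundary
    for mm in masks:
        boundary = start_boundary
        count = 0
        indices = range(b - a) if direction > 0 else range(b - a - 1, -1, -1)
        for off in indices:
            if mm[off]:
                count += 1
                if count > m:
                    break
            else:
                boundary = a + off
        if direction > 0:
            best = max(best, boundary)
        else:
            best = min(best, boundary)
    return best


def _extend_run(
    cohort: Cohort,
    si: int,
    sj: int,
    hap_pair: tuple[int, int],
    chrom: str,
    k0: int,
    k1: int,
    metric: str,
    m: int,
    bit: int,
) -> tuple[int, int]:
    """Extend a run of matching slices [k0, k1] into a marker interval.

    Returns the global (inclusive) marker index span of the extended
    segment.
    """
    lo, hi = cohort.chrom_range(chrom)
    n = hi - lo
    n_full = n // bit
    pairing = hap_pair if metric == "haploid" else None

    # slice-level extension leftward
    k = k0 - 1
    while k >= 0:
        count, _ = _slice_mismatch_count(
            cohort, si, sj, metric, pairing, lo + k * bit, lo + (k + 1) * bit
        )
        if count > m:
            break
        k -= 1
    left = lo + (k + 1) * bit
    if k >= 0:  # marker walk into the failing slice
        left = _refine_boundary(
            cohort, si, sj, metric, pairing,
            lo + k * bit, lo + (k + 1) * bit, m, -1, left,
        )

    # slice-level extension rightward
    k = k1 + 1
    while k < n_full:
        count, _ = _slice_mismatch_count(
            cohort, si, sj, metric, pairing, lo + k * bit, lo + (k + 1) * bit
        )
        if count > m:
            break
        k += 1
    right = lo + k * bit - 1
    if k < n_full:
        right = _refine_boundary(
            cohort, si, sj, metric, pairing,
            lo + k * bit, lo + (k + 1) * bit, m, +1, right,
        )
    elif n_full * bit < n:  # trailing partial slice: walk into it
        right = _refine_boundary(
            cohort, si, sj, metric, pairing,
            lo + n_full * bit, hi, m, +1, right,
        )
    return left, right


def extend_seed(
    cohort: Cohort, seed: SeedMatch, params: DetectParams
) -> IBDSegment | None:
    """Extend a single seed into a segment under ``params``.

    Returns ``None`` when the extended span is shorter than
    ``min_len_cm`` (or degenerates to a single marker).
    """
    si = cohort.samples.index(seed.sample_i)
    sj = cohort.samples.index(seed.sample_j)
    left, right = _extend_run(
        cohort, si, sj, (seed.hap_i, seed.hap_j), seed.chrom,
        seed.slice_index, seed.slice_index, params.metric, params.m,
        params.bit_size,
    )
    return _make_segment(cohort, seed.sample_i, seed.sample_j, seed.chrom,
                         left, right, params)


def _make_segment(
    cohort: Cohort, name_i: str, name_j: str, chrom: str,
    left: int, right: int, params: DetectParams, source: str = "exome",
) -> IBDSegment | None:
    if right <= left:
        return None
    length = float(cohort.cm[right] - cohort.cm[left])
    if length < params.min_len_cm:
        return None
    return IBDSegment(
        sample_i=name_i,
        sample_j=name_j,
        chrom=chrom,
        a_bp=int(cohort.pos_bp[left]),
        b_bp=int(cohort.pos_bp[right]),
        a_cm=float(cohort.cm[left]),
        b_cm=float(cohort.cm[right]),
        n_sites=right - left + 1,
        metric=params.metric,
        source=source,
    )


def _group_runs(slice_indices: Sequence[int]) -> list[tuple[int, int]]:
    """Group sorted slice indices into maximal consecutive runs."""
    runs: list[tuple[int, int]] = []
    start = prev = None
    for k in slice_indices:
        if start is None:
            start = prev = k
        elif k == prev + 1:
            prev = k
        else:
            runs.append((start, prev))
            start = prev = k
    if start is not None:
        runs.append((start, prev))
    return runs


def detect_ibd(cohort: Cohort, params: DetectParams, source: str = "exome") -> SegmentSet:
    """Full detection: seed, extend, merge, length-filter.

    Per sample pair and chromosome, extended marker intervals that
    overlap or touch are unioned before the ``min_len_cm`` filter is
    applied, so adjacent detections report as one segment.  Output is
    deterministic for a fixed input.
    """
    seeds = find_seeds(cohort, params)

    # group seeds into consecutive-slice runs per (pair, hap pairing)
    by_key: dict[tuple[str, str, int, int, str], list[int]] = {}
    for s in seeds:
        by_key.setdefault(
            (s.sample_i, s.sample_j, s.hap_i, s.hap_j, s.chrom), []
        ).append(s.slice_index)

    sample_idx = {name: i for i, name in enumerate(cohort.samples)}
    # extension is pairing-independent for genotype/haplotype metrics, so
    # covered-run skipping may pool across pairings there
    pool_pairings = params.metric in ("genotype", "haplotype")
    intervals: dict[tuple, list[tuple[int, int]]] = {}

    for key in sorted(by_key):
        name_i, name_j, h_i, h_j, chrom = key
        cover_key = (
            (name_i, name_j, chrom)
            if pool_pairings
            else (name_i, name_j, h_i, h_j, chrom)
        )
        done = intervals.setdefault(cover_key, [])
        si, sj = sample_idx[name_i], sample_idx[name_j]
        lo, _ = cohort.chrom_range(chrom)
        bit = params.bit_size
        for k0, k1 in _group_runs(sorted(by_key[key])):
            if k1 - k0 + 1 < params.min_seeds:
                continue
            run_lo, run_hi = lo + k0 * bit, lo + (k1 + 1) * bit - 1
            if any(l <= run_lo and run_hi <= r for l, r in done):
                continue
            left, right = _extend_run(
                cohort, si, sj, (h_i, h_j), chrom, k0, k1,
                params.metric, params.m, bit,
            )
            done.append((left, right))

    # merge per pair/chromosome and apply the length filter
    merged: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    for cover_key, ivs in intervals.items():
        name_i, name_j, chrom = cover_key[0], cover_key[1], cover_key[-1]
        merged.setdefault((name_i, name_j, chrom), []).extend(ivs)

    out = SegmentSet()
    for (name_i, name_j, chrom), ivs in sorted(merged.items()):
        ivs.sort()
        fused: list[list[int]] = []
        for l, r in ivs:
            if fused and l <= fused[-1][1] + 1:
                fused[-1][1] = max(fused[-1][1], r)
            else:
                fused.append([l, r])
        for l, r in fused:
            seg = _make_segment(cohort, name_i, name_j, chrom, l, r, params, source)
            if seg is not None:
                out.add(seg)
    return out
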