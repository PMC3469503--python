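"""Core containers: marker sites, diploid cohorts, genetic maps and slices.

A :class:`Cohort` holds an ordered marker panel (one or more chromosomes)
and per-sample diploid genotype calls, optionally phased into two haplotype
rows per sample, together with per-call genotype quality (GQ).  Genotypes
use a compact integer encoding:

====  ======================
code  meaning
====  ======================
 0    homozygous reference
 1    heterozygous
 2    homozygous alternate
-1    missing
====  ======================

Haplotype alleles are 0 (reference), 1 (alternate) or -1 (missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "MarkerSite",
    "Cohort",
    "GeneticMap",
    "interpolate_cm",
    "tile_slices",
    "Slice",
]


@dataclass(frozen=True)
class MarkerSite:
    """A single bi-allelic marker with physical and genetic coordinates.

    ``annotated`` marks membership in a reference variant catalogue
    (dbSNP-style); unannotated sites are treated as *novel* downstream.
    """

    chrom: str
    pos_bp: int
    cm: float
    ref_allele: str
    alt_allele: str
    annotated: bool = False

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"ref and alt allele identical ({self.ref_allele}) at "
                f"{self.chrom}:{self.pos_bp}"
            )


@dataclass(frozen=True)
class Slice:
    """A window of consecutive markers on one chromosome.

    Indices are chromosome-local, 0-based and half-open.  Full slices hold
    exactly ``bit_size`` markers; the trailing partial slice of a
    chromosome (if any) is never used for seeding.
    """

    chrom: str
    start_idx: int
    end_idx: int

    @property
    def n_markers(self) -> int:
        return self.end_idx - self.start_idx


def tile_slices(n_markers: int, bit_size: int) -> list[tuple[int, int]]:
    """Tile ``n_markers`` into non-overlapping windows of ``bit_size``.

    Returns half-open ``(start, end)`` index pairs for the *full* slices
    only; a trailing remainder shorter than ``bit_size`` is omitted (it can
    still be extended into, but never seeds a match).
    """
    if bit_size < 2:
        raise ValueError("bit_size must be >= 2")
    return [(k * bit_size, (k + 1) * bit_size) for k in range(n_markers // bit_size)]


def interpolate_cm(map_points: Sequence[tuple[float, float]], pos_bp: float) -> float:
    """Genetic position of ``pos_bp`` by linear interpolation of map points.

    ``map_points`` is a sorted ``(bp, cM)`` list with non-decreasing cM.
    Positions beyond either end take the boundary cM value (constant
    extrapolation).
    """
    if len(map_points) == 0:
        raise ValueError("empty genetic map")
    bps = np.asarray([p[0] for p in map_points], dtype=float)
    cms = np.asarray([p[1] for p in map_points], dtype=float)
    if len(map_points) == 1:
        return float(cms[0])
    if np.any(np.diff(bps) <= 0):
        raise ValueError("genetic map bp positions must be strictly increasing")
    if np.any(np.diff(cms) < 0):
        raise ValueError("genetic map cM values must be non-decreasing")
    return float(np.interp(pos_bp, bps, cms))


class GeneticMap:
    """Per-chromosome piecewise-linear bp -> cM map."""

    def __init__(self, points: dict[str, Sequence[tuple[float, float]]]):
        self._points: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pts in points.items():
            if len(pts) == 0:
                raise ValueError(f"empty map for chromosome {chrom}")
            bps = np.asarray([p[0] for p in pts], dtype=float)
            cms = np.asarray([p[1] for p in pts], dtype=float)
            order = np.argsort(bps)
            bps, cms = bps[order], cms[order]
            if np.any(np.diff(cms) < 0):
                raise ValueError(f"cM not monotone on chromosome {chrom}")
            self._points[chrom] = (bps, cms)

    @property
    def chroms(self) -> list[str]:
        return list(self._points)

    def interpolate(self, chrom: str, pos_bp) -> np.ndarray | float:
        """cM position(s) for bp position(s) on ``chrom`` (vectorised)."""
        if chrom not in self._points:
            raise KeyError(f"no genetic map for chromosome {chrom}")
        bps, cms = self._points[chrom]
        if len(bps) == 1:
            out = np.full_like(np.asarray(pos_bp, dtype=float), cms[0])
            return float(out) if np.isscalar(pos_bp) else out
        result = np.interp(pos_bp, bps, cms)
        return float(result) if np.isscalar(pos_bp) else result


@dataclass
class Cohort:
    """Samples x ordered marker sites with diploid calls, phase and GQ.

    Sites are stored in column-parallel arrays sorted by chromosome block
    and strictly increasing ``pos_bp`` within each block.  ``haplotypes``
    has shape ``(s, 2, n_sites)`` and is required for phase-aware
    operations; ``genotypes`` has shape ``(s, n_sites)``.
    """

    samples: list[str]
    chrom: np.ndarray           # (n,) object/str per-site chromosome label
    pos_bp: np.ndarray          # (n,) int64
    cm: np.ndarray              # (n,) float64
    ref: np.ndarray             # (n,) single-char codes
    alt: np.ndarray
    annotated: np.ndarray       # (n,) bool
    genotypes: np.ndarray       # (s, n) int8
    gq: np.ndarray              # (s, n) int32
    haplotypes: np.ndarray | None = None   # (s, 2, n) int8
    phased: bool = False
    _chrom_ranges: dict[str, tuple[int, int]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise ValueError("a cohort needs at least 2 samples")
        if np.any(self.gq < 0):
            raise ValueError("GQ values must be non-negative")
        self._chrom_ranges = {}
        start = 0
        labels = list(self.chrom)
        n = len(labels)
        i = 0
        while i < n:
            chrom = labels[i]
            j = i
            while j < n and labels[j] == chrom:
                j += 1
            if chrom in self._chrom_ranges:
                raise ValueError(f"chromosome {chrom} appears in two blocks")
            self._chrom_ranges[chrom] = (i, j)
            block_pos = self.pos_bp[i:j]
            if np.any(np.diff(block_pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            block_cm = self.cm[i:j]
            if np.any(np.diff(block_cm) < 0):
                raise ValueError(f"cM not monotone on {chrom}")
            i = j
        del start
        if self.phased:
            if self.haplotypes is None:
                raise ValueError("phased cohort requires haplotypes")
            self._check_phase_consistency()

    def _check_phase_consistency(self) -> None:
        h = self.haplotypes
        g = self.genotypes
        known = (h[:, 0, :] != MISSING) & (h[:, 1, :] != MISSING)
        implied = h[:, 0, :] + h[:, 1, :]
        ok = ~known | (g == implied) | (g == MISSING)
        if not np.all(ok):
            s, m = np.argwhere(~ok)[0]
            raise ValueError(
                f"genotype/haplotype mismatch for sample {self.samples[s]} "
                f"at {self.chrom[m]}:{self.pos_bp[m]}"
            )

    # -- panel accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos_bp)

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_ranges)

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Global half-open site-index range of one chromosome block."""
        return self._chrom_ranges[chrom]

    def site(self, idx: int) -> MarkerSite:
        return MarkerSite(
            chrom=str(self.chrom[idx]),
            pos_bp=int(self.pos_bp[idx]),
            cm=float(self.cm[idx]),
            ref_allele=str(self.ref[idx]),
            alt_allele=str(self.alt[idx]),
            annotated=bool(self.annotated[idx]),
        )

    def iter_sites(self) -> Iterator[MarkerSite]:
        for i in range(self.n_sites):
            yield self.site(i)

    def site_index_set(self) -> set[tuple[str, int]]:
        """(chrom, pos) identity of every site, for platform set-difference."""
        return {(str(c), int(p)) for c, p in zip(self.chrom, self.pos_bp)}

    def subset_sites(self, mask: np.ndarray) -> "Cohort":
        """New cohort restricted to the sites where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return Cohort(
            samples=list(self.samples),
            chrom=self.chrom[mask],
            pos_bp=self.pos_bp[mask],
            cm=self.cm[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            annotated=self.annotated[mask],
            genotypes=self.genotypes[:, mask],
            gq=self.gq[:, mask],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, mask],
            phased=self.phased,
        )

    def require_phased(self, what: str) -> None:
        if not self.phased or self.haplotypes is None:
            raise ValueError(f"{what} requires a phased cohort")
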