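"""Homozygous-variant concordance of IBD segments against sequence calls.

Given IBD segments detected on one platform (typically the array) and
genotype calls from another (the exome), concordance asks: at the sites
inside a segment where both members of the pair are homozygous and at
least one carries the variant allele, how often are the two alleles
identical?  Under true IBD (two shared chromosome copies) and error-free
calls every such site is concordant, so concordance near 100% validates
the segments, while low values indicate false IBD or miscalled
heterozygotes.

The analytic baseline is the concordance expected between *random*
pairs, computed per site from the observed homozygote carrier counts
without assuming Hardy-Weinberg equilibrium.  With ``h_ref`` homozygous
reference carriers, ``h_var`` homozygous variant carriers and sample
size ``s``, the probability that a random unordered pair is both
homozygous with at least one variant carrier is

    q(n) = [C(h_ref + h_var, 2) - C(h_ref, 2)] / C(s, 2)

and the conditional probability that such a pair is concordant is

    c(n) = C(h_var, 2) / [C(h_ref + h_var, 2) - C(h_ref, 2)].

The baseline is the q-weighted mean of c over sites, as a percentage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import MISSING, Cohort
from .segments import SegmentSet

log = logging.getLogger("ibdslice")

__all__ = [
    "SiteCounts",
    "site_weight_w",
    "segment_site_range",
    "concordance",
    "baseline_concordance",
    "carrier_counts",
    "concordance_table",
]

_PAIRINGS = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class SiteCounts:
    """Homozygote carrier counts at one site."""

    h_ref: int
    h_var: int
    s: int

    def __post_init__(self) -> None:
        if self.h_ref < 0 or self.h_var < 0:
            raise ValueError("carrier counts must be non-negative")
        if self.h_ref + self.h_var > self.s:
            raise ValueError("homozygote carriers exceed sample size")
        if self.s < 2:
            raise ValueError("sample size must be >= 2")


def site_weight_w(call_i: int, call_j: int) -> int:
    """Site selector w: 1 iff both calls are homozygous, non-missing, and
    at least one is homozygous-variant."""
    if call_i == MISSING or call_j == MISSING:
        return 0
    hom_i = call_i in (0, 2)
    hom_j = call_j in (0, 2)
    return int(hom_i and hom_j and (call_i == 2 or call_j == 2))


def segment_site_range(cohort: Cohort, chrom: str, a_bp: int, b_bp: int) -> tuple[int, int]:
    """Global half-open index range of cohort sites inside [a_bp, b_bp]."""
    lo, hi = cohort.chrom_range(chrom)
    pos = cohort.pos_bp[lo:hi]
    left = lo + int(np.searchsorted(pos, a_bp, side="left"))
    right = lo + int(np.searchsorted(pos, b_bp, side="right"))
    return left, right


def _class_mask(cohort: Cohort, site_class: str | None) -> np.ndarray:
    if site_class is None:
        return np.ones(cohort.n_sites, dtype=bool)
    if site_class == "annotated":
        return cohort.annotated.copy()
    if site_class == "novel":
        return ~cohort.annotated
    raise ValueError(f"unknown site class {site_class!r}")


def _platform_difference_mask(cohort: Cohort, exclude_sites_of: Cohort | None) -> np.ndarray:
    if exclude_sites_of is None:
        return np.ones(cohort.n_sites, dtype=bool)
    other = exclude_sites_of.site_index_set()
    return np.array(
        [(str(c), int(p)) not in other for c, p in zip(cohort.chrom, cohort.pos_bp)],
        dtype=bool,
    )


def _metric_site_mask(
    val: Cohort,
    si: int,
    sj: int,
    chrom: str,
    a_bp: int,
    b_bp: int,
    metric: str,
    bit_size: int,
    m: int,
    site_bps: np.ndarray,
) -> np.ndarray:
    """Keep mask for exome sites after slice-wise re-validation on ``val``.

    The validation cohort's chromosome block (the platform the segments
    were detected from) is tiled into windows of ``bit_size`` markers;
    each window overlapping [a_bp, b_bp] is checked under the extension
    metric on the validation calls, and every exome site whose position
    falls in a failing window's bp span is dropped.  Window k owns the bp
    range from its first marker up to the first marker of window k+1.
    For the haploid metric a single haplotype pairing is held fixed
    across the whole interval: the pairing whose windows pass most often.
    """
    lo, hi = val.chrom_range(chrom)
    pos = val.pos_bp[lo:hi]
    n = hi - lo
    n_win = max(1, (n + bit_size - 1) // bit_size)
    win_start_bp = pos[np.arange(n_win) * bit_size]

    def owning(bps):
        k = np.searchsorted(win_start_bp, bps, side="right") - 1
        return np.clip(k, 0, n_win - 1)

    k_first = int(owning(np.asarray([a_bp]))[0])
    k_last = int(owning(np.asarray([b_bp]))[0])
    windows = []
    for k in range(k_first, k_last + 1):
        a = lo + k * bit_size
        b = min(lo + (k + 1) * bit_size, hi)
        windows.append((a, b))

    def hap_mm(pairing, a, b):
        hi_ = val.haplotypes[si, pairing[0], a:b]
        hj_ = val.haplotypes[sj, pairing[1], a:b]
        return int(((hi_ != MISSING) & (hj_ != MISSING) & (hi_ != hj_)).sum())

    def geno_mm(a, b):
        gi = val.genotypes[si, a:b]
        gj = val.genotypes[sj, a:b]
        hom_i = (gi == 0) | (gi == 2)
        hom_j = (gj == 0) | (gj == 2)
        return int((hom_i & hom_j & (gi != gj)).sum())

    if metric == "genotype":
        passes = [geno_mm(a, b) <= m for a, b in windows]
    elif metric == "haplotype":
        val.require_phased("haplotype metric validation")
        passes = [min(hap_mm(p, a, b) for p in _PAIRINGS) <= m for a, b in windows]
    elif metric == "haploid":
        val.require_phased("haploid metric validation")
        per_pairing = [
            [hap_mm(p, a, b) <= m for a, b in windows] for p in _PAIRINGS
        ]
        best = max(range(4), key=lambda ix: sum(per_pairing[ix]))
        passes = per_pairing[best]
    else:
        raise ValueError(f"unknown metric {metric!r}")

    site_win = owning(site_bps)
    pass_by_win = dict(zip(range(k_first, k_last + 1), passes))
    return np.array([pass_by_win.get(int(k), False) for k in site_win], dtype=bool)


def concordance(
    array_segments: SegmentSet,
    exome: Cohort,
    gq_min: int = 0,
    site_class: str | None = None,
    metric: str | None = None,
    bit_size: int = 50,
    m: int = 0,
    exclude_sites_of: Cohort | None = None,
    validation_cohort: Cohort | None = None,
) -> float:
    """Mean per-interval homozygous-variant concordance, as a percentage.

    For each segment of each pair, the qualifying sites are those inside
    the interval (optionally restricted to a site class and to sites
    absent from ``exclude_sites_of``'s panel) where both calls survive
    the GQ threshold and ``site_weight_w`` is 1; the interval concordance
    is the fraction of those with identical alleles.  Intervals with no
    qualifying site are skipped; the result is the unweighted mean over
    the remaining intervals, or NaN if none qualify.

    When ``metric`` is given, each interval is first re-validated
    window-by-window under that extension metric on ``validation_cohort``
    (the platform the segments came from, typically the array) and exome
    sites in failing windows are excluded.  Validating on an independent
    platform keeps the concordance measurement out of the validation
    itself.
    """
    if metric is not None and validation_cohort is None:
        raise ValueError("metric re-validation requires a validation_cohort")
    site_mask = _class_mask(exome, site_class) & _platform_difference_mask(
        exome, exclude_sites_of
    )
    sample_idx = {name: i for i, name in enumerate(exome.samples)}
    if validation_cohort is not None:
        val_idx = {name: i for i, name in enumerate(validation_cohort.samples)}
    per_interval: list[float] = []
    for pair in array_segments.pairs():
        if pair[0] not in sample_idx or pair[1] not in sample_idx:
            raise ValueError(f"segment pair {pair} absent from exome cohort")
        si, sj = sample_idx[pair[0]], sample_idx[pair[1]]
        for seg in array_segments.get(*pair):
            if seg.chrom not in exome.chroms:
                continue
            left, right = segment_site_range(exome, seg.chrom, seg.a_bp, seg.b_bp)
            if right <= left:
                continue
            keep = site_mask[left:right].copy()
            if metric is not None:
                if seg.chrom not in validation_cohort.chroms:
                    continue
                if pair[0] not in val_idx or pair[1] not in val_idx:
                    raise ValueError(
                        f"segment pair {pair} absent from validation cohort"
                    )
                keep &= _metric_site_mask(
                    validation_cohort, val_idx[pair[0]], val_idx[pair[1]],
                    seg.chrom, seg.a_bp, seg.b_bp, metric, bit_size, m,
                    exome.pos_bp[left:right],
                )
            if not keep.any():
                continue
            gi = exome.genotypes[si, left:right].astype(np.int32)
            gj = exome.genotypes[sj, left:right].astype(np.int32)
            qi = exome.gq[si, left:right]
            qj = exome.gq[sj, left:right]
            gi = np.where(qi >= gq_min, gi, MISSING)
            gj = np.where(qj >= gq_min, gj, MISSING)
            hom_i = (gi == 0) | (gi == 2)
            hom_j = (gj == 0) | (gj == 2)
            w = keep & hom_i & hom_j & ((gi == 2) | (gj == 2))
            if not w.any():
                continue
            z = w & (gi == 2) & (gj == 2)
            per_interval.append(z.sum() / w.sum())
    if not per_interval:
        log.info("concordance undefined: no interval with a qualifying site")
        return math.nan
    return 100.0 * float(np.mean(per_interval))


def carrier_counts(
    exome: Cohort,
    gq_min: int = 0,
    site_class: str | None = None,
    exclude_sites_of: Cohort | None = None,
) -> list[SiteCounts]:
    """Per-site homozygote carrier counts after GQ masking and site filters."""
    mask = _class_mask(exome, site_class) & _platform_difference_mask(
        exome, exclude_sites_of
    )
    g = exome.genotypes
    q = exome.gq
    ok = q >= gq_min
    h_ref = ((g == 0) & ok).sum(axis=0)
    h_var = ((g == 2) & ok).sum(axis=0)
    s = exome.n_samples
    return [
        SiteCounts(h_ref=int(h_ref[i]), h_var=int(h_var[i]), s=s)
        for i in np.flatnonzero(mask)
    ]


def baseline_concordance(sites: Iterable[SiteCounts]) -> float:
    """Expected random-pair concordance from carrier counts, in percent.

    q-weighted mean of the per-site conditional concordance c (see module
    docstring); sites with q = 0 contribute nothing; NaN when every site
    has q = 0.
    """
    sites = list(sites)
    if not sites:
        return math.nan
    h_ref = np.array([x.h_ref for x in sites], dtype=float)
    h_var = np.array([x.h_var for x in sites], dtype=float)
    s = np.array([x.s for x in sites], dtype=float)

    def c2(x):
        return x * (x - 1) / 2.0

    q_num = c2(h_ref + h_var) - c2(h_ref)
    q = q_num / c2(s)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(q_num > 0, c2(h_var) / q_num, 0.0)
    if q.sum() == 0:
        log.info("baseline concordance undefined: all q(n) = 0")
        return math.nan
    return 100.0 * float((q * c).sum() / q.sum())


def concordance_table(
    array_segments: SegmentSet,
    exome: Cohort,
    gq_thresholds: Sequence[int] = (0, 10, 20, 30, 40),
    metrics: Sequence[str] = ("random", "genotype", "haplotype", "haploid"),
    bit_size: int = 50,
    m: int = 0,
    exclude_sites_of: Cohort | None = None,
    validation_cohort: Cohort | None = None,
    site_classes: Sequence[str] = ("novel", "annotated"),
) -> pd.DataFrame:
    """Concordance grid over GQ thresholds, site classes and metrics.

    Rows are (site_class, gq) pairs; one column per metric, where
    ``random`` is the analytic baseline recomputed from the GQ-masked
    carrier counts.  Cells are percentages; NaN marks undefined cells.
    When ``validation_cohort`` is omitted it defaults to
    ``exclude_sites_of`` (the array cohort plays both roles).
    """
    if validation_cohort is None:
        validation_cohort = exclude_sites_of
    rows = []
    index = []
    for site_class in site_classes:
        for gq in gq_thresholds:
            row = {}
            for metric in metrics:
                if metric == "random":
                    row[metric] = baseline_concordance(
                        carrier_counts(
                            exome, gq_min=gq, site_class=site_class,
                            exclude_sites_of=exclude_sites_of,
                        )
                    )
                else:
                    row[metric] = concordance(
                        array_segments, exome, gq_min=gq, site_class=site_class,
                        metric=metric, bit_size=bit_size, m=m,
                        exclude_sites_of=exclude_sites_of,
                        validation_cohort=validation_cohort,
                    )
            rows.append(row)
            index.append((site_class, gq))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["site_class", "gq"])
    )
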