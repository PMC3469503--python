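"""Independent reference implementations used to cross-check the package."""

from __future__ import annotations

import numpy as np

from ibdslice.cohort import MISSING, Cohort
from ibdslice.detect import SeedMatch


def brute_force_seeds(cohort: Cohort, bit_size: int) -> set[SeedMatch]:
    """All-pairs, all-slices exact comparison of haplotype words.

    Direct dense comparison of every haplotype pair in every full slice
    (no hashing); haplotype words containing a missing call cannot match.
    """
    seeds: set[SeedMatch] = set()
    s = cohort.n_samples
    H = cohort.haplotypes
    rows = [(i, h) for i in range(s) for h in (0, 1)]
    for chrom in cohort.chroms:
        lo, hi = cohort.chrom_range(chrom)
        n_full = (hi - lo) // bit_size
        for k in range(n_full):
            a, b = lo + k * bit_size, lo + (k + 1) * bit_size
            W = H[:, :, a:b].reshape(2 * s, bit_size)
            valid = ~(W == MISSING).any(axis=1)
            eq = (W[:, None, :] == W[None, :, :]).all(axis=2)
            for x in range(2 * s):
                if not valid[x]:
                    continue
                for y in range(x + 1, 2 * s):
                    if not valid[y] or not eq[x, y]:
                        continue
                    (si, hi_), (sj, hj) = rows[x], rows[y]
                    if si == sj:
                        continue
                    seeds.add(
                        SeedMatch(
                            sample_i=cohort.samples[si],
                            sample_j=cohort.samples[sj],
                            hap_i=hi_, hap_j=hj, chrom=chrom, slice_index=k,
                        )
                    )
    return seeds


def grid_overlap_length(
    pi: tuple[float, float], others, cell: float = 1e-3
) -> float:
    """Discretised overlap length: count fine grid cells of pi covered."""
    a, b = pi
    if b <= a:
        return 0.0
    edges = np.arange(a, b, cell)
    mids = edges + cell / 2
    covered = np.zeros(len(mids), dtype=bool)
    for x, y in others:
        covered |= (mids > x) & (mids < y)
    return float(covered.sum() * cell)


def monte_carlo_baseline(
    h_ref: np.ndarray,
    h_var: np.ndarray,
    s: int,
    rng: np.random.Generator,
    n_draws: int = 100_000,
) -> tuple[float, float]:
    """Random-pair concordance by simulation, with its standard error.

    Draws (site, unordered pair) uniformly over sites; conditional on the
    pair being mutually homozygous with at least one variant carrier,
    records whether both carry the variant.  Returns (percent, SE in
    percent).
    """
    n_sites = len(h_ref)
    site = rng.integers(0, n_sites, size=n_draws)
    # sample two distinct individuals by index
    a = rng.integers(0, s, size=n_draws)
    b = rng.integers(0, s - 1, size=n_draws)
    b = np.where(b >= a, b + 1, b)

    def state(ind, site_idx):
        # individuals 0..h_ref-1 are hom-ref, next h_var are hom-var, rest other
        hr, hv = h_ref[site_idx], h_var[site_idx]
        out = np.full(len(ind), 2)  # 2 = not homozygous
        out[ind < hr] = 0
        out[(ind >= hr) & (ind < hr + hv)] = 1  # 1 = hom-var
        return out

    sa, sb = state(a, site), state(b, site)
    w = (sa != 2) & (sb != 2) & ((sa == 1) | (sb == 1))
    z = (sa == 1) & (sb == 1)
    n_w = int(w.sum())
    if n_w == 0:
        return float("nan"), float("nan")
    p = z[w].mean()
    se = np.sqrt(max(p * (1 - p), 1e-12) / n_w)
    return 100.0 * float(p), 100.0 * float(se)
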