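"""Shared builders for small in-memory cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from ibdslice.cohort import Cohort


def make_cohort(
    haps: np.ndarray,
    pos_bp: np.ndarray | None = None,
    cm_per_site: float = 0.01,
    chrom: str = "1",
    gq: int = 99,
    annotated: np.ndarray | None = None,
    phased: bool = True,
) -> Cohort:
    """Cohort from a (s, 2, n) haplotype array on a uniform map.

    Genotypes are derived from the haplotypes (missing allele -> missing
    call); positions default to 1, 101, 201, ... with ``cm_per_site``
    centimorgans between adjacent sites.
    """
    haps = np.asarray(haps, dtype=np.int8)
    s, _, n = haps.shape
    if pos_bp is None:
        pos_bp = 1 + 100 * np.arange(n, dtype=np.int64)
    cm = cm_per_site * np.arange(n, dtype=float)
    geno = np.where(
        (haps[:, 0, :] < 0) | (haps[:, 1, :] < 0), -1, haps[:, 0, :] + haps[:, 1, :]
    ).astype(np.int8)
    return Cohort(
        samples=[f"S{i + 1}" for i in range(s)],
        chrom=np.asarray([chrom] * n, dtype=object),
        pos_bp=np.asarray(pos_bp, dtype=np.int64),
        cm=cm,
        ref=np.asarray(["A"] * n, dtype=object),
        alt=np.asarray(["G"] * n, dtype=object),
        annotated=(
            np.ones(n, dtype=bool) if annotated is None else np.asarray(annotated)
        ),
        genotypes=geno,
        gq=np.full((s, n), gq, dtype=np.int32),
        haplotypes=haps if phased else None,
        phased=phased,
    )


def make_genotype_cohort(
    geno: np.ndarray,
    gq: np.ndarray | None = None,
    annotated: np.ndarray | None = None,
    cm_per_site: float = 0.01,
) -> Cohort:
    """Unphased cohort directly from a (s, n) genotype matrix."""
    geno = np.asarray(geno, dtype=np.int8)
    s, n = geno.shape
    return Cohort(
        samples=[f"S{i + 1}" for i in range(s)],
        chrom=np.asarray(["1"] * n, dtype=object),
        pos_bp=1 + 100 * np.arange(n, dtype=np.int64),
        cm=cm_per_site * np.arange(n, dtype=float),
        ref=np.asarray(["A"] * n, dtype=object),
        alt=np.asarray(["G"] * n, dtype=object),
        annotated=(
            np.ones(n, dtype=bool) if annotated is None else np.asarray(annotated)
        ),
        genotypes=geno,
        gq=(
            np.full((s, n), 99, dtype=np.int32)
            if gq is None
            else np.asarray(gq, dtype=np.int32)
        ),
        haplotypes=None,
        phased=False,
    )


def random_cohort(
    rng: np.random.Generator,
    s: int,
    n: int,
    maf: float = 0.3,
    missing_rate: float = 0.0,
    copy_blocks: int = 0,
    block_len: int = 0,
) -> Cohort:
    """Random phased cohort, optionally with planted identical blocks.

    ``copy_blocks`` haplotype intervals of ``block_len`` markers are
    copied between random sample pairs to guarantee some seeds.
    """
    haps = (rng.random((s, 2, n)) < maf).astype(np.int8)
    for _ in range(copy_blocks):
        i, j = rng.choice(s, size=2, replace=False)
        a = int(rng.integers(0, max(1, n - block_len)))
        haps[j, 0, a: a + block_len] = haps[i, 0, a: a + block_len]
    if missing_rate > 0:
        mask = rng.random((s, 2, n)) < missing_rate
        haps[mask] = -1
    return make_cohort(haps)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
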