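"""Synthetic diploid cohorts with planted IBD and two ascertainment schemes.

The generator emulates the study design the detection and evaluation
code targets: one set of founder chromosomes is ascertained twice —

* *array*: markers at regular genetic spacing (dense, uniform coverage,
  SNP-array-like);
* *exome*: markers only inside simulated exon intervals whose per-cM
  count is overdispersed (negative-binomial), giving the highly
  irregular site density and multi-cM coverage gaps characteristic of
  hybrid-capture exome data.

Pairwise IBD=2 segments are planted by copying both haplotypes of a
donor onto a recipient over a genetic interval; the planted intervals
form the ground-truth segment set.  Per-platform genotype error, an
exome-only reference bias (true heterozygotes miscalled homozygous
reference), and a bimodal GQ model (low GQ for erroneous calls, high GQ
for correct calls) are applied after ascertainment.

Founder alleles are drawn independently per site from a 1/f-shaped
frequency spectrum; there is no background linkage disequilibrium, which
only inflates chance identity-by-state and is not needed to test
correctness.  Everything is deterministic given ``SimParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import Cohort, GeneticMap, MISSING
from .segments import IBDSegment, SegmentSet, write_match
from .vcfio import write_genetic_map, write_vcf

__all__ = [
    "ExonModel",
    "GQModel",
    "PlantedSegment",
    "SimParams",
    "draw_maf",
    "ascertain",
    "apply_errors",
    "simulate_cohort",
    "simulate_to_files",
]


@dataclass(frozen=True)
class ExonModel:
    """Exon-clustered site placement.

    Exon counts per 1-cM bin follow a negative binomial with mean
    ``exons_per_cm`` and shape ``dispersion`` (small shape = strong
    clumping, so some bins carry no exon at all and coverage gaps span
    several cM, as in real capture designs).  Sites inside an exon are
    placed every ``site_spacing_bp``.
    """

    exon_len_bp: int = 150
    exons_per_cm: float = 20.0
    dispersion: float = 0.35
    site_spacing_bp: int = 15


@dataclass(frozen=True)
class GQModel:
    """GQ ranges (inclusive) for erroneous and correct calls."""

    low: tuple[int, int] = (0, 39)
    high: tuple[int, int] = (40, 99)


@dataclass(frozen=True)
class PlantedSegment:
    """A ground-truth IBD=2 interval between two sample indices."""

    sample_i: int
    sample_j: int
    start_cm: float
    len_cm: float

    @property
    def end_cm(self) -> float:
        return self.start_cm + self.len_cm


@dataclass
class SimParams:
    """Study-design parameters for one simulated chromosome.

    Defaults describe the desk-scale regime used throughout the test
    suite: 20 samples on a 100 cM / 100 Mb chromosome, an array panel at
    300 sites/cM, an exon-clustered exome panel, and ten planted IBD=2
    segments of 5-20 cM between disjoint sample pairs.
    """

    s: int = 20
    chrom: str = "1"
    chrom_len_cm: float = 100.0
    chrom_len_bp: int = 100_000_000
    array_density: float = 300.0
    array_maf_min: float = 0.05
    pool_oversample: float = 5.0
    exon_model: ExonModel = field(default_factory=ExonModel)
    maf_dist: str = "one_over_f"       # or "uniform"
    maf_min: float = 0.005
    planted: list[PlantedSegment] | None = None
    n_planted: int = 10
    planted_len_range: tuple[float, float] = (5.0, 20.0)
    geno_error: float = 0.005
    ref_bias: float = 0.02
    gq_model: GQModel = field(default_factory=GQModel)
    novel_maf_cutoff: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimParams.seed is mandatory for reproducibility")
        for name in ("geno_error", "ref_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.s < 2:
            raise ValueError("need at least 2 samples")

    @property
    def bp_per_cm(self) -> float:
        return self.chrom_len_bp / self.chrom_len_cm

    def sample_names(self) -> list[str]:
        width = len(str(self.s))
        return [f"S{i + 1:0{width}d}" for i in range(self.s)]


def draw_maf(rng: np.random.Generator, n: int, dist: str, maf_min: float) -> np.ndarray:
    """Minor-allele frequencies from the named spectrum.

    ``one_over_f`` has density proportional to 1/f on [maf_min, 0.5]
    (neutral-spectrum-like: many rare, few common alleles);
    ``uniform`` is flat on the same range.
    """
    if dist == "one_over_f":
        u = rng.random(n)
        return maf_min * (0.5 / maf_min) ** u
    if dist == "uniform":
        return rng.uniform(maf_min, 0.5, size=n)
    raise ValueError(f"unknown maf distribution {dist!r}")


def _exon_intervals(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Sampled exon (start_bp, end_bp) intervals, sorted, shape (k, 2)."""
    em = params.exon_model
    n_bins = int(np.ceil(params.chrom_len_cm))
    r = em.dispersion
    p = r / (r + em.exons_per_cm)
    counts = rng.negative_binomial(r, p, size=n_bins)
    ivs = []
    bin_bp = params.bp_per_cm
    for b, cnt in enumerate(counts):
        if cnt == 0:
            continue
        lo = b * bin_bp
        hi = min((b + 1) * bin_bp, params.chrom_len_bp - em.exon_len_bp)
        if hi <= lo:
            continue
        starts = np.sort(rng.uniform(lo, hi, size=cnt))
        for s0 in starts:
            ivs.append((int(s0), int(s0) + em.exon_len_bp))
    return np.asarray(ivs, dtype=np.int64).reshape(-1, 2)


def _founder_positions(
    params: SimParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Founder site bp positions and the sampled exon intervals.

    The pool is the union of array-grid candidates (regular cM spacing,
    oversampled so the platform can skip rare-allele candidates) and
    exon-interior candidates, deduplicated and sorted.
    """
    n_array = int(round(params.chrom_len_cm * params.array_density * params.pool_oversample))
    grid_cm = (np.arange(n_array) + 0.5) * params.chrom_len_cm / n_array
    grid_bp = np.round(grid_cm * params.bp_per_cm).astype(np.int64)

    exons = _exon_intervals(params, rng)
    em = params.exon_model
    exon_bp = []
    for a, b in exons:
        phase = int(rng.integers(0, em.site_spacing_bp))
        exon_bp.extend(range(int(a) + phase, int(b), em.site_spacing_bp))
    pool = np.unique(np.concatenate([grid_bp, np.asarray(exon_bp, dtype=np.int64)]))
    pool = pool[(pool >= 1) & (pool <= params.chrom_len_bp)]
    return pool, exons


def ascertain(
    founder_bp: np.ndarray,
    scheme: str,
    params: SimParams,
    exon_intervals: np.ndarray | None = None,
    maf: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of the founder sites one platform observes.

    ``uniform`` picks, for each point of a regular cM grid at
    ``array_density`` sites/cM, the nearest founder site (deduplicated);
    when ``maf`` is given only sites with maf >= ``params.array_maf_min``
    are eligible, mirroring the common-SNP ascertainment of genotyping
    arrays.  ``exonic`` keeps exactly the founder sites inside the exon
    intervals (sequencing observes every variant it covers).
    """
    if scheme == "uniform":
        n = int(round(params.chrom_len_cm * params.array_density))
        eligible = np.arange(len(founder_bp))
        if maf is not None:
            eligible = np.flatnonzero(maf >= params.array_maf_min)
        if n > len(eligible):
            raise ValueError(
                f"requested {n} array sites but founder pool has only "
                f"{len(eligible)} eligible polymorphic sites"
            )
        cand_bp = founder_bp[eligible]
        targets = np.round(
            (np.arange(n) + 0.5) / params.array_density * params.bp_per_cm
        ).astype(np.int64)
        right = np.searchsorted(cand_bp, targets)
        left = np.clip(right - 1, 0, len(cand_bp) - 1)
        right = np.clip(right, 0, len(cand_bp) - 1)
        pick_right = np.abs(cand_bp[right] - targets) < np.abs(
            cand_bp[left] - targets
        )
        idx = np.where(pick_right, right, left)
        return eligible[np.unique(idx)]
    if scheme == "exonic":
        if exon_intervals is None:
            raise ValueError("exonic ascertainment requires exon intervals")
        if len(exon_intervals) == 0:
            return np.empty(0, dtype=np.int64)
        starts = exon_intervals[:, 0]
        ends = exon_intervals[:, 1]
        k = np.searchsorted(starts, founder_bp, side="right") - 1
        inside = (k >= 0) & (founder_bp < ends[np.clip(k, 0, None)])
        return np.flatnonzero(inside)
    raise ValueError(f"unknown ascertainment scheme {scheme!r}")


def _default_planted(params: SimParams, rng: np.random.Generator) -> list[PlantedSegment]:
    n = min(params.n_planted, params.s // 2)
    lo, hi = params.planted_len_range
    out = []
    for k in range(n):
        length = float(rng.uniform(lo, min(hi, params.chrom_len_cm)))
        start = float(rng.uniform(0.0, params.chrom_len_cm - length))
        out.append(PlantedSegment(2 * k, 2 * k + 1, start, length))
    return out


def _check_planted(planted: list[PlantedSegment], params: SimParams) -> None:
    for p in planted:
        if not (0 <= p.sample_i < params.s and 0 <= p.sample_j < params.s):
            raise ValueError(f"planted segment references sample outside cohort: {p}")
        if p.sample_i == p.sample_j:
            raise ValueError("planted segment needs two distinct samples")
        if p.start_cm < 0 or p.end_cm > params.chrom_len_cm:
            raise ValueError(f"planted segment outside chromosome: {p}")
    # copying rewrites the recipient's haplotypes, so any interval overlap
    # touching a shared sample is ambiguous and refused
    for a in range(len(planted)):
        for b in range(a + 1, len(planted)):
            pa, pb = planted[a], planted[b]
            shared = {pa.sample_i, pa.sample_j} & {pb.sample_i, pb.sample_j}
            if shared and pa.start_cm < pb.end_cm and pb.start_cm < pa.end_cm:
                raise ValueError(
                    f"planted segments {a} and {b} overlap on shared sample(s) "
                    f"{sorted(shared)}"
                )


def apply_errors(
    cohort: Cohort,
    geno_error: float,
    ref_bias: float,
    gq_model: GQModel,
    seed: int | np.random.Generator,
) -> Cohort:
    """Corrupt calls and assign GQ scores.

    Each call is replaced by a uniformly random *different* genotype
    state with probability ``geno_error``; surviving heterozygotes are
    additionally miscalled homozygous-reference with probability
    ``ref_bias`` (capture/alignment bias).  Erroneous calls draw GQ from
    the model's low range, correct calls from the high range.  Phase for
    an erroneously-heterozygous call is assigned at random.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = cohort.genotypes.copy()
    h = None if cohort.haplotypes is None else cohort.haplotypes.copy()
    shape = g.shape

    flip = (rng.random(shape) < geno_error) & (g != MISSING)
    # new state = one of the two others, chosen uniformly
    offset = rng.integers(1, 3, size=shape)
    g_flipped = (g + offset) % 3
    g = np.where(flip, g_flipped, g)

    bias = (rng.random(shape) < ref_bias) & (g == 1) & ~flip
    g = np.where(bias, 0, g)

    err = flip | bias
    lo, hi = gq_model.low, gq_model.high
    gq = np.where(
        err,
        rng.integers(lo[0], lo[1] + 1, size=shape),
        rng.integers(hi[0], hi[1] + 1, size=shape),
    ).astype(np.int32)

    if h is not None:
        het_flip = rng.integers(0, 2, size=shape)  # orientation for new hets
        changed = err
        h0 = h[:, 0, :]
        h1 = h[:, 1, :]
        h0 = np.where(changed, np.where(g == 1, het_flip, g // 2), h0)
        h1 = np.where(changed, np.where(g == 1, 1 - het_flip, g // 2), h1)
        h = np.stack([h0, h1], axis=1).astype(np.int8)

    return Cohort(
        samples=list(cohort.samples),
        chrom=cohort.chrom,
        pos_bp=cohort.pos_bp,
        cm=cohort.cm,
        ref=cohort.ref,
        alt=cohort.alt,
        annotated=cohort.annotated,
        genotypes=g.astype(np.int8),
        gq=gq,
        haplotypes=h,
        phased=cohort.phased and h is not None,
    )


_BASES = np.array(list("ACGT"))


def simulate_cohort(params: SimParams) -> tuple[Cohort, Cohort, SegmentSet]:
    """Generate (array_cohort, exome_cohort, truth) for one chromosome.

    The same founder chromosomes (with planted segments) underlie both
    cohorts; only the ascertained site panels and the error/bias models
    differ between platforms.
    """
    rng = np.random.default_rng(params.seed)
    pool_bp, exons = _founder_positions(params, rng)
    n = len(pool_bp)
    cm = pool_bp / params.bp_per_cm
    maf = draw_maf(rng, n, params.maf_dist, params.maf_min)

    haps = (rng.random((params.s, 2, n)) < maf).astype(np.int8)

    planted = params.planted
    if planted is None:
        planted = _default_planted(params, rng)
    _check_planted(planted, params)

    names = params.sample_names()
    truth = SegmentSet()
    for p in planted:
        a = int(np.searchsorted(cm, p.start_cm, side="left"))
        b = int(np.searchsorted(cm, p.end_cm, side="right"))
        haps[p.sample_j, :, a:b] = haps[p.sample_i, :, a:b]
        i, j = sorted((p.sample_i, p.sample_j))
        truth.add(
            IBDSegment(
                sample_i=names[i],
                sample_j=names[j],
                chrom=params.chrom,
                a_bp=max(1, int(round(p.start_cm * params.bp_per_cm))),
                b_bp=int(round(p.end_cm * params.bp_per_cm)),
                a_cm=p.start_cm,
                b_cm=p.end_cm,
                n_sites=b - a,
                metric="haplotype",
                source="truth",
            )
        )

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    # only sites polymorphic in the realized sample are callable variants
    alt_count = haps.sum(axis=(0, 1))
    poly = (alt_count > 0) & (alt_count < 2 * params.s)

    base = Cohort(
        samples=names,
        chrom=np.asarray([params.chrom] * n, dtype=object),
        pos_bp=pool_bp,
        cm=cm,
        ref=_BASES[ref_idx].astype(object),
        alt=_BASES[alt_idx].astype(object),
        annotated=maf >= params.novel_maf_cutoff,
        genotypes=(haps[:, 0, :] + haps[:, 1, :]).astype(np.int8),
        gq=np.zeros((params.s, n), dtype=np.int32),
        haplotypes=haps,
        phased=True,
    )

    array_idx = ascertain(pool_bp[poly], "uniform", params, maf=maf[poly])
    exome_idx = ascertain(pool_bp[poly], "exonic", params, exon_intervals=exons)
    poly_idx = np.flatnonzero(poly)
    array_mask = np.zeros(n, dtype=bool)
    array_mask[poly_idx[array_idx]] = True
    exome_mask = np.zeros(n, dtype=bool)
    exome_mask[poly_idx[exome_idx]] = True

    array_rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 1]))
    exome_rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 2]))
    array_cohort = apply_errors(
        base.subset_sites(array_mask), params.geno_error, 0.0, params.gq_model,
        array_rng,
    )
    exome_cohort = apply_errors(
        base.subset_sites(exome_mask), params.geno_error, params.ref_bias,
        params.gq_model, exome_rng,
    )
    return array_cohort, exome_cohort, truth


def genetic_map_for(params: SimParams) -> GeneticMap:
    """The (uniform) map underlying a simulation."""
    return GeneticMap(
        {params.chrom: [(0.0, 0.0), (float(params.chrom_len_bp), params.chrom_len_cm)]}
    )


def simulate_to_files(params: SimParams, outdir) -> dict[str, Path]:
    """Run the simulator and write array/exome VCFs, map and truth match."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    array_cohort, exome_cohort, truth = simulate_cohort(params)
    paths = {
        "array_vcf": outdir / "array.vcf",
        "exome_vcf": outdir / "exome.vcf",
        "map": outdir / "genetic_map.txt",
        "truth": outdir / "truth.match",
    }
    headers = [f"##simulation_seed={params.seed}"]
    write_vcf(array_cohort, paths["array_vcf"], extra_headers=headers)
    write_vcf(exome_cohort, paths["exome_vcf"], extra_headers=headers)
    write_genetic_map(genetic_map_for(params), paths["map"])
    write_match(truth, paths["truth"])
    return paths
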