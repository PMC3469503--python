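# Methods

## Detection model

Detection follows the hashing seed-and-extend paradigm for pairwise IBD in
population cohorts. Phased haplotypes over each chromosome are tiled into
non-overlapping slices of `bit_size` markers (the trailing remainder is
never seeded, but extension may run into it). Every haplotype word over a
full slice is hashed; words containing a missing call are omitted, since
exact identity cannot be asserted through missingness. Each dictionary
collision between haplotypes of two *different* samples is a seed, and the
seed set provably equals a brute-force all-pairs slice comparison (a test
enforces this against an independent dense implementation).

Runs of consecutive seeds for one (sample pair, haplotype pairing) are
extended outward slice by slice while the active metric's mismatch count
is ≤ `m`. The comparator is *at most* `m`, so `m = 0` demands exact
slices. The three metrics and the invariant they satisfy:

| metric | per-slice rule | phase handling |
| --- | --- | --- |
| genotype | mutually homozygous, non-missing sites that disagree | agnostic |
| haplotype | minimum mismatches over the 4 haplotype pairings | switching allowed between slices |
| haploid | mismatches on the seed's fixed pairing | no switching |

A mutually homozygous conflict mismatches all four pairings, and the fixed
pairing is one of the four, so for any seed the extended marker span nests:
haploid ⊆ haplotype ⊆ genotype. The suite asserts zero violations on
random cohorts.

Missing calls never count as mismatches during extension (a sensitivity-
favouring choice, logged in the module documentation); they only block
seeding. In the first slice that exceeds the budget, the boundary is
refined marker by marker: the walk stops before the (m+1)-th mismatch and
the segment ends at the last compatible marker (for the haplotype metric,
the pairing that reaches farthest wins). Sub-slice endpoints are an open
design point in this detection family; this rule is the package's choice
and is deterministic. Per pair, metric and chromosome, extended intervals
that overlap or touch are unioned, and only merged segments of genetic
length ≥ `min_len_cm` are reported. Segment endpoints are the physical
positions of the first and last marker inside the span (closed interval);
marker indices are 0-based half-open internally, bp positions 1-based as
in VCF.

Defaults: `bit_size=50`, `m=0`, `metric="haplotype"`, `min_len_cm=3.0`
(the detection literature sweeps reporting thresholds well above this;
3 cM keeps the raw output inspectable while the evaluation layer applies
stricter filters), `min_seeds=1`.

Haplotype-word seeding requires phased input. Phase-aware metrics refuse
unphased cohorts rather than guessing phase; how exome callsets acquire
phase is outside this package's scope (no phasing algorithm is included).

## Overlap evaluation

α(π, **IBD**′) is the genetic length of interval π intersected with the
*union* of the other set's intervals for the same sample pair, so shared
mass is never double-counted. Specificity pools Σα over all pairs and
exome intervals divided by total exome length; sensitivity is the
transpose. Pooling (rather than averaging per-pair ratios) is the default
because the quantities are length-weighted proportions of segment mass;
a `per_pair=True` mode computes the unweighted mean of per-pair ratios
instead. For canonical (per-pair non-overlapping) sets the two directions
satisfy spec(A,B)·len(A) = sens(A,B)·len(B), which the suite checks.
Undefined ratios (empty denominator set) are NaN, never 0. Lengths are
measured in cM because the thresholds of interest are genetic; a bp mode
exists for diagnostics.

`filter_segments` keeps segments with length ≥ `min_len_cm` and density
`n_sites / len_cm` ≥ `min_density`; zero-cM segments count as infinitely
dense and are kept (and logged). The filters commute and are idempotent.
`grid_search` sweeps (bit_size, m, metric) × (length, density) thresholds
and emits one table row per cell, detection being run once per parameter
triple.

## Concordance and its baseline

For an interval (a, b) between samples (i, j), a site qualifies when both
calls are non-missing homozygous and at least one is homozygous-variant
(w(n) = 1); it is concordant when the two alleles agree (z(n) = 1, i.e.
both homozygous-variant). Interval concordance is Σzw/Σw; the reported
value is the *unweighted* mean over intervals with Σw > 0, ×100. Restricting
to variant-carrying sites avoids the reference-homozygous bulk of the
genome. A call below the GQ threshold at either member removes the site
from both sums for that pair. Sites can further be restricted to a class
(novel vs annotated) and to *exome-only* sites — those absent from the
array cohort's (chrom, pos) panel — so the validation uses only data that
played no part in detection.

The random baseline uses the observed homozygote carrier counts directly
(no Hardy–Weinberg assumption): over unordered random pairs,
q(n) = [C(h,2) − C(h_ref,2)]/C(s,2) with h = h_ref + h_var is the
probability a pair qualifies and c(n) = C(h_var,2)/[C(h,2) − C(h_ref,2)]
the conditional concordance; the baseline is the q-weighted mean of c,
with q = 0 sites dropped. The without-replacement combinatorial form is
verified against a Monte-Carlo pair-sampling oracle in the suite. Carrier
counts are recomputed after GQ masking, so the baseline varies slightly
with the threshold, as it should.

The metric columns of the concordance table re-validate each interval
window by window under an extension metric — on the *validation cohort*
(the platform the segments were detected from, i.e. the array), never on
the exome calls being scored. Re-validating on the same calls at m = 0
would mechanically exclude every discordant mutually-homozygous site and
force 100% concordance, an information leak this design avoids. Windows
tile the validation panel in `bit_size` markers and own the bp range up
to the next window's first marker; exome sites in failing windows are
excluded. For the haploid column one pairing is held fixed across the
interval (the one passing the most windows). Because genotype-metric
mismatches are a subset of every pairing's mismatches, the surviving site
sets nest and the columns become increasingly stringent validations.

## Synthetic cohorts

The simulator emulates the study design the package targets: one set of
founder chromosomes observed by two platforms.

* **Founder sites.** A single chromosome (default 100 cM, 100 Mb, uniform
  map) carries a site pool that is the union of a regular genetic grid
  (5× oversampled relative to the array target density) and sites placed
  every 15 bp inside simulated exons. Minor-allele frequencies follow a
  1/f spectrum on [0.005, 0.5] (many rare, few common alleles); founder
  alleles are Bernoulli(maf) per haplotype. Only sites polymorphic in the
  realized sample enter either panel, as only those are callable variants.
* **Ascertainment contrast.** The *array* panel picks, for each point of a
  regular grid at 300 sites/cM, the nearest common site (MAF ≥ 0.05),
  mirroring the common-SNP design of genotyping arrays. The *exome* panel
  keeps every polymorphic site inside exons. Exon counts per 1-cM bin are
  negative-binomial (mean 20, shape 0.35, exons 150 bp), so counts are
  strongly overdispersed and some multi-cM stretches carry no site at all
  — the irregular coverage that makes slices span large genetic distances
  and lets chance identity-by-state masquerade as IBD.
* **Planted truth.** Ten IBD=2 segments (lengths uniform in 5–20 cM)
  between disjoint sample pairs, planted by copying both donor haplotypes
  onto the recipient; disjoint pairs prevent transitive sharing from
  contaminating the truth set. Overlapping planted intervals touching a
  shared sample are refused as ambiguous.
* **Errors and GQ.** Each call is replaced by a uniformly random other
  state with probability `geno_error` (default 0.005, both platforms);
  surviving heterozygotes are miscalled homozygous-reference with
  probability `ref_bias` (default 0.02, exome only — a capture/alignment
  artifact). Erroneous calls draw GQ uniformly from 0–39, correct calls
  from 40–99. The defaults are plausible placeholders, not estimates of
  any particular platform. Sites with MAF below 0.05 are labelled novel
  (rarity correlates strongly with absence from variant catalogues).

Everything is a deterministic function of `SimParams.seed`.

What the simulator does **not** model: background linkage disequilibrium
(founder alleles are independent per site), population structure,
coalescent segment-length distributions, read-level artifacts, IBD=1
(supported by planting a single haplotype, but off by default since the
homozygosity-concordance logic concerns two shared copies), or non-uniform
genetic maps (map non-uniformity is exercised by the interpolation tests
instead). Consequently, passing tests demonstrate the correctness of the
detection and evaluation machinery and reproduce the *direction* of the
sparse-ascertainment effects; absolute specificity/sensitivity values on
real exomes, where LD and shared ancestry inflate chance identity far
beyond independent-site levels, will differ.

## Numerical and degenerate-input choices

* Genetic-map interpolation is piecewise linear with constant
  extrapolation beyond the mapped range; a single-point map is constant.
* Zero-length (single-marker) extended spans are discarded; zero-cM
  segments pass density filters as infinitely dense.
* Undefined quantities (empty denominator sets, no qualifying site) are
  NaN and logged, never silently 0.
* Ties in best-pairing selection resolve to the first pairing in the fixed
  order (0,0), (0,1), (1,0), (1,1); all iteration is over sorted keys, so
  outputs are byte-deterministic for identical inputs.
* Missing GQ in a VCF loads as 0, so any positive threshold removes those
  calls.

## Problem sizes

The suite and the acceptance script run at desk scale: 20 samples on one
100 cM chromosome (~30k array / ~14k exome sites), brute-force oracle
cohorts up to 20 samples × 5000 markers, and Monte-Carlo baselines at
2–3 × 10⁴ draws. These sizes make every pipeline stage's behaviour visible
while keeping a full run in well under a minute per stage. The density
sweep's specificity gain concentrates between thresholds 0 and 60
sites/cM; beyond that, once essentially only true segments remain, the
tail of the curve is limited by sampling noise at this scale.
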