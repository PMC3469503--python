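# ibdslice

Seed-and-extend detection of identity-by-descent (IBD) segments in diploid
genotype data, built to study how well the approach transfers from dense,
uniform SNP-array panels to sparse, exon-clustered whole-exome panels — and
to quantify the damage with length-weighted overlap metrics, site-density
filtering, and homozygous-variant concordance against an analytic
random-pair baseline.

## Who this is for

Population and statistical geneticists who detect pairwise IBD in cohorts
of nominally unrelated individuals and want to know (a) how a
GERMLINE-style hashing detector behaves on exome-ascertained variants, and
(b) how to validate putative segments with an orthogonal platform's calls.
Everything runs on synthetic cohorts with planted ground truth, so the
entire pipeline is testable end to end without access data.

## The method

**Detection.** Each chromosome's phased haplotypes are cut into
non-overlapping *slices* of `bit_size` consecutive markers. Exact
allele-string matches between haplotypes of different samples within a
slice (*seeds*) are found by hashing the slice words into a dictionary.
Seeds are extended outward slice by slice while the per-slice mismatch
count stays ≤ *m*, under one of three increasingly restrictive metrics:

* **genotype** — only sites where both samples are homozygous may
  mismatch (phase-agnostic);
* **haplotype** — the best of the four haplotype pairings must fit the
  budget; the best pairing may switch between slices;
* **haploid** — the seed's haplotype pairing is held fixed over the whole
  segment.

The boundary inside the first failing slice is refined marker by marker,
and per pair the overlapping or adjacent extended intervals are merged.
Segments shorter than `min_len_cm` centimorgans are dropped.

**Overlap evaluation.** With segments **IBD**(i,j) from two platforms and
α(π, **IBD**′) the genetic length of interval π intersected with the union
of another set's intervals,

    specificity = Σ α(π, IBD_array) / Σ length(π)   over π ∈ IBD_exome
    sensitivity = Σ α(π, IBD_exome) / Σ length(π)   over π ∈ IBD_array

pooled over all sample pairs — the proportion of exome-reported segment
mass consistent with the array, and the proportion of array segment mass
the exome recovers. Segments can additionally be filtered by genetic
length and by marker density (sites/cM).

**Concordance.** For sites inside a putative segment where both samples
are homozygous and at least one carries the variant (selector *w(n)*),
concordance is the fraction with identical alleles, averaged per interval.
The expected value between *random* pairs is computed from the observed
homozygote carrier counts h_ref(n), h_var(n) in *s* samples:

    q(n) = [C(h_ref+h_var, 2) − C(h_ref, 2)] / C(s, 2)
    c(n) = C(h_var, 2) / [C(h_ref+h_var, 2) − C(h_ref, 2)]
    baseline = 100 × Σ q(n) c(n) / Σ q(n)

using homozygote frequencies directly, with no Hardy–Weinberg assumption.
Both observed and expected concordance are stratified by genotype-quality
(GQ) threshold and by whether a site is in a reference variant catalogue
(annotated) or novel.

## Worked example

```python
from ibdslice import (
    SimParams, simulate_cohort, DetectParams, detect_ibd,
    specificity, sensitivity, filter_segments,
)

params = SimParams(seed=1, geno_error=0.0, ref_bias=0.0)
array_cohort, exome_cohort, truth = simulate_cohort(params)
print("array sites:", array_cohort.n_sites, "exome sites:", exome_cohort.n_sites)

det = DetectParams(bit_size=10, m=0, metric="haplotype", min_len_cm=3.0)
exome_ibd = detect_ibd(exome_cohort, det)
print("exome segments:", len(exome_ibd))
print("specificity vs truth: %.3f" % specificity(exome_ibd, truth))
print("sensitivity vs truth: %.3f" % sensitivity(exome_ibd, truth))

dense = filter_segments(exome_ibd, min_density=130.0)
print("after density >= 130 sites/cM: %d segments, specificity %.3f, sensitivity %.3f"
      % (len(dense), specificity(dense, truth), sensitivity(dense, truth)))
```

Output:

```
array sites: 29785 exome sites: 14458
exome segments: 279
specificity vs truth: 0.097
sensitivity vs truth: 0.987
after density >= 130 sites/cM: 6 segments, specificity 0.966, sensitivity 0.526
```

The 20-sample, 100 cM cohort carries ten planted IBD=2 segments. On the
exon-clustered exome panel, 10-marker seeds spanning coverage gaps produce
hundreds of spurious segments, so only ~10% of the reported segment mass
is real even though nearly all true mass is found. Requiring ≥ 130
sites/cM discards the sparse false segments: specificity jumps to 0.97
while sensitivity falls to 0.53 — the sparse-data specificity/sensitivity
tradeoff this package exists to measure. The same detector on the uniform
array panel reaches specificity ≈ 0.998 with every planted segment
recovered essentially exactly.

The same workflow is available from the shell:

```bash
ibdslice simulate --config sim.yaml --out-dir sim/
ibdslice detect --vcf sim/exome.vcf --map sim/genetic_map.txt \
    --bit-size 10 --mismatch 0 --metric haplotype --min-cm 3 --out exome.match
ibdslice overlap --exome exome.match --array sim/truth.match
ibdslice concord --match sim/truth.match --vcf sim/exome.vcf \
    --map sim/genetic_map.txt --array-vcf sim/array.vcf --out table.tsv
```

## Layout

| module | contents |
| --- | --- |
| `ibdslice.cohort` | marker sites, diploid cohorts, genetic maps, slices |
| `ibdslice.vcfio` | VCF reader (cyvcf2) / writer, genetic-map readers |
| `ibdslice.segments` | IBD segments, segment sets, match-format I/O |
| `ibdslice.detect` | seed dictionary, extension metrics, full detection |
| `ibdslice.overlap` | α overlap, specificity/sensitivity, filters, grid search |
| `ibdslice.concordance` | homozygous-variant concordance and random baseline |
| `ibdslice.simulate` | planted-IBD simulator with array/exome ascertainment |
| `ibdslice.cli` | `ibdslice` command: simulate/detect/overlap/concord/grid |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
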