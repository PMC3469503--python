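"""Seed dictionary, seed finding, extension metrics and full detection."""

import numpy as np
import pytest

from ibdslice.cohort import Slice
from ibdslice.detect import (
    DetectParams,
    SeedMatch,
    build_dictionary,
    detect_ibd,
    extend_seed,
    extend_slice_ok,
    find_seeds,
)
from ibdslice.segments import write_match

from conftest import make_cohort, random_cohort
from oracles import brute_force_seeds


class TestBuildDictionary:
    def test_duplicate_word_shares_entry(self):
        haps = np.array(
            [[[0, 1, 0, 1], [0, 1, 0, 1]], [[1, 1, 1, 1], [0, 0, 0, 0]]],
            dtype=np.int8,
        )
        words = build_dictionary(make_cohort(haps), Slice("1", 0, 4))
        assert sorted(map(len, words.values())) == [1, 1, 2]

    def test_all_distinct_words_single_entries(self):
        haps = np.array(
            [[[0, 0], [0, 1]], [[1, 0], [1, 1]]], dtype=np.int8
        )
        words = build_dictionary(make_cohort(haps), Slice("1", 0, 2))
        assert len(words) == 4
        assert all(len(v) == 1 for v in words.values())

    def test_missing_call_omits_haplotype(self):
        haps = np.zeros((3, 2, 4), dtype=np.int8)
        haps[0, 1, 2] = -1
        words = build_dictionary(make_cohort(haps), Slice("1", 0, 4))
        assert sum(len(v) for v in words.values()) == 2 * 3 - 1


class TestFindSeeds:
    def test_planted_identity_yields_consecutive_seeds(self, rng):
        cohort = random_cohort(rng, s=4, n=100, maf=0.5)
        haps = cohort.haplotypes.copy()
        haps[1, 0, 30:80] = haps[0, 0, 30:80]  # slices 3..7 at bit 10
        cohort = make_cohort(haps)
        seeds = find_seeds(cohort, DetectParams(bit_size=10))
        planted = [
            s.slice_index for s in seeds
            if (s.sample_i, s.sample_j, s.hap_i, s.hap_j) == ("S1", "S2", 0, 0)
        ]
        assert set(planted) >= {3, 4, 5, 6, 7}

    def test_unrelated_bit50_no_seeds_matches_brute_force(self, rng):
        cohort = random_cohort(rng, s=2, n=500, maf=0.5)
        seeds = find_seeds(cohort, DetectParams(bit_size=50))
        assert set(seeds) == brute_force_seeds(cohort, 50)
        assert seeds == []

    @pytest.mark.parametrize("bit_size", [10, 50])
    @pytest.mark.parametrize("missing_rate", [0.0, 0.02])
    def test_equals_brute_force_oracle(self, rng, bit_size, missing_rate):
        cohort = random_cohort(
            rng, s=12, n=2000, maf=0.2, missing_rate=missing_rate,
            copy_blocks=5, block_len=300,
        )
        seeds = find_seeds(cohort, DetectParams(bit_size=bit_size))
        assert set(seeds) == brute_force_seeds(cohort, bit_size)
        assert len(seeds) == len(set(seeds))


class TestExtendSliceOk:
    def _cohort_identical_pairing(self):
        # pair identical on hap 0/0, rest random-ish but fixed
        haps = np.array(
            [[[0, 1, 0, 1], [1, 1, 0, 0]], [[0, 1, 0, 1], [0, 0, 1, 1]]],
            dtype=np.int8,
        )
        return make_cohort(haps)

    def test_identical_pairing_passes_all_metrics(self):
        cohort = self._cohort_identical_pairing()
        slc = Slice("1", 0, 4)
        for metric in ("genotype", "haplotype", "haploid"):
            ok, _ = extend_slice_ok(
                cohort, ("S1", "S2"), (0, 0), slc, metric, m=0
            )
            assert ok, metric

    def test_mutually_homozygous_conflict_fails_all_metrics(self):
        # one site 0/0 vs 1/1; such a site mismatches every pairing
        haps = np.array(
            [[[0, 0], [0, 0]], [[0, 1], [0, 1]]], dtype=np.int8
        )
        cohort = make_cohort(haps)
        slc = Slice("1", 0, 2)
        for metric in ("genotype", "haplotype", "haploid"):
            ok, _ = extend_slice_ok(cohort, ("S1", "S2"), (0, 0), slc, metric, m=0)
            assert not ok, metric
        # tolerated with a budget of one
        for metric in ("genotype", "haplotype", "haploid"):
            ok, _ = extend_slice_ok(cohort, ("S1", "S2"), (0, 0), slc, metric, m=1)
            assert ok, metric

    def test_het_phase_conflict_passes_genotype_fails_haplotype(self):
        # both samples het at every site with alternating phase: no
        # mutually homozygous site, but every pairing mismatches twice
        haps = np.array(
            [[[0, 1], [1, 0]], [[0, 0], [1, 1]]], dtype=np.int8
        )
        cohort = make_cohort(haps)
        slc = Slice("1", 0, 2)
        ok_g, _ = extend_slice_ok(cohort, ("S1", "S2"), None, slc, "genotype", m=0)
        ok_h, _ = extend_slice_ok(cohort, ("S1", "S2"), None, slc, "haplotype", m=0)
        assert ok_g and not ok_h

    def test_haploid_requires_pairing(self):
        cohort = self._cohort_identical_pairing()
        with pytest.raises(ValueError):
            extend_slice_ok(cohort, ("S1", "S2"), None, Slice("1", 0, 4), "haploid", 0)

    def test_missing_never_counts_as_mismatch(self):
        haps = np.array(
            [[[0, -1], [0, -1]], [[0, 1], [0, 1]]], dtype=np.int8
        )
        cohort = make_cohort(haps)
        for metric in ("genotype", "haplotype", "haploid"):
            ok, _ = extend_slice_ok(
                cohort, ("S1", "S2"), (0, 0), Slice("1", 0, 2), metric, 0
            )
            assert ok, metric


class TestExtendSeed:
    def test_whole_chromosome_identical_spans_all_markers(self, rng):
        cohort = random_cohort(rng, s=3, n=95, maf=0.5)
        haps = cohort.haplotypes.copy()
        haps[1, 1] = haps[0, 0]
        cohort = make_cohort(haps)
        seeds = [
            s for s in find_seeds(cohort, DetectParams(bit_size=10))
            if (s.hap_i, s.hap_j) == (0, 1) and (s.sample_i, s.sample_j) == ("S1", "S2")
        ]
        seg = extend_seed(
            cohort, seeds[0],
            DetectParams(bit_size=10, metric="haploid", min_len_cm=0),
        )
        # spans all 95 markers including the trailing partial slice
        assert seg.n_sites == 95
        assert seg.a_bp == int(cohort.pos_bp[0])
        assert seg.b_bp == int(cohort.pos_bp[-1])

    def test_planted_region_recovered_within_one_slice(self, rng):
        n, bit = 1000, 10
        cohort = random_cohort(rng, s=4, n=n, maf=0.5)
        haps = cohort.haplotypes.copy()
        a, b = 300, 800  # planted identical haplotype interval
        haps[2, 0, a:b] = haps[0, 1, a:b]
        cohort = make_cohort(haps)
        params = DetectParams(bit_size=bit, metric="haploid", min_len_cm=0)
        seeds = [
            s for s in find_seeds(cohort, params)
            if (s.sample_i, s.sample_j, s.hap_i, s.hap_j) == ("S1", "S3", 1, 0)
        ]
        seg = extend_seed(cohort, seeds[len(seeds) // 2], params)
        got = (
            int(np.searchsorted(cohort.pos_bp, seg.a_bp)),
            int(np.searchsorted(cohort.pos_bp, seg.b_bp)) + 1,
        )
        assert got[0] <= a + bit and got[1] >= b - bit  # covers planted core
        assert got[0] >= a - bit and got[1] <= b + bit  # within one slice of truth

    def test_metric_spans_nest(self, rng):
        # haploid span <= haplotype span <= genotype span for every seed
        cohort = random_cohort(rng, s=8, n=1500, maf=0.3, copy_blocks=6,
                               block_len=400)
        base = dict(bit_size=10, m=0, min_len_cm=0)
        seeds = find_seeds(cohort, DetectParams(**base))
        assert seeds
        for seed in seeds[:50]:
            spans = {}
            for metric in ("haploid", "haplotype", "genotype"):
                seg = extend_seed(cohort, seed, DetectParams(metric=metric, **base))
                spans[metric] = (seg.a_bp, seg.b_bp)
            assert spans["haplotype"][0] <= spans["haploid"][0]
            assert spans["haplotype"][1] >= spans["haploid"][1]
            assert spans["genotype"][0] <= spans["haplotype"][0]
            assert spans["genotype"][1] >= spans["haplotype"][1]


class TestDetectIbd:
    def test_no_sharing_empty(self, rng):
        cohort = random_cohort(rng, s=4, n=600, maf=0.5)
        out = detect_ibd(cohort, DetectParams(bit_size=50, min_len_cm=0))
        assert len(out) == 0

    def test_planted_pair_found_and_merged(self, rng):
        cohort = random_cohort(rng, s=6, n=3000, maf=0.4)
        haps = cohort.haplotypes.copy()
        haps[3, 0, 500:2500] = haps[1, 0, 500:2500]
        cohort = make_cohort(haps)
        out = detect_ibd(cohort, DetectParams(bit_size=10, min_len_cm=1.0))
        segs = out.get("S2", "S4")
        assert len(segs) == 1
        assert segs[0].len_cm >= 19.0  # 2000 markers at 0.01 cM/marker

    def test_deterministic_byte_identical(self, rng, tmp_path):
        cohort = random_cohort(rng, s=10, n=2000, maf=0.3, copy_blocks=4,
                               block_len=600)
        params = DetectParams(bit_size=10, min_len_cm=0.5)
        p1, p2 = tmp_path / "a.match", tmp_path / "b.match"
        write_match(detect_ibd(cohort, params), p1)
        write_match(detect_ibd(cohort, params), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_raising_mismatch_budget_never_shortens(self, rng):
        cohort = random_cohort(rng, s=6, n=2000, maf=0.3, copy_blocks=4,
                               block_len=500)
        by_m = {}
        for m in (0, 1, 2):
            params = DetectParams(bit_size=10, m=m, min_len_cm=0)
            by_m[m] = detect_ibd(cohort, params)
        for m_small, m_big in ((0, 1), (1, 2)):
            for seg in by_m[m_small]:
                covering = [
                    s for s in by_m[m_big].get(seg.sample_i, seg.sample_j)
                    if s.a_bp <= seg.a_bp and s.b_bp >= seg.b_bp
                ]
                assert covering, (m_small, m_big, seg)

    def test_raising_min_len_never_adds(self, rng):
        cohort = random_cohort(rng, s=6, n=2000, maf=0.3, copy_blocks=6,
                               block_len=300)
        loose = detect_ibd(cohort, DetectParams(bit_size=10, min_len_cm=0))
        strict = detect_ibd(cohort, DetectParams(bit_size=10, min_len_cm=2.0))
        loose_keys = {(s.sample_i, s.sample_j, s.a_bp, s.b_bp) for s in loose}
        strict_keys = {(s.sample_i, s.sample_j, s.a_bp, s.b_bp) for s in strict}
        assert strict_keys <= loose_keys
        assert all(s.len_cm >= 2.0 for s in strict)

    def test_unphased_cohort_refused(self, rng):
        cohort = random_cohort(rng, s=4, n=200, maf=0.3)
        unphased = cohort.subset_sites(np.ones(200, dtype=bool))
        unphased.phased = False
        unphased.haplotypes = None
        with pytest.raises(ValueError, match="phased"):
            detect_ibd(unphased, DetectParams(bit_size=10))
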