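"""Homozygous-variant concordance and its analytic random baseline."""

import math

import numpy as np
import pytest

from ibdslice.concordance import (
    SiteCounts,
    baseline_concordance,
    carrier_counts,
    concordance,
    concordance_table,
    site_weight_w,
)
from ibdslice.segments import IBDSegment, SegmentSet

from conftest import make_genotype_cohort
from oracles import monte_carlo_baseline

HOM_REF, HET, HOM_VAR, MISS = 0, 1, 2, -1


class TestSiteWeight:
    @pytest.mark.parametrize(
        "ci, cj, expected",
        [
            (HOM_VAR, HOM_VAR, 1),
            (HOM_REF, HOM_REF, 0),   # no variant carrier
            (HOM_VAR, HET, 0),       # het is not homozygous
            (HOM_VAR, HOM_REF, 1),   # discordant but qualifying
            (HOM_REF, HOM_VAR, 1),
            (MISS, HOM_VAR, 0),
            (HET, HET, 0),
        ],
    )
    def test_two_clause_rule(self, ci, cj, expected):
        assert site_weight_w(ci, cj) == expected


def interval(pair, a_bp, b_bp, chrom="1"):
    return IBDSegment(
        sample_i=pair[0], sample_j=pair[1], chrom=chrom, a_bp=a_bp, b_bp=b_bp,
        a_cm=a_bp / 1e6, b_cm=b_bp / 1e6, n_sites=10, source="array",
    )


class TestConcordance:
    def test_half_concordant_interval(self):
        # 4 qualifying sites, 2 concordant -> 50%
        geno = np.array(
            [
                [HOM_VAR, HOM_VAR, HOM_VAR, HOM_REF, HET],
                [HOM_VAR, HOM_VAR, HOM_REF, HOM_VAR, HOM_VAR],
            ]
        )
        cohort = make_genotype_cohort(geno)
        segs = SegmentSet([interval(("S1", "S2"), 1, 401)])
        assert concordance(segs, cohort) == pytest.approx(50.0)

    def test_unweighted_interval_average(self):
        # interval A: 4 sites 2 concordant (50%); interval B: 2/2 (100%)
        geno = np.array(
            [
                [HOM_VAR, HOM_VAR, HOM_VAR, HOM_REF, HOM_VAR, HOM_VAR],
                [HOM_VAR, HOM_VAR, HOM_REF, HOM_VAR, HOM_VAR, HOM_VAR],
            ]
        )
        cohort = make_genotype_cohort(geno)
        segs = SegmentSet(
            [interval(("S1", "S2"), 1, 320), interval(("S1", "S2"), 380, 520)]
        )
        assert concordance(segs, cohort) == pytest.approx(75.0)

    def test_gq_threshold_masks_calls(self):
        geno = np.array([[HOM_VAR, HOM_VAR], [HOM_REF, HOM_VAR]])
        gq = np.array([[50, 50], [10, 50]])
        cohort = make_genotype_cohort(geno, gq=gq)
        segs = SegmentSet([interval(("S1", "S2"), 1, 200)])
        assert concordance(segs, cohort, gq_min=0) == pytest.approx(50.0)
        # the discordant site's low-GQ call is masked at GQ>=20
        assert concordance(segs, cohort, gq_min=20) == pytest.approx(100.0)

    def test_site_class_restriction(self):
        geno = np.array([[HOM_VAR, HOM_VAR], [HOM_REF, HOM_VAR]])
        annotated = np.array([False, True])
        cohort = make_genotype_cohort(geno, annotated=annotated)
        segs = SegmentSet([interval(("S1", "S2"), 1, 200)])
        assert concordance(segs, cohort, site_class="novel") == pytest.approx(0.0)
        assert concordance(segs, cohort, site_class="annotated") == pytest.approx(100.0)

    def test_no_qualifying_site_is_nan(self):
        geno = np.array([[HET, HET], [HET, HET]])
        cohort = make_genotype_cohort(geno)
        segs = SegmentSet([interval(("S1", "S2"), 1, 200)])
        assert math.isnan(concordance(segs, cohort))

    def test_metric_mask_requires_validation_cohort(self):
        geno = np.array([[HOM_VAR, HOM_VAR], [HOM_VAR, HOM_VAR]])
        cohort = make_genotype_cohort(geno)
        segs = SegmentSet([interval(("S1", "S2"), 1, 200)])
        with pytest.raises(ValueError, match="validation"):
            concordance(segs, cohort, metric="genotype")

    def test_failing_validation_window_excludes_sites(self):
        # validation platform shows a mutually homozygous conflict in the
        # first window, so the exome sites there are excluded
        val = make_genotype_cohort(
            np.array([[HOM_VAR, HOM_REF, HOM_VAR, HOM_VAR],
                      [HOM_REF, HOM_REF, HOM_VAR, HOM_VAR]])
        )
        exo = make_genotype_cohort(
            np.array([[HOM_VAR, HOM_VAR, HOM_VAR, HOM_VAR],
                      [HOM_REF, HOM_VAR, HOM_VAR, HOM_VAR]])
        )
        segs = SegmentSet([interval(("S1", "S2"), 1, 400)])
        raw = concordance(segs, exo)
        masked = concordance(
            segs, exo, metric="genotype", bit_size=2, m=0, validation_cohort=val
        )
        assert raw == pytest.approx(75.0)
        assert masked == pytest.approx(100.0)


class TestBaseline:
    def test_all_hom_var_is_certain(self):
        assert baseline_concordance([SiteCounts(0, 6, 6)]) == pytest.approx(100.0)

    def test_enumerated_two_two_case(self):
        # s=4, h_ref=2, h_var=2: C(2,2)/(C(4,2)-C(2,2)) = 1/5 -> 20%
        assert baseline_concordance([SiteCounts(2, 2, 4)]) == pytest.approx(20.0)

    def test_sites_without_qualifying_pairs_dropped(self):
        sites = [SiteCounts(4, 0, 6), SiteCounts(0, 6, 6)]
        assert baseline_concordance(sites) == pytest.approx(100.0)
        assert math.isnan(baseline_concordance([SiteCounts(4, 0, 6)]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SiteCounts(3, 3, 4)

    def test_matches_monte_carlo_oracle(self, rng):
        for trial in range(50):
            s = int(rng.integers(4, 30))
            n_sites = int(rng.integers(1, 12))
            h_ref = rng.integers(0, s + 1, size=n_sites)
            h_var = np.array([rng.integers(0, s - hr + 1) for hr in h_ref])
            sites = [SiteCounts(int(a), int(b), s) for a, b in zip(h_ref, h_var)]
            analytic = baseline_concordance(sites)
            mc, se = monte_carlo_baseline(h_ref, h_var, s, rng, n_draws=20_000)
            if math.isnan(analytic):
                assert math.isnan(mc)
                continue
            assert abs(analytic - mc) <= max(3 * se, 0.5), trial


class TestCarrierCounts:
    def test_gq_masking_changes_counts(self):
        geno = np.array([[HOM_VAR, HOM_REF], [HOM_VAR, HOM_VAR], [HET, HOM_REF]])
        gq = np.array([[50, 50], [10, 50], [50, 50]])
        cohort = make_genotype_cohort(geno, gq=gq)
        loose = carrier_counts(cohort, gq_min=0)
        strict = carrier_counts(cohort, gq_min=20)
        assert (loose[0].h_var, strict[0].h_var) == (2, 1)


class TestConcordanceTable:
    def test_shape_and_random_column_independence(self):
        geno = np.array([[HOM_VAR, HOM_VAR, HOM_REF], [HOM_VAR, HOM_REF, HOM_REF]])
        cohort = make_genotype_cohort(
            geno, annotated=np.array([True, False, True])
        )
        segs = SegmentSet([interval(("S1", "S2"), 1, 300)])
        table = concordance_table(
            segs, cohort, metrics=("random", "genotype"),
            validation_cohort=cohort, bit_size=3,
        )
        assert table.shape == (10, 2)
        # baseline is computed from carrier counts only: same per threshold
        # regardless of which metric columns are requested
        t2 = concordance_table(
            segs, cohort, metrics=("random",), validation_cohort=cohort
        )
        assert np.allclose(
            table["random"].to_numpy(), t2["random"].to_numpy(), equal_nan=True
        )
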