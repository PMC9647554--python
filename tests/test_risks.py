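"""Risk-composition formulas: hazard chaining, re-falls, care pathway,
period conversion, and full event profiles."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from insomnia_cea.risks import (
    annual_to_period_prob,
    baseline_annual_risk,
    compose_fall_hazard,
    event_risk,
    fall_outcome_split,
    fall_relative_effect,
    falls_per_faller,
    mvc_relative_effect,
    period_to_annual_prob,
    scale_rate_by_employment,
    weighted_event_or,
    wpa_relative_effect,
)


class TestComposeFallHazard:
    def test_lemborexant_chain(self):
        # 0.68 x 1.48 ~ 1 once rounded to two decimals
        assert compose_fall_hazard(0.68, 1.48) == pytest.approx(1.0064)
        assert round(compose_fall_hazard(0.68, 1.48), 2) == 1.01

    def test_suvorexant_chain(self):
        assert compose_fall_hazard(0.85, 1.48) == pytest.approx(1.258)
        assert round(compose_fall_hazard(0.85, 1.48), 2) == 1.26

    def test_identity(self):
        assert compose_fall_hazard(1.0, 1.0) == 1.0

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            compose_fall_hazard(0.0, 1.48)

    @given(st.floats(0.1, 5), st.floats(0.1, 5), st.floats(0.1, 5))
    def test_commutative_and_associative(self, a, b, c):
        assert compose_fall_hazard(a, b) == pytest.approx(
            compose_fall_hazard(b, a)
        )
        assert compose_fall_hazard(compose_fall_hazard(a, b), c) == pytest.approx(
            compose_fall_hazard(a, compose_fall_hazard(b, c))
        )


class TestWeightedEventOr:
    def test_published_weighting(self):
        assert weighted_event_or(0.207, 1.79) == pytest.approx(1.62647)
        assert round(weighted_event_or(0.207, 1.79), 2) == 1.63

    def test_all_responders_revert_to_baseline(self):
        assert weighted_event_or(1.0, 1.79) == 1.0

    def test_all_nonresponders_keep_or(self):
        assert weighted_event_or(0.0, 1.79) == 1.79

    @given(st.floats(0, 1), st.floats(0.1, 5))
    def test_convex_combination_bounds(self, r, orr):
        w = weighted_event_or(r, orr)
        assert min(1.0, orr) - 1e-12 <= w <= max(1.0, orr) + 1e-12


class TestFallsPerFaller:
    def test_anchor_reproduced(self):
        # at the anchor rate the published 1.957 (0.957 extra falls) returns
        for slope in (0.0, 2.0, 10.0):
            assert falls_per_faller(0.25, 0.25, 1.957, slope) == pytest.approx(1.957)
        assert falls_per_faller(0.25, 0.25, 1.957, 5.0) - 1 == pytest.approx(0.957)

    def test_zero_slope_is_constant(self):
        vals = {falls_per_faller(p, 0.25, 1.957, 0.0) for p in (0.0, 0.1, 0.9)}
        assert vals == {1.957}

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_linearity_where_floor_inactive(self, a, b):
        f = lambda p: falls_per_faller(p, 0.1, 5.0, 2.0)  # floor never binds
        assert f(a) + f(b) == pytest.approx(2 * f((a + b) / 2), rel=1e-9)

    def test_floor_at_one_fall(self):
        assert falls_per_faller(0.0, 0.5, 1.2, 100.0) == 1.0


class TestPeriodConversion:
    def test_zero_risk(self):
        assert annual_to_period_prob(0.0, 0.5) == 0.0

    def test_one_year_identity(self):
        assert annual_to_period_prob(0.37, 1.0) == pytest.approx(0.37)

    def test_half_year_value(self):
        assert annual_to_period_prob(0.2, 0.5) == pytest.approx(
            0.105573, abs=1e-6
        )

    def test_degenerate_certainty_warns(self):
        with pytest.warns(UserWarning):
            assert annual_to_period_prob(1.0, 0.5) == 1.0

    @given(st.floats(0.0, 0.99), st.floats(0.05, 5))
    def test_round_trip_inverse(self, p, T):
        assert period_to_annual_prob(
            annual_to_period_prob(p, T), T
        ) == pytest.approx(p, abs=1e-12)

    @given(st.floats(0.01, 0.95), st.floats(0.01, 0.95))
    def test_strictly_increasing_in_probability(self, p1, p2):
        if p1 != p2:
            lo, hi = sorted([p1, p2])
            assert annual_to_period_prob(lo, 0.5) < annual_to_period_prob(hi, 0.5)


class TestFallOutcomeSplit:
    def test_published_admission_cells(self):
        split = fall_outcome_split(0.56, 0.08, 0.32, 0.53)
        assert split.p_admit_nonfracture == pytest.approx(0.0256)
        assert split.p_admit_nonhip_fracture == pytest.approx(0.025568)
        assert split.p_admit_hip_fracture == pytest.approx(0.028832)
        # printed as 2.56, 2.56 and 2.88%
        assert round(100 * split.p_admit_nonfracture, 2) == 2.56
        assert round(100 * split.p_admit_nonhip_fracture, 2) == 2.56
        assert round(100 * split.p_admit_hip_fracture, 2) == 2.88

    def test_outpatient_and_no_care_remainders(self):
        split = fall_outcome_split(0.56, 0.08, 0.32, 0.53)
        assert split.p_outpatient == pytest.approx(0.48)
        assert split.p_no_care == pytest.approx(0.44)

    def test_no_admissions(self):
        split = fall_outcome_split(0.5, 0.0, 0.32, 0.53)
        assert split.p_admit == 0.0

    def test_admit_cannot_exceed_any_care(self):
        with pytest.raises(ValueError):
            fall_outcome_split(0.05, 0.08, 0.32, 0.53)

    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    )
    def test_partition_sums_to_one(self, p_care, admit_frac, nf, hip):
        p_admit = p_care * admit_frac
        split = fall_outcome_split(p_care, p_admit, nf, hip)
        total = (
            split.p_no_care + split.p_outpatient + split.p_admit_nonfracture
            + split.p_admit_nonhip_fracture + split.p_admit_hip_fracture
        )
        assert total == pytest.approx(1.0, abs=1e-12)
        assert split.p_admit == pytest.approx(p_admit, abs=1e-12)


class TestEmploymentScaling:
    def test_published_ratio(self):
        assert scale_rate_by_employment(0.04, 0.243) == pytest.approx(0.00972)

    def test_zero_rate(self):
        assert scale_rate_by_employment(0.0, 0.243) == 0.0


class TestStrategyEffects:
    def test_fall_effects(self, ref):
        assert fall_relative_effect("untreated", ref) == 1.48
        assert fall_relative_effect("lemborexant", ref) == pytest.approx(
            0.68 * 1.48
        )
        assert fall_relative_effect("suvorexant", ref) == pytest.approx(
            0.85 * 1.48
        )
        assert fall_relative_effect("zolpidem_ir", ref) == ref.value(
            "fall_effect_vs_general.zolpidem_ir"
        )

    def test_all_drugs_share_zolpidem_mvc_effect(self, ref):
        z = ref.value("or_mvc.zolpidem")
        for s in ("lemborexant", "suvorexant", "zolpidem_ir"):
            assert mvc_relative_effect(s, ref) == z
        assert mvc_relative_effect("untreated", ref) == 2.7

    def test_untreated_wpa_keeps_full_or(self, ref):
        assert wpa_relative_effect("untreated", ref) == 1.79

    def test_drug_wpa_is_response_weighted(self, ref):
        assert wpa_relative_effect("lemborexant", ref) == pytest.approx(
            0.207 + 0.793 * 1.79
        )

    def test_older_wpa_baseline_scaled_by_employment(self, ref):
        younger = baseline_annual_risk("wpa", "younger", ref)
        assert baseline_annual_risk("wpa", "older", ref) == pytest.approx(
            0.243 * younger
        )


class TestEventRisk:
    def test_composition_of_baseline_effect_and_horizon(self, ref):
        ps = ref.replace_values(
            {
                "baseline_annual_risk.fall.younger": 0.1,
                "rr_fall_untreated_vs_general": 2.0,
                "horizon_years": 0.5,
            }
        )
        prof = event_risk("untreated", "fall", "younger", ps)
        assert prof.period_probability == pytest.approx(1 - 0.8 ** 0.5)

    def test_zero_baseline_gives_zero_profile(self, ref):
        ps = ref.replace_values({"baseline_annual_risk.mvc.older": 0.0})
        prof = event_risk("suvorexant", "mvc", "older", ps)
        assert prof.period_probability == 0.0
        assert prof.expected_count_per_capita == 0.0
        assert prof.death_probability == 0.0

    def test_fall_count_includes_refalls(self, ref):
        prof = event_risk("untreated", "fall", "older", ref)
        assert prof.expected_count_per_capita >= prof.period_probability

    def test_fall_death_bounded_by_admission_fraction(self, ref):
        prof = event_risk("zolpidem_ir", "fall", "older", ref)
        admit_frac = ref.value("fall_care.p_admit")
        assert prof.death_probability <= admit_frac * prof.period_probability

    def test_risk_above_one_clipped(self, ref, caplog):
        ps = ref.replace_values(
            {"baseline_annual_risk.fall.older": 0.9,
             "fall_effect_vs_general.zolpidem_ir": 3.0}
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="insomnia_cea.risks"):
            with pytest.warns(UserWarning):  # degenerate-hazard conversion
                prof = event_risk("zolpidem_ir", "fall", "older", ps)
        assert prof.period_probability == 1.0
        assert any("clipping" in r.getMessage() for r in caplog.records)
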