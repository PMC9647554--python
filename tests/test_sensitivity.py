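"""Tornado analysis, threshold bisection, and probabilistic SA."""

import numpy as np
import pytest

from insomnia_cea.engine import evaluate_all
from insomnia_cea.metrics import compare
from insomnia_cea.sensitivity import (
    DEFAULT_PAIRS,
    one_way_analysis,
    psa_summary,
    run_psa,
    threshold_search,
)

PAIR_ZOLP = ("lemborexant", "zolpidem_ir")
PAIR_UNTR = ("lemborexant", "untreated")


class TestOneWayAnalysis:
    def test_entries_sorted_by_descending_span(self, ref):
        entries, _, _ = one_way_analysis(ref, PAIR_ZOLP)
        spans = [e.span for e in entries]
        assert spans == sorted(spans, reverse=True)
        assert len(entries) > 10

    def test_zero_influence_parameter_has_zero_span(self, ref):
        entries, _, _ = one_way_analysis(ref, ("suvorexant", "untreated"))
        by_id = {e.parameter_id: e for e in entries}
        # lemborexant's own fall hazard cannot move a comparison without it
        assert by_id["hr_fall_vs_untreated.lemborexant"].span == 0.0

    def test_dominant_base_uses_nmb_tradeoff_uses_icer(self, ref):
        _, _, metric_dom = one_way_analysis(ref, PAIR_ZOLP)
        _, _, metric_icer = one_way_analysis(ref, PAIR_UNTR)
        assert metric_dom == "nmb"
        assert metric_icer == "icer"

    def test_comparator_fall_risk_raises_nmb_monotonically(self, ref):
        pid = "fall_effect_vs_general.zolpidem_ir"
        entries, base, _ = one_way_analysis(ref, PAIR_ZOLP, outcome="nmb")
        e = {x.parameter_id: x for x in entries}[pid]
        # more comparator fall risk -> intervention looks better
        assert e.outcome_low < base < e.outcome_high

    def test_endpoints_bracket_base_for_monotone_parameter(self, ref):
        entries, base, _ = one_way_analysis(ref, PAIR_UNTR, outcome="icer")
        e = {x.parameter_id: x for x in entries}["visit_cost_jpy"]
        lo, hi = sorted([e.outcome_low, e.outcome_high])
        assert lo <= base <= hi


class TestThresholdSearch:
    def test_known_root_on_synthetic_linear_parameter(self, ref):
        """delta-cost is linear in the comparator's unit MVC cost; solve the
        crossing analytically and require bisection to match to 1e-6."""
        ps = ref.replace_values({"or_mvc.untreated": 2.7})
        res = evaluate_all(ps)
        comp = compare(res[PAIR_UNTR[0]], res[PAIR_UNTR[1]])
        count_int = res[PAIR_UNTR[0]].cost_breakdown["mvc"] / ps.value("cost.mvc")
        count_cmp = res[PAIR_UNTR[1]].cost_breakdown["mvc"] / ps.value("cost.mvc")
        # delta_cost(c) = comp.delta_cost + (count_int - count_cmp)*(c - c0)
        c0 = ps.value("cost.mvc")
        slope = count_int - count_cmp
        root = c0 - comp.delta_cost_jpy / slope
        assert 0 < root  # the crossing is physical
        found = threshold_search(
            ps, "cost.mvc", PAIR_UNTR, "delta_cost", (0.0, root * 3)
        )
        assert found == pytest.approx(root, rel=1e-5)

    def test_no_sign_change_returns_none(self, ref):
        assert (
            threshold_search(
                ref, "visit_cost_jpy", PAIR_ZOLP, "delta_cost", (700.0, 760.0)
            )
            is None
        )

    def test_root_satisfies_criterion(self, ref):
        thr = threshold_search(
            ref, "fall_effect_vs_general.zolpidem_ir", PAIR_ZOLP,
            "delta_cost", (1.0, 4.0),
        )
        assert thr is not None
        res = evaluate_all(ref.replace_values(
            {"fall_effect_vs_general.zolpidem_ir": thr}))
        comp = compare(res[PAIR_ZOLP[0]], res[PAIR_ZOLP[1]])
        assert abs(comp.delta_cost_jpy) < 1.0  # JPY, vs totals ~4e4

    def test_agrees_with_dense_grid_scan(self, ref):
        pid = "fall_effect_vs_general.zolpidem_ir"
        lo, hi = 1.0, 4.0
        thr = threshold_search(ref, pid, PAIR_ZOLP, "delta_cost", (lo, hi))
        grid = np.linspace(lo, hi, 1000)

        def f(x):
            res = evaluate_all(ref.replace_values({pid: x}))
            return compare(res[PAIR_ZOLP[0]], res[PAIR_ZOLP[1]]).delta_cost_jpy

        vals = np.array([f(x) for x in grid])
        sign_flip = np.where(np.diff(np.sign(vals)) != 0)[0]
        assert len(sign_flip) == 1
        assert grid[sign_flip[0]] <= thr <= grid[sign_flip[0] + 1]


class TestRunPsa:
    def test_same_seed_bitwise_identical(self, ref):
        a = run_psa(ref, n_draws=50, seed=11)
        b = run_psa(ref, n_draws=50, seed=11)
        for pid in a.parameter_draws:
            assert np.array_equal(a.parameter_draws[pid], b.parameter_draws[pid])
        for nm in a.delta_cost:
            assert np.array_equal(a.delta_cost[nm], b.delta_cost[nm])
            assert np.array_equal(a.delta_qaly[nm], b.delta_qaly[nm])

    def test_different_seeds_differ(self, ref):
        a = run_psa(ref, n_draws=20, seed=1)
        b = run_psa(ref, n_draws=20, seed=2)
        nm = next(iter(a.delta_cost))
        assert not np.array_equal(a.delta_cost[nm], b.delta_cost[nm])

    def test_all_degenerate_reproduces_base_case(self, ref):
        import dataclasses

        specs = {
            pid: dataclasses.replace(ref[pid], family="fixed") for pid in ref
        }
        from insomnia_cea.params import ParameterSet

        ps = ParameterSet(specs)
        res = evaluate_all(ps)
        base = {
            f"{a}_vs_{b}": compare(res[a], res[b]) for a, b in DEFAULT_PAIRS
        }
        psa = run_psa(ps, n_draws=25, seed=3)
        assert psa.parameter_draws == {}
        for nm in psa.delta_cost:
            assert np.all(psa.delta_cost[nm] == base[nm].delta_cost_jpy)
            assert np.all(psa.delta_qaly[nm] == base[nm].delta_qaly)

    def test_parameter_streams_independent_of_set_membership(self, ref):
        """Freezing one parameter does not perturb another's draws."""
        import dataclasses

        from insomnia_cea.params import ParameterSet

        specs = dict(ref)
        specs["cost.mvc"] = dataclasses.replace(ref["cost.mvc"], family="fixed")
        frozen_one = ParameterSet(specs)
        a = run_psa(ref, n_draws=30, seed=5)
        b = run_psa(frozen_one, n_draws=30, seed=5)
        assert "cost.mvc" not in b.parameter_draws
        assert np.array_equal(
            a.parameter_draws["cost.wpa"], b.parameter_draws["cost.wpa"]
        )

    def test_sample_mean_approaches_base_case_for_linear_parameters(self, ref):
        """With only symmetric (normal) uncertainty on parameters that enter
        the increments linearly, the PSA mean must converge on the base case
        (law of large numbers, 3 Monte-Carlo standard errors)."""
        import dataclasses

        from insomnia_cea.params import ParameterSet

        linear = {"cost.mvc", "disutility.mvc"}
        specs = {}
        for pid in ref:
            fam = "normal" if pid in linear else "fixed"
            specs[pid] = dataclasses.replace(ref[pid], family=fam)
        ps = ParameterSet(specs)
        n = 20_000
        psa = run_psa(ps, n_draws=n, seed=9)
        res = evaluate_all(ps)
        for a, b in DEFAULT_PAIRS:
            nm = f"{a}_vs_{b}"
            base = compare(res[a], res[b])
            for arr, target in (
                (psa.delta_cost[nm], base.delta_cost_jpy),
                (psa.delta_qaly[nm], base.delta_qaly),
            ):
                se = arr.std(ddof=1) / np.sqrt(n)
                # floor covers float accumulation when a comparison is
                # insensitive to the sampled parameter (zero-variance draw)
                atol = max(3 * se, 1e-9 * max(1.0, abs(target)))
                assert abs(arr.mean() - target) <= atol


class TestPsaSummary:
    def test_counting_oracle_four_samples(self, ref):
        from insomnia_cea.sensitivity import PSAResult

        r = PSAResult(seed=0, n_draws=4)
        r.delta_cost = {"x": np.array([-10.0, 5.0, 5.0, 5.0])}
        r.delta_qaly = {"x": np.array([0.01, 0.01, -0.01, 0.0])}
        s = psa_summary(r, wtp=1000.0, pair="x")
        assert s["p_cost_saving"] == 0.25
        assert s["p_cost_saving_marginal"] == 0.25
        # NMB: 20, 5, -15, -5 -> 2 of 4 positive
        assert s["p_cost_effective"] == 0.5

    def test_all_dominant_gives_unit_fractions(self):
        from insomnia_cea.sensitivity import PSAResult

        r = PSAResult(seed=0, n_draws=3)
        r.delta_cost = {"x": np.array([-1.0, -2.0, -3.0])}
        r.delta_qaly = {"x": np.array([0.1, 0.2, 0.3])}
        s = psa_summary(r, wtp=5e6, pair="x")
        assert s["p_cost_saving"] == 1.0
        assert s["p_cost_effective"] == 1.0

    def test_ceac_at_zero_wtp_is_cost_saving_fraction(self, ref):
        psa = run_psa(ref, n_draws=200, seed=4)
        s = psa_summary(psa, wtp=5e6, pair=DEFAULT_PAIRS[0])
        ceac = dict(s["ceac"])
        assert ceac[0.0] == s["p_cost_saving_marginal"]
        assert 5e6 in ceac and 0.0 in ceac
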