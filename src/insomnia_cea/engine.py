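"""Decision-tree evaluation: expected QALYs and costs per strategy.

Each strategy/age cell is evaluated over the model horizon ``T`` (0.5 years
by default, with no discounting below one year):

QALY  = u*T  - (1-r)*d*T  - sum_events E[count] * event disutility
              - P(death) * u * T/2

where ``u`` is the general-population utility norm (responders are assumed
to regain it), ``r`` the strategy's responder rate and ``d`` the insomnia
disutility borne by non-responders.  Event disutilities are one-off QALY
losses per event (already duration-integrated); deaths occur at the horizon
midpoint, losing half the period's utility.

Cost  = drug cost/day * 365.25*T  + visits/month * 12*T * visit fee
        + sum_events sum_outcomes E[count] * P(outcome) * outcome cost

all scaled so that decedents accrue time-based costs only to the midpoint.
Untreated insomnia accrues no drug or physician-visit cost.  Events are
independent across types; expectations add with no competing-risk
adjustment within the horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .params import AGE_GROUPS, EVENTS, STRATEGIES, ParameterSet
from .risks import EventRiskProfile, event_risk, fall_outcome_split

__all__ = [
    "DAYS_PER_YEAR",
    "StrategyResult",
    "expected_qaly",
    "expected_cost",
    "evaluate",
    "evaluate_all",
]

DAYS_PER_YEAR = 365.25

COST_COMPONENTS = ("drug", "visits", "fall", "mvc", "wpa")
QALY_DECREMENTS = ("insomnia", "fall", "mvc", "wpa", "death")


@dataclass(frozen=True)
class StrategyResult:
    """Expected cost (JPY), QALYs and component breakdown for one strategy."""

    strategy: str
    age_group: str  # "younger", "older" or "mixed"
    expected_cost_jpy: float
    expected_qaly: float
    death_probability: float
    cost_breakdown: dict = field(default_factory=dict)
    qaly_decrements: dict = field(default_factory=dict)
    event_profiles: dict = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.cost_breakdown.values())
        if abs(total - self.expected_cost_jpy) > 1e-6:
            raise ValueError(
                f"cost breakdown ({total}) does not sum to total "
                f"({self.expected_cost_jpy})"
            )


def _event_profiles(
    strategy: str, age_group: str, params: ParameterSet
) -> dict[str, EventRiskProfile]:
    return {ev: event_risk(strategy, ev, age_group, params) for ev in EVENTS}


def _fall_unit_cost(params: ParameterSet) -> float:
    """Expected treatment cost of one fall across the care pathway."""
    split = fall_outcome_split(
        params.value("fall_care.p_any_care"),
        params.value("fall_care.p_admit"),
        params.value("fall_care.admit_nonfracture_frac"),
        params.value("fall_care.fracture_hip_frac"),
    )
    return (
        split.p_outpatient * params.value("cost.fall_outpatient")
        + split.p_admit_nonfracture * params.value("cost.fall_admit_nonfracture")
        + split.p_admit_nonhip_fracture
        * params.value("cost.fall_admit_nonhip_fracture")
        + split.p_admit_hip_fracture * params.value("cost.fall_admit_hip_fracture")
    )


def _fall_unit_disutility(params: ParameterSet) -> float:
    """Expected one-off QALY loss per fall.

    Unattended, outpatient and non-fracture admissions all carry the plain
    fall disutility (the non-fracture admission is conservatively treated as
    an ordinary fall); fracture admissions carry their own decrements.
    """
    split = fall_outcome_split(
        params.value("fall_care.p_any_care"),
        params.value("fall_care.p_admit"),
        params.value("fall_care.admit_nonfracture_frac"),
        params.value("fall_care.fracture_hip_frac"),
    )
    d_fall = params.value("disutility.fall")
    return (
        (split.p_no_care + split.p_outpatient + split.p_admit_nonfracture) * d_fall
        + split.p_admit_nonhip_fracture * params.value("disutility.fracture_nonhip")
        + split.p_admit_hip_fracture * params.value("disutility.fracture_hip")
    )


def evaluate(strategy: str, age_group: str, params: ParameterSet) -> StrategyResult:
    """Evaluate one strategy for one age group."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age group {age_group!r}")

    T = params.value("horizon_years")
    u = params.value("utility_norm")
    r = params.value(f"response_rate.sSOL.{strategy}")
    d_insomnia = params.value("insomnia_disutility.sSOL")

    profiles = _event_profiles(strategy, age_group, params)
    death_p = min(1.0, sum(p.death_probability for p in profiles.values()))

    # --- QALYs -----------------------------------------------------------
    decrements = {
        "insomnia": (1.0 - r) * d_insomnia * T,
        "fall": profiles["fall"].expected_count_per_capita
        * _fall_unit_disutility(params),
        "mvc": profiles["mvc"].expected_count_per_capita
        * params.value("disutility.mvc"),
        "wpa": profiles["wpa"].expected_count_per_capita
        * params.value("disutility.wpa"),
        "death": death_p * u * T / 2.0,
    }
    qaly = u * T - sum(decrements.values())
    if qaly < 0.0:
        warnings.warn(
            f"expected QALY for {strategy}/{age_group} is negative; flooring at 0",
            stacklevel=2,
        )
        qaly = 0.0

    # --- costs -----------------------------------------------------------
    # decedents accrue time-based (drug + visit) costs to the horizon midpoint
    time_factor = 1.0 - 0.5 * death_p
    if strategy == "untreated":
        drug_cost = 0.0
        visit_cost = 0.0
    else:
        drug_cost = (
            params.value(f"drug_cost_per_day.{strategy}")
            * DAYS_PER_YEAR
            * T
            * time_factor
        )
        visit_cost = (
            params.value("visit_frequency_per_month")
            * 12.0
            * T
            * params.value("visit_cost_jpy")
            * time_factor
        )
    breakdown = {
        "drug": drug_cost,
        "visits": visit_cost,
        "fall": profiles["fall"].expected_count_per_capita * _fall_unit_cost(params),
        "mvc": profiles["mvc"].expected_count_per_capita * params.value("cost.mvc"),
        "wpa": profiles["wpa"].expected_count_per_capita * params.value("cost.wpa"),
    }

    return StrategyResult(
        strategy=strategy,
        age_group=age_group,
        expected_cost_jpy=sum(breakdown.values()),
        expected_qaly=qaly,
        death_probability=death_p,
        cost_breakdown=breakdown,
        qaly_decrements=decrements,
        event_profiles=profiles,
    )


def expected_qaly(strategy: str, age_group: str, params: ParameterSet) -> float:
    """Expected QALYs over the horizon for one strategy/age cell."""
    return evaluate(strategy, age_group, params).expected_qaly


def expected_cost(strategy: str, age_group: str, params: ParameterSet) -> float:
    """Expected direct medical cost (JPY) for one strategy/age cell."""
    return evaluate(strategy, age_group, params).expected_cost_jpy


def _mix(results: dict[str, StrategyResult], weights: dict[str, float],
         strategy: str) -> StrategyResult:
    """Population-weighted (convex) combination of per-age results."""
    cost_bd = {
        k: sum(weights[a] * results[a].cost_breakdown[k] for a in weights)
        for k in COST_COMPONENTS
    }
    qaly_dec = {
        k: sum(weights[a] * results[a].qaly_decrements[k] for a in weights)
        for k in QALY_DECREMENTS
    }
    return StrategyResult(
        strategy=strategy,
        age_group="mixed",
        expected_cost_jpy=sum(cost_bd.values()),
        expected_qaly=sum(weights[a] * results[a].expected_qaly for a in weights),
        death_probability=sum(
            weights[a] * results[a].death_probability for a in weights
        ),
        cost_breakdown=cost_bd,
        qaly_decrements=qaly_dec,
        event_profiles={a: results[a].event_profiles for a in weights},
    )


def evaluate_all(
    params: ParameterSet, age_group: str | None = None
) -> dict[str, StrategyResult]:
    """Evaluate every strategy.

    With ``age_group=None`` each strategy's result is the population-weighted
    average of the per-age evaluations; otherwise the named subgroup is
    evaluated on its own.
    """
    if age_group is not None:
        return {s: evaluate(s, age_group, params) for s in STRATEGIES}
    weights = {a: params.value(f"age_weight.{a}") for a in AGE_GROUPS}
    out: dict[str, StrategyResult] = {}
    for s in STRATEGIES:
        per_age = {a: evaluate(s, a, params) for a in AGE_GROUPS}
        out[s] = _mix(per_age, weights, s)
    return out
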