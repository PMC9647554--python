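"""Event-risk composition: falls, motor vehicle collisions, workplace accidents.

The model layers published relative effects onto age-specific baseline annual
risks in the general (good-sleeper) population:

* falls — hazard ratios for the drug vs untreated insomnia are chained onto
  the relative risk of untreated insomnia vs the general population
  (e.g. 0.68 x 1.48 for the best-performing hypnotic); a regression-derived
  re-fall term converts the probability of being a faller into an expected
  number of falls per capita;
* motor vehicle collisions (MVC) — untreated insomnia carries its own odds
  ratio; all three drugs share the zolpidem-derived effect, the only one
  with published driving data;
* workplace accidents (WPA) — the non-responder odds ratio is averaged with
  1.0 in proportion to the strategy's responder rate (untreated insomnia has
  responder rate 0, so it keeps the full odds ratio), and the older group's
  baseline is scaled by the employment ratio.

Odds and hazard ratios are applied multiplicatively to baseline
probabilities, which is adequate at the small baseline risks involved.
Annual probabilities are converted to the model horizon under a
constant-hazard assumption.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from .params import AGE_GROUPS, EVENTS, STRATEGIES, ParameterSet

__all__ = [
    "EventRiskProfile",
    "FallOutcomeSplit",
    "compose_fall_hazard",
    "weighted_event_or",
    "falls_per_faller",
    "annual_to_period_prob",
    "period_to_annual_prob",
    "fall_outcome_split",
    "scale_rate_by_employment",
    "fall_relative_effect",
    "mvc_relative_effect",
    "wpa_relative_effect",
    "baseline_annual_risk",
    "event_risk",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EventRiskProfile:
    """Per-capita risk of one event type for one strategy and age group."""

    event: str
    strategy: str
    age_group: str
    period_probability: float  # probability of >=1 event over the horizon
    expected_count_per_capita: float  # events per capita over the horizon
    death_probability: float  # probability of dying of the event

    def __post_init__(self):
        if not 0.0 <= self.period_probability <= 1.0:
            raise ValueError("period_probability must lie in [0, 1]")
        if self.death_probability > self.period_probability + 1e-15:
            raise ValueError("death_probability cannot exceed period_probability")


@dataclass(frozen=True)
class FallOutcomeSplit:
    """Care-pathway partition conditional on a fall having occurred."""

    p_no_care: float
    p_outpatient: float
    p_admit_nonfracture: float
    p_admit_nonhip_fracture: float
    p_admit_hip_fracture: float

    def __post_init__(self):
        total = (
            self.p_no_care
            + self.p_outpatient
            + self.p_admit_nonfracture
            + self.p_admit_nonhip_fracture
            + self.p_admit_hip_fracture
        )
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"fall outcome split must sum to 1, got {total!r}")

    @property
    def p_admit(self) -> float:
        """Total hospitalization fraction among fallers."""
        return (
            self.p_admit_nonfracture
            + self.p_admit_nonhip_fracture
            + self.p_admit_hip_fracture
        )


def compose_fall_hazard(
    hr_drug_vs_untreated: float, rr_untreated_vs_general: float
) -> float:
    """Chain a drug-vs-untreated hazard ratio onto the untreated-vs-general
    relative risk, giving the drug's fall effect vs the general population.

    No rounding is applied here; reporting rounds to two decimals.
    """
    if hr_drug_vs_untreated <= 0 or rr_untreated_vs_general <= 0:
        raise ValueError("relative effects must be > 0")
    return hr_drug_vs_untreated * rr_untreated_vs_general


def weighted_event_or(response_rate: float, or_nonresponder: float) -> float:
    """Responder-weighted odds ratio: responders revert to baseline risk
    (OR 1), non-responders keep ``or_nonresponder``."""
    if not 0.0 <= response_rate <= 1.0:
        raise ValueError("response_rate must lie in [0, 1]")
    if or_nonresponder <= 0:
        raise ValueError("or_nonresponder must be > 0")
    return response_rate * 1.0 + (1.0 - response_rate) * or_nonresponder


def falls_per_faller(
    p_faller: float, anchor_rate: float, anchor_falls: float, slope: float
) -> float:
    """Mean falls per faller as a linear function of the annual faller
    proportion, anchored at the survey estimate and floored at one fall."""
    if anchor_falls < 1.0:
        raise ValueError("anchor_falls must be >= 1")
    return max(1.0, anchor_falls + slope * (p_faller - anchor_rate))


def annual_to_period_prob(p_annual: float, horizon_years: float) -> float:
    """Constant-hazard conversion of an annual probability to the horizon:
    ``1 - (1 - p)**T``."""
    if horizon_years <= 0:
        raise ValueError("horizon_years must be > 0")
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError("p_annual must lie in [0, 1]")
    if p_annual == 1.0:
        warnings.warn(
            "annual probability of 1 has no finite hazard; period probability is 1",
            stacklevel=2,
        )
        return 1.0
    return 1.0 - (1.0 - p_annual) ** horizon_years


def period_to_annual_prob(p_period: float, horizon_years: float) -> float:
    """Inverse of :func:`annual_to_period_prob`."""
    if horizon_years <= 0:
        raise ValueError("horizon_years must be > 0")
    if not 0.0 <= p_period < 1.0:
        raise ValueError("p_period must lie in [0, 1)")
    return 1.0 - (1.0 - p_period) ** (1.0 / horizon_years)


def fall_outcome_split(
    p_any_care: float,
    p_admit: float,
    admit_nonfracture_frac: float,
    fracture_hip_frac: float,
) -> FallOutcomeSplit:
    """Partition fallers into no-care, outpatient-only, and three admission
    categories (non-fracture / non-hip fracture / hip fracture).

    ``p_any_care`` is the fraction of fallers receiving any medical care and
    ``p_admit`` (a subset) the fraction admitted; admissions split into
    non-fractures vs fractures, and fractures into non-hip vs hip.
    """
    for name, v in (
        ("p_any_care", p_any_care),
        ("p_admit", p_admit),
        ("admit_nonfracture_frac", admit_nonfracture_frac),
        ("fracture_hip_frac", fracture_hip_frac),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if p_admit > p_any_care:
        raise ValueError(
            f"p_admit ({p_admit}) cannot exceed p_any_care ({p_any_care})"
        )
    admit_nf = p_admit * admit_nonfracture_frac
    fracture = p_admit * (1.0 - admit_nonfracture_frac)
    split = FallOutcomeSplit(
        p_no_care=1.0 - p_any_care,
        p_outpatient=p_any_care - p_admit,
        p_admit_nonfracture=admit_nf,
        p_admit_nonhip_fracture=fracture * (1.0 - fracture_hip_frac),
        p_admit_hip_fracture=fracture * fracture_hip_frac,
    )
    return split


def scale_rate_by_employment(annual_rate: float, employment_ratio: float) -> float:
    """Scale a working-age accident rate by the employment ratio of the
    older group."""
    if not 0.0 <= annual_rate <= 1.0 or not 0.0 <= employment_ratio <= 1.0:
        raise ValueError("inputs must lie in [0, 1]")
    return annual_rate * employment_ratio


# ---------------------------------------------------------------------------
# strategy-level relative effects
# ---------------------------------------------------------------------------

def fall_relative_effect(strategy: str, params: ParameterSet) -> float:
    """Fall risk multiplier vs the general (good-sleeper) population."""
    rr_untreated = params.value("rr_fall_untreated_vs_general")
    if strategy == "untreated":
        return rr_untreated
    if strategy == "zolpidem_ir":
        return params.value("fall_effect_vs_general.zolpidem_ir")
    return compose_fall_hazard(
        params.value(f"hr_fall_vs_untreated.{strategy}"), rr_untreated
    )


def mvc_relative_effect(strategy: str, params: ParameterSet) -> float:
    """MVC risk multiplier; all drugs share the zolpidem-derived effect."""
    if strategy == "untreated":
        return params.value("or_mvc.untreated")
    return params.value("or_mvc.zolpidem")


def wpa_relative_effect(strategy: str, params: ParameterSet) -> float:
    """Responder-weighted WPA odds ratio (untreated keeps the full OR since
    its responder rate is zero)."""
    return weighted_event_or(
        params.value(f"response_rate.sSOL.{strategy}"),
        params.value("or_wpa_nonresponder"),
    )


def baseline_annual_risk(event: str, age_group: str, params: ParameterSet) -> float:
    """General-population annual event risk for an age group."""
    if event == "wpa":
        younger = params.value("baseline_annual_risk.wpa.younger")
        if age_group == "younger":
            return younger
        return scale_rate_by_employment(
            younger, params.value("employment_ratio_older")
        )
    return params.value(f"baseline_annual_risk.{event}.{age_group}")


_RELATIVE_EFFECT = {
    "fall": fall_relative_effect,
    "mvc": mvc_relative_effect,
    "wpa": wpa_relative_effect,
}


def event_risk(
    strategy: str, event: str, age_group: str, params: ParameterSet
) -> EventRiskProfile:
    """Full per-capita risk profile of one event for one strategy/age cell.

    The annual faller/collision/accident probability is the baseline risk
    times the strategy's relative effect (clipped at 1 with a logged warning
    if a sensitivity analysis pushes it past certainty), converted to the
    model horizon.  For falls, the expected per-capita count inflates the
    faller probability by the regression-based falls-per-faller term, and
    fall deaths arise only from the hospitalized outcome categories —
    medically unattended and outpatient falls are minor injuries with no
    mortality.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if event not in EVENTS:
        raise ValueError(f"unknown event {event!r}")
    if age_group not in AGE_GROUPS:
        raise ValueError(f"unknown age group {age_group!r}")

    horizon = params.value("horizon_years")
    baseline = baseline_annual_risk(event, age_group, params)
    annual = baseline * _RELATIVE_EFFECT[event](strategy, params)
    if annual > 1.0:
        logger.warning(
            "annual %s risk for %s/%s is %.4f > 1; clipping to 1",
            event, strategy, age_group, annual,
        )
        annual = 1.0
    period = annual_to_period_prob(annual, horizon)

    if event == "fall":
        per_faller = falls_per_faller(
            annual,
            params.value("refall.anchor_rate"),
            params.value("refall.anchor_falls"),
            params.value("refall.slope"),
        )
        count = period * per_faller
        split = fall_outcome_split(
            params.value("fall_care.p_any_care"),
            params.value("fall_care.p_admit"),
            params.value("fall_care.admit_nonfracture_frac"),
            params.value("fall_care.fracture_hip_frac"),
        )
        fatality_given_fall = (
            split.p_admit_nonfracture * params.value("fall_fatality.admit_nonfracture")
            + split.p_admit_nonhip_fracture
            * params.value("fall_fatality.admit_nonhip_fracture")
            + split.p_admit_hip_fracture
            * params.value("fall_fatality.admit_hip_fracture")
        )
        death = period * fatality_given_fall
    elif event == "mvc":
        count = period
        death = period * params.value("mvc_fatality")
    else:  # wpa
        count = period
        death = period * params.value("wpa_fatality")

    return EventRiskProfile(
        event=event,
        strategy=strategy,
        age_group=age_group,
        period_probability=period,
        expected_count_per_capita=count,
        death_probability=death,
    )
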