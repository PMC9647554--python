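"""Scenario analyses: pure age subgroups and alternative response measures.

The base case defines treatment response by subjective sleep-onset latency
(sSOL).  Scenario analyses swap in responder rates defined by wake after
sleep onset (WASO) or latency to persistent sleep (LPS), together with the
insomnia disutility estimated under the same measure; everything else is
inherited from the base case.  Because the response rate enters the QALY
side (and, weakly, the responder-weighted workplace-accident odds ratio)
but no drug or visit cost, response-measure scenarios leave those cost
components bit-identical to the base case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .engine import StrategyResult, evaluate_all
from .metrics import Comparison, compare
from .params import AGE_GROUPS, STRATEGIES, ParameterSet, ValidationError
from .sensitivity import DEFAULT_PAIRS

__all__ = ["ScenarioSpec", "ScenarioResult", "run_scenario", "standard_scenarios"]

#: the only parameters a scenario may override directly
_ALLOWED_OVERRIDES = frozenset(
    {f"response_rate.sSOL.{s}" for s in STRATEGIES} | {"insomnia_disutility.sSOL"}
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Name, optional age restriction, response measure and overrides."""

    name: str
    age_restriction: str | None = None  # "younger", "older" or None
    response_measure: str = "sSOL"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.age_restriction is not None and self.age_restriction not in AGE_GROUPS:
            raise ValidationError(
                f"unknown age restriction {self.age_restriction!r}"
            )
        if self.response_measure not in ("sSOL", "WASO", "LPS"):
            raise ValidationError(
                f"unknown response measure {self.response_measure!r}"
            )
        bad = set(self.overrides) - _ALLOWED_OVERRIDES
        if bad:
            raise ValidationError(
                "scenario overrides may only touch response rates and the "
                f"insomnia disutility; got {sorted(bad)}"
            )


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    results: dict  # strategy -> StrategyResult
    comparisons: dict  # (intervention, comparator) -> Comparison


def scenario_parameters(params: ParameterSet, spec: ScenarioSpec) -> ParameterSet:
    """Base-case parameters with the scenario's response inputs swapped in."""
    updates: dict[str, float] = {}
    if spec.response_measure != "sSOL":
        m = spec.response_measure
        for s in STRATEGIES:
            updates[f"response_rate.sSOL.{s}"] = params.value(
                f"response_rate.{m}.{s}"
            )
        updates["insomnia_disutility.sSOL"] = params.value(
            f"insomnia_disutility.{m}"
        )
    updates.update(spec.overrides)
    return params.replace_values(updates) if updates else params


def run_scenario(params: ParameterSet, spec: ScenarioSpec) -> ScenarioResult:
    """Evaluate the full pipeline under a scenario's parameter overrides."""
    ps = scenario_parameters(params, spec)
    results = evaluate_all(ps, age_group=spec.age_restriction)
    comparisons = {
        pair: compare(results[pair[0]], results[pair[1]]) for pair in DEFAULT_PAIRS
    }
    return ScenarioResult(spec=spec, results=results, comparisons=comparisons)


def standard_scenarios() -> list[ScenarioSpec]:
    """The scenario battery: both pure age groups, WASO and LPS responses."""
    return [
        ScenarioSpec(name="younger_only", age_restriction="younger"),
        ScenarioSpec(name="older_only", age_restriction="older"),
        ScenarioSpec(name="waso_response", response_measure="WASO"),
        ScenarioSpec(name="lps_response", response_measure="LPS"),
    ]
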