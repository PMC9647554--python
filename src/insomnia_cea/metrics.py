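"""Pairwise cost-effectiveness comparison: ICER, dominance, NMB, currency.

Dominance follows the usual convention: the intervention dominates when it
is no more costly and more effective (or cheaper and no less effective),
with at least one margin strict.  An ICER is reported only when there is a
genuine trade-off (both increments of the same sign); it is computed from
full-precision model outputs and rounded only at the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .engine import StrategyResult

__all__ = [
    "Comparison",
    "classify_dominance",
    "compare",
    "compare_deltas",
    "net_monetary_benefit",
    "jpy_to_usd",
]


@dataclass(frozen=True)
class Comparison:
    """Incremental cost, incremental QALYs, and ICER/dominance label."""

    intervention: str
    comparator: str
    delta_cost_jpy: float
    delta_qaly: float
    icer_jpy_per_qaly: float | None
    label: str  # dominant | dominated | icer | equal


def classify_dominance(delta_cost: float, delta_qaly: float) -> str:
    """Dominance label from the signs of (delta cost, delta QALY).

    dominant: cheaper and/or more effective with one margin strict;
    dominated: the mirror image; equal: both increments zero; icer: a
    same-sign trade-off (pay more for more, or save money giving up effect).
    """
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return "equal"
    if delta_cost <= 0.0 and delta_qaly >= 0.0:
        return "dominant"
    if delta_cost >= 0.0 and delta_qaly <= 0.0:
        return "dominated"
    return "icer"


def compare_deltas(
    delta_cost: float, delta_qaly: float,
    intervention: str = "intervention", comparator: str = "comparator",
) -> Comparison:
    """Build a :class:`Comparison` from raw increments."""
    label = classify_dominance(delta_cost, delta_qaly)
    icer = delta_cost / delta_qaly if label == "icer" else None
    return Comparison(
        intervention=intervention,
        comparator=comparator,
        delta_cost_jpy=delta_cost,
        delta_qaly=delta_qaly,
        icer_jpy_per_qaly=icer,
        label=label,
    )


def compare(intervention: StrategyResult, comparator: StrategyResult) -> Comparison:
    """Incremental comparison of two strategy results from the same model run."""
    if intervention.age_group != comparator.age_group:
        raise ValueError(
            "comparison requires results for the same population "
            f"({intervention.age_group} vs {comparator.age_group})"
        )
    return compare_deltas(
        intervention.expected_cost_jpy - comparator.expected_cost_jpy,
        intervention.expected_qaly - comparator.expected_qaly,
        intervention=intervention.strategy,
        comparator=comparator.strategy,
    )


def net_monetary_benefit(result: Comparison, wtp: float) -> float:
    """NMB = WTP * dE - dC; positive means cost-effective at that WTP."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be > 0")
    return wtp * result.delta_qaly - result.delta_cost_jpy


def jpy_to_usd(amount_jpy: float, jpy_per_usd: float) -> int:
    """Convert JPY to whole USD, rounding half-up."""
    if jpy_per_usd <= 0:
        raise ValueError("jpy_per_usd must be > 0")
    if not math.isfinite(amount_jpy):
        raise ValueError("amount must be finite")
    usd = Decimal(repr(amount_jpy)) / Decimal(repr(jpy_per_usd))
    return int(usd.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
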