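"""Tabular writers for base-case, scenario, tornado, PSA and CEAC outputs.

Rounding profiles control the printed precision: the ``paper`` profile uses
the conventions of published cost-effectiveness tables (QALYs to four
decimals, JPY to whole yen, USD to whole dollars, relative effects to two
decimals, proportions to one decimal in percent); ``full`` leaves values
unrounded.
"""

from __future__ import annotations

import pandas as pd

from .engine import StrategyResult
from .metrics import Comparison, jpy_to_usd
from .params import STRATEGIES, ParameterSet
from .sensitivity import PSAResult, TornadoEntry

__all__ = [
    "ROUNDING_PROFILES",
    "base_case_table",
    "comparison_table",
    "tornado_table",
    "psa_scatter_table",
    "ceac_table",
    "provenance_summary",
]

ROUNDING_PROFILES = ("paper", "full")


def _round(value: float, kind: str, profile: str):
    if profile == "full" or value is None or pd.isna(value):
        return value
    if kind == "qaly":
        return round(value, 4)
    if kind == "jpy":
        return round(value)
    if kind == "usd":
        return round(value)
    if kind == "relative_effect":
        return round(value, 2)
    if kind == "percent":
        return round(value, 1)
    return value


def base_case_table(
    results: dict[str, StrategyResult],
    params: ParameterSet,
    profile: str = "paper",
    scenario: str = "base_case",
) -> pd.DataFrame:
    """One row per strategy: expected cost (JPY and USD), QALYs, breakdown."""
    rate = params.value("jpy_per_usd")
    rows = []
    for strat in STRATEGIES:
        r = results[strat]
        rows.append(
            {
                "scenario": scenario,
                "strategy": strat,
                "population": r.age_group,
                "expected_cost_jpy": _round(r.expected_cost_jpy, "jpy", profile),
                "expected_cost_usd": jpy_to_usd(r.expected_cost_jpy, rate),
                "expected_qaly": _round(r.expected_qaly, "qaly", profile),
                "death_probability": r.death_probability,
                **{
                    f"cost_{k}_jpy": _round(v, "jpy", profile)
                    for k, v in r.cost_breakdown.items()
                },
            }
        )
    return pd.DataFrame(rows)


def comparison_table(
    comparisons: dict[tuple, Comparison],
    params: ParameterSet,
    profile: str = "paper",
    scenario: str = "base_case",
) -> pd.DataFrame:
    """One row per pairwise comparison: increments, ICER or dominance."""
    rate = params.value("jpy_per_usd")
    rows = []
    for comp in comparisons.values():
        icer = comp.icer_jpy_per_qaly
        rows.append(
            {
                "scenario": scenario,
                "intervention": comp.intervention,
                "comparator": comp.comparator,
                "delta_cost_jpy": _round(comp.delta_cost_jpy, "jpy", profile),
                "delta_cost_usd": jpy_to_usd(comp.delta_cost_jpy, rate),
                "delta_qaly": _round(comp.delta_qaly, "qaly", profile),
                "label": comp.label,
                "icer_jpy_per_qaly": (
                    None if icer is None else _round(icer, "jpy", profile)
                ),
                "icer_usd_per_qaly": (
                    None if icer is None else jpy_to_usd(icer, rate)
                ),
            }
        )
    return pd.DataFrame(rows)


def tornado_table(
    entries: list[TornadoEntry],
    base_outcome: float,
    outcome_metric: str,
) -> pd.DataFrame:
    """Plot-ready tornado rows, widest span first."""
    return pd.DataFrame(
        [
            {
                "parameter_id": e.parameter_id,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "outcome_low": e.outcome_low,
                "outcome_high": e.outcome_high,
                "span": e.span,
                "base_outcome": base_outcome,
                "outcome_metric": outcome_metric,
            }
            for e in entries
        ]
    )


def psa_scatter_table(result: PSAResult) -> pd.DataFrame:
    """Cost-effectiveness plane points (one row per draw and comparison)."""
    frames = []
    for name in result.delta_cost:
        frames.append(
            pd.DataFrame(
                {
                    "comparison": name,
                    "draw_index": range(result.n_draws),
                    "delta_cost_jpy": result.delta_cost[name],
                    "delta_qaly": result.delta_qaly[name],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def ceac_table(summaries: list[dict]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves for all comparisons."""
    rows = []
    for s in summaries:
        for wtp, frac in s["ceac"]:
            rows.append(
                {
                    "comparison": s["comparison"],
                    "wtp_jpy_per_qaly": wtp,
                    "p_cost_effective": frac,
                }
            )
    return pd.DataFrame(rows)


def provenance_summary(params: ParameterSet) -> pd.DataFrame:
    """Count of printed vs placeholder inputs, for the run log."""
    counts: dict[str, int] = {}
    for spec in params.values():
        counts[spec.provenance] = counts.get(spec.provenance, 0) + 1
    return pd.DataFrame(
        [{"provenance": k, "n_parameters": v} for k, v in sorted(counts.items())]
    )
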