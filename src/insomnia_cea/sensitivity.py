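"""One-way (tornado) and probabilistic sensitivity analyses.

One-way analysis re-evaluates the full model at each parameter's low/high
endpoint (95% CI where reported, otherwise +/-20%), holding everything else
at base case, and ranks parameters by the span of the comparison outcome.
For dominant comparisons the outcome is net monetary benefit — the ICER is
undefined or unstable near a zero QALY increment — while trade-off
comparisons use the ICER (computed as the raw dC/dE ratio at perturbed
endpoints, which may leave the trade-off quadrant).

The probabilistic analysis follows the standard Monte-Carlo recipe: every
uncertain parameter is drawn independently from its moment-matched
distribution (2000 draws by default) and the model is re-evaluated per
draw.  Each parameter owns a counter-based random stream derived from the
seed and a stable hash of its id, so adding or removing one parameter never
perturbs another's draws.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .engine import evaluate_all
from .metrics import Comparison, compare, net_monetary_benefit
from .params import (
    AGE_GROUPS,
    ParameterError,
    ParameterSet,
    owa_range,
    psa_distribution,
)

__all__ = [
    "DEFAULT_PAIRS",
    "OWA_EXCLUDED",
    "TornadoEntry",
    "PSAResult",
    "one_way_analysis",
    "threshold_search",
    "run_psa",
    "psa_summary",
]

logger = logging.getLogger(__name__)

DEFAULT_PAIRS = (
    ("lemborexant", "suvorexant"),
    ("lemborexant", "zolpidem_ir"),
    ("lemborexant", "untreated"),
)

#: structural settings and scenario-only inputs that one-way analysis skips
OWA_EXCLUDED = frozenset(
    {
        "horizon_years",
        "wtp_jpy_per_qaly",
        "jpy_per_usd",
        "psa_draws",
        "psa_default_se_fraction",
        "owa_default_range_fraction",
        "falls_per_faller_mean",
    }
    | {f"age_weight.{a}" for a in AGE_GROUPS}
    | {
        f"response_rate.{m}.{s}"
        for m in ("WASO", "LPS")
        for s in ("lemborexant", "suvorexant", "zolpidem_ir", "untreated")
    }
    | {"insomnia_disutility.WASO", "insomnia_disutility.LPS"}
)


@dataclass(frozen=True)
class TornadoEntry:
    """One parameter's low/high outcome span for the tornado diagram."""

    parameter_id: str
    low_input: float
    high_input: float
    outcome_low: float
    outcome_high: float

    @property
    def span(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _comparison(
    params: ParameterSet, pair: tuple[str, str], age_group: str | None
) -> Comparison:
    results = evaluate_all(params, age_group=age_group)
    return compare(results[pair[0]], results[pair[1]])


def _outcome_fn(outcome: str, wtp: float):
    if outcome == "nmb":
        return lambda c: net_monetary_benefit(c, wtp)
    if outcome == "icer":
        # raw incremental ratio so perturbed endpoints that leave the
        # trade-off quadrant still chart on the tornado axis
        return lambda c: (
            c.delta_cost_jpy / c.delta_qaly if c.delta_qaly != 0.0 else float("nan")
        )
    raise ValueError(f"unknown outcome {outcome!r}")


def one_way_analysis(
    params: ParameterSet,
    comparison_pair: tuple[str, str] = ("lemborexant", "suvorexant"),
    outcome: str = "auto",
    wtp: float | None = None,
    age_group: str | None = None,
) -> tuple[list[TornadoEntry], float, str]:
    """Tornado analysis for one strategy pair.

    Returns ``(entries, base_outcome, outcome_metric)`` with entries sorted
    by descending span.  ``outcome='auto'`` picks NMB when the base-case
    comparison is dominant/dominated/equal and ICER for a trade-off.
    Perturbations that invalidate the parameter set are skipped with a
    logged reason.
    """
    wtp = params.value("wtp_jpy_per_qaly") if wtp is None else wtp
    default_f = params.value("owa_default_range_fraction")
    base = _comparison(params, comparison_pair, age_group)
    if outcome == "auto":
        outcome = "icer" if base.label == "icer" else "nmb"
    fn = _outcome_fn(outcome, wtp)
    base_outcome = fn(base)

    entries: list[TornadoEntry] = []
    for pid in params:
        if pid in OWA_EXCLUDED:
            continue
        low, high = owa_range(params[pid], default_f)
        outcomes = []
        try:
            for endpoint in (low, high):
                perturbed = params.replace_values({pid: endpoint})
                outcomes.append(fn(_comparison(perturbed, comparison_pair, age_group)))
        except (ParameterError, ValueError) as exc:
            logger.info("one-way analysis skipped %s: %s", pid, exc)
            continue
        if not all(np.isfinite(outcomes)):
            logger.info(
                "one-way analysis skipped %s: outcome not finite at an endpoint", pid
            )
            continue
        entries.append(TornadoEntry(pid, low, high, outcomes[0], outcomes[1]))
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries, base_outcome, outcome


def threshold_search(
    params: ParameterSet,
    parameter_id: str,
    comparison_pair: tuple[str, str],
    criterion: str,
    bracket: tuple[float, float],
    wtp: float | None = None,
    age_group: str | None = None,
    rtol: float = 1e-6,
    max_iter: int = 200,
) -> float | None:
    """Bisect one parameter for the value where a decision criterion flips.

    ``criterion`` is one of ``delta_cost`` (incremental cost crosses zero),
    ``icer_at_wtp`` (ICER crosses the willingness-to-pay) or ``nmb`` (net
    monetary benefit crosses zero).  Returns the crossing value to relative
    tolerance ``rtol``, or ``None`` when the criterion does not change sign
    over the bracket.
    """
    wtp = params.value("wtp_jpy_per_qaly") if wtp is None else wtp

    def f(x: float) -> float:
        comp = _comparison(
            params.replace_values({parameter_id: x}), comparison_pair, age_group
        )
        if criterion == "delta_cost":
            val = comp.delta_cost_jpy
        elif criterion == "icer_at_wtp":
            if comp.delta_qaly == 0.0:
                raise ValueError(
                    f"ICER undefined at {parameter_id}={x} (zero QALY increment)"
                )
            val = comp.delta_cost_jpy / comp.delta_qaly - wtp
        elif criterion == "nmb":
            val = net_monetary_benefit(comp, wtp)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if not np.isfinite(val):
            raise ValueError(
                f"criterion {criterion} not finite at {parameter_id}={x}"
            )
        return val

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        return None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if hi - lo <= rtol * max(abs(lo), abs(hi), 1e-300):
            return mid
        f_mid = f(mid)
        if f_mid == 0.0:
            return mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def _param_rng(seed: int, parameter_id: str, attempt: int = 0) -> np.random.Generator:
    """Independent, reproducible stream per (seed, parameter)."""
    key = zlib.crc32(parameter_id.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(key, attempt))
    )


@dataclass
class PSAResult:
    """Monte-Carlo draws of incremental outcomes for each comparison."""

    seed: int
    n_draws: int
    parameter_draws: dict = field(default_factory=dict)  # id -> ndarray
    delta_cost: dict = field(default_factory=dict)  # pair name -> ndarray
    delta_qaly: dict = field(default_factory=dict)
    resample_count: int = 0

    def pair_name(self, pair: tuple[str, str]) -> str:
        return f"{pair[0]}_vs_{pair[1]}"


def run_psa(
    params: ParameterSet,
    n_draws: int | None = None,
    seed: int = 0,
    pairs: tuple = DEFAULT_PAIRS,
    age_group: str | None = None,
) -> PSAResult:
    """Monte-Carlo probabilistic sensitivity analysis.

    Identical ``(params, n_draws, seed)`` give bitwise-identical draws.
    Draws whose assembled parameter set fails validation are resampled from
    per-parameter overflow streams, with the count recorded.
    """
    if n_draws is None:
        n_draws = int(params.value("psa_draws"))
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    default_se_f = params.value("psa_default_se_fraction")

    dists = {pid: psa_distribution(params[pid], default_se_f) for pid in params}
    draws: dict[str, np.ndarray] = {}
    for pid, dist in dists.items():
        if dist.family == "fixed":
            continue
        draws[pid] = np.asarray(dist.sample(_param_rng(seed, pid), n_draws))

    result = PSAResult(seed=seed, n_draws=n_draws, parameter_draws=draws)
    names = [result.pair_name(p) for p in pairs]
    dc = {nm: np.empty(n_draws) for nm in names}
    de = {nm: np.empty(n_draws) for nm in names}

    for i in range(n_draws):
        overrides = {pid: float(v[i]) for pid, v in draws.items()}
        attempt = 0
        while True:
            try:
                ps_i = params.replace_values(overrides)
                break
            except ParameterError as exc:
                attempt += 1
                result.resample_count += 1
                if attempt > 100:
                    raise RuntimeError(
                        f"PSA draw {i} failed validation 100 times: {exc}"
                    ) from exc
                logger.info("PSA draw %d resampled (attempt %d): %s", i, attempt, exc)
                for pid, v in draws.items():
                    overrides[pid] = float(
                        dists[pid].sample(_param_rng(seed, pid, attempt), i + 1)[i]
                    )
        results = evaluate_all(ps_i, age_group=age_group)
        for pair, nm in zip(pairs, names):
            comp = compare(results[pair[0]], results[pair[1]])
            dc[nm][i] = comp.delta_cost_jpy
            de[nm][i] = comp.delta_qaly
    result.delta_cost = dc
    result.delta_qaly = de
    return result


def psa_summary(
    result: PSAResult,
    wtp: float,
    pair: tuple[str, str] | str | None = None,
    ceac_grid: np.ndarray | None = None,
) -> dict:
    """Cost-effectiveness summaries of a PSA for one comparison.

    ``p_cost_saving`` is the joint fraction of draws with negative
    incremental cost and non-negative incremental QALYs (the dominance
    usage); the marginal fraction with negative cost alone is also
    reported.  The CEAC evaluates P(NMB > 0) on a WTP grid that always
    includes 0 and the stated threshold.
    """
    if isinstance(pair, tuple):
        name = result.pair_name(pair)
    elif pair is None:
        if len(result.delta_cost) != 1:
            raise ValueError("pair must be named when the PSA holds several")
        name = next(iter(result.delta_cost))
    else:
        name = pair
    dc = result.delta_cost[name]
    de = result.delta_qaly[name]
    if dc.size == 0:
        raise ValueError("empty PSA sample")

    if ceac_grid is None:
        ceac_grid = np.linspace(0.0, 2.0 * wtp, 21)
    grid = np.union1d(np.asarray(ceac_grid, dtype=float), [0.0, float(wtp)])
    ceac = [
        (float(l), float(np.mean(l * de - dc > 0.0))) for l in grid
    ]
    return {
        "comparison": name,
        "n_draws": int(dc.size),
        "p_cost_saving": float(np.mean((dc < 0.0) & (de >= 0.0))),
        "p_cost_saving_marginal": float(np.mean(dc < 0.0)),
        "p_cost_effective": float(np.mean(wtp * de - dc > 0.0)),
        "ceac": ceac,
    }
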