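"""Reference parameter set and random generators for testing.

The reference set embeds every model input whose value is printed in the
published description of the Japanese insomnia cost-effectiveness model
(``provenance: printed``) and supplies documented, clearly flagged
assumptions (``provenance: placeholder``) for the inputs whose table cells
are not publicly reproduced — baseline event risks, unit event costs, the
utility norm, event disutilities and the scenario response rates.
Placeholder magnitudes are chosen from Japanese population statistics and
fee-schedule orders of magnitude so that the reference evaluation
reproduces the published qualitative pattern (the newest hypnotic dominant
over both active comparators and trading off against no treatment below
the willingness-to-pay); they are not the unpublished table values.

:func:`random_parameters` draws structurally valid parameter sets from wide
ranges for property-based testing.
"""

from __future__ import annotations

import csv
import io
from importlib import resources

import numpy as np

from .params import (
    AGE_GROUPS,
    STRATEGIES,
    ParameterSet,
    ParameterSpec,
    load_parameter_set,
    required_parameters,
    serialize_parameter_set,
)

__all__ = [
    "REFERENCE_TABLE",
    "reference_parameters",
    "reference_config_text",
    "manifest_rows",
    "manifest_csv",
    "random_parameters",
]

# id: (value, ci, se, family, provenance, source)
_P = "placeholder"
_PRINTED = "printed"

REFERENCE_TABLE: dict[str, dict] = {
    # --- framework settings ------------------------------------------------
    "horizon_years": dict(value=0.5, family="fixed", provenance=_PRINTED,
                          source="model setting: 6-month horizon, no discounting"),
    "wtp_jpy_per_qaly": dict(value=5_000_000, family="fixed", provenance=_PRINTED,
                             source="Japanese HTA willingness-to-pay threshold"),
    "jpy_per_usd": dict(value=107, family="fixed", provenance=_PRINTED,
                        source="Bank of Japan exchange rate, September 2020"),
    "psa_draws": dict(value=2000, family="fixed", provenance=_PRINTED,
                      source="model setting: Monte-Carlo simulation count"),
    "psa_default_se_fraction": dict(value=0.10, family="fixed", provenance=_PRINTED,
                                    source="model setting: assumed s.e. when unreported"),
    "owa_default_range_fraction": dict(value=0.20, family="fixed", provenance=_PRINTED,
                                       source="model setting: +/-20% when no CI"),
    "age_weight.younger": dict(value=0.65, family="fixed", provenance=_P,
                               source="assumed: Japanese adult age structure"),
    "age_weight.older": dict(value=0.35, family="fixed", provenance=_P,
                             source="assumed: Japanese adult age structure"),
    # --- treatment response ------------------------------------------------
    "response_rate.sSOL.lemborexant": dict(value=0.207, provenance=_PRINTED,
                                           source="SUNRISE 1 sSOL responder rate"),
    "response_rate.sSOL.suvorexant": dict(value=0.207, provenance=_PRINTED,
                                          source="assumed equal to lemborexant (published assumption)"),
    "response_rate.sSOL.zolpidem_ir": dict(value=0.12, provenance=_P,
                                           source="assumed: below the orexin antagonists per network meta-analysis direction"),
    "response_rate.sSOL.untreated": dict(value=0.0, family="fixed", provenance=_PRINTED,
                                         source="untreated insomnia: no improvement by definition"),
    "response_rate.WASO.lemborexant": dict(value=0.42, provenance=_P,
                                           source="assumed scenario input"),
    "response_rate.WASO.suvorexant": dict(value=0.42, provenance=_P,
                                          source="assumed scenario input"),
    "response_rate.WASO.zolpidem_ir": dict(value=0.30, provenance=_P,
                                           source="assumed scenario input"),
    "response_rate.WASO.untreated": dict(value=0.0, family="fixed", provenance=_PRINTED,
                                         source="untreated insomnia: no improvement by definition"),
    "response_rate.LPS.lemborexant": dict(value=0.40, provenance=_P,
                                          source="assumed scenario input"),
    "response_rate.LPS.suvorexant": dict(value=0.40, provenance=_P,
                                         source="assumed scenario input"),
    "response_rate.LPS.zolpidem_ir": dict(value=0.25, provenance=_P,
                                          source="assumed scenario input"),
    "response_rate.LPS.untreated": dict(value=0.0, family="fixed", provenance=_PRINTED,
                                        source="untreated insomnia: no improvement by definition"),
    # --- utilities -----------------------------------------------------------
    "utility_norm": dict(value=0.86, provenance=_P,
                         source="assumed: Japanese general-population EQ-5D norm"),
    "insomnia_disutility.sSOL": dict(value=0.026, provenance=_PRINTED,
                                     source="SUNRISE 1 EQ-5D-3L ANCOVA, non-responders"),
    "insomnia_disutility.WASO": dict(value=0.030, provenance=_P,
                                     source="assumed scenario input"),
    "insomnia_disutility.LPS": dict(value=0.029, provenance=_P,
                                    source="assumed scenario input"),
    "disutility.fall": dict(value=0.07, provenance=_P,
                            source="assumed: US Medicare falls model order of magnitude"),
    "disutility.fracture_nonhip": dict(value=0.05, provenance=_P,
                                       source="assumed: US Medicare falls model order of magnitude"),
    "disutility.fracture_hip": dict(value=0.10, provenance=_P,
                                    source="assumed: US Medicare falls model order of magnitude"),
    "disutility.mvc": dict(value=0.03, provenance=_P,
                           source="assumed: weighted median utility loss per collision"),
    "disutility.wpa": dict(value=0.0, family="fixed", provenance=_PRINTED,
                           source="set to zero: no data identified"),
    # --- baseline risks ------------------------------------------------------
    "baseline_annual_risk.fall.younger": dict(value=0.10, provenance=_P,
                                              source="assumed: NILS-LSA faller proportion, younger adults"),
    "baseline_annual_risk.fall.older": dict(value=0.20, provenance=_P,
                                            source="assumed: NILS-LSA faller proportion, older adults"),
    "baseline_annual_risk.mvc.younger": dict(value=0.010, provenance=_P,
                                             source="assumed: Japanese collision statistics per driver"),
    "baseline_annual_risk.mvc.older": dict(value=0.008, provenance=_P,
                                           source="assumed: Japanese collision statistics per driver"),
    "baseline_annual_risk.wpa.younger": dict(value=0.005, provenance=_P,
                                             source="assumed: MHLW occupational-accident survey"),
    "employment_ratio_older": dict(value=0.243, provenance=_PRINTED,
                                   source="employment rate at age >=65, statistics bureau"),
    # --- relative effects ----------------------------------------------------
    "rr_fall_untreated_vs_general": dict(value=1.48, provenance=_PRINTED,
                                         source="Study of Osteoporotic Fractures, untreated chronic insomnia"),
    "hr_fall_vs_untreated.lemborexant": dict(value=0.68, provenance=_PRINTED,
                                             source="network meta-analysis, falls hazard ratio"),
    "hr_fall_vs_untreated.suvorexant": dict(value=0.85, provenance=_PRINTED,
                                            source="network meta-analysis, falls hazard ratio"),
    "fall_effect_vs_general.zolpidem_ir": dict(value=2.5, provenance=_P,
                                               source="assumed: pooled analysis of zolpidem falls in older adults"),
    "or_mvc.untreated": dict(value=2.7, provenance=_PRINTED,
                             source="population-based case-control study, short sleep"),
    "or_mvc.zolpidem": dict(value=2.2, provenance=_P,
                            source="assumed: US health-plan driving study; applied to all drugs"),
    "or_wpa_nonresponder": dict(value=1.79, provenance=_PRINTED,
                                source="National Health Interview Survey, short sleepers"),
    # --- re-fall regression ----------------------------------------------------
    "refall.anchor_falls": dict(value=1.957, ci=[0.90, 2.02], provenance=_PRINTED,
                                source="2019 MCBS: annual falls per faller"),
    "refall.anchor_rate": dict(value=0.25, provenance=_P,
                               source="assumed: MCBS annual faller proportion"),
    "refall.slope": dict(value=4.0, provenance=_P,
                         source="assumed: precision-weighted regression slope (positive)"),
    "falls_per_faller_mean": dict(value=2.5, ci=[2.0, 3.0], family="fixed",
                                  provenance=_PRINTED,
                                  source="annual mean falls per faller used to weight the regression"),
    # --- fall care pathway ------------------------------------------------------
    "fall_care.p_any_care": dict(value=0.56, provenance=_PRINTED,
                                 source="NILS-LSA: fallers receiving medical care"),
    "fall_care.p_admit": dict(value=0.08, provenance=_PRINTED,
                              source="NILS-LSA: fallers hospitalized"),
    "fall_care.admit_nonfracture_frac": dict(value=0.32, provenance=_PRINTED,
                                             source="US Medicare falls model: non-fracture admissions"),
    "fall_care.fracture_hip_frac": dict(value=0.53, provenance=_PRINTED,
                                        source="US Medicare falls model: hip share of fracture admissions"),
    "fall_fatality.admit_nonfracture": dict(value=0.06, provenance=_PRINTED,
                                            source="US Medicare falls model: in-hospital fatality"),
    "fall_fatality.admit_nonhip_fracture": dict(value=0.001, provenance=_PRINTED,
                                                source="US Medicare falls model: in-hospital fatality"),
    "fall_fatality.admit_hip_fracture": dict(value=0.20, provenance=_PRINTED,
                                             source="US Medicare falls model: in-hospital fatality"),
    "mvc_fatality": dict(value=0.01, provenance=_P,
                         source="assumed: deaths per reported collision, Japan"),
    "wpa_fatality": dict(value=0.002, provenance=_P,
                         source="assumed: MHLW occupational fatality share"),
    # --- costs ---------------------------------------------------------------
    "cost.fall_outpatient": dict(value=20_000, provenance=_P,
                                 source="assumed: NHI outpatient episode"),
    "cost.fall_admit_nonfracture": dict(value=300_000, provenance=_P,
                                        source="assumed: NHI admission, non-fracture"),
    "cost.fall_admit_nonhip_fracture": dict(value=500_000, provenance=_P,
                                            source="assumed: NHI admission, non-hip fracture"),
    "cost.fall_admit_hip_fracture": dict(value=1_200_000, provenance=_P,
                                         source="assumed: NHI admission incl. hip surgery"),
    "cost.mvc": dict(value=300_000, provenance=_P,
                     source="assumed: general insurance data, medical cost per collision"),
    "cost.wpa": dict(value=200_000, provenance=_P,
                     source="assumed: general insurance data, medical cost per accident"),
    "drug_cost_per_day.lemborexant": dict(value=92.0, provenance=_PRINTED,
                                          source="2020 NHI drug tariff"),
    "drug_cost_per_day.suvorexant": dict(value=96.7, provenance=_PRINTED,
                                         source="2020 NHI drug tariff"),
    "drug_cost_per_day.zolpidem_ir": dict(value=28.4, provenance=_PRINTED,
                                          source="2020 NHI drug tariff, brand/generic market-share weighted"),
    "drug_cost_per_day.untreated": dict(value=0.0, family="fixed", provenance=_PRINTED,
                                        source="untreated insomnia: no prescription"),
    "visit_frequency_per_month": dict(value=1.3, provenance=_PRINTED,
                                      source="JMDC claims database, mean of 1.33 and 1.29"),
    "visit_cost_jpy": dict(value=730, provenance=_P,
                           source="assumed: NHI re-examination fee"),
}


def reference_parameters() -> ParameterSet:
    """The validated reference parameter set (deterministic)."""
    roles = required_parameters()
    specs = {}
    for pid, entry in REFERENCE_TABLE.items():
        ci = entry.get("ci")
        specs[pid] = ParameterSpec(
            id=pid,
            value=float(entry["value"]),
            role=roles[pid],
            family=entry.get("family"),
            ci_low=None if ci is None else float(ci[0]),
            ci_high=None if ci is None else float(ci[1]),
            se=entry.get("se"),
            provenance=entry["provenance"],
            description=entry["source"],
        )
    return ParameterSet(specs)


def reference_config_text() -> str:
    """The reference set serialized as the shipped YAML configuration."""
    return serialize_parameter_set(reference_parameters())


def packaged_reference_config() -> str:
    """Text of the configuration file shipped inside the package."""
    return (
        resources.files("insomnia_cea")
        .joinpath("data/reference_parameters.yaml")
        .read_text()
    )


def manifest_rows() -> list[dict]:
    """One manifest row per parameter: id, value, provenance, source."""
    return [
        {
            "id": pid,
            "value": REFERENCE_TABLE[pid]["value"],
            "provenance": REFERENCE_TABLE[pid]["provenance"],
            "source": REFERENCE_TABLE[pid]["source"],
        }
        for pid in sorted(REFERENCE_TABLE)
    ]


def manifest_csv() -> str:
    """The manifest as CSV text."""
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=["id", "value", "provenance", "source"])
    writer.writeheader()
    writer.writerows(manifest_rows())
    return buf.getvalue()


# ---------------------------------------------------------------------------
# random generator for property-based testing
# ---------------------------------------------------------------------------

def _loguniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def random_parameters(seed: int) -> ParameterSet:
    """A structurally valid random parameter set (same seed, same set).

    Ranges are deliberately wide — probabilities up to 0.5, relative effects
    log-uniform in [0.25, 4], costs spanning orders of magnitude — so the
    generated configurations exercise both dominance and trade-off regimes.
    """
    rng = np.random.default_rng(seed)
    base = reference_parameters()
    updates: dict[str, float] = {}

    for measure in ("sSOL", "WASO", "LPS"):
        for strat in ("lemborexant", "suvorexant", "zolpidem_ir"):
            updates[f"response_rate.{measure}.{strat}"] = rng.uniform(0.0, 0.5)
        updates[f"insomnia_disutility.{measure}"] = rng.uniform(0.0, 0.1)
    updates["utility_norm"] = rng.uniform(0.6, 1.0)
    for key in (
        "disutility.fall",
        "disutility.fracture_nonhip",
        "disutility.fracture_hip",
        "disutility.mvc",
    ):
        updates[key] = rng.uniform(0.0, 0.15)
    for age in AGE_GROUPS:
        updates[f"baseline_annual_risk.fall.{age}"] = rng.uniform(0.0, 0.3)
        updates[f"baseline_annual_risk.mvc.{age}"] = rng.uniform(0.0, 0.05)
    updates["baseline_annual_risk.wpa.younger"] = rng.uniform(0.0, 0.05)
    updates["employment_ratio_older"] = rng.uniform(0.0, 1.0)
    for key in (
        "rr_fall_untreated_vs_general",
        "hr_fall_vs_untreated.lemborexant",
        "hr_fall_vs_untreated.suvorexant",
        "fall_effect_vs_general.zolpidem_ir",
        "or_mvc.untreated",
        "or_mvc.zolpidem",
        "or_wpa_nonresponder",
    ):
        updates[key] = _loguniform(rng, 0.25, 4.0)
    p_any = rng.uniform(0.2, 0.9)
    updates["fall_care.p_any_care"] = p_any
    updates["fall_care.p_admit"] = p_any * rng.uniform(0.02, 0.5)
    updates["fall_care.admit_nonfracture_frac"] = rng.uniform(0.0, 1.0)
    updates["fall_care.fracture_hip_frac"] = rng.uniform(0.0, 1.0)
    for key in (
        "fall_fatality.admit_nonfracture",
        "fall_fatality.admit_nonhip_fracture",
        "fall_fatality.admit_hip_fracture",
    ):
        updates[key] = rng.uniform(0.0, 0.3)
    updates["mvc_fatality"] = rng.uniform(0.0, 0.05)
    updates["wpa_fatality"] = rng.uniform(0.0, 0.05)
    updates["refall.anchor_falls"] = rng.uniform(1.0, 3.0)
    updates["refall.anchor_rate"] = rng.uniform(0.05, 0.5)
    updates["refall.slope"] = rng.uniform(0.0, 8.0)
    for key in ("cost.fall_outpatient", "cost.wpa", "cost.mvc"):
        updates[key] = _loguniform(rng, 5_000, 500_000)
    for key in (
        "cost.fall_admit_nonfracture",
        "cost.fall_admit_nonhip_fracture",
        "cost.fall_admit_hip_fracture",
    ):
        updates[key] = _loguniform(rng, 50_000, 2_000_000)
    for strat in ("lemborexant", "suvorexant", "zolpidem_ir"):
        updates[f"drug_cost_per_day.{strat}"] = _loguniform(rng, 10.0, 300.0)
    updates["visit_frequency_per_month"] = rng.uniform(0.0, 4.0)
    updates["visit_cost_jpy"] = _loguniform(rng, 100.0, 5_000.0)
    w = rng.uniform(0.0, 1.0)
    updates["age_weight.younger"] = w
    updates["age_weight.older"] = 1.0 - w
    return base.replace_values(updates)
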