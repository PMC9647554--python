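"""Model inputs: parameter specifications, validation, and uncertainty metadata.

Every input to the decision-tree model is a :class:`ParameterSpec` — a point
value plus optional uncertainty information (95% CI, standard error,
distribution family) and a provenance flag separating values taken from the
published model description (``printed``) from values this package supplies
as documented assumptions (``placeholder``).  A validated collection of all
required specs is a :class:`ParameterSet`, the single object every other
module consumes.

Uncertainty conventions follow standard cost-effectiveness practice:

* one-way ranges use the reported 95% CI when available, otherwise
  ``value * (1 ± f)`` with a default ``f = 0.20``, clipped to the
  parameter's admissible domain;
* probabilistic distributions are moment-matched to ``(value, se)`` with
  ``se`` falling back to ``(ci_high - ci_low)/3.92`` and then to a default
  fraction (10%) of the mean; families default to beta for probabilities and
  utilities, gamma for costs and rates, log-normal for relative effects.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "STRATEGIES",
    "DRUG_STRATEGIES",
    "AGE_GROUPS",
    "EVENTS",
    "RESPONSE_MEASURES",
    "ROLES",
    "FAMILIES",
    "ParameterError",
    "MissingParameterError",
    "ValidationError",
    "ParameterSpec",
    "ParameterSet",
    "Distribution",
    "required_parameters",
    "default_family",
    "load_parameter_set",
    "serialize_parameter_set",
    "owa_range",
    "psa_distribution",
    "effective_se",
]

STRATEGIES = ("lemborexant", "suvorexant", "zolpidem_ir", "untreated")
DRUG_STRATEGIES = ("lemborexant", "suvorexant", "zolpidem_ir")
AGE_GROUPS = ("younger", "older")
EVENTS = ("fall", "mvc", "wpa")
RESPONSE_MEASURES = ("sSOL", "WASO", "LPS")

ROLES = frozenset(
    {"probability", "relative_effect", "cost_jpy", "utility", "count_rate", "fraction"}
)
FAMILIES = frozenset({"beta", "gamma", "lognormal", "normal", "fixed"})

#: roles whose admissible domain is the unit interval
_UNIT_ROLES = frozenset({"probability", "fraction", "utility"})
#: roles whose admissible domain is the non-negative half line
_NONNEG_ROLES = frozenset({"cost_jpy", "count_rate"})


class ParameterError(ValueError):
    """Base class for parameter loading/validation failures."""


class MissingParameterError(ParameterError):
    """Raised when required parameter ids are absent from a configuration."""

    def __init__(self, missing: list[str]):
        self.missing = sorted(missing)
        super().__init__(f"missing required parameters: {', '.join(self.missing)}")


class ValidationError(ParameterError):
    """Raised when a parameter value violates its role's invariant."""


def _registry() -> dict[str, str]:
    """Map every required parameter id to its semantic role."""
    reg: dict[str, str] = {
        "horizon_years": "count_rate",
        "wtp_jpy_per_qaly": "cost_jpy",
        "jpy_per_usd": "cost_jpy",
        "psa_draws": "count_rate",
        "psa_default_se_fraction": "fraction",
        "owa_default_range_fraction": "fraction",
        "utility_norm": "utility",
        "employment_ratio_older": "fraction",
        "visit_frequency_per_month": "count_rate",
        "visit_cost_jpy": "cost_jpy",
        "or_wpa_nonresponder": "relative_effect",
        "rr_fall_untreated_vs_general": "relative_effect",
        "hr_fall_vs_untreated.lemborexant": "relative_effect",
        "hr_fall_vs_untreated.suvorexant": "relative_effect",
        "fall_effect_vs_general.zolpidem_ir": "relative_effect",
        "or_mvc.untreated": "relative_effect",
        "or_mvc.zolpidem": "relative_effect",
        "refall.anchor_falls": "count_rate",
        "refall.anchor_rate": "probability",
        "refall.slope": "count_rate",
        "falls_per_faller_mean": "count_rate",
        "fall_care.p_any_care": "probability",
        "fall_care.p_admit": "probability",
        "fall_care.admit_nonfracture_frac": "fraction",
        "fall_care.fracture_hip_frac": "fraction",
        "fall_fatality.admit_nonfracture": "probability",
        "fall_fatality.admit_nonhip_fracture": "probability",
        "fall_fatality.admit_hip_fracture": "probability",
        "mvc_fatality": "probability",
        "wpa_fatality": "probability",
        "cost.fall_outpatient": "cost_jpy",
        "cost.fall_admit_nonfracture": "cost_jpy",
        "cost.fall_admit_nonhip_fracture": "cost_jpy",
        "cost.fall_admit_hip_fracture": "cost_jpy",
        "cost.mvc": "cost_jpy",
        "cost.wpa": "cost_jpy",
        "disutility.fall": "utility",
        "disutility.fracture_nonhip": "utility",
        "disutility.fracture_hip": "utility",
        "disutility.mvc": "utility",
        "disutility.wpa": "utility",
    }
    for age in AGE_GROUPS:
        reg[f"age_weight.{age}"] = "fraction"
        reg[f"baseline_annual_risk.fall.{age}"] = "probability"
        reg[f"baseline_annual_risk.mvc.{age}"] = "probability"
    # WPA baseline is supplied for the younger group only; the older group's
    # rate is derived from it by the employment ratio.
    reg["baseline_annual_risk.wpa.younger"] = "probability"
    for measure in RESPONSE_MEASURES:
        reg[f"insomnia_disutility.{measure}"] = "utility"
        for strat in STRATEGIES:
            reg[f"response_rate.{measure}.{strat}"] = "probability"
    for strat in STRATEGIES:
        reg[f"drug_cost_per_day.{strat}"] = "cost_jpy"
    return reg


_REGISTRY = _registry()


def required_parameters() -> dict[str, str]:
    """Return ``{parameter_id: role}`` for every required model input."""
    return dict(_REGISTRY)


def default_family(role: str) -> str:
    """Conventional distribution family for a role when none is declared."""
    if role in _UNIT_ROLES:
        return "beta"
    if role in _NONNEG_ROLES:
        return "gamma"
    if role == "relative_effect":
        return "lognormal"
    return "normal"


@dataclass(frozen=True)
class ParameterSpec:
    """One model input with its value, uncertainty metadata and provenance."""

    id: str
    value: float
    role: str
    family: str | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    se: float | None = None
    provenance: str = "placeholder"
    description: str = ""

    def validate(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"{self.id}: unknown role {self.role!r}")
        if self.family is not None and self.family not in FAMILIES:
            raise ValidationError(f"{self.id}: unknown family {self.family!r}")
        if self.provenance not in ("printed", "placeholder"):
            raise ValidationError(
                f"{self.id}: provenance must be 'printed' or 'placeholder'"
            )
        v = self.value
        if not math.isfinite(v):
            raise ValidationError(f"{self.id}: value {v!r} is not finite")
        if self.role in _UNIT_ROLES and not 0.0 <= v <= 1.0:
            raise ValidationError(
                f"{self.id}: role {self.role} requires value in [0, 1], got {v}"
            )
        if self.role in _NONNEG_ROLES and v < 0.0:
            raise ValidationError(
                f"{self.id}: role {self.role} requires value >= 0, got {v}"
            )
        if self.role == "relative_effect" and v <= 0.0:
            raise ValidationError(
                f"{self.id}: role relative_effect requires value > 0, got {v}"
            )
        if self.se is not None and self.se < 0.0:
            raise ValidationError(f"{self.id}: se must be >= 0, got {self.se}")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValidationError(f"{self.id}: ci_low and ci_high must come together")
        if self.ci_low is not None and not self.ci_low <= v <= self.ci_high:
            raise ValidationError(
                f"{self.id}: value {v} outside CI [{self.ci_low}, {self.ci_high}]"
            )


def _clip_to_role(low: float, high: float, role: str) -> tuple[float, float]:
    if role in _UNIT_ROLES:
        return max(low, 0.0), min(high, 1.0)
    if role in _NONNEG_ROLES:
        return max(low, 0.0), high
    if role == "relative_effect":
        return max(low, 1e-12), high
    return low, high


def owa_range(spec: ParameterSpec, default_fraction: float) -> tuple[float, float]:
    """Low/high endpoints for one-way sensitivity analysis.

    The reported 95% CI is used when present; otherwise a symmetric
    ``± default_fraction`` band around the base value, clipped to the
    role's admissible domain.
    """
    if not math.isfinite(spec.value):
        raise ValueError(f"{spec.id}: value must be finite")
    if default_fraction < 0:
        raise ValueError("default_fraction must be >= 0")
    if spec.ci_low is not None and spec.ci_high is not None:
        low, high = spec.ci_low, spec.ci_high
    else:
        low = spec.value * (1.0 - default_fraction)
        high = spec.value * (1.0 + default_fraction)
        if low > high:  # negative values (not expected, but keep ordering)
            low, high = high, low
    return _clip_to_role(low, high, spec.role)


def effective_se(spec: ParameterSpec, default_se_fraction: float) -> float:
    """Standard error used for probabilistic sampling.

    Preference order: the declared ``se``; a normal-approximation
    ``(ci_high - ci_low)/3.92`` when only a 95% CI is reported; otherwise
    ``default_se_fraction * |value|``.
    """
    if spec.se is not None:
        return spec.se
    if spec.ci_low is not None and spec.ci_high is not None:
        return (spec.ci_high - spec.ci_low) / 3.92
    return default_se_fraction * abs(spec.value)


@dataclass(frozen=True)
class Distribution:
    """A moment-matched sampling distribution for one parameter."""

    family: str
    params: dict
    mean: float
    sd: float

    def sample(self, rng: np.random.Generator, size: int | None = None):
        p = self.params
        if self.family == "fixed":
            if size is None:
                return self.mean
            return np.full(size, self.mean)
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size=size)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size=size)
        if self.family == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], size=size)
        if self.family == "normal":
            return rng.normal(p["loc"], p["scale"], size=size)
        raise ValueError(f"unknown family {self.family!r}")


def psa_distribution(
    spec: ParameterSpec, default_se_fraction: float
) -> Distribution:
    """Moment-matched sampling distribution with mean ``value`` and sd ``se``.

    Values on a support boundary (a probability of exactly 0 or 1, a zero
    cost) degrade to a point mass with a warning rather than failing.
    """
    family = spec.family or default_family(spec.role)
    m = float(spec.value)
    if family == "fixed":
        return Distribution("fixed", {}, m, 0.0)
    if family == "beta" and (m <= 0.0 or m >= 1.0):
        warnings.warn(
            f"{spec.id}: value {m} on beta support boundary; using point mass",
            stacklevel=2,
        )
        return Distribution("fixed", {}, m, 0.0)
    s = float(effective_se(spec, default_se_fraction))
    if s == 0.0:
        return Distribution("fixed", {}, m, 0.0)

    if family == "beta":
        s_max = math.sqrt(m * (1.0 - m))
        if s >= s_max:
            warnings.warn(
                f"{spec.id}: se {s} infeasible for beta mean {m}; shrinking",
                stacklevel=2,
            )
            s = 0.99 * s_max
        nu = m * (1.0 - m) / (s * s) - 1.0
        return Distribution(
            "beta", {"alpha": m * nu, "beta": (1.0 - m) * nu}, m, s
        )
    if family == "gamma":
        if m <= 0.0:
            warnings.warn(
                f"{spec.id}: non-positive mean {m} for gamma; using point mass",
                stacklevel=2,
            )
            return Distribution("fixed", {}, m, 0.0)
        return Distribution(
            "gamma", {"shape": (m / s) ** 2, "scale": s * s / m}, m, s
        )
    if family == "lognormal":
        if m <= 0.0:
            warnings.warn(
                f"{spec.id}: non-positive mean {m} for lognormal; using point mass",
                stacklevel=2,
            )
            return Distribution("fixed", {}, m, 0.0)
        sigma2 = math.log1p((s / m) ** 2)
        return Distribution(
            "lognormal",
            {"mu": math.log(m) - sigma2 / 2.0, "sigma": math.sqrt(sigma2)},
            m,
            s,
        )
    if family == "normal":
        return Distribution("normal", {"loc": m, "scale": s}, m, s)
    raise ValidationError(f"{spec.id}: unknown family {family!r}")


class ParameterSet(Mapping):
    """Validated, immutable collection of all model inputs.

    Behaves as a read-only mapping from parameter id to
    :class:`ParameterSpec`; use :meth:`value` for the point value and
    :meth:`replace_values` to derive perturbed sets for sensitivity analyses.
    """

    __slots__ = ("_specs",)

    def __init__(self, specs: Mapping[str, ParameterSpec], validate: bool = True):
        self._specs = dict(specs)
        if validate:
            self.validate()

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, key: str) -> ParameterSpec:
        return self._specs[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self._specs == other._specs

    def __repr__(self) -> str:
        return f"ParameterSet({len(self._specs)} parameters)"

    # -- accessors --------------------------------------------------------
    def value(self, key: str) -> float:
        return self._specs[key].value

    def spec(self, key: str) -> ParameterSpec:
        return self._specs[key]

    def replace_values(
        self, updates: Mapping[str, float], validate: bool = True
    ) -> "ParameterSet":
        """New set with the given point values substituted (metadata kept)."""
        specs = dict(self._specs)
        for key, val in updates.items():
            if key not in specs:
                raise MissingParameterError([key])
            old = specs[key]
            ci_low, ci_high = old.ci_low, old.ci_high
            if ci_low is not None and not (ci_low <= val <= ci_high):
                ci_low = ci_high = None  # perturbed value may leave the CI
            specs[key] = dataclasses.replace(
                old, value=float(val), ci_low=ci_low, ci_high=ci_high
            )
        return ParameterSet(specs, validate=validate)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        missing = [k for k in _REGISTRY if k not in self._specs]
        if missing:
            raise MissingParameterError(missing)
        unknown = [k for k in self._specs if k not in _REGISTRY]
        if unknown:
            raise ValidationError(f"unknown parameters: {', '.join(sorted(unknown))}")
        for spec in self._specs.values():
            expected_role = _REGISTRY[spec.id]
            if spec.role != expected_role:
                raise ValidationError(
                    f"{spec.id}: role {spec.role!r} does not match "
                    f"registry role {expected_role!r}"
                )
            spec.validate()
        for measure in RESPONSE_MEASURES:
            key = f"response_rate.{measure}.untreated"
            if self.value(key) != 0.0:
                raise ValidationError(
                    f"{key}: untreated insomnia has response rate 0 by definition"
                )
        w = sum(self.value(f"age_weight.{a}") for a in AGE_GROUPS)
        if abs(w - 1.0) > 1e-9:
            raise ValidationError(f"age weights must sum to 1, got {w}")
        if self.value("fall_care.p_admit") > self.value("fall_care.p_any_care"):
            raise ValidationError(
                "fall_care.p_admit exceeds fall_care.p_any_care: admissions "
                "must be a subset of medically attended falls"
            )
        for key in ("horizon_years", "wtp_jpy_per_qaly", "jpy_per_usd"):
            if self.value(key) <= 0:
                raise ValidationError(f"{key} must be > 0")
        if self.value("drug_cost_per_day.untreated") != 0.0:
            raise ValidationError("untreated insomnia incurs no drug cost")
        if self.value("refall.anchor_falls") < 1.0:
            raise ValidationError("refall.anchor_falls must be >= 1 fall per faller")


_SPEC_KEYS = {"value", "ci", "se", "family", "provenance", "description"}


def load_parameter_set(config_text: str) -> ParameterSet:
    """Parse and validate a hierarchical key-value (YAML/JSON) configuration.

    Each entry is either a bare number or a mapping with keys drawn from
    ``value`` (required), ``ci`` (two-element [low, high]), ``se``,
    ``family``, ``provenance`` and ``description``.  Monetary values are JPY;
    rates are annual unless the id says ``_per_month`` or ``_per_day``.
    """
    try:
        raw = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ParameterError(f"configuration does not parse: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ParameterError("configuration must be a mapping of parameter ids")

    specs: dict[str, ParameterSpec] = {}
    for key, entry in raw.items():
        role = _REGISTRY.get(key)
        if role is None:
            raise ValidationError(f"unknown parameter id: {key}")
        if isinstance(entry, Mapping):
            extra = set(entry) - _SPEC_KEYS
            if extra:
                raise ValidationError(
                    f"{key}: unknown fields {sorted(extra)} in configuration"
                )
            if "value" not in entry:
                raise ValidationError(f"{key}: entry missing 'value'")
            ci = entry.get("ci")
            if ci is not None and len(ci) != 2:
                raise ValidationError(f"{key}: ci must be [low, high]")
            specs[key] = ParameterSpec(
                id=key,
                value=float(entry["value"]),
                role=role,
                family=entry.get("family"),
                ci_low=None if ci is None else float(ci[0]),
                ci_high=None if ci is None else float(ci[1]),
                se=None if entry.get("se") is None else float(entry["se"]),
                provenance=entry.get("provenance", "placeholder"),
                description=entry.get("description", ""),
            )
        elif isinstance(entry, (int, float)) and not isinstance(entry, bool):
            specs[key] = ParameterSpec(id=key, value=float(entry), role=role)
        else:
            raise ValidationError(f"{key}: entry must be a number or a mapping")
    return ParameterSet(specs)


def serialize_parameter_set(params: ParameterSet) -> str:
    """YAML text that :func:`load_parameter_set` reads back identically."""
    out: dict[str, dict] = {}
    for key in sorted(params):
        spec = params[key]
        entry: dict = {"value": spec.value, "provenance": spec.provenance}
        if spec.ci_low is not None:
            entry["ci"] = [spec.ci_low, spec.ci_high]
        if spec.se is not None:
            entry["se"] = spec.se
        if spec.family is not None:
            entry["family"] = spec.family
        if spec.description:
            entry["description"] = spec.description
        out[key] = entry
    return yaml.safe_dump(out, sort_keys=True, width=88)
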