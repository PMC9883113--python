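"""Typed model inputs, JSON config I/O, validation, and arm assembly.

A full model configuration consists of

* ``settings`` — horizon, cycle length, discount rate, background mortality,
  willingness-to-pay threshold;
* ``arms`` — structural description of the two radiotherapy strategies
  (fractionation scheme, delivery technique, calibrated Weibull survival
  models, toxicity incidence);
* ``parameters`` — a registry of named :class:`ParameterSpec` entries (every
  unit cost and health-state utility, with base value, low/high range, and
  distribution family for sensitivity analysis);
* ``composition`` — the documented rules that assemble per-arm cost and
  utility schedules out of the registry (follow-up visit frequency, androgen
  deprivation therapy duration, progressive-state drug mix, how the
  progressive-state utility is obtained).

:func:`build_arm_model` resolves a registry value mapping (base case by
default, overridden during sensitivity analysis) into a concrete
:class:`ArmModel` that the Markov engine and economics layer consume.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

from .errors import ConfigurationError, RangeError, ValidationError
from .survival_models import WeibullSurvival

__all__ = [
    "ParameterSpec",
    "FractionationScheme",
    "CostSchedule",
    "UtilitySet",
    "ModelSettings",
    "ArmStructure",
    "Composition",
    "Config",
    "ArmModel",
    "compose_ps_utility",
    "resolve_values",
    "build_arm_model",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
]

DIST_FAMILIES = ("beta", "gamma", "fixed")

# registry names grouped by the cost-composition role they play
PLANNING_ITEMS = (
    "c_radiation_oncologist",
    "c_pelvic_ct",
    "c_mask",
    "c_body_membrane",
    "c_body_frame",
    "c_rt_monitoring",
    "c_xray_positioning",
    "c_tps",
)
WORKUP_ITEMS = ("c_mri", "c_head_ct", "c_bone_scan", "c_ecg")
FOLLOWUP_ITEMS = ("c_psa_test", "c_dre", "c_routine_blood", "c_biochem_blood")


def _require(cond: bool, message: str, exc=ValidationError) -> None:
    if not cond:
        raise exc(message)


@dataclass(frozen=True)
class ParameterSpec:
    """A named model input with base value, range, and distribution family.

    ``low <= base <= high`` always; beta-family parameters must lie within
    [0, 1] (they are probabilities or utilities), gamma-family parameters
    must be non-negative (they are costs).
    """

    name: str
    base: float
    low: float
    high: float
    dist_family: str = "fixed"
    units: str = ""

    def __post_init__(self) -> None:
        _require(bool(self.name), "parameter name must be non-empty")
        for f in ("base", "low", "high"):
            v = getattr(self, f)
            _require(
                isinstance(v, (int, float)) and math.isfinite(v),
                f"{self.name}.{f} must be a finite number, got {v!r}",
            )
            object.__setattr__(self, f, float(v))
        _require(
            self.low <= self.base <= self.high,
            f"{self.name}: require low <= base <= high "
            f"(got {self.low}, {self.base}, {self.high})",
            RangeError,
        )
        _require(
            self.dist_family in DIST_FAMILIES,
            f"{self.name}.dist_family must be one of {DIST_FAMILIES}, "
            f"got {self.dist_family!r}",
        )
        if self.dist_family == "beta":
            _require(
                0.0 <= self.low and self.high <= 1.0,
                f"{self.name}: beta-family parameter range must lie in [0, 1]",
            )
        if self.dist_family == "gamma":
            _require(self.low >= 0.0, f"{self.name}: gamma-family low must be >= 0")


@dataclass(frozen=True)
class FractionationScheme:
    """A radiotherapy schedule: total dose D, dose per fraction d, count n.

    Invariant: D = d * n (within 1e-9 relative), all strictly positive.
    ``alpha_beta_Gy`` is the tissue alpha/beta ratio used for the
    biologically effective dose, 3 Gy for prostate tumour tissue.
    """

    total_dose_Gy: float
    dose_per_fraction_Gy: float
    n_fractions: int
    alpha_beta_Gy: float

    def __post_init__(self) -> None:
        for f in ("total_dose_Gy", "dose_per_fraction_Gy", "alpha_beta_Gy"):
            v = float(getattr(self, f))
            _require(v > 0 and math.isfinite(v), f"scheme.{f} must be > 0, got {v}")
            object.__setattr__(self, f, v)
        _require(
            int(self.n_fractions) == self.n_fractions and self.n_fractions > 0,
            f"scheme.n_fractions must be a positive integer, got {self.n_fractions}",
        )
        object.__setattr__(self, "n_fractions", int(self.n_fractions))
        prod = self.dose_per_fraction_Gy * self.n_fractions
        _require(
            math.isclose(prod, self.total_dose_Gy, rel_tol=1e-9),
            "scheme: total_dose_Gy must equal dose_per_fraction_Gy * n_fractions "
            f"({self.total_dose_Gy} != {prod})",
        )


@dataclass(frozen=True)
class CostSchedule:
    """Resolved per-arm cost structure in 2020 USD.

    ``one_time_costs`` are charged undiscounted at model entry;
    ``per_cycle_ffs``/``per_cycle_ps`` accrue per Markov cycle weighted by
    state occupancy; androgen deprivation therapy (ADT) is charged monthly to
    failure-free occupancy for ``adt_duration_months``; the urinary-toxicity
    cost is a one-time charge scaled by its incidence.
    """

    one_time_costs: tuple[tuple[str, float], ...]
    per_cycle_ffs: float
    per_cycle_ps: float
    adt_monthly: float
    adt_duration_months: int
    toxicity_cost: float
    toxicity_incidence: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "one_time_costs", tuple(
            (str(n), float(v)) for n, v in self.one_time_costs
        ))
        for n, v in self.one_time_costs:
            _require(v >= 0, f"one-time cost '{n}' must be >= 0, got {v}")
        for f in ("per_cycle_ffs", "per_cycle_ps", "adt_monthly", "toxicity_cost"):
            v = float(getattr(self, f))
            _require(v >= 0, f"costs.{f} must be >= 0, got {v}")
            object.__setattr__(self, f, v)
        _require(
            int(self.adt_duration_months) == self.adt_duration_months
            and self.adt_duration_months >= 0,
            "costs.adt_duration_months must be a non-negative integer",
        )
        object.__setattr__(self, "adt_duration_months", int(self.adt_duration_months))
        _require(
            0.0 <= self.toxicity_incidence <= 1.0,
            f"costs.toxicity_incidence must be in [0, 1], got {self.toxicity_incidence}",
        )
        object.__setattr__(self, "toxicity_incidence", float(self.toxicity_incidence))

    @property
    def total_one_time(self) -> float:
        return sum(v for _, v in self.one_time_costs)


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities on [0, 1] for one arm.

    ``u_ffs`` is arm-specific (it embeds the grade >= 2 urinary-toxicity
    burden of the radiotherapy technique); ``u_ps`` is the progressive-state
    utility, optionally composed as a weighted mean of the
    biochemical-recurrence and clinical-metastasis utilities.
    """

    u_ffs: float
    u_ps: float
    u_br: float
    u_cm: float
    w_br: float
    composed: bool = False

    def __post_init__(self) -> None:
        for f in ("u_ffs", "u_ps", "u_br", "u_cm"):
            v = float(getattr(self, f))
            _require(0.0 <= v <= 1.0, f"utility {f} must be in [0, 1], got {v}")
            object.__setattr__(self, f, v)
        _require(0.0 <= self.w_br <= 1.0, f"w_br must be in [0, 1], got {self.w_br}")
        object.__setattr__(self, "w_br", float(self.w_br))
        if self.composed:
            lo, hi = min(self.u_br, self.u_cm), max(self.u_br, self.u_cm)
            _require(
                lo - 1e-12 <= self.u_ps <= hi + 1e-12,
                f"composed u_ps = {self.u_ps} must lie between component "
                f"utilities [{lo}, {hi}]",
            )


def compose_ps_utility(u_br: float, u_cm: float, w_br: float) -> float:
    """Progressive-state utility as ``w_br*u_br + (1 - w_br)*u_cm``.

    The progressive state pools biochemical recurrence (weight ``w_br``) and
    clinical metastasis (weight ``1 - w_br``).
    """
    for name, v in (("u_br", u_br), ("u_cm", u_cm)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    if not 0.0 <= w_br <= 1.0:
        raise ValidationError(f"w_br must be in [0, 1], got {w_br}")
    return w_br * u_br + (1.0 - w_br) * u_cm


@dataclass(frozen=True)
class ModelSettings:
    """Global run settings for the cohort model."""

    horizon_years: float = 15.0
    cycle_length_years: float = 1.0
    annual_discount_rate: float = 0.03
    background_mortality_per_cycle: float = 0.0003
    wtp_per_qaly: float = 31510.0
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        _require(self.horizon_years > 0, "settings.horizon_years must be > 0")
        _require(self.cycle_length_years > 0, "settings.cycle_length_years must be > 0")
        _require(
            0.0 <= self.annual_discount_rate <= 1.0,
            "settings.annual_discount_rate must be in [0, 1], "
            f"got {self.annual_discount_rate}",
        )
        _require(
            0.0 <= self.background_mortality_per_cycle <= 1.0,
            "settings.background_mortality_per_cycle must be in [0, 1]",
        )
        _require(self.wtp_per_qaly >= 0, "settings.wtp_per_qaly must be >= 0")
        n = self.horizon_years / self.cycle_length_years
        _require(
            math.isclose(n, round(n), rel_tol=0, abs_tol=1e-9),
            f"settings.cycle_length_years ({self.cycle_length_years}) must divide "
            f"horizon_years ({self.horizon_years}) into an integer cycle count",
            ConfigurationError,
        )
        for f in (
            "horizon_years",
            "cycle_length_years",
            "annual_discount_rate",
            "background_mortality_per_cycle",
            "wtp_per_qaly",
        ):
            object.__setattr__(self, f, float(getattr(self, f)))
        object.__setattr__(self, "half_cycle_correction", bool(self.half_cycle_correction))

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_length_years))


@dataclass(frozen=True)
class ArmStructure:
    """Structural description of one treatment strategy.

    ``delivery`` selects the cost-composition branch: ``"imrt"`` charges the
    intensity-modulated delivery fee per fraction; ``"xknife"`` charges
    X-knife plus image-guided radiotherapy with separate first-session and
    subsequent-session fees.
    """

    key: str
    label: str
    scheme: FractionationScheme
    ffs_to_ps: WeibullSurvival
    ps_to_death: WeibullSurvival
    treatment_days: int
    toxicity_incidence: float
    u_ffs_param: str
    delivery: str

    def __post_init__(self) -> None:
        _require(self.delivery in ("imrt", "xknife"),
                 f"arm.delivery must be 'imrt' or 'xknife', got {self.delivery!r}")
        _require(self.treatment_days >= 0, "arm.treatment_days must be >= 0")
        _require(0.0 <= self.toxicity_incidence <= 1.0,
                 "arm.toxicity_incidence must be in [0, 1]")
        object.__setattr__(self, "treatment_days", int(self.treatment_days))
        object.__setattr__(self, "toxicity_incidence", float(self.toxicity_incidence))


@dataclass(frozen=True)
class Composition:
    """Rules that turn registry values into per-arm schedules.

    ``ps_drug_weights`` maps monthly-cost parameter names to the fraction of
    progressive-state patient-months on that item (supportive care weight 1).
    ``ps_utility_mode`` is ``"direct"`` (read the registered u_ps parameter)
    or ``"composed"`` (weighted mean of u_br and u_cm via w_br).
    """

    followup_visits_per_year: float = 2.0
    adt_duration_months: int = 24
    adt_items: tuple[str, ...] = ("c_goserelin_month", "c_bicalutamide_month")
    ps_drug_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "c_supportive_month": 1.0,
            "c_docetaxel_month": 0.25,
            "c_abiraterone_month": 0.25,
            "c_cabazitaxel_month": 0.05,
        }
    )
    ps_utility_mode: str = "direct"

    def __post_init__(self) -> None:
        _require(self.followup_visits_per_year >= 0,
                 "composition.followup_visits_per_year must be >= 0")
        _require(self.ps_utility_mode in ("direct", "composed"),
                 "composition.ps_utility_mode must be 'direct' or 'composed'")
        for name, w in dict(self.ps_drug_weights).items():
            _require(w >= 0, f"composition.ps_drug_weights[{name}] must be >= 0")
        object.__setattr__(
            self,
            "ps_drug_weights",
            MappingProxyType({str(k): float(v) for k, v in dict(self.ps_drug_weights).items()}),
        )
        object.__setattr__(self, "adt_items", tuple(self.adt_items))
        object.__setattr__(self, "adt_duration_months", int(self.adt_duration_months))


@dataclass(frozen=True)
class Config:
    """Immutable full model configuration (two arms + settings + registry)."""

    settings: ModelSettings
    arms: Mapping[str, ArmStructure]
    parameters: Mapping[str, ParameterSpec]
    composition: Composition = field(default_factory=Composition)

    def __post_init__(self) -> None:
        arms = dict(self.arms)
        params = dict(self.parameters)
        _require(len(arms) == 2, f"config must define exactly 2 arms, got {len(arms)}")
        for key, arm in arms.items():
            _require(arm.key == key, f"arm key mismatch: {key!r} vs {arm.key!r}")
            _require(
                arm.u_ffs_param in params,
                f"arm '{key}' references unknown utility parameter "
                f"'{arm.u_ffs_param}'",
            )
        for name, spec in params.items():
            _require(spec.name == name, f"parameter key mismatch: {name!r} vs {spec.name!r}")
        object.__setattr__(self, "arms", MappingProxyType(arms))
        object.__setattr__(self, "parameters", MappingProxyType(params))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Config):
            return NotImplemented
        return (
            self.settings == other.settings
            and dict(self.arms) == dict(other.arms)
            and dict(self.parameters) == dict(other.parameters)
            and self.composition == other.composition
        )


@dataclass(frozen=True)
class ArmModel:
    """Everything needed to run and value one arm: survival dynamics,
    fractionation scheme, resolved utilities and cost schedule."""

    key: str
    label: str
    scheme: FractionationScheme
    ffs_to_ps: WeibullSurvival
    ps_to_death: WeibullSurvival
    utilities: UtilitySet
    costs: CostSchedule


def resolve_values(
    config: Config, overrides: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Registry values at base case, with optional named overrides."""
    values = {name: spec.base for name, spec in config.parameters.items()}
    if overrides:
        unknown = set(overrides) - set(values)
        if unknown:
            raise ConfigurationError(f"unknown parameter override(s): {sorted(unknown)}")
        values.update({k: float(v) for k, v in overrides.items()})
    return values


def _course_cost(arm: ArmStructure, v: Mapping[str, float]) -> float:
    """One-time radiotherapy course cost for an arm.

    Planning/simulation items are shared; delivery is technique-specific
    (per-fraction IMRT fee, or X-knife + image guidance with a first-session
    fee and a lower fee for the remaining fractions); transport accrues per
    fraction and hospitalization per treatment day.
    """
    total = sum(v[item] for item in PLANNING_ITEMS)
    n = arm.scheme.n_fractions
    if arm.delivery == "imrt":
        total += v["c_imrt_fraction"] * n
    else:  # xknife
        total += v["c_xknife_first"] + v["c_xknife"] * (n - 1)
        total += v["c_igrt_first"] + v["c_igrt"] * (n - 1)
    total += v["c_transport"] * n
    total += v["c_hospital_day"] * arm.treatment_days
    return total


def build_arm_model(
    config: Config, arm_key: str, values: Mapping[str, float] | None = None
) -> ArmModel:
    """Assemble a concrete :class:`ArmModel` from registry values."""
    if arm_key not in config.arms:
        raise ConfigurationError(f"unknown arm '{arm_key}'")
    arm = config.arms[arm_key]
    comp = config.composition
    v = dict(values) if values is not None else resolve_values(config)

    u_ps = (
        compose_ps_utility(v["u_br"], v["u_cm"], v["w_br"])
        if comp.ps_utility_mode == "composed"
        else v["u_ps"]
    )
    utilities = UtilitySet(
        u_ffs=v[arm.u_ffs_param],
        u_ps=u_ps,
        u_br=v["u_br"],
        u_cm=v["u_cm"],
        w_br=v["w_br"],
        composed=comp.ps_utility_mode == "composed",
    )

    c = config.settings.cycle_length_years
    visit_cost = sum(v[item] for item in FOLLOWUP_ITEMS)
    ps_monthly = sum(w * v[name] for name, w in comp.ps_drug_weights.items())
    costs = CostSchedule(
        one_time_costs=(
            ("rt_course", _course_cost(arm, v)),
            ("diagnostic_workup", sum(v[item] for item in WORKUP_ITEMS)),
        ),
        per_cycle_ffs=comp.followup_visits_per_year * visit_cost * c,
        per_cycle_ps=12.0 * ps_monthly * c,
        adt_monthly=sum(v[item] for item in comp.adt_items),
        adt_duration_months=comp.adt_duration_months,
        toxicity_cost=v["c_urinary_toxicity"],
        toxicity_incidence=arm.toxicity_incidence,
    )
    return ArmModel(
        key=arm.key,
        label=arm.label,
        scheme=arm.scheme,
        ffs_to_ps=arm.ffs_to_ps,
        ps_to_death=arm.ps_to_death,
        utilities=utilities,
        costs=costs,
    )


# ---------------------------------------------------------------------------
# JSON serialization


def _scheme_to_dict(s: FractionationScheme) -> dict:
    return {
        "total_dose_Gy": s.total_dose_Gy,
        "dose_per_fraction_Gy": s.dose_per_fraction_Gy,
        "n_fractions": s.n_fractions,
        "alpha_beta_Gy": s.alpha_beta_Gy,
    }


def _weibull_to_dict(w: WeibullSurvival) -> dict:
    return {"lam": w.lam, "gamma_shape": w.gamma_shape}


def config_to_dict(config: Config) -> dict:
    """Canonical plain-dict (JSON-ready) form of a configuration."""
    return {
        "settings": dataclasses.asdict(config.settings),
        "arms": {
            key: {
                "label": arm.label,
                "scheme": _scheme_to_dict(arm.scheme),
                "survival": {
                    "ffs_to_ps": _weibull_to_dict(arm.ffs_to_ps),
                    "ps_to_death": _weibull_to_dict(arm.ps_to_death),
                },
                "treatment_days": arm.treatment_days,
                "toxicity_incidence": arm.toxicity_incidence,
                "u_ffs_param": arm.u_ffs_param,
                "delivery": arm.delivery,
            }
            for key, arm in config.arms.items()
        },
        "parameters": {
            name: {
                "base": p.base,
                "low": p.low,
                "high": p.high,
                "dist_family": p.dist_family,
                "units": p.units,
            }
            for name, p in config.parameters.items()
        },
        "composition": {
            "followup_visits_per_year": config.composition.followup_visits_per_year,
            "adt_duration_months": config.composition.adt_duration_months,
            "adt_items": list(config.composition.adt_items),
            "ps_drug_weights": dict(config.composition.ps_drug_weights),
            "ps_utility_mode": config.composition.ps_utility_mode,
        },
    }


def _get(section: Mapping, key: str, where: str):
    try:
        return section[key]
    except (KeyError, TypeError):
        raise ConfigurationError(f"config section '{where}' missing field '{key}'")


def config_from_dict(d: Mapping) -> Config:
    """Parse and validate a plain-dict configuration."""
    settings_d = _get(d, "settings", "<root>")
    try:
        settings = ModelSettings(**settings_d)
    except TypeError as e:
        raise ConfigurationError(f"settings: {e}")
    arms = {}
    for key, ad in _get(d, "arms", "<root>").items():
        sd = _get(ad, "scheme", f"arms.{key}")
        surv = _get(ad, "survival", f"arms.{key}")
        arms[key] = ArmStructure(
            key=key,
            label=_get(ad, "label", f"arms.{key}"),
            scheme=FractionationScheme(**sd),
            ffs_to_ps=WeibullSurvival(**_get(surv, "ffs_to_ps", f"arms.{key}.survival")),
            ps_to_death=WeibullSurvival(
                **_get(surv, "ps_to_death", f"arms.{key}.survival")
            ),
            treatment_days=_get(ad, "treatment_days", f"arms.{key}"),
            toxicity_incidence=_get(ad, "toxicity_incidence", f"arms.{key}"),
            u_ffs_param=_get(ad, "u_ffs_param", f"arms.{key}"),
            delivery=_get(ad, "delivery", f"arms.{key}"),
        )
    params = {}
    for name, pd_ in _get(d, "parameters", "<root>").items():
        params[name] = ParameterSpec(
            name=name,
            base=_get(pd_, "base", f"parameters.{name}"),
            low=_get(pd_, "low", f"parameters.{name}"),
            high=_get(pd_, "high", f"parameters.{name}"),
            dist_family=pd_.get("dist_family", "fixed"),
            units=pd_.get("units", ""),
        )
    comp_d = dict(d.get("composition", {}))
    if "adt_items" in comp_d:
        comp_d["adt_items"] = tuple(comp_d["adt_items"])
    composition = Composition(**comp_d)
    return Config(settings=settings, arms=arms, parameters=params, composition=composition)


def load_config(path) -> Config:
    """Load and validate a JSON configuration file."""
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file not found: {p}")
    with open(p) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as e:
            raise ConfigurationError(f"config file {p} is not valid JSON: {e}")
    return config_from_dict(d)


def save_config(config: Config, path) -> None:
    """Write the canonical normalized JSON dump of a configuration."""
    with open(path, "w") as fh:
        json.dump(config_to_dict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
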