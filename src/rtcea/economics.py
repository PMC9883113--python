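"""Discounting, cost/QALY accumulation, ICER/NMB, and biologically
effective dose.

Quality-adjusted life years are accrued per cycle as
``sum_k df(k) * c * (ffs_k * u_ffs + ps_k * u_ps)`` with the discount factor
``df(k) = (1 + r)^(-k*c)`` (r annual, c the cycle length in years) and
occupancy taken at the start of each cycle; the optional half-cycle
correction replaces start-of-cycle occupancy with the mean of adjacent
boundaries. Costs add one-time entry charges (radiotherapy course,
diagnostic work-up, urinary toxicity scaled by incidence) to discounted
per-cycle follow-up, progressive-state care, and androgen deprivation
therapy while within its fixed duration.

The incremental cost-effectiveness ratio (ICER) divides the incremental
cost of the reference strategy by its incremental effectiveness; the net
monetary benefit (NMB) at willingness-to-pay w is ``w*QALY - cost``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .markov_core import CohortTrace, run_cohort
from .parameters_io import (
    ArmModel,
    Config,
    CostSchedule,
    FractionationScheme,
    ModelSettings,
    UtilitySet,
    build_arm_model,
    resolve_values,
)

__all__ = [
    "CEResult",
    "discount_factor",
    "accumulate",
    "compute_icer",
    "net_monetary_benefit",
    "bed",
    "evaluate_config",
]

# dominance flags on CEResult
REFERENCE_DOMINANT = "reference_dominant"
COMPARATOR_DOMINANT = "comparator_dominant"
EQUAL_EFFECTIVENESS = "equal effectiveness, compare costs"


@dataclass(frozen=True)
class CEResult:
    """Cost-effectiveness comparison of a reference arm against a comparator.

    Increments are reference minus comparator. ``icer`` is NaN when
    incremental effectiveness is zero (see ``dominance`` flag); average
    cost-effectiveness is computed on unrounded internal values.
    """

    reference: str
    comparator: str
    cost_ref: float
    qaly_ref: float
    cost_comp: float
    qaly_comp: float
    incremental_cost: float
    incremental_effectiveness: float
    icer: float
    dominance: str | None
    avg_ce_ref: float
    avg_ce_comp: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_dataframe(self) -> pd.DataFrame:
        """Summary table with one row per quantity and one column per arm."""
        return pd.DataFrame(
            {
                "quantity": [
                    "effectiveness_qaly",
                    "cost_usd",
                    "incremental_effectiveness_qaly",
                    "incremental_cost_usd",
                    "icer_usd_per_qaly",
                    "average_ce_usd_per_qaly",
                ],
                self.reference: [
                    self.qaly_ref,
                    self.cost_ref,
                    self.incremental_effectiveness,
                    self.incremental_cost,
                    self.icer,
                    self.avg_ce_ref,
                ],
                self.comparator: [
                    self.qaly_comp,
                    self.cost_comp,
                    np.nan,
                    np.nan,
                    np.nan,
                    self.avg_ce_comp,
                ],
            }
        )


def discount_factor(settings: ModelSettings, cycle: int) -> float:
    """Discount factor ``(1 + r)^(-cycle * cycle_length_years)``; 1 at cycle 0."""
    if cycle < 0:
        raise ValidationError("cycle must be >= 0")
    r = settings.annual_discount_rate
    if r < 0:
        raise ValidationError("annual_discount_rate must be >= 0")
    return (1.0 + r) ** (-cycle * settings.cycle_length_years)


def accumulate(
    trace: CohortTrace,
    utilities: UtilitySet,
    costs: CostSchedule,
    settings: ModelSettings,
) -> tuple[float, float]:
    """Discounted (cost USD, QALYs) accrued over a cohort trace."""
    c = settings.cycle_length_years
    if not math.isclose(c, trace.cycle_length_years, rel_tol=1e-12):
        raise ConfigurationError(
            f"settings cycle length ({c}) does not match trace "
            f"({trace.cycle_length_years})"
        )
    if trace.n_cycles != settings.n_cycles:
        raise ConfigurationError(
            f"trace has {trace.n_cycles} cycles but settings imply "
            f"{settings.n_cycles}"
        )
    n = trace.n_cycles
    occ = trace.occupancy
    occ_used = (occ[:-1] + occ[1:]) / 2.0 if settings.half_cycle_correction else occ[:-1]
    k = np.arange(n)
    df = (1.0 + settings.annual_discount_rate) ** (-k * c)

    qalys = float(
        np.sum(df * c * (occ_used[:, 0] * utilities.u_ffs + occ_used[:, 1] * utilities.u_ps))
    )

    months_per_cycle = 12.0 * c
    # ADT months billed within cycle k: overlap of [k, k+1)*months with the
    # fixed treatment duration, weighted by failure-free occupancy
    adt_months = np.clip(costs.adt_duration_months - k * months_per_cycle, 0.0, months_per_cycle)
    per_cycle = (
        occ_used[:, 0] * costs.per_cycle_ffs
        + occ_used[:, 1] * costs.per_cycle_ps
        + occ_used[:, 0] * costs.adt_monthly * adt_months
    )
    cost = (
        costs.total_one_time
        + costs.toxicity_cost * costs.toxicity_incidence
        + float(np.sum(df * per_cycle))
    )
    return cost, qalys


def compute_icer(
    a: tuple[float, float],
    b: tuple[float, float],
    reference: str = "CRT",
    comparator: str = "UHRT",
) -> CEResult:
    """ICER of strategy ``a`` (reference) versus ``b`` (comparator).

    Each argument is a (cost, qaly) pair. When one strategy is both cheaper
    and more effective the dominance flag is set; when incremental
    effectiveness is zero the ICER is undefined and flagged.
    """
    cost_a, qaly_a = float(a[0]), float(a[1])
    cost_b, qaly_b = float(b[0]), float(b[1])
    d_cost = cost_a - cost_b
    d_eff = qaly_a - qaly_b
    dominance: str | None = None
    if d_eff == 0.0:
        icer = math.nan
        dominance = EQUAL_EFFECTIVENESS
    else:
        icer = d_cost / d_eff
        if d_cost < 0 and d_eff > 0:
            dominance = REFERENCE_DOMINANT
        elif d_cost > 0 and d_eff < 0:
            dominance = COMPARATOR_DOMINANT
    return CEResult(
        reference=reference,
        comparator=comparator,
        cost_ref=cost_a,
        qaly_ref=qaly_a,
        cost_comp=cost_b,
        qaly_comp=qaly_b,
        incremental_cost=d_cost,
        incremental_effectiveness=d_eff,
        icer=icer,
        dominance=dominance,
        avg_ce_ref=cost_a / qaly_a if qaly_a != 0 else math.nan,
        avg_ce_comp=cost_b / qaly_b if qaly_b != 0 else math.nan,
    )


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """NMB = wtp * qaly - cost (USD)."""
    if wtp < 0:
        raise ValidationError(f"wtp must be >= 0, got {wtp}")
    return wtp * qaly - cost


def bed(scheme: FractionationScheme) -> float:
    """Biologically effective dose ``D * (1 + d / (alpha/beta))`` in Gy."""
    if scheme.alpha_beta_Gy <= 0:
        raise ValidationError("alpha/beta ratio must be > 0")
    return scheme.total_dose_Gy * (
        1.0 + scheme.dose_per_fraction_Gy / scheme.alpha_beta_Gy
    )


def evaluate_config(
    config: Config,
    overrides: Mapping[str, float] | None = None,
    reference: str = "crt",
    traces: Mapping[str, CohortTrace] | None = None,
):
    """Run both arms and compare them; returns (CEResult, traces dict).

    ``overrides`` replaces registry base values by name; an overridden
    ``discount_rate`` also replaces the settings' annual rate. Precomputed
    ``traces`` may be supplied when only valuation parameters change (the
    survival dynamics are structural and do not depend on the registry).
    """
    values = resolve_values(config, overrides)
    settings = config.settings
    if "discount_rate" in values and not math.isclose(
        values["discount_rate"], settings.annual_discount_rate, rel_tol=0, abs_tol=0
    ):
        settings = dataclasses.replace(
            settings, annual_discount_rate=values["discount_rate"]
        )
    arm_keys = list(config.arms)
    if reference not in arm_keys:
        raise ConfigurationError(f"reference arm '{reference}' not in config")
    comparator = next(k for k in arm_keys if k != reference)

    outcomes: dict[str, tuple[float, float]] = {}
    out_traces: dict[str, CohortTrace] = {}
    for key in (reference, comparator):
        arm: ArmModel = build_arm_model(config, key, values)
        trace = traces[key] if traces is not None else run_cohort(arm, config.settings)
        out_traces[key] = trace
        outcomes[key] = accumulate(trace, arm.utilities, arm.costs, settings)

    result = compute_icer(
        outcomes[reference],
        outcomes[comparator],
        reference=config.arms[reference].label,
        comparator=config.arms[comparator].label,
    )
    return result, out_traces
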