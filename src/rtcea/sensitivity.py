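"""Deterministic and probabilistic sensitivity analysis.

One-way deterministic analysis (tornado) re-runs the full model at each
parameter's low and high value with all others at base and ranks parameters
by the induced ICER spread. Probabilistic analysis draws every uncertain
parameter simultaneously — beta distributions for utilities and the discount
rate, gamma for unit costs, both constructed by method of moments from the
printed mean and range with the range read as a 95% interval
(SE = (high - low) / 3.92) — re-runs both arms per draw, and summarizes
decision uncertainty as a cost-effectiveness acceptability curve (CEAC).
``threshold_search`` bisects a scalar knob (willingness-to-pay, discount
rate, or any registry parameter) for the point where the base-case decision
flips sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .economics import evaluate_config, net_monetary_benefit
from .errors import InfeasibleMomentsError, ValidationError
from .markov_core import run_cohort
from .parameters_io import Config, ParameterSpec, build_arm_model, resolve_values

__all__ = [
    "TornadoEntry",
    "PSASample",
    "CEACPoint",
    "ThresholdResult",
    "beta_from_mean_range",
    "gamma_from_mean_range",
    "one_way_dsa",
    "run_psa",
    "ceac",
    "threshold_search",
    "dsa_to_dataframe",
    "psa_to_dataframe",
    "ceac_to_dataframe",
]

#: divisor converting a (low, high) range into a standard error when the
#: range is read as a central 95% interval; alternatives in use are 4
#: (±2 SE) and 2*sqrt(3) (uniform).
DEFAULT_RANGE_DIVISOR = 3.92


def beta_from_mean_range(
    mean: float, low: float, high: float, divisor: float = DEFAULT_RANGE_DIVISOR
) -> tuple[float, float]:
    """Method-of-moments beta shape pair (alpha, beta) from mean and range.

    SE = (high - low)/divisor; alpha = mean*nu, beta = (1-mean)*nu with
    nu = mean(1-mean)/SE**2 - 1. The resulting distribution has exactly the
    requested mean.
    """
    if not 0.0 < mean < 1.0:
        raise ValidationError(f"beta mean must be in (0, 1), got {mean}")
    if not low < high:
        raise ValidationError(f"beta range requires low < high, got ({low}, {high})")
    se = (high - low) / divisor
    var = se * se
    if var >= mean * (1.0 - mean):
        raise InfeasibleMomentsError(
            f"variance {var:.4g} >= mean(1-mean) = {mean * (1 - mean):.4g}; "
            "no beta distribution has these moments"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_mean_range(
    mean: float, low: float, high: float, divisor: float = DEFAULT_RANGE_DIVISOR
) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale) from mean and range.

    SE = (high - low)/divisor; shape = mean^2/SE^2, scale = SE^2/mean, so the
    analytic mean is exactly the input mean and the variance is SE^2.
    """
    if mean <= 0:
        raise ValidationError(f"gamma mean must be > 0, got {mean}")
    if not low < high:
        raise ValidationError(f"gamma range requires low < high, got ({low}, {high})")
    se = (high - low) / divisor
    var = se * se
    return mean * mean / var, var / mean


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float
    flag_low: str | None
    flag_high: str | None
    spread: float


@dataclass(frozen=True)
class PSASample:
    """One Monte Carlo draw: sampled parameter values and per-arm outcomes."""

    draw_index: int
    values: Mapping[str, float]
    outcomes: Mapping[str, tuple[float, float]]  # arm key -> (cost, qaly)


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    prob_cost_effective: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_cost_effective <= 1.0:
            raise ValidationError("CEAC probability must be in [0, 1]")


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a bisection crossover search.

    ``found`` is False when the decision never changes sign on the interval
    (a no-crossover result, not an error).
    """

    knob: str
    found: bool
    value: float | None
    iterations: int


def one_way_dsa(
    config: Config,
    parameters: Sequence[str] | None = None,
    reference: str = "crt",
) -> list[TornadoEntry]:
    """Tornado analysis: ICER at each parameter's low and high, others at base.

    A model failure at an extreme is recorded as a flagged entry (NaN ICER),
    never dropped. Entries are sorted by non-increasing spread; entries with
    an undefined endpoint (dominance or failure) sort first.
    """
    names = list(parameters) if parameters is not None else sorted(config.parameters)
    base_values = resolve_values(config)
    entries = []
    for name in names:
        spec: ParameterSpec = config.parameters[name]
        icers: list[float] = []
        flags: list[str | None] = []
        for bound in (spec.low, spec.high):
            try:
                res, _ = evaluate_config(config, {name: bound}, reference=reference)
                icers.append(res.icer)
                flags.append(res.dominance)
            except Exception as e:  # record, don't drop
                icers.append(math.nan)
                flags.append(f"error: {e}")
        if all(math.isfinite(v) for v in icers) and all(
            f is None for f in flags
        ):
            spread = abs(icers[1] - icers[0])
        elif (
            math.isclose(spec.low, base_values[name])
            and math.isclose(spec.high, base_values[name])
        ):
            spread = 0.0
        else:
            spread = math.inf  # undefined endpoint: most influential bucket
        entries.append(
            TornadoEntry(
                parameter=name,
                low=spec.low,
                high=spec.high,
                icer_low=icers[0],
                icer_high=icers[1],
                flag_low=flags[0],
                flag_high=flags[1],
                spread=spread,
            )
        )
    entries.sort(key=lambda e: -e.spread)
    return entries


def _build_samplers(config: Config, divisor: float) -> dict[str, object]:
    """Frozen scipy distributions (or None for fixed) per registry parameter.

    Constructed before any sampling so infeasible moments fail fast.
    Zero-width ranges degrade to fixed regardless of family.
    """
    samplers: dict[str, object] = {}
    for name, spec in config.parameters.items():
        if spec.dist_family == "fixed" or spec.low == spec.high:
            samplers[name] = None
        elif spec.dist_family == "beta":
            a, b = beta_from_mean_range(spec.base, spec.low, spec.high, divisor)
            samplers[name] = stats.beta(a, b)
        else:  # gamma
            shape, scale = gamma_from_mean_range(spec.base, spec.low, spec.high, divisor)
            samplers[name] = stats.gamma(shape, scale=scale)
    return samplers


def run_psa(
    config: Config,
    n_draws: int,
    seed: int,
    reference: str = "crt",
    divisor: float = DEFAULT_RANGE_DIVISOR,
) -> list[PSASample]:
    """Probabilistic sensitivity analysis: ``n_draws`` seeded Monte Carlo runs.

    Every uncertain parameter is sampled once per draw and the single draw is
    applied to both arms (shared unit costs and utilities are thereby
    correlated across arms; arm-specific utilities are separate registry
    entries and hence independent draws). Beta draws are clipped to [0, 1]
    (a no-op for exact beta sampling, kept as a guard for truncated ranges).

    The cohort traces depend only on the structural survival models, not on
    the sampled valuation parameters, so they are computed once and reused.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    samplers = _build_samplers(config, divisor)
    rng = np.random.default_rng(seed)

    # one survival trace per arm, shared across draws
    base_values = resolve_values(config)
    traces = {
        key: run_cohort(build_arm_model(config, key, base_values), config.settings)
        for key in config.arms
    }

    names = sorted(config.parameters)
    samples: list[PSASample] = []
    for i in range(n_draws):
        values = {}
        for name in names:
            sampler = samplers[name]
            if sampler is None:
                values[name] = config.parameters[name].base
            else:
                v = float(sampler.rvs(random_state=rng))
                if config.parameters[name].dist_family == "beta":
                    v = min(max(v, 0.0), 1.0)
                values[name] = v
        res, _ = evaluate_config(config, values, reference=reference, traces=traces)
        key_ref, key_comp = reference, next(k for k in config.arms if k != reference)
        samples.append(
            PSASample(
                draw_index=i,
                values=values,
                outcomes={
                    key_ref: (res.cost_ref, res.qaly_ref),
                    key_comp: (res.cost_comp, res.qaly_comp),
                },
            )
        )
    return samples


def ceac(
    samples: Sequence[PSASample],
    wtp_grid: Sequence[float],
    reference: str = "crt",
) -> list[CEACPoint]:
    """Cost-effectiveness acceptability curve for the reference arm.

    At each willingness-to-pay value, the probability that the reference arm
    is cost-effective is the fraction of draws in which its net monetary
    benefit exceeds the comparator's; exact ties count 0.5.
    """
    if len(samples) == 0:
        raise ValidationError("ceac requires a non-empty sample list")
    if len(wtp_grid) == 0:
        raise ValidationError("ceac requires a non-empty WTP grid")
    arm_keys = list(samples[0].outcomes)
    if reference not in arm_keys:
        raise ValidationError(f"reference arm '{reference}' not present in samples")
    comparator = next(k for k in arm_keys if k != reference)
    cost_r = np.array([s.outcomes[reference][0] for s in samples])
    qaly_r = np.array([s.outcomes[reference][1] for s in samples])
    cost_c = np.array([s.outcomes[comparator][0] for s in samples])
    qaly_c = np.array([s.outcomes[comparator][1] for s in samples])
    points = []
    for w in wtp_grid:
        if w < 0:
            raise ValidationError("WTP values must be >= 0")
        diff = (w * qaly_r - cost_r) - (w * qaly_c - cost_c)
        prob = float(np.mean((diff > 0) + 0.5 * (diff == 0)))
        points.append(CEACPoint(wtp=float(w), prob_cost_effective=prob))
    return points


def threshold_search(
    config: Config,
    knob: str,
    interval: tuple[float, float],
    tol: float = 1e-6,
    reference: str = "crt",
) -> ThresholdResult:
    """Bisect a scalar knob for the deterministic decision crossover.

    The decision function is the incremental net monetary benefit of the
    reference arm at the base case. ``knob`` is ``"wtp"``, ``"discount_rate"``
    (when registered), or any registry parameter name. Returns a
    no-crossover result when the sign is constant on the interval.
    """
    lo, hi = float(interval[0]), float(interval[1])
    if not lo < hi:
        raise ValidationError(f"interval must satisfy lo < hi, got ({lo}, {hi})")

    if knob == "wtp":
        base, _ = evaluate_config(config, reference=reference)
        d_eff, d_cost = base.incremental_effectiveness, base.incremental_cost

        def decision(x: float) -> float:
            return x * d_eff - d_cost

    elif knob in config.parameters:

        def decision(x: float) -> float:
            res, _ = evaluate_config(config, {knob: x}, reference=reference)
            return net_monetary_benefit(
                res.cost_ref, res.qaly_ref, config.settings.wtp_per_qaly
            ) - net_monetary_benefit(
                res.cost_comp, res.qaly_comp, config.settings.wtp_per_qaly
            )

    else:
        raise ValidationError(
            f"unknown knob '{knob}': expected 'wtp' or a registry parameter name"
        )

    f_lo, f_hi = decision(lo), decision(hi)
    if f_lo == 0.0:
        return ThresholdResult(knob=knob, found=True, value=lo, iterations=0)
    if f_hi == 0.0:
        return ThresholdResult(knob=knob, found=True, value=hi, iterations=0)
    if math.copysign(1.0, f_lo) == math.copysign(1.0, f_hi):
        return ThresholdResult(knob=knob, found=False, value=None, iterations=0)

    iterations = 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = decision(mid)
        iterations += 1
        if f_mid == 0.0:
            return ThresholdResult(knob=knob, found=True, value=mid, iterations=iterations)
        if math.copysign(1.0, f_mid) == math.copysign(1.0, f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
        if iterations > 200:  # guard: tol below float resolution
            break
    return ThresholdResult(
        knob=knob, found=True, value=0.5 * (lo + hi), iterations=iterations
    )


# ---------------------------------------------------------------------------
# tabular exports


def dsa_to_dataframe(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "flag_low": [e.flag_low for e in entries],
            "flag_high": [e.flag_high for e in entries],
            "spread": [e.spread for e in entries],
        }
    )


def psa_to_dataframe(samples: Sequence[PSASample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = {"draw": s.draw_index}
        for key, (cost, qaly) in s.outcomes.items():
            row[f"cost_{key}"] = cost
            row[f"qaly_{key}"] = qaly
        row.update(s.values)
        rows.append(row)
    return pd.DataFrame(rows)


def ceac_to_dataframe(points: Sequence[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "wtp": [p.wtp for p in points],
            "probability": [p.prob_cost_effective for p in points],
        }
    )
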