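"""Weibull survival models and per-cycle transition probabilities.

The engine represents each transition pathway (failure-free -> progressive,
progressive -> death) with a two-parameter Weibull survival function in the
*rate* parameterization

    S(t) = exp(-lam * t**gamma),   lam >= 0, gamma > 0,

so the per-cycle probability of leaving the state between times ``t`` and
``t + 1`` (in cycle units) is the conditional event probability

    P(t -> t+1) = 1 - S(t+1) / S(t) = 1 - exp(lam*t**gamma - lam*(t+1)**gamma).

``gamma > 1`` gives an increasing hazard (event risk accelerates with time),
``gamma < 1`` a decreasing hazard, and ``gamma = 1`` recovers the
memoryless exponential with constant per-cycle probability.

Two ways of obtaining a model are provided:

* :func:`fit_weibull` — least squares on the complementary log-log
  linearization ``ln(-ln S) = ln lam + gamma * ln t`` applied to digitized or
  synthetic Kaplan-Meier step-curve points, and
* :func:`calibrate_weibull` — exact two-point calibration from milestone
  survival probabilities (e.g. a printed 5-year failure-free survival rate),
  which substitutes for curve digitization when only milestones are known.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, InsufficientDataError, ValidationError

__all__ = [
    "WeibullSurvival",
    "KMCurve",
    "WeibullFit",
    "survival_at",
    "transition_probability",
    "fit_weibull",
    "calibrate_weibull",
]


@dataclass(frozen=True)
class WeibullSurvival:
    """Weibull survival function ``S(t) = exp(-lam * t**gamma_shape)``.

    Parameters
    ----------
    lam:
        Rate-like scale parameter (units: per year**gamma_shape). ``lam = 0``
        is allowed and denotes a no-event pathway (``S(t) = 1`` for all t).
    gamma_shape:
        Dimensionless shape parameter, strictly positive.
    """

    lam: float
    gamma_shape: float

    def __post_init__(self) -> None:
        if not (self.lam >= 0.0) or not math.isfinite(self.lam):
            raise ValidationError(f"lam must be finite and >= 0, got {self.lam}")
        if not (self.gamma_shape > 0.0) or not math.isfinite(self.gamma_shape):
            raise ValidationError(
                f"gamma_shape must be finite and > 0, got {self.gamma_shape}"
            )
        # normalize to plain floats so frozen instances round-trip through JSON
        object.__setattr__(self, "lam", float(self.lam))
        object.__setattr__(self, "gamma_shape", float(self.gamma_shape))

    def survival(self, t):
        """S(t) for scalar or array ``t >= 0`` (years)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValidationError("survival time t must be >= 0")
        out = np.exp(-self.lam * np.power(t, self.gamma_shape))
        return float(out) if out.ndim == 0 else out

    def hazard(self, t):
        """Instantaneous hazard ``h(t) = lam * gamma * t**(gamma-1)``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValidationError("hazard time t must be >= 0")
        out = self.lam * self.gamma_shape * np.power(t, self.gamma_shape - 1.0)
        return float(out) if out.ndim == 0 else out

    @property
    def scale_parameter(self) -> float:
        """Equivalent scale sigma of ``S(t) = exp(-(t/sigma)**gamma)``."""
        if self.lam <= 0:
            raise ValidationError("scale parameterization undefined for lam = 0")
        return self.lam ** (-1.0 / self.gamma_shape)

    @classmethod
    def from_scale(cls, scale: float, shape: float) -> "WeibullSurvival":
        """Build from the scale parameterization ``S(t) = exp(-(t/scale)**shape)``."""
        if scale <= 0:
            raise ValidationError(f"scale must be > 0, got {scale}")
        return cls(lam=scale ** (-float(shape)), gamma_shape=float(shape))


def survival_at(model: WeibullSurvival, t) -> float:
    """Survival probability ``S(t) = exp(-lam * t**gamma)`` at time t (years)."""
    return model.survival(t)


def transition_probability(
    model: WeibullSurvival, t, cycle_length_years: float = 1.0
) -> float:
    """Per-cycle event probability between cycle boundaries ``t`` and ``t+1``.

    ``t`` is the current cycle index (>= 0); ``cycle_length_years`` converts
    cycle indices to model time so that

        P = 1 - S((t+1)*c) / S(t*c)

    which reduces to ``1 - exp(lam*t**gamma - lam*(t+1)**gamma)`` for annual
    cycles. The returned value lies in [0, 1).
    """
    t = float(t)
    if t < 0:
        raise ValidationError("cycle index t must be >= 0")
    c = float(cycle_length_years)
    if c <= 0:
        raise ValidationError("cycle_length_years must be > 0")
    g = model.gamma_shape
    exponent = model.lam * (t * c) ** g - model.lam * ((t + 1.0) * c) ** g
    return -math.expm1(exponent)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier step-curve points (time in years, survival probability).

    Times must be strictly increasing and survival non-increasing; if a point
    at t = 0 is present it must have survival 1.
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValidationError("times and survival must be 1-D and equal length")
        if t.size == 0:
            raise ValidationError("KMCurve needs at least one point")
        if np.any(t < 0):
            raise ValidationError("KM times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("KM times must be strictly increasing")
        if np.any((s < 0) | (s > 1)):
            raise ValidationError("KM survival must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValidationError("KM survival must be non-increasing")
        if t[0] == 0 and not math.isclose(s[0], 1.0, abs_tol=1e-12):
            raise ValidationError("KM survival at t = 0 must equal 1")
        if self.n_at_risk is not None:
            n = np.asarray(self.n_at_risk, dtype=float)
            if n.shape != t.shape:
                raise ValidationError("n_at_risk must match times in length")
            object.__setattr__(self, "n_at_risk", n)

    def __len__(self) -> int:
        return int(self.times.size)

    def to_dataframe(self) -> pd.DataFrame:
        d = {"time_years": self.times, "survival": self.survival}
        if self.n_at_risk is not None:
            d["n_at_risk"] = self.n_at_risk
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "KMCurve":
        """Read a curve from CSV with columns ``time_years,survival[,n_at_risk]``."""
        df = pd.read_csv(path)
        for col in ("time_years", "survival"):
            if col not in df.columns:
                raise ValidationError(f"KM CSV missing required column '{col}'")
        n = df["n_at_risk"].to_numpy() if "n_at_risk" in df.columns else None
        return cls(
            times=df["time_years"].to_numpy(),
            survival=df["survival"].to_numpy(),
            n_at_risk=n,
        )


@dataclass(frozen=True)
class WeibullFit:
    """A fitted model plus least-squares diagnostics on the log-log scale."""

    model: WeibullSurvival
    r_squared: float
    residuals: np.ndarray
    n_used: int
    n_dropped: int


def fit_weibull(curve: KMCurve) -> WeibullFit:
    """Fit (lam, gamma) by least squares on ``ln(-ln S) = ln lam + gamma ln t``.

    Points with survival exactly 0 or 1, or with t = 0, carry no information
    on the log-log scale and are dropped with a warning. At least two usable
    points are required.
    """
    t = curve.times
    s = curve.survival
    usable = (s > 0.0) & (s < 1.0) & (t > 0.0)
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        warnings.warn(
            f"fit_weibull: dropped {n_dropped} point(s) with survival 0/1 or t=0",
            stacklevel=2,
        )
    if int(np.sum(usable)) < 2:
        raise InsufficientDataError(
            "fit_weibull needs >= 2 points with 0 < survival < 1 and t > 0"
        )
    x = np.log(t[usable])
    y = np.log(-np.log(s[usable]))
    gamma, log_lam = np.polyfit(x, y, 1)
    if gamma <= 0:
        raise CalibrationError(
            f"fitted shape gamma = {gamma:.4g} is not positive; "
            "curve is inconsistent with a Weibull survival model"
        )
    yhat = log_lam + gamma * x
    resid = y - yhat
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return WeibullFit(
        model=WeibullSurvival(lam=float(np.exp(log_lam)), gamma_shape=float(gamma)),
        r_squared=r2,
        residuals=resid,
        n_used=int(np.sum(usable)),
        n_dropped=n_dropped,
    )


def calibrate_weibull(
    milestone1: tuple[float, float], milestone2: tuple[float, float]
) -> WeibullSurvival:
    """Solve (lam, gamma) exactly from two milestone (time, survival) pairs.

    Uses gamma = ln(ln S1 / ln S2) / ln(t1 / t2) and lam = -ln S1 / t1**gamma,
    so that ``survival_at`` reproduces both milestones to machine precision.
    """
    (t1, s1), (t2, s2) = milestone1, milestone2
    for t, s in ((t1, s1), (t2, s2)):
        if t <= 0:
            raise CalibrationError(f"milestone times must be > 0, got {t}")
        if not (0.0 < s < 1.0):
            raise CalibrationError(f"milestone survival must be in (0, 1), got {s}")
    if t1 == t2:
        raise CalibrationError("milestone times must be distinct")
    # survival must decrease with time
    if (t2 > t1 and s2 >= s1) or (t2 < t1 and s2 <= s1):
        raise CalibrationError(
            "milestone survivals must decrease strictly with time "
            f"(got S({t1})={s1}, S({t2})={s2})"
        )
    gamma = math.log(math.log(s1) / math.log(s2)) / math.log(t1 / t2)
    if gamma <= 0 or not math.isfinite(gamma):
        raise CalibrationError(f"calibrated shape gamma = {gamma} is invalid")
    lam = -math.log(s1) / t1**gamma
    return WeibullSurvival(lam=lam, gamma_shape=gamma)
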