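"""Three-state cohort engine: failure-free survival, progression, death.

The cohort starts fully in the failure-free (FFS) state. Each cycle a
row-stochastic 3x3 matrix moves occupancy:

* FFS -> PS with the time-dependent Weibull transition probability,
* FFS -> death with a constant background mortality per cycle,
* PS -> death with the progressive-state Weibull transition probability,
* death is absorbing; PS cannot return to FFS.

``run_cohort`` propagates expected occupancy deterministically;
``microsim_oracle`` simulates individual trajectories from the same matrices
and serves as an independent stochastic cross-check of the cohort algebra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .parameters_io import ArmModel, ModelSettings
from .survival_models import transition_probability

__all__ = [
    "STATE_FFS",
    "STATE_PS",
    "STATE_DEAD",
    "CohortTrace",
    "build_transition_matrix",
    "run_cohort",
    "microsim_oracle",
]

STATE_FFS, STATE_PS, STATE_DEAD = 0, 1, 2


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy at every cycle boundary 0..N.

    ``occupancy`` has shape (N+1, 3) with columns (ffs, ps, dead); each row
    sums to 1 and the cohort starts at (1, 0, 0).
    """

    occupancy: np.ndarray
    cycle_length_years: float

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.ndim != 2 or occ.shape[1] != 3 or occ.shape[0] < 1:
            raise ValidationError("occupancy must have shape (N+1, 3)")
        if np.any(occ < -1e-12) or np.any(occ > 1 + 1e-12):
            raise ValidationError("occupancy fractions must lie in [0, 1]")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("occupancy rows must sum to 1")
        if self.cycle_length_years <= 0:
            raise ValidationError("cycle_length_years must be > 0")
        object.__setattr__(self, "cycle_length_years", float(self.cycle_length_years))

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def ffs(self) -> np.ndarray:
        return self.occupancy[:, STATE_FFS]

    @property
    def ps(self) -> np.ndarray:
        return self.occupancy[:, STATE_PS]

    @property
    def dead(self) -> np.ndarray:
        return self.occupancy[:, STATE_DEAD]

    @property
    def times(self) -> np.ndarray:
        """Model time in years at each cycle boundary."""
        return np.arange(self.occupancy.shape[0]) * self.cycle_length_years

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.occupancy.shape[0]),
                "time_years": self.times,
                "ffs": self.ffs,
                "ps": self.ps,
                "dead": self.dead,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_transition_matrix(
    arm: ArmModel, settings: ModelSettings, t: int
) -> np.ndarray:
    """Row-stochastic 3x3 transition matrix for cycle index ``t``.

    FFS competes progression against background mortality additively; if the
    two probabilities would exceed 1, progression is clipped with a warning.
    """
    if t < 0:
        raise ValidationError("cycle index t must be >= 0")
    c = settings.cycle_length_years
    p_prog = transition_probability(arm.ffs_to_ps, t, c)
    p_die_ps = transition_probability(arm.ps_to_death, t, c)
    p_bg = settings.background_mortality_per_cycle
    if p_prog + p_bg > 1.0:
        warnings.warn(
            f"cycle {t}: FFS exit probabilities overflow "
            f"(progression {p_prog:.4g} + background {p_bg:.4g} > 1); "
            "progression clipped",
            stacklevel=2,
        )
        p_prog = 1.0 - p_bg
    m = np.array(
        [
            [1.0 - p_prog - p_bg, p_prog, p_bg],
            [0.0, 1.0 - p_die_ps, p_die_ps],
            [0.0, 0.0, 1.0],
        ]
    )
    return m


def run_cohort(arm: ArmModel, settings: ModelSettings) -> CohortTrace:
    """Propagate expected state occupancy over the full horizon."""
    n = settings.n_cycles
    occ = np.zeros((n + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    for k in range(n):
        occ[k + 1] = occ[k] @ build_transition_matrix(arm, settings, k)
    return CohortTrace(occupancy=occ, cycle_length_years=settings.cycle_length_years)


def microsim_oracle(
    arm: ArmModel, settings: ModelSettings, n_individuals: int, seed: int
) -> CohortTrace:
    """Empirical occupancy from ``n_individuals`` simulated trajectories.

    Each individual draws its next state from the same per-cycle matrices the
    cohort engine uses; the empirical trace converges to the deterministic
    one at the binomial rate sqrt(p(1-p)/n).
    """
    if n_individuals < 1:
        raise ValidationError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    n_cycles = settings.n_cycles
    states = np.zeros(n_individuals, dtype=np.int64)  # all start in FFS
    occ = np.zeros((n_cycles + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    for k in range(n_cycles):
        m = build_transition_matrix(arm, settings, k)
        cum = np.cumsum(m, axis=1)
        u = rng.random(n_individuals)
        # next state = first column whose cumulative probability exceeds u
        states = (u[:, None] > cum[states]).sum(axis=1)
        counts = np.bincount(states, minlength=3)
        occ[k + 1] = counts / n_individuals
    return CohortTrace(occupancy=occ, cycle_length_years=settings.cycle_length_years)
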