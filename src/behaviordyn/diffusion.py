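"""Aggregate (non-network) behavior-adoption models.

Three nested views of the same diffusion process:

* a discrete recurrence ``S(t) = S(t-1) + a(1-S(t-1)) + b(1-S(t-1))S(t-1)``
  where ``a`` is the rate of spontaneous/environmental behavior contraction
  and ``b`` the rate of contraction by social imitation;
* its continuous limit ``dS/dt = (a + b S)(1 - S)`` with a logistic-type
  closed form for ``S(0) = 0``;
* stock-and-flow formulations in counts: a word-of-mouth adoption model
  (PotentialAdopters/Adopters with AdoptionFromImitation and
  AdoptionFromWOM flows) and a classic SIR compartment model.

All ODE integration uses an adaptive explicit Runge-Kutta scheme
(``scipy.integrate.solve_ivp``) with fixed output sampling; the models are
non-stiff at realistic parameter ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "DiffusionParams",
    "AdoptionTrajectory",
    "SDAdoptionParams",
    "SIRParams",
    "step_discrete_adoption",
    "simulate_discrete_adoption",
    "adoption_closed_form",
    "simulate_sd_adoption",
    "simulate_sir",
    "time_to_adoption",
]


@dataclass(frozen=True)
class DiffusionParams:
    """Rates of the difference-equation model.

    alpha : spontaneous/environmental contraction rate per unit time (>= 0)
    beta  : social/imitation contraction rate per unit time (>= 0)
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


@dataclass(frozen=True)
class AdoptionTrajectory:
    """Adopted fraction S(t) sampled at strictly increasing time points."""

    times: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fraction, dtype=float)
        if t.ndim != 1 or t.shape != f.shape:
            raise ValueError("times and fraction must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("trajectory must contain at least one point")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fraction", f)


@dataclass(frozen=True)
class SDAdoptionParams:
    """Fixed factors of the stock-and-flow adoption model.

    total_population         : population size N (> 0)
    contact_rate             : contacts per person per unit time (>= 0)
    adoption_fraction        : probability a contact yields adoption, in [0, 1]
    imitation_effectiveness  : per-unit-time spontaneous-adoption hazard, in [0, 1]
    """

    total_population: float
    contact_rate: float
    adoption_fraction: float
    imitation_effectiveness: float

    def __post_init__(self) -> None:
        if self.total_population <= 0:
            raise ValueError("total_population must be positive")
        if self.contact_rate < 0:
            raise ValueError("contact_rate must be non-negative")
        if not 0.0 <= self.adoption_fraction <= 1.0:
            raise ValueError("adoption_fraction must be in [0, 1]")
        if not 0.0 <= self.imitation_effectiveness <= 1.0:
            raise ValueError("imitation_effectiveness must be in [0, 1]")


@dataclass(frozen=True)
class SIRParams:
    """SIR model in counts.

    Either supply the mechanistic factors (contact_rate_c, infectivity,
    avg_duration) or build from normalized rates via :meth:`from_rates`.
    InfectionRate = c * i * S * I / N, RecoveryRate = I / D.
    """

    contact_rate_c: float
    infectivity: float
    avg_duration: float
    total_population: float
    initial_infectious: float
    initial_recovered: float = 0.0

    def __post_init__(self) -> None:
        if min(self.contact_rate_c, self.infectivity, self.total_population) < 0:
            raise ValueError("rates and population must be non-negative")
        if not 0.0 <= self.infectivity <= 1.0:
            raise ValueError("infectivity must be in [0, 1]")
        if self.avg_duration <= 0:
            raise ValueError("avg_duration must be positive")
        if not 0 <= self.initial_infectious <= self.total_population:
            raise ValueError("initial_infectious must be in [0, total_population]")

    @classmethod
    def from_rates(
        cls,
        rho: float,
        recovery_rate: float,
        initial_infectious_fraction: float,
        total_population: float = 1.0,
    ) -> "SIRParams":
        """Normalized parameterization: transmission rate rho, recovery rate."""
        if recovery_rate <= 0:
            raise ValueError("recovery_rate must be positive")
        return cls(
            contact_rate_c=rho,
            infectivity=1.0,
            avg_duration=1.0 / recovery_rate,
            total_population=total_population,
            initial_infectious=initial_infectious_fraction * total_population,
        )

    @property
    def rho(self) -> float:
        return self.contact_rate_c * self.infectivity

    @property
    def recovery_rate(self) -> float:
        return 1.0 / self.avg_duration


def step_discrete_adoption(s_prev: float, params: DiffusionParams) -> float:
    """One step of the adoption recurrence, clipped to [0, 1].

    Returns ``s + alpha*(1-s) + beta*(1-s)*s``. Large ``alpha + beta`` can
    overshoot 1 in the raw recurrence; the result is clipped because S is a
    population fraction.
    """
    if not 0.0 <= s_prev <= 1.0:
        raise ValueError(f"s_prev must be in [0, 1], got {s_prev}")
    s_new = s_prev + params.alpha * (1.0 - s_prev) + params.beta * (1.0 - s_prev) * s_prev
    return min(max(s_new, 0.0), 1.0)


def simulate_discrete_adoption(
    params: DiffusionParams, s0: float, n_steps: int, dt: float = 1.0
) -> AdoptionTrajectory:
    """Iterate the recurrence for ``n_steps`` steps starting from ``s0``.

    With ``dt != 1`` the rates are scaled by ``dt`` per step (Euler view of
    the continuous model); times are reported as multiples of ``dt``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0.0 <= s0 <= 1.0:
        raise ValueError("s0 must be in [0, 1]")
    scaled = DiffusionParams(params.alpha * dt, params.beta * dt)
    values = np.empty(n_steps + 1)
    values[0] = s0
    s = s0
    for k in range(1, n_steps + 1):
        s = step_discrete_adoption(s, scaled)
        values[k] = s
    times = dt * np.arange(n_steps + 1)
    return AdoptionTrajectory(times=times, fraction=values)


def adoption_closed_form(params: DiffusionParams, t) -> np.ndarray | float:
    """Continuous-time solution of dS/dt = (alpha + beta S)(1 - S) with S(0)=0.

    S(t) = (1 - e^{-(a+b)t}) / (1 + (b/a) e^{-(a+b)t}); requires alpha > 0
    (the expression is undefined as written for alpha = 0).
    """
    if params.alpha <= 0:
        raise ValueError("closed form requires alpha > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    e = np.exp(-(params.alpha + params.beta) * t_arr)
    out = (1.0 - e) / (1.0 + (params.beta / params.alpha) * e)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _sd_flows(potential: np.ndarray, params: SDAdoptionParams):
    adopters = params.total_population - potential
    from_imitation = potential * params.imitation_effectiveness
    from_wom = (
        adopters
        * potential
        * params.contact_rate
        * params.adoption_fraction
        / params.total_population
    )
    return from_imitation, from_wom


def simulate_sd_adoption(
    params: SDAdoptionParams,
    adopters0: float,
    horizon: float,
    dt: float,
    rtol: float = 1e-9,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Integrate the stock-and-flow adoption model.

    State: PotentialAdopters P with d(P)/dt = -(AdoptionFromImitation +
    AdoptionFromWOM); Adopters = N - P by conservation. Returns one row per
    output time with both stocks and all flows.
    """
    if not 0 <= adopters0 <= params.total_population:
        raise ValueError("adopters0 must be in [0, total_population]")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= horizon:
        raise ValueError("dt must be smaller than horizon")

    def rhs(_t, y):
        fi, fw = _sd_flows(y, params)
        return -(fi + fw)

    t_eval = np.arange(0.0, horizon + 0.5 * dt, dt)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        [params.total_population - adopters0],
        t_eval=t_eval,
        method="RK45",
        rtol=rtol,
        atol=atol * params.total_population,
    )
    if not sol.success:  # pragma: no cover - non-stiff model
        raise RuntimeError(f"integration failed: {sol.message}")
    potential = np.clip(sol.y[0], 0.0, params.total_population)
    fi, fw = _sd_flows(potential, params)
    return pd.DataFrame(
        {
            "time": sol.t,
            "potential_adopters": potential,
            "adopters": params.total_population - potential,
            "adoption_from_imitation": fi,
            "adoption_from_wom": fw,
            "adoption_rate": fi + fw,
        }
    )


def simulate_sir(
    params: SIRParams,
    horizon: float,
    dt: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Integrate the SIR model in compartment fractions.

    Initial state: S(0) = N - I0 - R0, R(0) = R0 (default 0). Columns s, i, r
    are fractions of the total population; conservation s+i+r = 1 holds to
    integration tolerance.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= horizon:
        raise ValueError("dt must be smaller than horizon")
    n = params.total_population
    i0 = params.initial_infectious / n
    r0 = params.initial_recovered / n
    s0 = 1.0 - i0 - r0
    rho, gamma = params.rho, params.recovery_rate

    def rhs(_t, y):
        s, i = y
        inf = rho * s * i
        return [-inf, inf - gamma * i]

    t_eval = np.arange(0.0, horizon + 0.5 * dt, dt)
    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), [s0, i0], t_eval=t_eval,
                    method="RK45", rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"integration failed: {sol.message}")
    s, i = sol.y
    if np.any(s < -1e-9) or np.any(i < -1e-9):
        raise RuntimeError("negative compartment encountered; reduce dt or tolerances")
    return pd.DataFrame({"time": sol.t, "s": s, "i": i, "r": 1.0 - s - i})


def time_to_adoption(traj: AdoptionTrajectory, level: float) -> Optional[float]:
    """First time the trajectory crosses ``level``, linearly interpolated.

    Returns None if the level is never reached. ``level`` must lie strictly
    between 0 and 1.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    t = np.asarray(traj.times, dtype=float)
    f = np.asarray(traj.fraction, dtype=float)
    if t.size == 0:
        raise ValueError("empty trajectory")
    if f[0] >= level:
        return float(t[0])
    above = np.nonzero(f >= level)[0]
    if above.size == 0:
        return None
    k = above[0]
    t0, t1, f0, f1 = t[k - 1], t[k], f[k - 1], f[k]
    if f1 == f0:  # exact hit handled above; defensive
        return float(t1)
    return float(t0 + (level - f0) * (t1 - t0) / (f1 - f0))


def sd_trajectory_to_adoption(df: pd.DataFrame, total_population: float) -> AdoptionTrajectory:
    """Convert a stock-and-flow run (counts) to an adopted-fraction trajectory."""
    return AdoptionTrajectory(
        times=df["time"].to_numpy(), fraction=df["adopters"].to_numpy() / total_population
    )
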