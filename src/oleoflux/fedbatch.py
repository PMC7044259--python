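"""Exponential fed-batch feeding design and bioreactor mass-balance simulation.

The open-loop exponential feed

    F(t) = Y_XS * mu0 * x0 * V0 * exp(mu0 * t) / (c_f - c_s)

delivers substrate at exactly the rate a culture growing at constant mu0
consumes it (Y_XS is the substrate consumed per biomass formed, g/gDW), so
under ideal growth the vessel substrate concentration stays at its starting
value and total biomass follows x0*V0*exp(mu0*t).  The simulator integrates
the vessel mass balances with a fixed-step classical Runge-Kutta scheme and
also supports a phased growth schedule, for exploring what happens when the
culture does not follow the design assumption (substrate then accumulates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FedBatchPlan", "FedBatchTrajectory", "feed_rate", "simulate"]


@dataclass
class FedBatchPlan:
    """Design parameters of the exponential feed.

    y_xs: substrate consumed per biomass formed (g/gDW); mu0: design growth
    rate (1/h); cf: feed substrate concentration (g/L); cs0: vessel substrate
    concentration at feed start (g/L, the design treats it as constant);
    x0: biomass at feed start (gDW/L); v0: volume at feed start (L).
    """

    y_xs: float
    mu0: float
    cf: float
    cs0: float
    x0: float
    v0: float
    duration: float = 48.0

    def __post_init__(self) -> None:
        if not self.cf > self.cs0 >= 0:
            raise ValueError(
                f"feed concentration ({self.cf} g/L) must exceed the vessel "
                f"concentration ({self.cs0} g/L), which must be non-negative"
            )
        if self.mu0 < 0:
            raise ValueError(f"mu0 must be non-negative, got {self.mu0}")
        if self.x0 <= 0 or self.v0 <= 0:
            raise ValueError("x0 and v0 must be positive")
        if self.y_xs <= 0:
            raise ValueError(f"y_xs must be positive, got {self.y_xs}")


@dataclass
class FedBatchTrajectory:
    """Time series of vessel state: V (L), x (gDW/L), cs (g/L), F (L/h)."""

    time: np.ndarray
    volume: np.ndarray
    biomass: np.ndarray
    substrate: np.ndarray
    feed: np.ndarray
    substrate_limited: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.time,
                "V": self.volume,
                "x": self.biomass,
                "cs": self.substrate,
                "F": self.feed,
            }
        )

    @property
    def total_biomass(self) -> np.ndarray:
        """x*V in gDW."""
        return self.biomass * self.volume


def feed_rate(plan: FedBatchPlan, t: float | np.ndarray) -> float | np.ndarray:
    """Feed flow in L/h at time t (h) for the exponential design."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    rate = plan.y_xs * plan.mu0 * plan.x0 * plan.v0 * np.exp(plan.mu0 * t) / (
        plan.cf - plan.cs0
    )
    return rate if rate.ndim else float(rate)


def _mu_schedule(growth_model, mu0: float):
    if growth_model == "ideal":
        return lambda t, cs: mu0
    # phased: list of (duration h, mu 1/h); last phase extends indefinitely
    phases = list(growth_model)
    edges = np.concatenate([[0.0], np.cumsum([d for d, _ in phases])])
    mus = [mu for _, mu in phases]

    def mu_at(t: float, cs: float) -> float:
        idx = int(np.searchsorted(edges, t, side="right")) - 1
        return mus[min(idx, len(mus) - 1)]

    return mu_at


def simulate(
    plan: FedBatchPlan,
    growth_model="ideal",
    dt: float = 0.01,
) -> FedBatchTrajectory:
    """Integrate the fed-batch mass balances at fixed step dt (h).

    State: V (volume), X = x*V (total biomass, gDW), M = cs*V (total
    substrate, g).  dV/dt = F;  dX/dt = mu_eff*X;  dM/dt = F*cf -
    Y_XS*mu_eff*X.  ``growth_model`` is "ideal" (mu_eff = mu0) or a list of
    (duration, mu) phases.  When the vessel substrate is exhausted, growth
    is capped at the rate the incoming feed can support (consumption equals
    supply), the substrate mass is clipped at zero, and the trajectory is
    flagged substrate-limited.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    mu_at = _mu_schedule(growth_model, plan.mu0)
    n_steps = int(round(plan.duration / dt))
    times = np.arange(n_steps + 1) * dt
    V = np.empty(n_steps + 1)
    X = np.empty(n_steps + 1)
    M = np.empty(n_steps + 1)
    V[0], X[0], M[0] = plan.v0, plan.x0 * plan.v0, plan.cs0 * plan.v0
    limited = False

    def deriv(t: float, state: np.ndarray) -> np.ndarray:
        nonlocal limited
        v, x_tot, m = state
        F = feed_rate(plan, t)
        mu = mu_at(t, m / v)
        supply = F * plan.cf
        demand = plan.y_xs * mu * x_tot
        if m <= 0.0 and demand > supply * (1.0 + 1e-9):
            limited = True
            mu = supply / (plan.y_xs * x_tot) if x_tot > 0 else 0.0
            demand = supply
        return np.array([F, mu * x_tot, supply - demand])

    state = np.array([V[0], X[0], M[0]])
    for i in range(n_steps):
        t = times[i]
        k1 = deriv(t, state)
        k2 = deriv(t + dt / 2, state + dt / 2 * k1)
        k3 = deriv(t + dt / 2, state + dt / 2 * k2)
        k4 = deriv(t + dt, state + dt * k3)
        state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if state[2] < 0.0:
            limited = True
            state[2] = 0.0
        V[i + 1], X[i + 1], M[i + 1] = state

    return FedBatchTrajectory(
        time=times,
        volume=V,
        biomass=X / V,
        substrate=M / V,
        feed=np.asarray(feed_rate(plan, times)),
        substrate_limited=limited,
    )
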