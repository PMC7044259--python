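"""Linear-programming core: FBA, flux variability, and solution-space sampling.

All solves go through :func:`scipy.optimize.linprog` with the HiGHS backend.
The steady-state problem is

    max/min  c^T v   s.t.  S v = 0,  lb <= v <= ub,

with fluxes in mmol/gDW/h (biomass in 1/h).  Alternate optima are not
tie-broken; they are surfaced through FVA and through random sampling of the
solution space, in which each sample is the optimal vertex of a uniformly
random-weighted, random-signed linear objective over all reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .gem_core import StoichiometricModel

__all__ = [
    "FluxDistribution",
    "FluxRange",
    "FluxSample",
    "InfeasibleModelError",
    "fba",
    "fva",
    "random_sample",
]

#: contract-level tolerance on S·v = 0 and bound violations
STEADY_STATE_TOL = 1e-6


class InfeasibleModelError(RuntimeError):
    """Raised when an operation requires a feasible model but the LP is not."""


@dataclass
class FluxDistribution:
    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class FluxRange:
    """Per-reaction feasible flux intervals, both endpoints achievable."""

    minimum: dict[str, float]
    maximum: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"min_flux": pd.Series(self.minimum), "max_flux": pd.Series(self.maximum)}
        ).rename_axis("reaction")

    def contains(self, fluxes: dict[str, float], tol: float = STEADY_STATE_TOL) -> bool:
        return all(
            self.minimum[r] - tol <= v <= self.maximum[r] + tol
            for r, v in fluxes.items()
            if r in self.minimum
        )


@dataclass
class FluxSample:
    """n_samples x n_reactions matrix of vertex solutions."""

    matrix: np.ndarray
    reaction_ids: list[str]
    seed: int
    n: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n == 0:
            self.n = self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.reaction_ids)

    def column(self, rxn_id: str) -> np.ndarray:
        return self.matrix[:, self.reaction_ids.index(rxn_id)]

    def mean(self) -> dict[str, float]:
        return dict(zip(self.reaction_ids, self.matrix.mean(axis=0)))

    def summary(self) -> pd.DataFrame:
        """Per-reaction mean and central 95% interval."""
        q = np.quantile(self.matrix, [0.025, 0.975], axis=0)
        return pd.DataFrame(
            {
                "mean": self.matrix.mean(axis=0),
                "q2.5": q[0],
                "q97.5": q[1],
            },
            index=pd.Index(self.reaction_ids, name="reaction"),
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _solve(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    direction: str,
) -> tuple[str, np.ndarray | None, float | None]:
    sign = -1.0 if direction == "max" else 1.0
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9, "dual_feasibility_tolerance": 1e-9},
    )
    if res.status == 2:
        return "infeasible", None, None
    if res.status == 3:
        return "unbounded", None, None
    if res.status != 0:  # pragma: no cover - solver failure
        raise RuntimeError(f"LP solver failed: {res.message}")
    return "optimal", res.x, sign * res.fun


def fba(
    model: StoichiometricModel,
    objective: dict[str, float] | None = None,
    direction: str = "max",
) -> FluxDistribution:
    """Flux balance analysis: optimize a linear objective over the flux cone.

    ``objective`` maps reaction id to weight; when omitted the model's own
    objective (or its biomass reaction) is used.  The returned status is
    ``optimal``, ``infeasible`` or ``unbounded``; fluxes are only present for
    optimal solves.
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    obj = objective or model.objective or {model.biomass_reaction_id: 1.0}
    rxn_pos = {r: j for j, r in enumerate(model.reaction_ids)}
    c = np.zeros(len(model.reactions))
    for rxn_id, weight in obj.items():
        c[rxn_pos[rxn_id]] = weight
    lb, ub = model.bounds()
    status, x, value = _solve(model.stoichiometric_matrix(), lb, ub, c, direction)
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=None, status=status)
    return FluxDistribution(
        fluxes=dict(zip(model.reaction_ids, x)), objective_value=value, status=status
    )


def fva(
    model: StoichiometricModel,
    reactions: list[str] | None = None,
    fraction_of_optimum: float | None = None,
) -> FluxRange:
    """Flux variability analysis: per-reaction min and max flux.

    With ``fraction_of_optimum`` f, the model objective is first maximized and
    the constraint  c^T v >= f * optimum  is appended before iterating.
    """
    work = model.copy()
    if fraction_of_optimum is not None:
        if not 0.0 <= fraction_of_optimum <= 1.0:
            raise ValueError("fraction_of_optimum must lie in [0, 1]")
        sol = fba(work)
        if sol.status != "optimal":
            raise InfeasibleModelError(f"model {model.id} is {sol.status}; cannot run FVA")
        # encode c^T v >= f*opt as an extra "objective" pseudo-metabolite row
        # by fixing the objective reaction set via an inequality -> use A_ub
        S = work.stoichiometric_matrix()
        lb, ub = work.bounds()
        obj = work.objective or {work.biomass_reaction_id: 1.0}
        rxn_pos = {r: j for j, r in enumerate(work.reaction_ids)}
        c_obj = np.zeros(len(work.reactions))
        for rxn_id, weight in obj.items():
            c_obj[rxn_pos[rxn_id]] = weight
        target = fraction_of_optimum * sol.objective_value
        minimum, maximum = {}, {}
        for j, rxn_id in enumerate(work.reaction_ids):
            c = np.zeros(len(work.reactions))
            c[j] = 1.0
            for direction, store in (("min", minimum), ("max", maximum)):
                sign = -1.0 if direction == "max" else 1.0
                res = linprog(
                    sign * c,
                    A_eq=S,
                    b_eq=np.zeros(S.shape[0]),
                    A_ub=-c_obj[None, :],
                    b_ub=np.array([-target]),
                    bounds=list(zip(lb, ub)),
                    method="highs",
                )
                if res.status != 0:
                    raise InfeasibleModelError(
                        f"FVA subproblem for {rxn_id} returned status {res.status}"
                    )
                store[rxn_id] = sign * res.fun
        return FluxRange(minimum=minimum, maximum=maximum)

    S = work.stoichiometric_matrix()
    lb, ub = work.bounds()
    probe = _solve(S, lb, ub, np.zeros(len(work.reactions)), "min")
    if probe[0] != "optimal":
        raise InfeasibleModelError(f"model {model.id} is {probe[0]}; cannot run FVA")
    ids = reactions if reactions is not None else work.reaction_ids
    minimum, maximum = {}, {}
    for rxn_id in ids:
        j = work.reaction_ids.index(rxn_id)
        c = np.zeros(len(work.reactions))
        c[j] = 1.0
        for direction, store in (("min", minimum), ("max", maximum)):
            status, x, value = _solve(S, lb, ub, c, direction)
            if status != "optimal":  # bounded box -> cannot be unbounded
                raise InfeasibleModelError(f"FVA for {rxn_id}: {status}")
            store[rxn_id] = value
    return FluxRange(minimum=minimum, maximum=maximum)


def random_sample(model: StoichiometricModel, n: int, seed: int) -> FluxSample:
    """Random-objective vertex sampling of the solution space.

    Each of the ``n`` samples is the optimal vertex of maximizing a random
    objective with independent standard-normal weights over every reaction
    (weights are symmetric about zero, so reaction directions are sampled
    without bias).  Deterministic given ``seed``; equivariant under reaction
    reordering because sample ``i`` draws one weight vector from a generator
    seeded with ``(seed, i)`` and assigns it to reactions in lexicographic id
    order, not storage order.
    """
    if n <= 0:
        raise ValueError(f"number of samples must be positive, got {n}")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds()
    probe = _solve(S, lb, ub, np.zeros(len(model.reactions)), "min")
    if probe[0] != "optimal":
        raise InfeasibleModelError(f"model {model.id} is {probe[0]}; cannot sample")
    lex_order = np.argsort(np.array(model.reaction_ids))
    rows = np.empty((n, len(model.reactions)))
    for i in range(n):
        c = np.empty(len(model.reactions))
        c[lex_order] = np.random.default_rng([seed, i]).standard_normal(
            len(model.reactions)
        )
        status, x, _ = _solve(S, lb, ub, c, "max")
        if status != "optimal":  # pragma: no cover - bounded by construction
            raise InfeasibleModelError(f"sampling LP {i} returned {status}")
        rows[i] = x
    return FluxSample(matrix=rows, reaction_ids=list(model.reaction_ids), seed=seed, n=n)
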