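"""Steady-state flux polytope and linear programming utilities.

The feasible set of a metabolic model at quasi-steady state is the polytope
``{v : S v = 0, lb <= v <= ub}`` with S the stoichiometric matrix.  Carving,
flux variability analysis and polytope sampling all operate on this object;
LPs are solved with HiGHS through :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import numpy as np
from cobra.util.array import create_stoichiometric_matrix
from scipy.optimize import linprog

__all__ = ["FluxPolytope", "polytope_from_model", "maximize", "fva"]


class InfeasibleError(RuntimeError):
    """The steady-state constraints admit no flux vector within bounds."""


@dataclass
class FluxPolytope:
    """``S v = 0``, ``lb <= v <= ub`` with named reaction/metabolite axes."""

    S: np.ndarray  # metabolites x reactions
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    _bounds: list[tuple[float, float]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._bounds = list(zip(self.lb.tolist(), self.ub.tolist()))

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    def index(self, reaction_id: str) -> int:
        return self.reaction_ids.index(reaction_id)

    def contains(self, v: np.ndarray, tol_eq: float = 1e-6, tol_bound: float = 1e-9) -> bool:
        v = np.asarray(v, dtype=float)
        return bool(
            np.all(np.abs(self.S @ v) <= tol_eq)
            and np.all(v >= self.lb - tol_bound)
            and np.all(v <= self.ub + tol_bound)
        )


def polytope_from_model(model: cobra.Model) -> FluxPolytope:
    S = create_stoichiometric_matrix(model, array_type="dense")
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return FluxPolytope(
        S=np.asarray(S, dtype=float),
        lb=lb,
        ub=ub,
        reaction_ids=[r.id for r in model.reactions],
        metabolite_ids=[m.id for m in model.metabolites],
    )


def maximize(pol: FluxPolytope, c: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximize ``c . v`` over the polytope; returns (optimal vertex, optimum)."""
    res = linprog(
        -np.asarray(c, dtype=float),
        A_eq=pol.S,
        b_eq=np.zeros(pol.S.shape[0]),
        bounds=pol._bounds,
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError("steady-state constraints are infeasible within bounds")
    if res.status != 0:
        raise InfeasibleError(f"LP failed (HiGHS status {res.status}): {res.message}")
    return res.x, -res.fun


def fva(pol: FluxPolytope, indices: list[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-reaction flux minima and maxima (flux variability analysis)."""
    if indices is None:
        indices = list(range(pol.n_reactions))
    mins = np.empty(len(indices))
    maxs = np.empty(len(indices))
    c = np.zeros(pol.n_reactions)
    for k, i in enumerate(indices):
        c[:] = 0.0
        c[i] = 1.0
        _, maxs[k] = maximize(pol, c)
        c[i] = -1.0
        _, neg = maximize(pol, c)
        mins[k] = -neg
    return mins, maxs
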