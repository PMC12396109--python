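"""Context-specific model extraction by evidence-weighted reaction carving.

Top-down carving keeps the subnetwork of a universal metabolic model that
best agrees with a condition's expressed-gene list while still sustaining a
minimum biomass flux.  Each reaction gets an evidence score from evaluating
its GPR rule against the expressed set (+1 supported, -penalty_absent
contradicted, 0 for GPR-less reactions, which carry a small parsimony
penalty instead).  A mixed-integer program then selects the reaction subset
maximizing total evidence subject to steady state, bounds, and biomass
functionality; supported reactions are only rewarded when they carry a
non-negligible flux in the optimal solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import LinearConstraint, milp

from . import lp
from .gpr import evaluate_gpr, parse_gpr
from .model_io import biomass_id

__all__ = [
    "CarveConfig",
    "CarveResult",
    "score_reactions",
    "max_biomass",
    "carve",
    "remove_blocked",
]

logger = logging.getLogger(__name__)


@dataclass
class CarveConfig:
    """Carving parameters.

    f_min
        Fraction of the universal model's maximal biomass flux the carved
        model must sustain (dimensionless, default 0.1).
    penalty_absent
        Weight against keeping a reaction whose GPR evaluates FALSE
        (dimensionless, default 1.0 — one supported reaction balances one
        contradicted one).
    penalty_nogpr
        Parsimony weight against GPR-less reactions (default 0.01, so one
        supported reaction outweighs many spontaneous/transport carriers).
    flux_activation_eps
        Minimum |flux| for a supported reaction to count as active, in the
        model's flux units (default 1e-4).
    solver_gap
        Relative MILP optimality gap (default 1e-6).
    """

    f_min: float = 0.1
    penalty_absent: float = 1.0
    penalty_nogpr: float = 0.01
    flux_activation_eps: float = 1e-4
    solver_gap: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.f_min <= 1:
            raise ValueError("f_min must lie in (0, 1]")
        if self.penalty_absent < 0 or self.penalty_nogpr < 0:
            raise ValueError("penalties must be non-negative")
        if self.flux_activation_eps <= 0:
            raise ValueError("flux_activation_eps must be positive")


@dataclass
class CarveResult:
    model: cobra.Model
    report: pd.DataFrame  # reaction_id, score, included, flux
    objective_value: float
    included: list[str] = field(default_factory=list)


def score_reactions(
    model: cobra.Model,
    expressed: set[str] | frozenset[str],
    config: CarveConfig | None = None,
) -> dict[str, float]:
    """Evidence score per reaction from GPR evaluation against ``expressed``.

    +1 if the rule is satisfied, ``-penalty_absent`` if contradicted, 0 for
    reactions without a rule.  Expressed ids absent from the model's gene
    namespace are ignored (count logged).
    """
    config = config or CarveConfig()
    expressed = frozenset(g.strip() for g in expressed)
    known: set[str] = set()
    scores: dict[str, float] = {}
    for rxn in model.reactions:
        expr = parse_gpr(rxn.gene_reaction_rule)
        if expr is None:
            scores[rxn.id] = 0.0
            continue
        known |= expr.genes()
        scores[rxn.id] = 1.0 if evaluate_gpr(expr, expressed) else -config.penalty_absent
    unknown = len(expressed - known)
    if unknown:
        logger.info("%d expressed ids not in the model's gene namespace (ignored)", unknown)
    return scores


def max_biomass(model: cobra.Model) -> float:
    """LP optimum of biomass flux subject to ``S v = 0`` and bounds."""
    pol = lp.polytope_from_model(model)
    c = np.zeros(pol.n_reactions)
    c[pol.index(biomass_id(model))] = 1.0
    _, opt = lp.maximize(pol, c)
    if opt <= 0:
        logger.warning(
            "maximal biomass flux is %g; carving will be unconstrained by functionality", opt
        )
    return opt


def _build_milp(pol, scores, bio_idx, vmax, config):
    """Assemble the carving MILP in scipy.optimize.milp form.

    Variable layout: fluxes v (n), then per positive-score reaction two
    direction binaries (y+, y-), then per non-positive-score reaction one
    inclusion binary y.  Supported reactions are rewarded only when active
    (|v| >= eps), enforced by eps*y+ + lb*y- <= v <= ub*y+ - eps*y- with
    y+ + y- <= 1; the biomass reaction is unconditionally included.
    """
    n = pol.n_reactions
    eps = config.flux_activation_eps
    pos = [i for i in range(n) if scores[i] > 0 and i != bio_idx]
    other = [i for i in range(n) if scores[i] <= 0 and i != bio_idx]

    n_var = n + 2 * len(pos) + len(other)
    cost = np.zeros(n_var)
    integrality = np.zeros(n_var)
    var_lb = np.concatenate([pol.lb, np.zeros(n_var - n)])
    var_ub = np.concatenate([pol.ub, np.ones(n_var - n)])
    integrality[n:] = 1
    var_lb[n + np.arange(2 * len(pos) + len(other))] = 0.0
    # biomass functionality: v_bio >= f_min * vmax
    var_lb[bio_idx] = max(pol.lb[bio_idx], config.f_min * vmax)

    rows, cols, vals = [], [], []
    con_lb, con_ub = [], []
    row = 0

    def add(entries, lo, hi):
        nonlocal row
        for j, a in entries:
            rows.append(row)
            cols.append(j)
            vals.append(a)
        con_lb.append(lo)
        con_ub.append(hi)
        row += 1

    # S v = 0
    S = sparse.coo_matrix(pol.S)
    for i, j, a in zip(S.row, S.col, S.data):
        rows.append(int(i))
        cols.append(int(j))
        vals.append(float(a))
    row = pol.S.shape[0]
    con_lb.extend([0.0] * row)
    con_ub.extend([0.0] * row)

    for k, i in enumerate(pos):
        jp = n + 2 * k  # y+
        jm = n + 2 * k + 1  # y-
        add([(i, 1.0), (jp, -pol.ub[i]), (jm, eps)], -np.inf, 0.0)  # v <= ub*y+ - eps*y-
        add([(i, 1.0), (jp, -eps), (jm, -pol.lb[i])], 0.0, np.inf)  # v >= eps*y+ + lb*y-
        add([(jp, 1.0), (jm, 1.0)], -np.inf, 1.0)
        cost[jp] = cost[jm] = -scores[i]  # milp minimizes
    for k, i in enumerate(other):
        j = n + 2 * len(pos) + k
        add([(i, 1.0), (j, -pol.ub[i])], -np.inf, 0.0)  # v <= ub*y
        add([(i, 1.0), (j, -pol.lb[i])], 0.0, np.inf)  # v >= lb*y
        cost[j] = config.penalty_nogpr if scores[i] == 0 else -scores[i]

    A = sparse.csr_matrix((vals, (rows, cols)), shape=(len(con_lb), n_var))
    constraints = LinearConstraint(A, np.array(con_lb), np.array(con_ub))
    return cost, integrality, (var_lb, var_ub), constraints, pos, other


def carve(
    model: cobra.Model,
    scores: dict[str, float],
    config: CarveConfig | None = None,
) -> CarveResult:
    """Solve the carving MILP and return the context-specific submodel.

    The returned model contains exactly the selected reactions (biomass
    always among them) and the metabolites they reference; ids, bounds,
    stoichiometry and GPRs of retained reactions are unchanged.
    """
    config = config or CarveConfig()
    pol = lp.polytope_from_model(model)
    bio = biomass_id(model)
    bio_idx = pol.index(bio)
    vmax = max_biomass(model)
    score_vec = np.array([scores[r] for r in pol.reaction_ids])

    cost, integrality, bounds, constraints, pos, other = _build_milp(
        pol, score_vec, bio_idx, vmax, config
    )
    from scipy.optimize import Bounds

    res = milp(
        c=cost,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(bounds[0], bounds[1]),
        options={"mip_rel_gap": config.solver_gap},
    )
    if res.status == 2:
        raise lp.InfeasibleError(
            f"carving MILP infeasible at f_min={config.f_min}; try a lower --f-min"
        )
    if res.status != 0:
        raise RuntimeError(f"carving MILP failed (status {res.status}): {res.message}")

    n = pol.n_reactions
    x = res.x
    included_mask = np.zeros(n, dtype=bool)
    included_mask[bio_idx] = True
    for k, i in enumerate(pos):
        included_mask[i] = x[n + 2 * k] + x[n + 2 * k + 1] > 0.5
    for k, i in enumerate(other):
        included_mask[i] = x[n + 2 * len(pos) + k] > 0.5

    fluxes = x[:n]
    report = pd.DataFrame(
        {
            "reaction_id": pol.reaction_ids,
            "score": score_vec,
            "included": included_mask,
            "flux": fluxes,
        }
    )
    objective = float(
        score_vec[included_mask & (np.arange(n) != bio_idx) & (score_vec != 0)].sum()
        - config.penalty_nogpr
        * np.count_nonzero(included_mask & (np.arange(n) != bio_idx) & (score_vec == 0))
    )

    carved = model.copy()
    drop = [r for r, keep in zip(pol.reaction_ids, included_mask) if not keep]
    carved.remove_reactions([carved.reactions.get_by_id(r) for r in drop], remove_orphans=True)
    carved.id = f"{model.id}_carved" if model.id else "carved"
    carved.objective = bio
    kept = [r for r, keep in zip(pol.reaction_ids, included_mask) if keep]
    return CarveResult(model=carved, report=report, objective_value=objective, included=kept)


def remove_blocked(model: cobra.Model, tol: float = 1e-6) -> cobra.Model:
    """Drop reactions whose flux-variability range is within ``[-tol, tol]``.

    Blocked reactions make the sampling polytope degenerate; removing them
    (and then-orphaned metabolites) leaves a bounded, full-dimensional
    solution space.  Idempotent.
    """
    pol = lp.polytope_from_model(model)
    mins, maxs = lp.fva(pol)
    blocked = [
        r for r, lo, hi in zip(pol.reaction_ids, mins, maxs) if lo >= -tol and hi <= tol
    ]
    if not blocked:
        return model
    out = model.copy()
    out.remove_reactions([out.reactions.get_by_id(r) for r in blocked], remove_orphans=True)
    return out
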