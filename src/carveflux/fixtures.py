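"""Self-contained toy universal models and synthetic count tables.

These generators stand in for a curated human universal model plus real UMI
count tables so that every pipeline stage can be exercised with known ground
truth and no download.  The toy universal model is a linear uptake ->
backbone -> biomass -> sink chain with optional gene-labeled branch routes;
the synthetic counts follow a negative-binomial on/off model whose default
separation makes expression filtering recover each condition's expressed
gene set essentially deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import cobra
import numpy as np
import pandas as pd

from .filtering import ExpressionMatrix
from .model_io import model_genes

__all__ = ["ToySpec", "make_toy_universal", "make_synthetic_counts", "two_condition_fixture"]

_UB = 1000.0  # internal-reaction upper bound, flux units


@dataclass
class ToySpec:
    """Shape of a toy universal model.

    n_linear: backbone reactions (chain length); n_branches: alternative
    routes between backbone metabolites; genes_per_reaction: genes AND-ed
    into each internal reaction's GPR; uptake_bound: exchange flux cap
    (default 10, so the maximal biomass flux equals 10).
    """

    n_linear: int = 3
    n_branches: int = 1
    genes_per_reaction: int = 1
    seed: int = 0
    uptake_bound: float = 10.0

    def __post_init__(self) -> None:
        if self.n_linear < 2:
            raise ValueError("n_linear must be >= 2")
        if self.uptake_bound <= 0:
            raise ValueError("uptake_bound must be positive")


def _gpr_for(base: str, genes_per_reaction: int) -> str:
    if genes_per_reaction <= 1:
        return base
    return " and ".join(f"{base}_{i}" for i in range(1, genes_per_reaction + 1))


def make_toy_universal(
    spec: ToySpec, endpoints: list[tuple[int, int]] | None = None
) -> cobra.Model:
    """Build the toy universal model described by ``spec``.

    Layout: ``EX_A -> M0 -r1-> M1 ... -r{n}-> M{n} -bio-> BIO -EX_bio->``
    with each internal reaction carrying a distinct GPR and each branch a
    shortcut ``M_a -> M_b`` (a < b, spanning at least two backbone steps).
    ``endpoints`` fixes the branch endpoints instead of drawing them from
    the seeded RNG.
    """
    rng = np.random.default_rng(spec.seed)
    model = cobra.Model(f"toy_universal_seed{spec.seed}")
    n = spec.n_linear
    mets = {i: cobra.Metabolite(f"M{i}", compartment="c") for i in range(n + 1)}
    bio_met = cobra.Metabolite("BIO", compartment="c")

    def add(rid, stoich, lb, ub, gpr="", name=""):
        rxn = cobra.Reaction(rid, name=name or rid, lower_bound=lb, upper_bound=ub)
        model.add_reactions([rxn])
        rxn.add_metabolites(stoich)
        if gpr:
            rxn.gene_reaction_rule = gpr
        return rxn

    add("EX_A", {mets[0]: 1.0}, 0.0, spec.uptake_bound, name="uptake of A")
    for k in range(1, n + 1):
        add(
            f"r{k}",
            {mets[k - 1]: -1.0, mets[k]: 1.0},
            0.0,
            _UB,
            gpr=_gpr_for(f"g{k}", spec.genes_per_reaction),
        )
    add("bio", {mets[n]: -1.0, bio_met: 1.0}, 0.0, _UB, name="biomass")
    add("EX_bio", {bio_met: -1.0}, 0.0, _UB, name="biomass sink")

    if endpoints is None:
        endpoints = []
        for _ in range(spec.n_branches):
            while True:
                a, b = sorted(rng.choice(n + 1, size=2, replace=False).tolist())
                if b - a >= 2:
                    break
            endpoints.append((a, b))
    for t, (a, b) in enumerate(endpoints, start=1):
        if not (0 <= a < b <= n and b - a >= 2):
            raise ValueError(f"branch endpoints {(a, b)} must span >= 2 backbone steps")
        add(
            f"branch{t}",
            {mets[a]: -1.0, mets[b]: 1.0},
            0.0,
            _UB,
            gpr=_gpr_for(f"gb{t}", spec.genes_per_reaction),
        )
    model.objective = "bio"
    return model


def make_synthetic_counts(
    model: cobra.Model,
    conditions: list[str],
    expressed_per_condition: dict[str, set[str]],
    n_samples_per_condition: int = 3,
    seed: int = 0,
    nb_mean_on: float = 200.0,
    nb_mean_off: float = 1.0,
    nb_dispersion: float = 0.1,
) -> ExpressionMatrix:
    """Synthetic UMI counts: negative-binomial on/off expression per condition.

    Genes in a condition's expressed set draw counts with mean ``nb_mean_on``,
    others with ``nb_mean_off``; the shared dispersion gives variance
    ``mu + dispersion * mu**2``.  Defaults (200 vs 1, dispersion 0.1) separate
    on from off so widely that the default expression filter recovers each
    expressed set exactly with overwhelming probability.
    """
    genes = sorted(model_genes(model))
    for cond in conditions:
        extra = set(expressed_per_condition.get(cond, set())) - set(genes)
        if extra:
            raise ValueError(f"expressed genes not in model for {cond!r}: {sorted(extra)}")
    rng = np.random.default_rng(seed)
    shape = 1.0 / nb_dispersion  # NB size parameter

    columns: dict[str, np.ndarray] = {}
    design: dict[str, str] = {}
    for cond in conditions:
        on = expressed_per_condition.get(cond, set())
        mu = np.where(np.isin(genes, sorted(on)), nb_mean_on, nb_mean_off)
        p = shape / (shape + mu)
        for s in range(1, n_samples_per_condition + 1):
            sample = f"{cond}_s{s}"
            columns[sample] = rng.negative_binomial(shape, p)
            design[sample] = cond
    counts = pd.DataFrame(columns, index=genes)
    return ExpressionMatrix(counts=counts, design=pd.Series(design))


def two_condition_fixture(
    seed: int = 0, n_linear: int = 3, n_samples: int = 3
) -> tuple[cobra.Model, ExpressionMatrix, dict[str, set[str]]]:
    """Ground-truth pair: conditions differing by exactly one branch's genes.

    The single branch spans the full backbone (M0 -> Mn), so condition A's
    carved model differs from B's by exactly the branch reaction, and the
    branch gene is the only one whose mean sampled flux rises by more than
    half a flux unit in A versus B (backbone reactions lose flux to the
    branch; exchanges and biomass carry no GPR).
    """
    spec = ToySpec(n_linear=n_linear, n_branches=1, seed=seed)
    model = make_toy_universal(spec, endpoints=[(0, n_linear)])
    backbone = {f"g{k}" for k in range(1, n_linear + 1)}
    expressed = {"A": backbone | {"gb1"}, "B": set(backbone)}
    counts = make_synthetic_counts(
        model, ["A", "B"], expressed, n_samples_per_condition=n_samples, seed=seed + 1
    )
    return model, counts, expressed
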