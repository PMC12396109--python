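"""Carving: evidence scores, biomass LP, MILP vs exhaustive enumeration."""

import itertools

import cobra
import numpy as np
import pytest

from carveflux import lp
from carveflux.carve import (
    CarveConfig,
    carve,
    max_biomass,
    remove_blocked,
    score_reactions,
)
from carveflux.fixtures import ToySpec, make_toy_universal
from carveflux.model_io import biomass_id, model_genes


def diamond_model():
    """EX_A -> A; r1: A->B (g1); r2: B->C (g2); r3: A->C (g3); bio: C->BIO; EX_bio."""
    m = cobra.Model("diamond")
    A, B, C, BIO = (cobra.Metabolite(x, compartment="c") for x in "A B C BIO".split())

    def add(rid, stoich, ub=1000.0, gpr=""):
        r = cobra.Reaction(rid, lower_bound=0.0, upper_bound=ub)
        m.add_reactions([r])
        r.add_metabolites(stoich)
        if gpr:
            r.gene_reaction_rule = gpr

    add("EX_A", {A: 1}, ub=10.0)
    add("r1", {A: -1, B: 1}, gpr="g1")
    add("r2", {B: -1, C: 1}, gpr="g2")
    add("r3", {A: -1, C: 1}, gpr="g3")
    add("bio", {C: -1, BIO: 1})
    add("EX_bio", {BIO: -1})
    m.objective = "bio"
    return m


# ---------- brute-force oracle ----------


def brute_force_carve(model, scores, config):
    """Enumerate all reaction subsets containing biomass; feasibility by LP
    (excluded reactions pinned to zero, included supported reactions forced
    to carry >= eps flux — all fixture reactions are irreversible), objective
    by direct evaluation.  Returns (best objective, set of optimal subsets).
    """
    pol = lp.polytope_from_model(model)
    bio = biomass_id(model)
    bio_idx = pol.index(bio)
    vmax = max_biomass(model)
    ids = pol.reaction_ids
    others = [i for i in range(len(ids)) if i != bio_idx]
    best, optimal = -np.inf, []
    for mask in itertools.product([0, 1], repeat=len(others)):
        subset = {bio_idx} | {i for i, keep in zip(others, mask) if keep}
        lb = pol.lb.copy()
        ub = pol.ub.copy()
        for i in range(len(ids)):
            if i not in subset:
                lb[i] = ub[i] = 0.0
            elif scores[ids[i]] > 0 and i != bio_idx:
                assert pol.lb[i] >= 0, "oracle assumes irreversible reactions"
                lb[i] = config.flux_activation_eps
        lb[bio_idx] = max(lb[bio_idx], config.f_min * vmax)
        sub_pol = lp.FluxPolytope(pol.S, lb, ub, ids, pol.metabolite_ids)
        try:
            c = np.zeros(len(ids))
            c[bio_idx] = 1.0
            lp.maximize(sub_pol, c)
        except lp.InfeasibleError:
            continue
        obj = sum(
            scores[ids[i]] if scores[ids[i]] != 0 else -config.penalty_nogpr
            for i in subset
            if i != bio_idx
        )
        if obj > best + 1e-9:
            best, optimal = obj, [frozenset(ids[i] for i in subset)]
        elif abs(obj - best) <= 1e-9:
            optimal.append(frozenset(ids[i] for i in subset))
    return best, optimal


def random_instance(seed):
    rng = np.random.default_rng(seed)
    spec = ToySpec(
        n_linear=int(rng.integers(2, 4)),
        n_branches=int(rng.integers(0, 3)),
        seed=seed,
    )
    model = make_toy_universal(spec)
    if len(model.reactions) > 8:
        model = make_toy_universal(ToySpec(n_linear=2, n_branches=2, seed=seed))
    genes = sorted(model_genes(model))
    expressed = {g for g in genes if rng.random() < 0.5}
    return model, expressed


class TestScoreReactions:
    def test_or_rule_satisfied_by_one_gene(self, toy_model):
        m = diamond_model()
        m.reactions.r1.gene_reaction_rule = "g1 or g2"
        assert score_reactions(m, {"g2"})["r1"] == 1.0

    def test_and_rule_contradicted(self):
        m = diamond_model()
        m.reactions.r1.gene_reaction_rule = "g1 and g2"
        assert score_reactions(m, {"g2"})["r1"] == -1.0
        assert score_reactions(m, {"g2"}, CarveConfig(penalty_absent=2.5))["r1"] == -2.5

    def test_gprless_reaction_scores_zero(self):
        scores = score_reactions(diamond_model(), {"g1"})
        assert scores["EX_A"] == 0.0 and scores["bio"] == 0.0

    def test_unknown_expressed_ids_ignored(self):
        scores = score_reactions(diamond_model(), {"g1", "not_a_gene"})
        assert scores["r1"] == 1.0


class TestMaxBiomass:
    def test_linear_chain_bounded_by_uptake(self, chain_model):
        assert max_biomass(chain_model) == pytest.approx(10.0)

    def test_closed_exchanges_give_zero(self, chain_model):
        m = chain_model.copy()
        m.reactions.EX_A.upper_bound = 0.0
        assert max_biomass(m) == pytest.approx(0.0)

    def test_diamond_matches_vertex_enumeration(self):
        m = diamond_model()
        # flux conservation: bio = r2 + r3 <= EX_A <= 10, so the optimum is 10
        assert max_biomass(m) == pytest.approx(10.0)
        _, opt = brute_force_carve(m, score_reactions(m, set()), CarveConfig())
        assert opt  # feasibility of the enumeration itself


class TestCarve:
    def test_diamond_expressed_path_selected(self):
        m = diamond_model()
        result = carve(m, score_reactions(m, {"g1", "g2"}))
        assert set(result.included) == {"EX_A", "r1", "r2", "bio", "EX_bio"}

    def test_all_genes_keeps_all_flux_capable_positive_reactions(self):
        m = diamond_model()
        result = carve(m, score_reactions(m, {"g1", "g2", "g3"}))
        assert {"r1", "r2", "r3"} <= set(result.included)

    def test_empty_expressed_keeps_minimal_backbone(self):
        m = diamond_model()
        result = carve(m, score_reactions(m, set()))
        # one of the two A->C routes must stay to feed biomass; both carry
        # penalty_absent so exactly one is kept
        assert {"EX_A", "bio", "EX_bio"} <= set(result.included)
        assert len({"r1", "r2", "r3"} & set(result.included)) <= 2

    def test_carved_is_subset_with_unchanged_reactions(self, fixture_pair, carved_pair):
        model, _, _ = fixture_pair
        for result in carved_pair.values():
            for rxn in result.model.reactions:
                orig = model.reactions.get_by_id(rxn.id)
                assert rxn.lower_bound == orig.lower_bound
                assert rxn.upper_bound == orig.upper_bound
                assert rxn.gene_reaction_rule == orig.gene_reaction_rule

    def test_functionality_maintained(self, fixture_pair, carved_pair):
        model, _, _ = fixture_pair
        vmax = max_biomass(model)
        config = CarveConfig()
        for result in carved_pair.values():
            assert max_biomass(result.model) >= config.f_min * vmax - 1e-6

    def test_matches_brute_force_on_seeded_instances(self):
        config = CarveConfig()
        for seed in range(6):
            model, expressed = random_instance(seed)
            scores = score_reactions(model, expressed, config)
            result = carve(model, scores, config)
            best, optimal = brute_force_carve(model, scores, config)
            assert result.objective_value == pytest.approx(best, abs=1e-6), seed
            assert frozenset(result.included) in optimal, seed

    def test_adding_evidence_never_lowers_objective(self):
        m = diamond_model()
        obj = [
            carve(m, score_reactions(m, exp)).objective_value
            for exp in [set(), {"g1"}, {"g1", "g2"}, {"g1", "g2", "g3"}]
        ]
        assert all(a <= b + 1e-9 for a, b in zip(obj, obj[1:]))

    def test_closed_model_carves_to_zero_flux_network(self):
        m = diamond_model()
        m.reactions.EX_A.upper_bound = 0.0  # no input: vmax = 0, functionality vacuous
        result = carve(m, score_reactions(m, {"g1"}), CarveConfig(f_min=0.5))
        assert "bio" in result.included

    def test_infeasible_forced_flux_reports_f_min(self):
        m = diamond_model()
        # a forced dead-end flux cannot balance at steady state
        dead = cobra.Metabolite("DEAD", compartment="c")
        r = cobra.Reaction("forced", lower_bound=1.0, upper_bound=2.0)
        m.add_reactions([r])
        r.add_metabolites({m.metabolites.A: -1, dead: 1})
        with pytest.raises(Exception, match="f_min|[Ii]nfeasible"):
            carve(m, score_reactions(m, {"g1"}), CarveConfig(f_min=0.5))


class TestRemoveBlocked:
    def test_dead_end_reaction_removed(self, chain_model):
        m = chain_model.copy()
        dead = cobra.Metabolite("DEAD", compartment="c")
        r = cobra.Reaction("to_dead", lower_bound=0, upper_bound=5)
        m.add_reactions([r])
        r.add_metabolites({m.metabolites.M1: -1, dead: 1})
        cleaned = remove_blocked(m)
        assert "to_dead" not in [x.id for x in cleaned.reactions]
        assert "DEAD" not in [x.id for x in cleaned.metabolites]

    def test_fully_coupled_chain_unchanged(self, chain_model):
        cleaned = remove_blocked(chain_model)
        assert sorted(r.id for r in cleaned.reactions) == sorted(
            r.id for r in chain_model.reactions
        )

    def test_idempotent_and_matches_fva(self):
        for seed in range(3):
            model, _ = random_instance(seed)
            once = remove_blocked(model)
            twice = remove_blocked(once)
            assert sorted(r.id for r in once.reactions) == sorted(
                r.id for r in twice.reactions
            )
            pol = lp.polytope_from_model(model)
            mins, maxs = lp.fva(pol)
            expected_blocked = {
                rid
                for rid, lo, hi in zip(pol.reaction_ids, mins, maxs)
                if lo >= -1e-6 and hi <= 1e-6
            }
            kept = {r.id for r in once.reactions}
            assert kept == set(pol.reaction_ids) - expected_blocked
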