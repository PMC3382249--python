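import math
import warnings

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from oracles import grid_parsimony_cost, random_rooted_binary
from spidrevo.simulate import sim_species_tree, sim_traits
from spidrevo.traits import (
    EvoModel,
    ancestral_linear_parsimony,
    bm_loglik,
    fit_all,
    fit_model,
    model_grid,
    phylo_covariance,
    transform_tree,
)
from spidrevo.trees import tree_from_newick


class TestLinearParsimony:
    def test_constant_trait_costs_nothing(self):
        t = tree_from_newick("((a,b),(c,d));")
        res = ancestral_linear_parsimony(t, {x: 5.0 for x in "abcd"})
        assert res.cost == 0.0
        assert all(iv == (5.0, 5.0) for iv in res.intervals.values())

    def test_three_tip_median_and_cost(self):
        t = tree_from_newick("((a,b),c);")
        traits = {"a": 1.0, "b": 2.0, "c": 10.0}
        res = ancestral_linear_parsimony(t, traits)
        assert res.cost == 9.0
        lo, hi = res.root_interval
        assert lo <= 2.0 <= hi  # the median is among the optimal root states
        assert res.cost == grid_parsimony_cost(t, traits)

    def test_balanced_four_tip_gap(self):
        t = tree_from_newick("((a,b),(c,d));")
        traits = {"a": 0.0, "b": 0.0, "c": 10.0, "d": 10.0}
        res = ancestral_linear_parsimony(t, traits)
        assert res.cost == 10.0
        assert res.root_interval == (0.0, 10.0)

    def test_cost_matches_grid_brute_force(self, rng):
        for n_tips in (4, 5, 6):
            for _ in range(5):
                t = random_rooted_binary([f"t{i}" for i in range(n_tips)], rng)
                traits = {f"t{i}": float(rng.integers(0, 20)) for i in range(n_tips)}
                res = ancestral_linear_parsimony(t, traits)
                assert res.cost == pytest.approx(grid_parsimony_cost(t, traits))

    def test_missing_tip_rejected(self):
        t = tree_from_newick("((a,b),c);")
        with pytest.raises(ValueError, match="missing"):
            ancestral_linear_parsimony(t, {"a": 1.0, "b": 2.0})


class TestBmLoglik:
    def test_two_tip_closed_form(self):
        b1, b2, s2, z0 = 0.7, 1.9, 2.3, 4.0
        t = tree_from_newick(f"(a:{b1},b:{b2});")
        y = {"a": 5.1, "b": 2.8}
        got = bm_loglik(t, y, s2, z0)
        # two independent increments from the root state
        expected = norm.logpdf(y["a"], z0, math.sqrt(s2 * b1)) + norm.logpdf(
            y["b"], z0, math.sqrt(s2 * b2)
        )
        assert got == pytest.approx(expected, abs=1e-8)

    def test_star_tree_tips_are_independent(self):
        t = tree_from_newick("(a:2,b:2,c:2);")
        t.rooted = True  # basal polytomy, but a star is fine for the covariance
        y = {"a": 1.0, "b": -0.5, "c": 2.5}
        got = bm_loglik(t, y, 1.3, 0.2)
        expected = sum(norm.logpdf(v, 0.2, math.sqrt(1.3 * 2)) for v in y.values())
        assert got == pytest.approx(expected, abs=1e-10)

    def test_profiled_root_state_is_gls_mean(self, rng):
        tree = sim_species_tree(12, seed=5)
        traits = sim_traits(tree, "bm_distance", sigma2=2.0, z0=3.0, seed=8)
        fit = fit_model(tree, traits, EvoModel("pure_phylogenetic", "distance"))
        tips, C0 = phylo_covariance(tree)
        y = np.array([traits[t] for t in tips])
        Cinv = np.linalg.inv(C0)
        ones = np.ones(len(y))
        gls = (ones @ Cinv @ y) / (ones @ Cinv @ ones)
        assert fit.z0 == pytest.approx(gls, rel=1e-8)
        # and no nearby z0 does better
        nll = lambda z: -bm_loglik(tree, traits, fit.sigma2, z)  # noqa: E731
        opt = minimize_scalar(nll, bounds=(gls - 5, gls + 5), method="bounded")
        assert opt.x == pytest.approx(gls, abs=1e-4)


class TestModelGrid:
    def test_nine_models_per_threshold(self):
        grid = model_grid([100.0])
        assert len(grid) == 9
        assert len({(m.mode, m.lengths) for m in grid}) == 9

    def test_aic_identity_holds_for_every_fit(self):
        tree = sim_species_tree(8, seed=2)
        traits = sim_traits(tree, "bm_distance", seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = fit_all(tree, traits, T_list=[100.0])
        for f in fits:
            assert f.aic == pytest.approx(2 * f.k - 2 * f.logL)
            assert f.sigma2 >= 0

    def test_equal_lengths_fit_ignores_input_lengths(self, rng):
        tree = sim_species_tree(8, seed=4)
        traits = sim_traits(tree, "bm_distance", seed=5)
        f1 = fit_model(tree, traits, EvoModel("pure_phylogenetic", "equal"))
        scaled = tree.copy()
        for n in scaled.postorder():
            if n is not scaled.root:
                n.length = float(rng.uniform(0.1, 9.0))
        f2 = fit_model(scaled, traits, EvoModel("pure_phylogenetic", "equal"))
        assert f1.logL == pytest.approx(f2.logL)

    def test_distance_mode_requires_lengths(self):
        tree = tree_from_newick("((a,b),c);")
        with pytest.raises(Exception, match="lengths"):
            fit_model(tree, {"a": 1.0, "b": 2.0, "c": 3.0},
                      EvoModel("pure_phylogenetic", "distance"))


class TestTransformTree:
    def test_equal_sets_all_lengths_to_one(self):
        t = tree_from_newick("((a:3,b:0.2):1,c:9);")
        out = transform_tree(t, "pure_phylogenetic", "equal")
        assert all(n.length == 1.0 for n in out.postorder() if n is not out.root)

    def test_star_tree_for_non_phylogenetic(self):
        t = tree_from_newick("((a:3,b:1):1,c:9);")
        out = transform_tree(t, "non_phylogenetic", "equal")
        assert len(out.root.children) == 3
        assert all(c.is_leaf() and c.length == 1.0 for c in out.root.children)

    def test_punctuated_sister_ratio_is_threshold(self):
        t = tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        out = transform_tree(t, "punctuated_average", "equal", T=100.0)
        for n in out.postorder():
            if len(n.children) == 2:
                l1, l2 = (c.length for c in n.children)
                assert max(l1, l2) / min(l1, l2) == pytest.approx(100.0)
                assert l1 + l2 == pytest.approx(2.0)  # pair sum preserved


class TestModelRecovery:
    @pytest.mark.parametrize(
        "sim_mode,family",
        [
            ("bm_distance", {("pure_phylogenetic", "distance")}),
            ("star", {("non_phylogenetic", l) for l in ("distance", "equal", "free")}),
            ("speciational", {("pure_phylogenetic", "equal"),
                              ("punctuated_average", "equal")}),
        ],
    )
    def test_matching_family_wins_most_replicates(self, sim_mode, family):
        tree = sim_species_tree(32, seed=1)
        wins = 0
        reps = 25
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(reps):
                traits = sim_traits(tree, sim_mode, sigma2=1.0, z0=10.0, seed=seed)
                best = fit_all(tree, traits, T_list=[100.0])[0]
                wins += (best.model.mode, best.model.lengths) in family
        assert wins / reps >= 0.7
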