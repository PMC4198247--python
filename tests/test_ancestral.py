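"""Gain/loss CTMC: transition matrix, pruning likelihood, ML, MCMC, regression."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from conftest import brute_force_loglik
from premito import trees
from premito.ancestral import (
    GainLossModel,
    McmcConfig,
    call_ancestral_content,
    genome_size_regression,
    pruning_loglik,
    read_matrix_tsv,
    transition_matrix,
    write_matrix_tsv,
)
from premito.simulate import simulate_presence_absence, simulate_species_tree


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        assert np.allclose(transition_matrix(0.3, 0.7, 0.0), np.eye(2))

    def test_zero_rates_identity_for_any_time(self):
        assert np.allclose(transition_matrix(0.0, 0.0, 5.0), np.eye(2))

    def test_symmetric_long_time_limit(self):
        P = transition_matrix(1.0, 1.0, 200.0)
        assert np.allclose(P, 0.5, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        for _ in range(50):
            q01, q10, t = rng.uniform(0, 3, 3)
            P = transition_matrix(q01, q10, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert (P >= 0).all()

    def test_matches_matrix_exponential(self, rng):
        for _ in range(200):
            q01, q10 = rng.uniform(0.01, 5, 2)
            t = rng.uniform(0, 4)
            Q = np.array([[-q01, q01], [q10, -q10]])
            assert np.abs(transition_matrix(q01, q10, t) - expm(Q * t)).max() < 1e-10

    def test_chapman_kolmogorov(self, rng):
        for _ in range(100):
            q01, q10 = rng.uniform(0.01, 5, 2)
            s, t = rng.uniform(0, 3, 2)
            lhs = transition_matrix(q01, q10, s + t)
            rhs = transition_matrix(q01, q10, s) @ transition_matrix(q01, q10, t)
            assert np.abs(lhs - rhs).max() < 1e-10

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(0.1, 0.1, -1.0)


class TestPruningLikelihood:
    def test_single_branch_closed_form(self):
        t = trees.parse_newick("(A:0.7,B:0.0);")
        # B missing: the A branch is the only information
        q01, q10 = 0.4, 0.9
        s = q01 + q10
        pi = (q10 / s, q01 / s)
        P = transition_matrix(q01, q10, 0.7)
        expected = math.log(pi[0] * P[0, 1] + pi[1] * P[1, 1])
        got = pruning_loglik(t, {"A": 1}, q01, q10, root_prior=pi)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_conflicting_states_on_zero_branches(self):
        t = trees.parse_newick("(A:0.0,B:0.0);")
        assert pruning_loglik(t, {"A": 1, "B": 0}, 0.3, 0.3) == -np.inf

    def test_all_missing_rejected(self):
        t = trees.parse_newick("(A:1.0,B:1.0);")
        with pytest.raises(ValueError):
            pruning_loglik(t, {"A": None, "B": None}, 0.3, 0.3)

    def test_unknown_tip_rejected(self):
        t = trees.parse_newick("(A:1.0,B:1.0);")
        with pytest.raises(ValueError):
            pruning_loglik(t, {"Z": 1}, 0.3, 0.3)

    def test_invariant_to_child_order_and_branch_splitting(self):
        q01, q10 = 0.5, 1.1
        states = {"A": 1, "B": 0, "C": 1}
        base = pruning_loglik(
            trees.parse_newick("((A:0.3,B:0.4):0.2,C:0.6);"), states, q01, q10)
        reordered = pruning_loglik(
            trees.parse_newick("(C:0.6,(B:0.4,A:0.3):0.2);"), states, q01, q10)
        # degree-2 node splitting the 0.2 branch into 0.05 + 0.15
        split = pruning_loglik(
            trees.parse_newick("(((A:0.3,B:0.4):0.05):0.15,C:0.6);"), states, q01, q10)
        assert reordered == pytest.approx(base, abs=1e-12)
        assert split == pytest.approx(base, abs=1e-12)

    def test_missing_tips_marginalized(self):
        q01, q10 = 0.5, 0.8
        t = trees.parse_newick("((A:0.3,B:0.4):0.2,C:0.6);")
        got = pruning_loglik(t, {"A": 1, "B": None, "C": 0}, q01, q10)
        oracle = brute_force_loglik(t, {"A": 1, "C": 0}, q01, q10)
        assert got == pytest.approx(oracle, abs=1e-12)


class TestMLRates:
    def test_all_present_pushes_loss_to_zero(self):
        tree = simulate_species_tree(8, seed=1)
        mat = pd.DataFrame(np.ones((20, 8)),
                           index=[f"f{i}" for i in range(20)],
                           columns=trees.leaf_labels(tree))
        res = GainLossModel(mat, tree).fit()
        assert res.q10 < 1e-3
        assert res.at_bound

    def test_matches_grid_search_on_fixture(self):
        tree = trees.parse_newick("((A:0.4,B:0.6):0.3,(C:0.5,D:0.2):0.4);")
        mat = pd.DataFrame(
            [[1, 1, 0, 0], [1, 0, 1, 1], [0, 0, 0, 1], [1, 1, 1, 1], [0, 1, 0, 1]],
            index=[f"f{i}" for i in range(5)], columns=["A", "B", "C", "D"],
            dtype=float)
        model = GainLossModel(mat, tree)
        res = model.fit()
        grid = np.linspace(0.02, 6.0, 200)
        best, best_ll = None, -np.inf
        for a in grid:
            for b in grid:
                ll = model.loglik(a, b).sum()
                if ll > best_ll:
                    best, best_ll = (a, b), ll
        step = grid[1] - grid[0]
        assert res.q01 == pytest.approx(best[0], abs=step)
        assert res.q10 == pytest.approx(best[1], abs=step)
        assert res.loglik >= best_ll - 1e-9

    def test_parameter_recovery_on_simulated_matrix(self):
        tree = simulate_species_tree(30, seed=5)
        mat, _ = simulate_presence_absence(tree, 0.2, 0.8, 1000, seed=7)
        res = GainLossModel(mat, tree).fit()
        assert res.q01 == pytest.approx(0.2, rel=0.2)
        assert res.q10 == pytest.approx(0.8, rel=0.2)


class TestMcmc:
    def test_symmetric_configuration_gives_half(self):
        """Mirror-symmetric tree, states and priors force posterior 0.5 at the root."""
        tree = trees.parse_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")
        mat = pd.DataFrame([[1.0, 1.0, 0.0, 0.0]], index=["f0"],
                           columns=["A", "B", "C", "D"])
        model = GainLossModel(mat, tree)
        cfg = McmcConfig(iterations=20_000, burnin=2_000, seed=9,
                         prior_shape=2.0, prior_scale=0.5)
        res = model.fit_mcmc(model._pt.root_index, cfg)
        assert res.posteriors.iloc[0] == pytest.approx(0.5, abs=0.03)

    def test_all_present_low_loss_prior_posterior_near_one(self):
        tree = trees.parse_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")
        mat = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]], index=["f0"],
                           columns=["A", "B", "C", "D"])
        model = GainLossModel(mat, tree)
        cfg = McmcConfig(iterations=10_000, burnin=1_000, seed=4,
                         prior_shape=2.0, prior_scale=0.01)  # loss prior near 0
        res = model.fit_mcmc(model._pt.root_index, cfg)
        assert res.posteriors.iloc[0] >= 0.99

    def test_seeded_chain_is_reproducible(self):
        tree = trees.parse_newick("((A:0.4,B:0.6):0.3,(C:0.5,D:0.2):0.4);")
        mat = pd.DataFrame([[1.0, 1.0, 0.0, 1.0], [0.0, 1.0, 1.0, 0.0]],
                           index=["f0", "f1"], columns=["A", "B", "C", "D"])
        model = GainLossModel(mat, tree)
        cfg = McmcConfig(iterations=3000, burnin=300, seed=42, prior_shape=2.0,
                         prior_scale=0.5)
        r1 = model.fit_mcmc([["A", "B"]], cfg)
        r2 = model.fit_mcmc([["A", "B"]], cfg)
        assert (r1.posteriors == r2.posteriors).all()
        assert r1.acceptance_rate == r2.acceptance_rate

    def test_hyperprior_chain_runs_and_is_reproducible(self):
        tree = trees.parse_newick("((A:0.4,B:0.6):0.3,(C:0.5,D:0.2):0.4);")
        mat = pd.DataFrame([[1.0, 1.0, 0.0, 1.0]], index=["f0"],
                           columns=["A", "B", "C", "D"])
        model = GainLossModel(mat, tree)
        cfg = McmcConfig(iterations=3000, burnin=300, seed=5, hyperprior=True)
        r1 = model.fit_mcmc([["A", "B"]], cfg)
        r2 = model.fit_mcmc([["A", "B"]], cfg)
        assert (r1.posteriors == r2.posteriors).all()
        assert 0.0 <= r1.posteriors.iloc[0] <= 1.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(iterations=100, burnin=100)


class TestCalls:
    def test_threshold_semantics(self):
        post = pd.Series({"a": 0.93, "b": 0.89, "c": 0.56, "d": 0.12})
        called, n = call_ancestral_content(post, 0.5)
        assert n == 3 and "d" not in called
        assert call_ancestral_content(post, 1.0)[1] == 0
        assert call_ancestral_content(post, 0.0)[1] == 4

    def test_nested_thresholds(self, rng):
        post = pd.Series(rng.uniform(0, 1, 50), index=[f"f{i}" for i in range(50)])
        lo, _ = call_ancestral_content(post, 0.3)
        hi, _ = call_ancestral_content(post, 0.7)
        assert set(hi) <= set(lo)


class TestGenomeSizeRegression:
    def test_collinear_points_predict_exactly(self):
        df = pd.DataFrame({"family_count": [100, 200, 300],
                           "gene_count": [200, 400, 600],
                           "genome_size_mb": [1.0, 2.0, 3.0]})
        fit = genome_size_regression(df, 250)
        assert fit.gene_prediction == pytest.approx(500.0)
        assert fit.gene_interval == pytest.approx((500.0, 500.0))
        assert fit.size_prediction == pytest.approx(2.5)

    def test_matches_normal_equation_oracle(self, rng):
        x = rng.uniform(100, 900, 10)
        y = 2.1 * x + 30 + rng.normal(0, 15, 10)
        z = 0.002 * x + 0.3 + rng.normal(0, 0.05, 10)
        df = pd.DataFrame({"family_count": x, "gene_count": y, "genome_size_mb": z})
        fit = genome_size_regression(df, 500)
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.gene_params[0] == pytest.approx(beta[0], abs=1e-9)
        assert fit.gene_params[1] == pytest.approx(beta[1], abs=1e-9)
        assert fit.gene_prediction == pytest.approx(beta[0] + 500 * beta[1], abs=1e-9)
        # 95% prediction interval from the closed form
        n = 10
        resid = y - X @ beta
        s2 = resid @ resid / (n - 2)
        from scipy.stats import t as tdist
        xbar = x.mean()
        se = math.sqrt(s2 * (1 + 1 / n + (500 - xbar) ** 2 / ((x - xbar) ** 2).sum()))
        tcrit = tdist.ppf(0.975, n - 2)
        assert fit.gene_interval[0] == pytest.approx(
            beta[0] + 500 * beta[1] - tcrit * se, abs=1e-6)
        assert fit.gene_interval[1] == pytest.approx(
            beta[0] + 500 * beta[1] + tcrit * se, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        dup = pd.DataFrame({"family_count": [100, 100, 100],
                            "gene_count": [200, 200, 200],
                            "genome_size_mb": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            genome_size_regression(dup, 250)
        with pytest.raises(ValueError):
            genome_size_regression(dup.iloc[:2], 250)


def test_matrix_tsv_roundtrip(tmp_path):
    mat = pd.DataFrame([[1.0, 0.0, np.nan], [0.0, 1.0, 1.0]],
                       index=["f0", "f1"], columns=["A", "B", "C"])
    p = tmp_path / "m.tsv"
    write_matrix_tsv(mat, p)
    back = read_matrix_tsv(p)
    assert back.equals(mat)
    assert "?" in p.read_text()
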