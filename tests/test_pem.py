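"""PEM basis construction, steepness fit, forward selection, prediction."""

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import random_yule_graph
from genlen.pem import (
    aicc,
    build_pem,
    fit_steepness,
    forward_select_aicc,
    predict_pem,
)
from genlen.phylograph import graph_locations, tree_to_graph


class TestBuildPem:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("a", [0.0, 0.5, 1.0])
    def test_count_orthonormality_zero_mean(self, seed, a):
        g = random_yule_graph(15, seed=seed)
        basis = build_pem(g, a)
        U = basis.scores
        assert U.shape == (15, 14)  # exactly n-1 eigenvectors
        np.testing.assert_allclose(U.T @ U, np.eye(14), atol=1e-10)
        np.testing.assert_allclose(U.mean(axis=0), 0.0, atol=1e-12)
        assert np.all(np.diff(basis.singular_values) <= 1e-12)  # decreasing order

    def test_star_tree_matches_dense_oracle(self):
        """4-tip star with equal branches: singular values and the spanned
        score space match a brute-force decomposition of the hand-written
        4x4 weighted influence matrix.  The spectrum is triply degenerate
        here, so the comparison is on values and projectors, not on the
        (rotationally arbitrary) individual columns."""
        g = tree_to_graph("(A:1,B:1,C:1,D:1);")
        for a in (0.0, 0.4, 1.0):
            basis = build_pem(g, a)
            U, s, _, _, tips = oracles.pem_scores_dense(*oracles.tree_arrays(g)[:2], a)
            np.testing.assert_allclose(basis.singular_values, s, atol=1e-10)
            np.testing.assert_allclose(
                basis.scores @ basis.scores.T, U @ U.T, atol=1e-8
            )
            # hand-written check: every weighted influence entry is w(1) = 1^((1-a)/2)
            W, _ = oracles.weighted_influence(*oracles.tree_arrays(g)[:2], a)
            np.testing.assert_allclose(W, np.eye(4), atol=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_random_tree_matches_dense_oracle(self, seed):
        g = random_yule_graph(12, seed=seed)
        basis = build_pem(g, 0.3)
        U, s, _, _, _ = oracles.pem_scores_dense(*oracles.tree_arrays(g)[:2], 0.3)
        np.testing.assert_allclose(basis.singular_values, s, atol=1e-9)
        np.testing.assert_allclose(basis.scores, U, atol=1e-7)

    def test_sign_convention(self):
        g = random_yule_graph(10, seed=7)
        basis = build_pem(g, 0.2)
        for k in range(basis.n_eigenvectors):
            col = basis.scores[:, k]
            # first element attaining the maximum magnitude (within a
            # relative tie tolerance) is positive
            j = np.flatnonzero(np.abs(col) >= (1 - 1e-9) * np.abs(col).max())[0]
            assert col[j] > 0

    def test_scale_equivariance(self):
        """Uniform branch-length rescaling leaves tip scores unchanged."""
        g = random_yule_graph(10, seed=8)
        g2 = g.with_lengths(g.length * 3.7)
        b1, b2 = build_pem(g, 0.4), build_pem(g2, 0.4)
        np.testing.assert_allclose(b1.scores, b2.scores, atol=1e-9)

    def test_single_tip_rejected(self):
        import genlen.phylograph as pg
        # a 2-vertex chain root->tip is the smallest graph object; PEM needs 2 tips
        chain = pg.PhyloGraph(parent=np.array([-1, 0]), length=np.array([0.0, 1.0]),
                              labels=(None, "A"))
        with pytest.raises(ValueError, match="two tips"):
            build_pem(chain, 0.0)

    def test_saturated_fit_reproduces_trait(self, rng):
        """Regressing any trait on intercept + all n-1 eigenvectors gives a
        zero-residual fit."""
        g = random_yule_graph(12, seed=10)
        basis = build_pem(g, 0.6)
        y = rng.normal(size=12)
        X = np.column_stack([np.ones(12), basis.scores])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.abs(y - X @ beta).max() < 1e-9

    def test_equal_branch_variant_keeps_properties(self):
        from genlen.phylograph import branch_length_variants
        g = branch_length_variants(random_yule_graph(12, seed=11), "equal")
        basis = build_pem(g, 0.5)
        assert basis.n_eigenvectors == 11
        np.testing.assert_allclose(basis.scores.T @ basis.scores, np.eye(11), atol=1e-10)


class TestFitSteepness:
    def test_brownian_regime_recovers_low_a(self):
        """Traits evolved with edge variance ∝ branch length (gradual
        change) should yield steepness estimates near 0."""
        rng = np.random.default_rng(21)
        a_hats = []
        for _ in range(20):
            g = random_yule_graph(30, seed=int(rng.integers(2**31)))
            phi = g.length[1:]
            y = g.influence_matrix() @ rng.normal(0, np.sqrt(phi))
            a_hats.append(fit_steepness(g, y).a)
        assert np.median(a_hats) < 0.2

    def test_abrupt_regime_recovers_high_a(self):
        rng = np.random.default_rng(22)
        a_hats = []
        for _ in range(20):
            g = random_yule_graph(30, seed=int(rng.integers(2**31)))
            y = g.influence_matrix() @ rng.normal(0, 1.0, g.n_edges)
            a_hats.append(fit_steepness(g, y).a)
        assert np.median(a_hats) > 0.5

    def test_estimate_always_in_unit_interval(self, rng):
        for seed in range(5):
            g = random_yule_graph(10, seed=seed)
            y = rng.normal(size=10)
            assert 0.0 <= fit_steepness(g, y).a <= 1.0

    def test_constant_trait_flat_likelihood(self):
        g = random_yule_graph(10, seed=3)
        with pytest.warns(UserWarning, match="flat"):
            fit = fit_steepness(g, np.ones(10))
        assert fit.a == 0.0 and fit.flat


class TestForwardSelection:
    def test_exact_candidate_selected_first(self, rng):
        n = 25
        x = rng.normal(size=n)
        cands = pd.DataFrame({"noise": rng.normal(size=n), "signal": x})
        model = forward_select_aicc(cands, x)
        assert model.terms[0] == "signal"
        assert model.rss < 1e-18

    def test_pure_noise_selects_intercept_mostly(self):
        """Under the null, forward AICc keeps the intercept-only model in
        most replicates."""
        rng = np.random.default_rng(33)
        kept_empty = 0
        for _ in range(20):
            cands = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
            y = rng.normal(size=30)
            model = forward_select_aicc(cands, y)
            kept_empty += len(model.terms) == 0
        assert kept_empty >= 11

    def test_aicc_hand_formula(self):
        n, k, rss = 10, 3, 2.5
        expected = n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert aicc(n, k, rss) == pytest.approx(expected)
        assert aicc(n, k, rss) == pytest.approx(oracles.aicc_value(n, k, rss))

    def test_collinear_candidate_skipped(self, rng):
        n = 20
        x = rng.normal(size=n)
        cands = pd.DataFrame({"x": x, "x2": 2 * x, "z": rng.normal(size=n)})
        y = x + 0.1 * rng.normal(size=n)
        model = forward_select_aicc(cands, y)
        # one of the two collinear twins is selected, the other is skipped
        selected_twin = next(t for t in model.terms if t in ("x", "x2"))
        assert set(model.skipped) == {"x", "x2"} - {selected_twin}
        assert model.aicc <= min(a for _, a in model.path)

    def test_selected_aicc_is_path_minimum(self, rng):
        cands = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
        y = cands["a"] + 0.5 * cands["b"] + rng.normal(scale=0.3, size=30)
        model = forward_select_aicc(cands, y)
        assert model.aicc == pytest.approx(min(a for _, a in model.path))


class TestPredict:
    def _fitted(self, seed=14, a=0.4):
        g = random_yule_graph(12, seed=seed)
        rng = np.random.default_rng(seed)
        target = g.tip_labels[4]
        reduced, locs = graph_locations(g, [target])
        basis = build_pem(reduced, a)
        y = rng.normal(size=11)
        model = forward_select_aicc(basis.scores_frame(), y)
        return basis, model, locs, y

    def test_zero_score_target_predicts_intercept(self):
        basis, model, locs, _ = self._fitted()
        loc = locs[0]
        scores = basis.location_scores([loc])
        pred = predict_pem(basis, model, locs)
        manual = model.coef["intercept"] + sum(
            model.coef[t] * scores[0, basis.names.index(t)] for t in model.terms
        )
        assert pred["fit"].iloc[0] == pytest.approx(manual)

    def test_interval_contains_fit_and_grows_with_sigma(self):
        basis, model, locs, y = self._fitted()
        pred = predict_pem(basis, model, locs)
        assert (pred["lower95"] <= pred["fit"]).all() and (pred["fit"] <= pred["upper95"]).all()

    def test_unknown_eigenvector_rejected(self):
        basis, model, locs, y = self._fitted()
        from dataclasses import replace
        bad = replace(model, terms=("V99",), coef={"intercept": 0.0, "V99": 1.0})
        with pytest.raises(ValueError, match="absent"):
            predict_pem(basis, bad, locs)

    def test_location_scores_match_dense_oracle(self):
        g = random_yule_graph(12, seed=15)
        target = g.tip_labels[3]
        reduced, (loc,) = graph_locations(g, [target])
        basis = build_pem(reduced, 0.3)
        parent, length, _ = oracles.tree_arrays(reduced)
        U, s, mu, Wc, _ = oracles.pem_scores_dense(parent, length, 0.3)
        row = oracles.target_score_row(parent, length, loc.edge, loc.distance, 0.3, 1.0,
                                       mu, Wc, s, U)
        np.testing.assert_allclose(basis.location_scores([loc])[0], row, atol=1e-8)
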