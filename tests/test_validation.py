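"""LOOCV, P², identity-line test, Genizi importance, allometry."""

import numpy as np
import pandas as pd
import pytest

from genlen.validation import (
    allometric_regression,
    genizi_importance,
    identity_line_test,
    loocv,
    prediction_coefficient,
)


def toy(values):
    return pd.DataFrame({"y": values}, index=[f"sp{i}" for i in range(len(values))])


class TestLoocv:
    def test_constant_predictor(self):
        preds = loocv(toy([1.0, 2.0, 3.0]), lambda train, row: 7.0)
        assert (preds == 7.0).all()

    def test_mean_predictor_hand_values(self):
        preds = loocv(toy([2.0, 4.0, 6.0]), lambda train, row: train["y"].mean())
        assert list(preds) == [5.0, 4.0, 3.0]

    def test_row_shuffle_invariance(self, rng):
        data = toy(list(rng.normal(size=8)))
        proc = lambda train, row: train["y"].median()
        a = loocv(data, proc)
        b = loocv(data.sample(frac=1, random_state=3), proc)
        assert (a.sort_index() == b.sort_index()).all()

    def test_infeasible_fold_recorded_not_dropped(self):
        preds = loocv(toy([1.0, 2.0, 3.0]),
                      lambda train, row: None if row.name == "sp1" else 0.0)
        assert np.isnan(preds["sp1"]) and preds.notna().sum() == 2

    def test_leakage_guard(self):
        def peeking(train, row):
            assert row.name not in train.index
            return 0.0
        loocv(toy([1.0, 2.0, 3.0]), peeking)


class TestPredictionCoefficient:
    def test_perfect_prediction(self):
        assert prediction_coefficient([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert prediction_coefficient(obs, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_hand_example(self):
        assert prediction_coefficient([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_zero_observed_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            prediction_coefficient([2, 2, 2], [1, 2, 3])


class TestIdentityLine:
    def test_doubled_predictions_slope_and_t(self, rng):
        pred = rng.normal(size=20)
        obs = 2.0 * pred + rng.normal(scale=0.1, size=20)
        out = identity_line_test(obs, pred)
        # closed-form OLS oracle
        X = np.column_stack([np.ones(20), pred])
        beta = np.linalg.inv(X.T @ X) @ X.T @ obs
        resid = obs - X @ beta
        s2 = resid @ resid / 18
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert out.slope == pytest.approx(beta[1])
        from scipy import stats
        t_hand = (beta[1] - 1.0) / se
        assert out.p_slope_vs_1 == pytest.approx(2 * stats.t.sf(abs(t_hand), 18))
        assert out.p_slope_vs_1 < 0.01  # slope 2 is detectably not 1

    def test_unbiased_predictions_pass_in_most_replicates(self):
        rng = np.random.default_rng(55)
        passed = 0
        for _ in range(20):
            pred = rng.uniform(2, 9, 40)
            obs = pred + rng.normal(scale=0.4, size=40)
            out = identity_line_test(obs, pred)
            passed += (out.p_slope_vs_1 > 0.05) and (out.p_intercept_vs_0 > 0.05)
        assert passed >= 15

    def test_minimal_n_and_degenerate_fit(self):
        out = identity_line_test([1.0, 2.0, 3.0], [1.0, 2.5, 3.5])
        assert out.n == 3
        perfect = identity_line_test([1.0, 2.0, 3.0, 4.0], [0.5, 1.0, 1.5, 2.0])
        assert perfect.degenerate and perfect.p_slope_vs_1 is None
        assert perfect.slope == pytest.approx(2.0)


class TestGenizi:
    def test_single_predictor_share_is_r2(self, rng):
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        out = genizi_importance(pd.DataFrame({"x": x}), y)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert out.shares[0] == pytest.approx(r2)
        assert out.total_r2 == pytest.approx(r2)

    def test_orthogonal_shares_equal_squared_correlations(self, rng):
        n = 64
        # exactly orthogonal, mean-zero columns: QR of a centred matrix
        M = rng.normal(size=(n, 3))
        Q, _ = np.linalg.qr(M - M.mean(0))
        X = pd.DataFrame(Q / Q.std(0, ddof=1), columns=["a", "b", "c"])
        y = 1.0 * X["a"] - 0.5 * X["b"] + rng.normal(size=n)
        out = genizi_importance(X, y)
        for j, col in enumerate(X.columns):
            r2_marg = np.corrcoef(X[col], y)[0, 1] ** 2
            assert out.shares[j] == pytest.approx(r2_marg, abs=1e-6)

    def test_shares_sum_to_r2_random_designs(self):
        rng = np.random.default_rng(66)
        for _ in range(5):
            X = pd.DataFrame(rng.normal(size=(50, 6)),
                             columns=[f"x{i}" for i in range(6)])
            X["x1"] = X["x0"] * 0.5 + X["x1"]  # induce correlation, keep full rank
            y = X @ rng.normal(size=6) + rng.normal(size=50)
            out = genizi_importance(X, y)
            assert np.all(out.shares >= -1e-12)
            assert out.shares.sum() == pytest.approx(out.total_r2)

    def test_grouped_shares_invariant_to_column_order(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=["V1", "V2", "V3", "m"])
        y = X @ np.array([1.0, 0.5, 0.0, 2.0]) + rng.normal(size=40)
        groups = {"V1": "phylo", "V2": "phylo", "V3": "phylo", "m": "mass"}
        out1 = genizi_importance(X, y, groups)
        out2 = genizi_importance(X[["m", "V3", "V1", "V2"]], y, groups)
        assert out1.grouped["phylo"] == pytest.approx(out2.grouped["phylo"])
        assert out1.grouped["mass"] == pytest.approx(out2.grouped["mass"])

    def test_rank_deficiency_rejected_with_columns(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"x": x, "x2": 2 * x, "z": rng.normal(size=30)})
        with pytest.raises(ValueError, match="rank-deficient"):
            genizi_importance(X, rng.normal(size=30))


class TestAllometry:
    def test_exact_linear_data(self):
        mass = np.array([1e3, 1e4, 1e5, 1e6])
        gl = 1.0 + 1.5 * np.log10(mass)
        out = allometric_regression(gl, mass)
        assert out.r_squared == pytest.approx(1.0)
        assert out.slope == pytest.approx(1.5)
        assert out.intercept == pytest.approx(1.0)

    def test_matches_normal_equations_on_four_points(self):
        mass = np.array([100.0, 1000.0, 5000.0, 60000.0])
        gl = np.array([2.0, 3.5, 4.0, 6.5])
        x = np.log10(mass)
        X = np.column_stack([np.ones(4), x])
        beta = np.linalg.inv(X.T @ X) @ X.T @ gl
        out = allometric_regression(gl, mass)
        assert out.intercept == pytest.approx(beta[0])
        assert out.slope == pytest.approx(beta[1])

    def test_noise_lowers_r2(self, rng):
        mass = 10 ** rng.uniform(2, 6, 40)
        clean = 1.0 + 1.5 * np.log10(mass)
        noisy = clean + rng.normal(scale=1.0, size=40)
        assert (
            allometric_regression(noisy, mass).r_squared
            < allometric_regression(clean, mass).r_squared
        )

    def test_constant_mass_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            allometric_regression([1.0, 2.0, 3.0], [10.0, 10.0, 10.0])
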