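"""Cross-lagged panel network tests: lasso solutions, prediction summaries
and maximum-likelihood fit indices.

The lasso oracle is a from-scratch cyclic coordinate-descent solver for the
objective ``1/(2n) ||y - Xb||^2 + lambda ||b||_1`` (the parameterization the
package's solver uses), iterated to a 1e-12 coordinate-change tolerance.
"""

import numpy as np
import pytest

from panelnet.crosslagged import (
    CLPNModel,
    fit_clpn,
    fit_structure_to_cov,
    in_prediction,
    out_prediction,
    out_prediction_values,
    path_model_fit,
)
from panelnet.datasets import OrdinalPanelDataset, TwoWavePanel
from panelnet.synthetic import SyntheticConfig, generate_truth, simulate_panel


def cd_lasso(X, y, lam, n_iter=5000, tol=1e-12):
    """Coordinate-descent oracle with exact soft-thresholding."""
    n, p = X.shape
    b = np.zeros(p)
    col_ss = (X**2).sum(axis=0) / n
    for _ in range(n_iter):
        max_change = 0.0
        for j in range(p):
            r = y - X @ b + X[:, j] * b[j]
            rho = X[:, j] @ r / n
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_ss[j]
            max_change = max(max_change, abs(new - b[j]))
            b[j] = new
        if max_change < tol:
            break
    return b


def _panel_from_arrays(x1, x2):
    labels = [f"A{i + 1}" for i in range(x1.shape[1])]
    comm = {lab: "anxiety" for lab in labels}
    rev = {lab: False for lab in labels}

    def mk(x, wave):
        return OrdinalPanelDataset(
            responses=x,
            item_labels=labels,
            community_labels=comm,
            wave_id=wave,
            reverse_coded=rev,
            n_categories=int(max(x1.max(), x2.max())),
        )

    return TwoWavePanel(t1=mk(x1, "T1"), t2=mk(x2, "T2"))


class TestLassoSolutions:
    def test_matches_coordinate_descent_oracle(self):
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(0)
        for trial in range(5):
            X = rng.standard_normal((300, 5))
            X = (X - X.mean(0)) / X.std(0)
            beta_true = np.array([0.5, -0.3, 0.0, 0.0, 0.2])
            y = X @ beta_true + rng.standard_normal(300)
            y = y - y.mean()
            lam = 0.05 * (1 + trial)
            fit = Lasso(alpha=lam, fit_intercept=False, max_iter=100000, tol=1e-14)
            fit.fit(X, y)
            oracle = cd_lasso(X, y, lam)
            assert np.allclose(fit.coef_, oracle, atol=1e-8)
            # exact zeros, not merely small values
            assert set(np.flatnonzero(fit.coef_ == 0)) == set(
                np.flatnonzero(oracle == 0)
            )

    def test_copied_item_gets_autoregressive_path_only(self, default_truth):
        panel = simulate_panel(default_truth, n=1000, seed=13)
        panel2 = TwoWavePanel(t1=panel.t1, t2=panel.t1)  # T2 := copy of T1
        model = fit_clpn(panel2, seed=1)
        diag = np.diag(model.beta)
        assert np.all(diag >= 0.99)
        off = model.beta[~np.eye(17, dtype=bool)]
        assert np.allclose(off, 0.0)
        assert np.all(model.in_prediction >= 0.99)

    def test_pure_noise_outcome_screened_out_by_conservative_rule(
        self, default_truth
    ):
        all_zero = 0
        reps = 10
        for rep in range(reps):
            panel = simulate_panel(default_truth, n=1000, seed=40 + rep)
            x2 = panel.t2.responses.copy()
            rng = np.random.default_rng(900 + rep)
            x2[:, 0] = rng.integers(1, 5, size=1000)  # A1_T2 pure noise
            noisy = _rebuild(panel, x2)
            model = fit_clpn(noisy, seed=rep, selection_rule="1se")
            all_zero += np.all(model.beta[:, 0] == 0)
        assert all_zero / reps >= 0.9

    def test_deterministic_given_seed(self, default_truth):
        panel = simulate_panel(default_truth, n=500, seed=21)
        a = fit_clpn(panel, seed=3)
        b = fit_clpn(panel, seed=3)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.selected_lambda, b.selected_lambda)

    def test_unpaired_waves_rejected(self, default_truth):
        panel = simulate_panel(default_truth, n=100, seed=2)
        from panelnet.datasets import DataValidationError

        with pytest.raises(DataValidationError, match="not paired"):
            TwoWavePanel(
                t1=panel.t1,
                t2=OrdinalPanelDataset(
                    responses=panel.t2.responses[:50],
                    item_labels=panel.t2.item_labels,
                    community_labels=panel.t2.community_labels,
                    wave_id="T2",
                    reverse_coded=panel.t2.reverse_coded,
                ),
            )


def _rebuild(panel, x2):
    return TwoWavePanel(
        t1=panel.t1,
        t2=OrdinalPanelDataset(
            responses=x2,
            item_labels=panel.t2.item_labels,
            community_labels=panel.t2.community_labels,
            wave_id="T2",
            reverse_coded=panel.t2.reverse_coded,
            n_categories=panel.t2.n_categories,
        ),
    )


class TestPredictionSummaries:
    def _zero_model(self, p=4):
        labels = [f"A{i + 1}" for i in range(p)]
        import pandas as pd

        return CLPNModel(
            beta=np.zeros((p, p)),
            item_labels=labels,
            selected_lambda=np.ones(p),
            cv_folds=10,
            in_prediction=pd.Series(0.0, index=labels),
            out_prediction=pd.Series(0.0, index=labels),
            seed=0,
            transform="raw",
        )

    def test_null_model_in_prediction_zero(self):
        rng = np.random.default_rng(5)
        x1 = rng.integers(1, 5, (200, 4))
        x2 = rng.integers(1, 5, (200, 4))
        panel = _panel_from_arrays(x1, x2)
        model = self._zero_model()
        r2 = in_prediction(model, panel)
        assert (r2 == 0).all()

    def test_out_prediction_hand_value_and_autoregressive_exclusion(self):
        model = self._zero_model(3)
        model.beta = np.array(
            [
                [0.7, 0.3, -0.4],
                [0.0, 0.5, 0.0],
                [0.0, 0.0, 0.0],
            ]
        )
        out = out_prediction(model)
        assert out.iloc[0] == pytest.approx(0.09 + 0.16)
        assert out.iloc[1] == 0.0  # only the autoregressive path
        out_incl = out_prediction(model, include_autoregressive=True)
        assert out_incl.iloc[0] == pytest.approx(0.49 + 0.09 + 0.16)

    def test_out_prediction_matches_brute_force_loop(self):
        rng = np.random.default_rng(6)
        beta = rng.standard_normal((8, 8)) * (rng.random((8, 8)) < 0.3)
        labels = [f"V{i}" for i in range(8)]
        got = out_prediction_values(beta, labels).to_numpy()
        expected = np.array(
            [
                sum(beta[s, t] ** 2 for t in range(8) if t != s)
                for s in range(8)
            ]
        )
        assert np.allclose(got, expected, atol=0)

    def test_in_prediction_invariant_to_other_node_relabeling(
        self, default_truth
    ):
        panel = simulate_panel(default_truth, n=500, seed=33)
        model = fit_clpn(panel, seed=2)
        r2 = in_prediction(model, panel)
        # permute the other columns consistently in data and model
        perm = np.r_[0, np.random.default_rng(1).permutation(np.arange(1, 17))]
        x1p = panel.t1.responses[:, perm]
        x2p = panel.t2.responses[:, perm]
        panel_p = _panel_from_arrays(x1p, x2p)
        model_p = CLPNModel(
            beta=model.beta[np.ix_(perm, perm)],
            item_labels=panel_p.item_labels,
            selected_lambda=model.selected_lambda[perm],
            cv_folds=model.cv_folds,
            in_prediction=model.in_prediction,
            out_prediction=model.out_prediction,
            seed=0,
            transform=model.transform,
        )
        r2p = in_prediction(model_p, panel_p)
        assert r2p.iloc[0] == pytest.approx(r2["A1"], abs=1e-12)


class TestFitIndices:
    def test_no_retained_path_rejected(self, default_truth):
        panel = simulate_panel(default_truth, n=200, seed=3)
        model = TestPredictionSummaries()._zero_model(17)
        model.item_labels = panel.item_labels
        with pytest.raises(ValueError, match="no retained path"):
            path_model_fit(panel, model)

    def test_cfi_guard_when_baseline_not_exceeding_df(self):
        # independence covariance: the baseline fits perfectly, so the
        # documented convention returns CFI = TLI = 1
        p = 4
        S = np.eye(2 * p)
        support = np.zeros((p, p), dtype=bool)
        support[0, 0] = True
        fit = fit_structure_to_cov(S, support, n=200)
        assert fit.cfi == 1.0
        assert fit.tli == 1.0

    def test_saturated_structure_on_own_implied_covariance_is_exact(self):
        rng = np.random.default_rng(9)
        p = 6
        A = rng.standard_normal((2 * p, 2 * p))
        S = A @ A.T / (2 * p) + np.eye(2 * p)
        sat = np.ones((p, p), dtype=bool)
        first = fit_structure_to_cov(S, sat, n=500)
        # feed the model its own implied covariance: misfit vanishes
        S11 = S[:p, :p]
        B = np.linalg.solve(S11, S[:p, p:])
        resid = S[p:, p:] - S[p:, :p] @ B
        sigma = np.block(
            [[S11, S11 @ B], [(S11 @ B).T, B.T @ S11 @ B + np.diag(np.diag(resid))]]
        )
        refit = fit_structure_to_cov(sigma, sat, n=500)
        assert refit.chi_square == pytest.approx(0.0, abs=1e-8)
        assert refit.srmr == pytest.approx(0.0, abs=1e-9)
        assert refit.cfi == 1.0
        assert first.srmr >= refit.srmr

    def test_recovered_structure_fits_well_under_diagonal_residuals(self):
        cfg = SyntheticConfig(
            cross_lagged=[("D6", "A1", 0.3), ("L2", "D1", 0.3), ("L3", "A1", 0.4)],
            autoregressive_coeff=0.4,
            t2_structure="diagonal_residual",
        )
        truth = generate_truth(cfg)
        panel = simulate_panel(truth, n=2000, seed=8)
        model = fit_clpn(panel, seed=1)
        fit = path_model_fit(panel, model)
        assert fit.rmsea < 0.05
        assert fit.cfi > 0.95
        assert fit.srmr < 0.05
        assert fit.tli <= 1.0
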