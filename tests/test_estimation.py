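"""Graphical-lasso path, RIC selection and partial-correlation mapping tests.

The independent optimization oracle is an ADMM solver for the penalized
log-likelihood, written here from scratch so it shares nothing with the
coordinate-descent route used by the package.
"""

import numpy as np
import pytest

from panelnet.estimation import (
    EstimatorConfig,
    WeightedNetwork,
    estimate_network,
    estimate_pcor,
    fit_glasso,
    glasso_objective,
    glasso_path,
    lambda_grid,
    pcor_matrix,
    rotation_lambda,
    select_ric,
)
from panelnet.preprocessing import nonparanormal_transform, npn_scores
from panelnet.synthetic import simulate_panel


def admm_glasso(S, lam, rho=1.0, n_iter=3000):
    """Generic convex-solver oracle: ADMM on the penalized likelihood."""
    p = S.shape[0]
    Z = np.eye(p)
    U = np.zeros((p, p))
    K = np.eye(p)
    for _ in range(n_iter):
        w, Q = np.linalg.eigh(rho * (Z - U) - S)
        kappa = (w + np.sqrt(w**2 + 4 * rho)) / (2 * rho)
        K = Q @ np.diag(kappa) @ Q.T
        A = K + U
        Z = np.sign(A) * np.maximum(np.abs(A) - lam / rho, 0.0)
        np.fill_diagonal(Z, np.diag(A))  # diagonal unpenalized
        U = U + K - Z
    return Z


@pytest.fixture(scope="module")
def fixture_S():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((200, 4)) @ np.linalg.cholesky(
        np.array(
            [
                [1.0, 0.5, 0.2, 0.0],
                [0.5, 1.0, 0.3, 0.1],
                [0.2, 0.3, 1.0, 0.4],
                [0.0, 0.1, 0.4, 1.0],
            ]
        )
    ).T
    return np.corrcoef(X, rowvar=False)


class TestGlasso:
    def test_saturation_bound_gives_empty_network(self, fixture_S):
        lam = np.max(np.abs(fixture_S - np.diag(np.diag(fixture_S)))) * 1.001
        K = fit_glasso(fixture_S, lam)
        off = K[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0)

    def test_zero_penalty_recovers_plain_inverse(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((500, 3))
        S = np.corrcoef(X, rowvar=False)
        K = fit_glasso(S, 0.0)
        assert np.allclose(K, np.linalg.inv(S), atol=1e-4)

    def test_objective_matches_admm_oracle(self, fixture_S):
        lam = 0.1
        K = fit_glasso(fixture_S, lam, tol=1e-10, max_iter=10_000)
        K_oracle = admm_glasso(fixture_S, lam)
        obj = glasso_objective(K, fixture_S, lam)
        obj_oracle = glasso_objective(K_oracle, fixture_S, lam)
        assert obj == pytest.approx(obj_oracle, abs=1e-6)

    def test_path_sparsity_monotone(self, default_panel):
        scores = nonparanormal_transform(default_panel.t1)
        path = glasso_path(scores, n_lambdas=25)
        # sparsity (fraction nonzero) non-decreasing as lambda shrinks
        assert np.all(np.diff(path.sparsities) >= -1e-12)
        assert np.all(np.diff(path.lambdas) < 0)


class TestRIC:
    def test_deterministic_given_seed(self, default_panel):
        scores = nonparanormal_transform(default_panel.t1)
        lams = lambda_grid(np.corrcoef(scores.scores, rowvar=False))
        a = select_ric(scores, lams, n_rotations=1, seed=3)
        b = select_ric(scores, lams, n_rotations=1, seed=3)
        assert a == b

    def test_rotation_penalty_tracks_null_maximum(self):
        # independent columns: lambda* should sit near the expected maximum
        # absolute null correlation, approximated by direct simulation
        rng = np.random.default_rng(7)
        n, p = 2000, 10
        X = rng.standard_normal((n, p))
        lam_star = rotation_lambda(X, n_rotations=50, seed=1)
        null_max = np.empty(50)
        for r in range(50):
            Y = np.random.default_rng(100 + r).standard_normal((n, p))
            R = np.corrcoef(Y, rowvar=False)
            null_max[r] = np.max(np.abs(R[~np.eye(p, dtype=bool)]))
        assert lam_star == pytest.approx(null_max.mean(), abs=0.01)

    def test_duplicated_column_does_not_inflate_penalty(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((1000, 8))
        X_dup = np.column_stack([X, X[:, 0]])  # perfect duplicate
        lam_plain = rotation_lambda(X_dup[:, :8], n_rotations=40, seed=2)
        lam_dup = rotation_lambda(X_dup, n_rotations=40, seed=2)
        # rotation destroys the duplication; only the extra-column null
        # maximum moves the penalty, not the perfect correlation
        assert abs(lam_dup - lam_plain) < 0.02

    def test_penalty_above_path_returns_largest_with_warning(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 5))
        with pytest.warns(UserWarning, match="above the entire path"):
            lam, idx = select_ric(X, np.array([1e-4, 1e-5]), seed=0)
        assert idx == 0

    def test_null_columns_yield_near_empty_network(self):
        # specificity: with independent columns the RIC penalty admits at
        # most a couple of spurious edges in nearly all replications (the
        # mean-of-maxima penalty sits at the centre of the null-max
        # distribution, so a single borderline edge can slip through)
        clean = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(500 + rep)
            X = rng.standard_normal((500, 8))
            P, _ = estimate_pcor(X, EstimatorConfig(seed=rep), transformed=True)
            clean += np.count_nonzero(P[np.triu_indices(8, 1)]) <= 2
        assert clean / reps >= 0.95


class TestPcor:
    def test_identity_precision_gives_zero_network(self):
        assert np.allclose(pcor_matrix(np.eye(6)), 0)

    def test_two_by_two_hand_value(self):
        K = np.array([[2.0, -1.0], [-1.0, 2.0]])
        P = pcor_matrix(K)
        assert P[0, 1] == pytest.approx(0.5)

    def test_random_precision_matches_inverse_covariance_oracle(self):
        rng = np.random.default_rng(21)
        A = rng.standard_normal((5, 5))
        K = A @ A.T + 5 * np.eye(5)
        P = pcor_matrix(K)
        # oracle: partial correlation from the inverse of the covariance
        cov = np.linalg.inv(K)
        Kb = np.linalg.inv(cov)
        d = 1 / np.sqrt(np.diag(Kb))
        expected = -Kb * np.outer(d, d)
        np.fill_diagonal(expected, 0)
        assert np.allclose(P, expected, atol=1e-10)

    def test_non_positive_definite_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            pcor_matrix(K)


class TestEstimateNetwork:
    def test_deterministic_given_seed(self, default_panel, fast_estimator):
        a = estimate_network(default_panel.t1, fast_estimator)
        b = estimate_network(default_panel.t1, fast_estimator)
        assert np.array_equal(a.weights, b.weights)
        assert a.metadata["lambda"] == b.metadata["lambda"]

    def test_network_invariants(self, default_panel, fast_estimator):
        net = estimate_network(default_panel.t1, fast_estimator)
        assert np.max(np.abs(net.weights - net.weights.T)) <= 1e-10
        assert np.all(np.diag(net.weights) == 0)
        assert np.max(np.abs(net.weights)) < 1
        assert net.metadata["criterion"] == "ric"

    def test_error_shrinks_with_sample_size(self, default_truth):
        errs = []
        for n in (500, 2000, 8000):
            panel = simulate_panel(default_truth, n=n, seed=31)
            net = estimate_network(panel.t1, EstimatorConfig(seed=4))
            errs.append(
                np.linalg.norm(net.weights - default_truth.pcor_T1, "fro")
            )
        assert errs[0] > errs[1] > errs[2]

    def test_solution_at_least_as_good_as_truth_precision(
        self, default_truth, default_panel
    ):
        scores = npn_scores(default_panel.t1.responses)
        S = np.corrcoef(scores, rowvar=False)
        cfg = EstimatorConfig(seed=4)
        net = estimate_network(default_panel.t1, cfg)
        lam = net.metadata["lambda"]
        K_hat = fit_glasso(S, lam)
        assert glasso_objective(K_hat, S, lam) >= (
            glasso_objective(default_truth.precision_T1, S, lam) - 1e-6
        )

    def test_ebic_alternative_runs(self, default_panel):
        cfg = EstimatorConfig(criterion="ebic", n_lambdas=20, seed=1)
        net = estimate_network(default_panel.t1, cfg)
        assert net.metadata["criterion"] == "ebic"
        assert 0 < np.count_nonzero(net.upper_triangle())

    def test_lean_and_full_paths_agree(self, default_panel):
        cfg = EstimatorConfig(seed=12)
        net = estimate_network(default_panel.t1, cfg)
        P, lam = estimate_pcor(default_panel.t1.responses, cfg)
        assert lam == net.metadata["lambda"]
        assert np.allclose(P, net.weights, atol=1e-12)


class TestNetworkIO:
    def test_adjacency_roundtrip(self, default_panel, fast_estimator, tmp_path):
        net = estimate_network(default_panel.t1, fast_estimator)
        path = tmp_path / "adj.csv"
        net.to_adjacency_csv(path)
        back = WeightedNetwork.from_adjacency_csv(path)
        assert back.node_labels == net.node_labels
        assert np.allclose(back.weights, net.weights, atol=1e-12)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            WeightedNetwork(np.array([[0, 0.2], [0.1, 0]]), ["a", "b"])
        with pytest.raises(ValueError, match="diagonal"):
            WeightedNetwork(np.array([[0.5, 0.2], [0.2, 0.5]]), ["a", "b"])
        with pytest.raises(ValueError, match="magnitude"):
            WeightedNetwork(np.array([[0, 1.2], [1.2, 0]]), ["a", "b"])
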