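"""Sparse partial-correlation (Gaussian graphical model) estimation.

The estimator is the graphical lasso on the correlation matrix of
nonparanormal-transformed scores, with the regularization parameter chosen by
a rotation information criterion (RIC): columns of the data are independently
permuted ("rotated"), destroying all cross-column dependence, and the
penalty is set to the average of the maximal absolute correlations such null
rotations produce.  Edges stronger than what pure noise generates survive.

The graphical lasso maximizes ``log det K - tr(S K) - lambda * sum_{i!=j}
|K_ij|`` (diagonal unpenalized); the network's edge weights are the implied
partial correlations ``w_ij = -K_ij / sqrt(K_ii K_jj)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_glasso

try:  # lean solver entry point (skips re-validating the input each call);
    # behaviour verified against the public function in the test suite
    from sklearn.covariance._graph_lasso import _graphical_lasso as _sk_glasso_core
except ImportError:  # pragma: no cover
    _sk_glasso_core = None

from .datasets import OrdinalPanelDataset
from .preprocessing import GaussianScores, nonparanormal_transform


class EstimationError(RuntimeError):
    pass


@dataclass
class WeightedNetwork:
    """Symmetric signed partial-correlation network on labelled nodes."""

    weights: np.ndarray
    node_labels: list[str]
    node_community: dict[str, str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if W.shape[0] != len(self.node_labels):
            raise ValueError("label count does not match matrix size")
        if np.max(np.abs(W - W.T)) > 1e-10:
            raise ValueError("weights must be symmetric (tolerance 1e-10)")
        if np.any(np.abs(np.diag(W)) > 1e-12):
            raise ValueError("diagonal must be zero")
        off = W[~np.eye(W.shape[0], dtype=bool)]
        if off.size and np.max(np.abs(off)) >= 1.0:
            raise ValueError("partial correlations must have magnitude < 1")
        self.weights = (W + W.T) / 2.0
        np.fill_diagonal(self.weights, 0.0)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.p, 1)
        return self.weights[iu]

    def edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(self.p, 1)
        mask = self.weights[iu] != 0
        return pd.DataFrame(
            {
                "node_a": [self.node_labels[i] for i in iu[0][mask]],
                "node_b": [self.node_labels[j] for j in iu[1][mask]],
                "weight": self.weights[iu][mask],
            }
        )

    def global_strength(self) -> float:
        """Sum of absolute edge weights (each edge counted once)."""
        return float(np.abs(self.upper_triangle()).sum())

    def to_graph(self):
        """networkx Graph over the nonzero edges (weights as attributes)."""
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.node_labels)
        if self.node_community:
            nx.set_node_attributes(G, self.node_community, "community")
        for _, row in self.edge_list().iterrows():
            G.add_edge(row.node_a, row.node_b, weight=float(row.weight))
        return G

    # --- I/O ------------------------------------------------------------
    def to_adjacency_csv(self, path) -> None:
        pd.DataFrame(
            self.weights, index=self.node_labels, columns=self.node_labels
        ).to_csv(path)

    def to_edge_csv(self, path) -> None:
        self.edge_list().to_csv(path, index=False)

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_graph(), path)

    @classmethod
    def from_adjacency_csv(cls, path) -> "WeightedNetwork":
        df = pd.read_csv(path, index_col=0)
        return cls(weights=df.to_numpy(), node_labels=list(df.columns))


@dataclass
class LambdaPath:
    """A decreasing penalty path with the fitted precision at each value."""

    lambdas: np.ndarray
    precisions: list[np.ndarray]
    sparsities: np.ndarray  # fraction of nonzero off-diagonal entries

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lambdas) >= 0):
            raise ValueError("lambdas must be strictly decreasing")


@dataclass
class EstimatorConfig:
    """Settings of the contemporaneous-network estimator."""

    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    n_rotations: int = 20
    criterion: str = "ric"  # or "ebic"
    ebic_gamma: float = 0.5
    tol: float = 1e-4
    max_iter: int = 1000
    seed: int = 0


def lambda_grid(
    S: np.ndarray, n_lambdas: int = 100, lambda_min_ratio: float = 0.01
) -> np.ndarray:
    """Log-spaced decreasing grid from the lasso saturation bound down."""
    lam_max = float(np.max(np.abs(S - np.diag(np.diag(S)))))
    if lam_max <= 0:
        lam_max = 1.0
    return np.logspace(
        np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambdas
    )


def _correlation(scores: GaussianScores | np.ndarray) -> np.ndarray:
    X = scores.scores if isinstance(scores, GaussianScores) else np.asarray(scores)
    return np.corrcoef(X, rowvar=False)


def fit_glasso(
    S: np.ndarray, lam: float, tol: float = 1e-4, max_iter: int = 1000
) -> np.ndarray:
    """Single graphical-lasso fit; ``lam = 0`` falls back to plain inversion."""
    if lam <= 0:
        return np.linalg.inv(S)
    try:
        if _sk_glasso_core is not None:
            # inner lasso solved tightly (enet_tol) so the duality-gap
            # convergence check is reliable; with a loose inner tolerance the
            # gap estimate bottoms out below zero and the sweep never stops
            _, K = _sk_glasso_core(
                np.asarray(S, dtype=np.float64),
                alpha=lam,
                tol=tol,
                enet_tol=1e-7,
                max_iter=max_iter,
                verbose=False,
                eps=np.finfo(np.float64).eps,
            )[:2]
        else:  # pragma: no cover - exercised only on other sklearn versions
            _, K = _sk_glasso(S, alpha=lam, tol=tol, max_iter=max_iter)
    except FloatingPointError as err:  # pragma: no cover - numerical failure
        raise EstimationError(f"graphical lasso failed at lambda={lam}: {err}")
    return K


def glasso_objective(K: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Penalized log-likelihood maximized by the graphical lasso."""
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    penalty = lam * (np.abs(K).sum() - np.abs(np.diag(K)).sum())
    return float(logdet - np.trace(S @ K) - penalty)


def glasso_path(
    scores: GaussianScores | np.ndarray,
    lambdas: Sequence[float] | None = None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> LambdaPath:
    """Fit the graphical lasso along a decreasing penalty path.

    Warns when ``n <= p`` (the unregularized end of the path is unreliable).
    """
    X = scores.scores if isinstance(scores, GaussianScores) else np.asarray(scores)
    n, p = X.shape
    if p < 3:
        raise ValueError("need at least 3 variables")
    if n <= p:
        warnings.warn("n <= p: path estimates may be unstable", stacklevel=2)
    S = _correlation(X)
    lams = (
        np.asarray(sorted(lambdas, reverse=True), dtype=float)
        if lambdas is not None
        else lambda_grid(S, n_lambdas, lambda_min_ratio)
    )
    precisions, sparsities = [], []
    off_mask = ~np.eye(p, dtype=bool)
    for idx, lam in enumerate(lams):
        try:
            K = fit_glasso(S, float(lam), tol=tol, max_iter=max_iter)
        except EstimationError as err:
            raise EstimationError(f"path index {idx}: {err}") from err
        precisions.append(K)
        sparsities.append(np.mean(K[off_mask] != 0))
    return LambdaPath(
        lambdas=lams, precisions=precisions, sparsities=np.asarray(sparsities)
    )


def rotation_lambda(
    scores: GaussianScores | np.ndarray, n_rotations: int = 20, seed: int = 0
) -> float:
    """RIC penalty: mean over rotations of the max absolute null correlation.

    Each rotation permutes the rows of every column independently, destroying
    cross-column dependence while preserving the marginals.
    """
    X = scores.scores if isinstance(scores, GaussianScores) else np.asarray(scores)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    # standardize once: permutations leave the marginals untouched, so the
    # correlation of permuted columns is just the cross-product / n
    Z = X - X.mean(axis=0)
    Z = Z / Z.std(axis=0, ddof=0)
    off = ~np.eye(p, dtype=bool)
    maxima = np.empty(n_rotations)
    for r in range(n_rotations):
        rotated = rng.permuted(Z, axis=0)
        R = rotated.T @ rotated / n
        maxima[r] = np.max(np.abs(R[off]))
    return float(maxima.mean())


def select_ric(
    scores: GaussianScores | np.ndarray,
    path: LambdaPath | np.ndarray,
    n_rotations: int = 20,
    seed: int = 0,
) -> tuple[float, int]:
    """Pick the smallest path penalty at least as large as the RIC penalty.

    Returns ``(lambda, index)``.  If the RIC penalty exceeds the whole path,
    the largest path value is returned with a warning.
    """
    lams = path.lambdas if isinstance(path, LambdaPath) else np.asarray(path)
    if lams.size == 0:
        raise ValueError("empty lambda path")
    lam_star = rotation_lambda(scores, n_rotations=n_rotations, seed=seed)
    eligible = np.flatnonzero(lams >= lam_star)
    if eligible.size == 0:
        warnings.warn(
            f"RIC penalty {lam_star:.4f} above the entire path; "
            "returning the largest path value",
            stacklevel=2,
        )
        return float(lams[0]), 0
    idx = int(eligible[-1])  # lams decreasing: last eligible is the smallest
    return float(lams[idx]), idx


def ebic_score(
    K: np.ndarray, S: np.ndarray, n: int, gamma: float = 0.5
) -> float:
    """Extended BIC of a fitted precision matrix (lower is better)."""
    sign, logdet = np.linalg.slogdet(K)
    loglik = n / 2.0 * (logdet - np.trace(S @ K))
    p = K.shape[0]
    iu = np.triu_indices(p, 1)
    nedges = int(np.sum(K[iu] != 0))
    return float(
        -2 * loglik + nedges * np.log(n) + 4 * nedges * gamma * np.log(p)
    )


def pcor_matrix(K: np.ndarray) -> np.ndarray:
    """Partial correlations implied by a positive-definite precision matrix."""
    K = np.asarray(K, dtype=float)
    try:
        np.linalg.cholesky(K)
    except np.linalg.LinAlgError as err:
        raise ValueError("precision matrix is not positive definite") from err
    d = 1.0 / np.sqrt(np.diag(K))
    P = -K * np.outer(d, d)
    P = (P + P.T) / 2.0
    np.fill_diagonal(P, 0.0)
    return P


def precision_to_pcor(
    K: np.ndarray,
    node_labels: list[str] | None = None,
    node_community: dict[str, str] | None = None,
    metadata: dict | None = None,
) -> WeightedNetwork:
    """Wrap the partial correlations of a precision matrix as a network."""
    P = pcor_matrix(K)
    labels = node_labels or [f"V{i + 1}" for i in range(P.shape[0])]
    return WeightedNetwork(
        weights=P,
        node_labels=labels,
        node_community=node_community,
        metadata=metadata or {},
    )


def estimate_pcor(
    responses: np.ndarray,
    config: EstimatorConfig | None = None,
    transformed: bool = False,
) -> tuple[np.ndarray, float]:
    """Lean array-level estimator: returns ``(pcor matrix, selected lambda)``.

    Runs transform -> RIC penalty -> graphical lasso on a raw response
    matrix without any container plumbing; this is the inner loop of the
    permutation comparison test and the stability resampling.  Only the
    ``ric`` criterion is supported here.
    """
    from .preprocessing import npn_scores

    cfg = config or EstimatorConfig()
    X = np.asarray(responses) if transformed else npn_scores(responses)
    S = np.corrcoef(X, rowvar=False)
    lams = lambda_grid(S, cfg.n_lambdas, cfg.lambda_min_ratio)
    lam_star = rotation_lambda(X, n_rotations=cfg.n_rotations, seed=cfg.seed)
    eligible = np.flatnonzero(lams >= lam_star)
    lam = float(lams[eligible[-1]] if eligible.size else lams[0])
    K = fit_glasso(S, lam, tol=cfg.tol, max_iter=cfg.max_iter)
    d = 1.0 / np.sqrt(np.diag(K))
    P = -K * np.outer(d, d)
    P = (P + P.T) / 2.0
    np.fill_diagonal(P, 0.0)
    return P, lam


def estimate_network(
    data: OrdinalPanelDataset | GaussianScores,
    config: EstimatorConfig | None = None,
) -> WeightedNetwork:
    """Full estimator: transform -> penalty selection -> glasso -> pcor.

    Accepts raw ordinal data (transformed internally) or pre-transformed
    scores.  With the default RIC criterion only the selected penalty is
    fitted (selection does not depend on the other path fits); with
    ``criterion="ebic"`` the whole path is fitted and scored.
    """
    cfg = config or EstimatorConfig()
    if isinstance(data, OrdinalPanelDataset):
        scores = nonparanormal_transform(data)
        communities = dict(data.community_labels)
        wave = data.wave_id
    else:
        scores = data
        communities = dict(data.communities) if data.communities else None
        wave = data.source_wave
    X = scores.scores
    S = _correlation(X)
    lams = lambda_grid(S, cfg.n_lambdas, cfg.lambda_min_ratio)

    if cfg.criterion == "ric":
        lam_star = rotation_lambda(X, n_rotations=cfg.n_rotations, seed=cfg.seed)
        eligible = np.flatnonzero(lams >= lam_star)
        idx = int(eligible[-1]) if eligible.size else 0
        lam = float(lams[idx])
        K = fit_glasso(S, lam, tol=cfg.tol, max_iter=cfg.max_iter)
    elif cfg.criterion == "ebic":
        path = glasso_path(
            X, lambdas=lams, tol=cfg.tol, max_iter=cfg.max_iter
        )
        scores_ = [
            ebic_score(K, S, X.shape[0], cfg.ebic_gamma) for K in path.precisions
        ]
        idx = int(np.argmin(scores_))
        lam = float(path.lambdas[idx])
        K = path.precisions[idx]
    else:
        raise ValueError(f"unknown criterion {cfg.criterion!r}")

    metadata = {
        "lambda": lam,
        "lambda_index": idx,
        "criterion": cfg.criterion,
        "n": int(X.shape[0]),
        "n_lambdas": cfg.n_lambdas,
        "n_rotations": cfg.n_rotations,
        "wave": wave,
        "estimator": "glasso",
        "ric_aggregation": "mean of per-rotation maxima",
    }
    return precision_to_pcor(
        K, node_labels=list(scores.item_labels),
        node_community=communities, metadata=metadata,
    )
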