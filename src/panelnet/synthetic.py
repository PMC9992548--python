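"""Synthetic two-wave ordinal panel generator with known network ground truth.

The generative model mirrors the assumptions under which the analysis pipeline
operates: each wave's item responses are discretized latent Gaussian scores
(the nonparanormal view of ordinal data), the within-wave dependence is a
sparse Gaussian graphical model, and wave 2 depends on wave 1 through a sparse
standardized cross-lagged coefficient matrix.

Within-wave structure
    The precision matrix is ``K = I - W`` where ``W`` places the configured
    partial correlation at every structural edge.  Within each community the
    structural edges form a ring (each item tied to its two neighbours;
    complete for communities of size <= 3), plus explicit cross-community
    bridge edges.  Because ``diag(K) = 1``, the implied partial correlation at
    an edge equals its configured weight exactly.  A ring keeps the default
    weight of 0.25 positive definite, which a complete 7-clique of equal
    partial correlations cannot be.

Between-wave structure
    Latent wave-2 scores are ``z2 = A z1 + e`` with ``A = B^T`` and
    ``B[s, t]`` the standardized effect of item ``s`` at T1 on item ``t`` at
    T2 (autoregressive effects on the diagonal).  The noise covariance is
    chosen so that the *marginal* T2 latent correlation matrix equals the one
    implied by ``precision_T2`` — so the T2 contemporaneous network has known
    ground truth too, and configured cross-lagged coefficients are on the
    standardized scale.

Discretization
    Item ``j`` maps latent ``z`` to category ``1 + #{thresholds < z}``.  The
    default thresholds are the standard-normal quartile cuts shifted by
    ``threshold_skew`` (+ for anxiety/loneliness items, - for reverse-keyed
    depression items), reproducing the heavy floor/ceiling skew typical of
    these instruments in general-population surveys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .datasets import (
    DEFAULT_COMMUNITIES,
    DEFAULT_ITEMS,
    DEFAULT_REVERSE_CODED,
    OrdinalPanelDataset,
    TwoWavePanel,
)


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration is internally inconsistent."""


#: default cross-community bridge edges (within-wave partial correlations),
#: loosely patterned on the anxiety-depression and depression-loneliness
#: overlaps this kind of data shows
DEFAULT_BRIDGES = [
    ("A2", "D1", 0.15),
    ("A4", "D3", 0.15),
    ("D4", "L2", 0.15),
    ("D5", "L1", 0.15),
]

#: default standardized cross-lagged paths (T1 item -> T2 item)
DEFAULT_CROSS_LAGGED = [
    ("L3", "A1", 0.35),
    ("D6", "L2", 0.30),
    ("L2", "A1", 0.25),
]


@dataclass
class SyntheticConfig:
    """Configuration of the two-wave generative model.

    Attributes
    ----------
    n_participants:
        Default panel size drawn by :func:`simulate_panel` when none given.
    community_sizes:
        Community sizes summing to p; default ``[7, 7, 3]``.
    within_edge_weight:
        Partial correlation placed on each within-community ring edge.
    bridge_edges:
        ``(item_i, item_j, weight)`` cross-community partial correlations.
    cross_lagged:
        ``(source_T1, target_T2, standardized coefficient)`` paths.
    autoregressive_coeff:
        Scalar or per-item sequence in ``[0, 1)``; diagonal of the
        cross-wave coefficient matrix.
    n_categories:
        Ordinal categories per item.
    threshold_skew:
        Shift applied to the quartile thresholds; larger values push more
        mass into the floor (or ceiling, for reverse-keyed items) category.
    t2_structure:
        ``"matched"`` (default): the marginal T2 latent correlations equal
        the ones implied by the configured T2 network, so the T2
        contemporaneous network has known ground truth (T2 residuals are
        then correlated).  ``"diagonal_residual"``: T2 = A z1 + diagonal
        noise, the data-generating process assumed by the cross-lagged path
        model (the T2 network is then whatever the cross-paths induce).
    seed:
        Seed used by :func:`simulate_panel` when none given.
    """

    n_participants: int = 2000
    community_sizes: tuple[int, ...] = (7, 7, 3)
    within_edge_weight: float = 0.25
    bridge_edges: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_BRIDGES)
    )
    cross_lagged: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_CROSS_LAGGED)
    )
    autoregressive_coeff: float | tuple[float, ...] = 0.3
    n_categories: int = 4
    threshold_skew: float = 0.8
    t2_structure: str = "matched"  # or "diagonal_residual"
    seed: int = 42

    @property
    def p(self) -> int:
        return int(sum(self.community_sizes))

    def item_labels(self) -> list[str]:
        if tuple(self.community_sizes) == (7, 7, 3):
            return list(DEFAULT_ITEMS)
        labels = []
        for c, size in enumerate(self.community_sizes):
            labels += [f"C{c + 1}I{i + 1}" for i in range(size)]
        return labels

    def community_of(self) -> dict[str, str]:
        labels = self.item_labels()
        if tuple(self.community_sizes) == (7, 7, 3):
            return dict(DEFAULT_COMMUNITIES)
        out, k = {}, 0
        for c, size in enumerate(self.community_sizes):
            for _ in range(size):
                out[labels[k]] = f"community{c + 1}"
                k += 1
        return out


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated panel.

    ``pcor_ij = -K_ij / sqrt(K_ii K_jj)`` holds exactly for the stored
    precision matrices, and ``beta_cross[s, t]`` is the standardized latent
    effect of T1 item ``s`` on T2 item ``t`` (autoregressive on the diagonal).
    """

    precision_T1: np.ndarray
    precision_T2: np.ndarray
    pcor_T1: np.ndarray
    pcor_T2: np.ndarray
    beta_cross: np.ndarray
    thresholds: np.ndarray
    item_labels: list[str]
    community_labels: dict[str, str]
    reverse_coded: dict[str, bool]
    seed: int
    n_categories: int = 4

    @property
    def p(self) -> int:
        return self.precision_T1.shape[0]

    def latent_corr(self, wave: str = "T1") -> np.ndarray:
        """Marginal latent correlation matrix implied by the precision."""
        K = self.precision_T1 if wave == "T1" else self.precision_T2
        cov = np.linalg.inv(K)
        d = 1.0 / np.sqrt(np.diag(cov))
        return cov * np.outer(d, d)

    def to_json(self, path) -> None:
        payload = {
            "precision_T1": self.precision_T1.tolist(),
            "precision_T2": self.precision_T2.tolist(),
            "pcor_T1": self.pcor_T1.tolist(),
            "pcor_T2": self.pcor_T2.tolist(),
            "beta_cross": self.beta_cross.tolist(),
            "thresholds": self.thresholds.tolist(),
            "item_labels": self.item_labels,
            "community_labels": self.community_labels,
            "reverse_coded": self.reverse_coded,
            "seed": self.seed,
            "n_categories": self.n_categories,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            precision_T1=np.asarray(d["precision_T1"]),
            precision_T2=np.asarray(d["precision_T2"]),
            pcor_T1=np.asarray(d["pcor_T1"]),
            pcor_T2=np.asarray(d["pcor_T2"]),
            beta_cross=np.asarray(d["beta_cross"]),
            thresholds=np.asarray(d["thresholds"]),
            item_labels=list(d["item_labels"]),
            community_labels=dict(d["community_labels"]),
            reverse_coded=dict(d["reverse_coded"]),
            seed=int(d["seed"]),
            n_categories=int(d["n_categories"]),
        )


def _ring_edges(offset: int, size: int) -> list[tuple[int, int]]:
    """Ring (cycle) edge list over ``offset..offset+size-1``."""
    if size < 2:
        return []
    if size == 2:
        return [(offset, offset + 1)]
    nodes = list(range(offset, offset + size))
    return [(nodes[i], nodes[(i + 1) % size]) for i in range(size)]


def precision_from_edges(
    p: int, edges: list[tuple[int, int, float]]
) -> np.ndarray:
    """Unit-diagonal precision matrix whose partial correlations equal the
    configured edge weights exactly (``K = I - W``)."""
    K = np.eye(p)
    for i, j, w in edges:
        K[i, j] = K[j, i] = -w
    return K


def pcor_from_precision(K: np.ndarray) -> np.ndarray:
    d = 1.0 / np.sqrt(np.diag(K))
    P = -K * np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return P


def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Build the ground-truth networks, cross-lagged matrix and thresholds.

    Raises
    ------
    ConfigurationError
        If the implied precision matrix is not positive definite (the error
        names the smallest eigenvalue), if the T2 residual covariance is not
        positive definite, or if labels/coefficients are out of range.
    """
    p = config.p
    labels = config.item_labels()
    index = {lab: i for i, lab in enumerate(labels)}

    edges: list[tuple[int, int, float]] = []
    offset = 0
    for size in config.community_sizes:
        edges += [
            (i, j, config.within_edge_weight) for i, j in _ring_edges(offset, size)
        ]
        offset += size
    for a, b, w in config.bridge_edges:
        if a not in index or b not in index:
            raise ConfigurationError(f"unknown bridge item in ({a}, {b})")
        edges.append((index[a], index[b], float(w)))

    K = precision_from_edges(p, edges)
    eigmin = float(np.linalg.eigvalsh(K)[0])
    if eigmin <= 0:
        raise ConfigurationError(
            "implied precision matrix is not positive definite: smallest "
            f"eigenvalue = {eigmin:.4f}; reduce edge weights"
        )

    ar = config.autoregressive_coeff
    ar_vec = np.full(p, float(ar)) if np.isscalar(ar) else np.asarray(ar, float)
    if ar_vec.shape != (p,):
        raise ConfigurationError("autoregressive_coeff must be scalar or length p")
    if np.any(ar_vec < 0) or np.any(ar_vec >= 1):
        raise ConfigurationError("autoregressive coefficients must lie in [0, 1)")
    beta = np.diag(ar_vec.copy())
    for s, t, b in config.cross_lagged:
        if s not in index or t not in index:
            raise ConfigurationError(f"unknown cross-lagged item in ({s}, {t})")
        beta[index[s], index[t]] = float(b)

    sigma1 = _corr_from_precision(K)
    A = beta.T
    M = A @ sigma1 @ A.T
    if config.t2_structure == "matched":
        # same contemporaneous structure at both waves (the two observed
        # networks in this population are near-identical); residual
        # covariance makes T2 marginals exactly the target correlations
        K2 = K.copy()
        sigma2 = _corr_from_precision(K2)
        psi = sigma2 - M
    elif config.t2_structure == "diagonal_residual":
        # T2 = A z1 + independent noise topping variances up to 1
        d = 1.0 - np.diag(M)
        if np.any(d <= 0):
            raise ConfigurationError(
                "cross-lagged coefficients imply T2 variance >= 1 before noise"
            )
        sigma2 = M + np.diag(d)
        K2 = np.linalg.inv(sigma2)
        psi = np.diag(d)
    else:
        raise ConfigurationError(
            f"unknown t2_structure {config.t2_structure!r}"
        )
    psi_eigmin = float(np.linalg.eigvalsh(psi)[0])
    if psi_eigmin <= 0:
        raise ConfigurationError(
            "cross-lagged coefficients too large for the target T2 structure: "
            f"residual covariance smallest eigenvalue = {psi_eigmin:.4f}"
        )

    if config.n_categories < 2:
        raise ConfigurationError("need at least 2 response categories")
    base = norm.ppf(np.linspace(0, 1, config.n_categories + 1)[1:-1])
    reverse = {
        lab: DEFAULT_REVERSE_CODED.get(lab, False) for lab in labels
    }
    thresholds = np.array(
        [
            base - config.threshold_skew
            if reverse[lab]
            else base + config.threshold_skew
            for lab in labels
        ]
    )
    if np.any(np.diff(thresholds, axis=1) <= 0):
        raise ConfigurationError("category thresholds must be strictly increasing")

    return SyntheticTruth(
        precision_T1=K,
        precision_T2=K2,
        pcor_T1=pcor_from_precision(K),
        pcor_T2=pcor_from_precision(K2),
        beta_cross=beta,
        thresholds=thresholds,
        item_labels=labels,
        community_labels=config.community_of(),
        reverse_coded=reverse,
        seed=config.seed,
        n_categories=config.n_categories,
    )


def _corr_from_precision(K: np.ndarray) -> np.ndarray:
    cov = np.linalg.inv(K)
    d = 1.0 / np.sqrt(np.diag(cov))
    return cov * np.outer(d, d)


def simulate_latent(
    truth: SyntheticTruth, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw paired latent Gaussian scores for both waves (unit variances)."""
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    sigma1 = truth.latent_corr("T1")
    sigma2 = truth.latent_corr("T2")
    A = truth.beta_cross.T
    psi = sigma2 - A @ sigma1 @ A.T
    try:
        L1 = np.linalg.cholesky(sigma1)
        Lpsi = np.linalg.cholesky(psi)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular latent covariance: {err}") from err
    z1 = rng.standard_normal((n, truth.p)) @ L1.T
    z2 = z1 @ A.T + rng.standard_normal((n, truth.p)) @ Lpsi.T
    return z1, z2


def _discretize(z: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    # category = 1 + number of thresholds strictly below the latent score
    out = np.ones(z.shape, dtype=int)
    for j in range(z.shape[1]):
        out[:, j] += np.searchsorted(thresholds[j], z[:, j]).astype(int)
    return out


def simulate_panel(
    truth: SyntheticTruth, n: int | None = None, seed: int | None = None
) -> TwoWavePanel:
    """Simulate a paired two-wave ordinal panel from the ground truth.

    Deterministic given ``seed`` (defaults to the truth's own seed).
    """
    if n is None:
        n = 2000
    if seed is None:
        seed = truth.seed
    z1, z2 = simulate_latent(truth, n, seed)
    x1 = _discretize(z1, truth.thresholds)
    x2 = _discretize(z2, truth.thresholds)

    def _wave(x, wave_id):
        return OrdinalPanelDataset(
            responses=x,
            item_labels=list(truth.item_labels),
            community_labels=dict(truth.community_labels),
            wave_id=wave_id,
            reverse_coded=dict(truth.reverse_coded),
            n_categories=truth.n_categories,
        )

    return TwoWavePanel(t1=_wave(x1, "T1"), t2=_wave(x2, "T2"))
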