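"""Cross-lagged panel network (CLPN) with lasso-regularized regressions.

Each wave-2 item is regressed on *all* wave-1 items (itself included) with a
lasso penalty, so small cross-time paths shrink to exactly zero while the
surviving directed paths form a sparse temporal network.  The penalty for
each outcome is picked from a 100-value log-spaced path (lambda_min =
1e-4 * lambda_max) by k-fold cross-validation, choosing the lambda with the
lowest CV squared error.  All variables enter standardized (after the
nonparanormal transform, keeping the temporal analysis on the same scale as
the contemporaneous one), so coefficients are standardized betas.

Summary statistics:

* in-prediction of a T2 item — proportion of its variance explained by the
  full set of T1 items through the selected model (0..1);
* out-prediction of a T1 item — sum of squared outgoing standardized
  cross-lagged coefficients (autoregressive path excluded by default);
* fit indices of the selected path structure refit without penalty by
  maximum likelihood on the 2p-variable covariance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .datasets import TwoWavePanel
from .preprocessing import npn_scores


@dataclass
class CLPNModel:
    """Fitted cross-lagged panel network.

    ``beta[s, t]`` is the standardized coefficient of T1 item ``s``
    predicting T2 item ``t``; the diagonal holds autoregressive effects.
    Zeros are exact (lasso soft-thresholding).
    """

    beta: np.ndarray
    item_labels: list[str]
    selected_lambda: np.ndarray  # per T2 outcome
    cv_folds: int
    in_prediction: pd.Series
    out_prediction: pd.Series
    seed: int
    transform: str = "nonparanormal"

    @property
    def p(self) -> int:
        return self.beta.shape[0]

    def edge_table(self) -> pd.DataFrame:
        src, tgt = np.nonzero(self.beta)
        return pd.DataFrame(
            {
                "source_T1": [self.item_labels[s] for s in src],
                "target_T2": [self.item_labels[t] for t in tgt],
                "beta": self.beta[src, tgt],
                "autoregressive": src == tgt,
            }
        )

    def to_beta_csv(self, path) -> None:
        pd.DataFrame(
            self.beta, index=self.item_labels, columns=self.item_labels
        ).to_csv(path)

    def to_graphml(self, path) -> None:
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(self.item_labels)
        for _, row in self.edge_table().iterrows():
            G.add_edge(row.source_T1, row.target_T2, weight=float(row.beta))
        nx.write_graphml(G, path)


@dataclass
class FitIndices:
    """Maximum-likelihood fit of the selected path structure."""

    chi_square: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    baseline_chi_square: float
    baseline_df: int
    n: int

    def to_json_payload(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "CFI": self.cfi,
            "TLI": self.tli,
            "RMSEA": self.rmsea,
            "SRMR": self.srmr,
        }


def _standardize(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance column")
    return X / sd


def _panel_scores(panel: TwoWavePanel, transform: bool) -> tuple[np.ndarray, np.ndarray]:
    if transform:
        x1 = npn_scores(panel.t1.responses)
        x2 = npn_scores(panel.t2.responses)
    else:
        x1 = panel.t1.responses.astype(float)
        x2 = panel.t2.responses.astype(float)
    return _standardize(x1), _standardize(x2)


def fit_clpn(
    panel: TwoWavePanel,
    n_lambda: int = 100,
    cv_folds: int = 10,
    seed: int = 0,
    transform: bool = True,
    selection_rule: str = "min",
) -> CLPNModel:
    """Fit the lasso cross-lagged panel network on a paired two-wave panel.

    ``selection_rule="min"`` (default) takes the lambda with the lowest mean
    CV squared error; ``"1se"`` takes the largest lambda within one standard
    error of that minimum — a more conservative model with far fewer small
    spurious paths.  Warns when ``n < 10 p``.  Deterministic given ``seed``
    (used for the CV fold assignment of every outcome).
    """
    if selection_rule not in ("min", "1se"):
        raise ValueError("selection_rule must be 'min' or '1se'")
    x1, x2 = _panel_scores(panel, transform)
    n, p = x1.shape
    if n < 10 * p:
        warnings.warn(
            f"n={n} below the recommended 10*p={10 * p}; "
            "coefficients may be unstable",
            stacklevel=2,
        )
    beta = np.zeros((p, p))
    lambdas = np.empty(p)
    for t in range(p):
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        model = LassoCV(
            alphas=n_lambda,  # size of the log-spaced path
            eps=1e-4,  # lambda_min = 1e-4 * lambda_max
            cv=cv,
            fit_intercept=True,
            max_iter=50000,
            tol=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign convergence chatter
            model.fit(x1, x2[:, t])
        if selection_rule == "min":
            beta[:, t] = model.coef_
            lambdas[t] = model.alpha_
        else:
            mse = model.mse_path_.mean(axis=1)
            se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv_folds)
            imin = int(np.argmin(mse))
            within = np.flatnonzero(mse <= mse[imin] + se[imin])
            alpha = float(model.alphas_[within[0]])  # alphas_ descending
            refit = Lasso(alpha=alpha, max_iter=50000, tol=1e-6)
            refit.fit(x1, x2[:, t])
            beta[:, t] = refit.coef_
            lambdas[t] = alpha
    in_pred = _in_prediction_values(beta, x1, x2, panel.item_labels)
    out_pred = out_prediction_values(beta, panel.item_labels)
    return CLPNModel(
        beta=beta,
        item_labels=list(panel.item_labels),
        selected_lambda=lambdas,
        cv_folds=cv_folds,
        in_prediction=in_pred,
        out_prediction=out_pred,
        seed=seed,
        transform="nonparanormal" if transform else "raw",
    )


def _in_prediction_values(
    beta: np.ndarray, x1: np.ndarray, x2: np.ndarray, labels
) -> pd.Series:
    fitted = x1 @ beta
    tss = (x2**2).sum(axis=0)  # columns are standardized, mean 0
    rss = ((x2 - fitted) ** 2).sum(axis=0)
    r2 = np.clip(1.0 - rss / tss, 0.0, 1.0)
    return pd.Series(r2, index=list(labels), name="in_prediction")


def in_prediction(model: CLPNModel, panel: TwoWavePanel) -> pd.Series:
    """Variance of each T2 item explained by the selected model's T1 paths."""
    x1, x2 = _panel_scores(panel, model.transform == "nonparanormal")
    return _in_prediction_values(model.beta, x1, x2, model.item_labels)


def out_prediction_values(
    beta: np.ndarray, labels, include_autoregressive: bool = False
) -> pd.Series:
    out = (beta**2).sum(axis=1)
    if not include_autoregressive:
        out = out - np.diag(beta) ** 2
    return pd.Series(out, index=list(labels), name="out_prediction")


def out_prediction(
    model: CLPNModel, include_autoregressive: bool = False
) -> pd.Series:
    """Sum of squared outgoing standardized coefficients per T1 item."""
    return out_prediction_values(
        model.beta, model.item_labels, include_autoregressive
    )


def path_model_fit(panel: TwoWavePanel, model: CLPNModel) -> FitIndices:
    """Refit the selected path structure by ML and compute fit indices.

    The model frees the retained paths (others fixed at zero), saturates the
    T1 covariance block, and takes T2 residuals uncorrelated.  With a
    saturated exogenous block the ML estimates are equation-wise OLS on each
    outcome's selected predictors.  ``chi^2 = (n - 1) F_ML``; CFI/TLI are
    computed against the independence baseline; when the baseline chi^2 does
    not exceed its df the model is taken as fitting perfectly (CFI = 1).
    """
    if not np.any(model.beta != 0):
        raise ValueError("model has no retained path")
    x1, x2 = _panel_scores(panel, model.transform == "nonparanormal")
    n = x1.shape[0]
    S11 = x1.T @ x1 / n
    S12 = x1.T @ x2 / n
    S22 = x2.T @ x2 / n
    S = np.block([[S11, S12], [S12.T, S22]])
    return fit_structure_to_cov(S, model.beta != 0, n)


def fit_structure_to_cov(
    S: np.ndarray, support: np.ndarray, n: int
) -> FitIndices:
    """ML fit indices of a path structure against a 2p-variable covariance.

    ``S`` stacks T1 then T2 variables; ``support[s, t]`` marks a free path
    from T1 variable ``s`` to T2 variable ``t``.  With the T1 block
    saturated and T2 residuals uncorrelated, the ML path estimates are the
    covariance-level OLS solutions on each outcome's support.
    """
    support = np.asarray(support, dtype=bool)
    p = support.shape[0]
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError as err:
        raise ValueError("sample covariance is not positive definite") from err
    S11 = S[:p, :p]
    S12 = S[:p, p:]
    S22 = S[p:, p:]

    B = np.zeros((p, p))
    resid_var = np.empty(p)
    n_paths = 0
    for t in range(p):
        sup = np.flatnonzero(support[:, t])
        if sup.size:
            coef = np.linalg.solve(S11[np.ix_(sup, sup)], S12[sup, t])
            B[sup, t] = coef
            resid_var[t] = S22[t, t] - S12[sup, t] @ coef
            n_paths += sup.size
        else:
            resid_var[t] = S22[t, t]

    sigma12 = S11 @ B
    sigma22 = B.T @ S11 @ B + np.diag(resid_var)
    sigma = np.block([[S11, sigma12], [sigma12.T, sigma22]])

    q = 2 * p
    f_model = _f_ml(S, sigma, q)
    n_free = p * (p + 1) // 2 + n_paths + p
    df = q * (q + 1) // 2 - n_free
    chi2 = (n - 1) * f_model

    sigma_base = np.diag(np.diag(S))
    f_base = _f_ml(S, sigma_base, q)
    df_base = q * (q + 1) // 2 - q
    chi2_base = (n - 1) * f_base

    if chi2_base <= df_base or df <= 0:
        cfi, tli = 1.0, 1.0
    else:
        cfi = 1.0 - max(chi2 - df, 0.0) / max(chi2_base - df_base, chi2 - df, 1e-12)
        tli = ((chi2_base / df_base) - (chi2 / df)) / ((chi2_base / df_base) - 1.0)
        tli = min(tli, 1.0)  # overfit models can push the ratio past 1
    rmsea = (
        np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))) if df > 0 else 0.0
    )

    d = np.sqrt(np.diag(S))
    resid_std = (S - sigma) / np.outer(d, d)
    il = np.tril_indices(q)
    srmr = float(np.sqrt(np.mean(resid_std[il] ** 2)))

    return FitIndices(
        chi_square=float(chi2),
        df=int(df),
        cfi=float(cfi),
        tli=float(tli),
        rmsea=float(rmsea),
        srmr=srmr,
        baseline_chi_square=float(chi2_base),
        baseline_df=int(df_base),
        n=n,
    )


def _f_ml(S: np.ndarray, sigma: np.ndarray, q: int) -> float:
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValueError("implied covariance is not positive definite")
    _, logdet_s = np.linalg.slogdet(S)
    return float(
        logdet_sigma - logdet_s + np.trace(S @ np.linalg.inv(sigma)) - q
    )
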