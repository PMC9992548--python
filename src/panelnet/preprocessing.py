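"""Descriptives, redundancy screening and rank-based Gaussianization.

Three steps precede network estimation on ordinal item data:

* per-item descriptive statistics (mean, SD, skewness, excess kurtosis and
  the item-rest correlation within each instrument);
* a Goldbricker screen for redundant item pairs — two items that correlate
  highly *and* correlate with the remaining items in statistically
  indistinguishable ways measure the same thing and should be collapsed;
* the nonparanormal (shrunken empirical-CDF) transform, which maps each
  ordinal column to Gaussian scores through its mid-ranks so that a Gaussian
  graphical model is a sensible description of the transformed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import kurtosis, norm, rankdata, skew

from .datasets import OrdinalPanelDataset


@dataclass
class GaussianScores:
    """Continuous scores produced by the nonparanormal transform.

    Columns are centred (mean 0 to 1e-8) with unit variance and are strictly
    monotone in the source ranks.
    """

    scores: np.ndarray
    item_labels: list[str]
    source_wave: str = "T1"
    communities: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def p(self) -> int:
        return self.scores.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=self.item_labels)


def compute_descriptives(data: OrdinalPanelDataset) -> pd.DataFrame:
    """Per-item mean, SD, skewness, excess kurtosis and item-rest correlation.

    SD uses the n-1 denominator; skewness and kurtosis are plain moment-based
    (kurtosis on the excess convention, 0 for a normal distribution).  The
    item-rest correlation is the Pearson correlation of each item with the
    sum of the *other* items of its own instrument.

    Raises
    ------
    ValueError
        If any instrument contains a single item (item-rest undefined).
    """
    X = data.responses.astype(float)
    comms = np.array(data.communities)
    rows = []
    for j, label in enumerate(data.item_labels):
        col = X[:, j]
        own = np.flatnonzero((comms == comms[j]))
        rest = [k for k in own if k != j]
        if not rest:
            raise ValueError(
                f"instrument {comms[j]!r} has a single item; "
                "item-rest correlation undefined"
            )
        rest_sum = X[:, rest].sum(axis=1)
        rows.append(
            {
                "item": label,
                "community": comms[j],
                "mean": col.mean(),
                "sd": col.std(ddof=1),
                "skewness": skew(col, bias=True),
                "kurtosis": kurtosis(col, fisher=True, bias=True),
                "item_rest_corr": np.corrcoef(col, rest_sum)[0, 1],
            }
        )
    return pd.DataFrame(rows).set_index("item")


def steiger_z(r_ik: float, r_jk: float, r_ij: float, n: int) -> tuple[float, float]:
    """Steiger's test for two dependent correlations sharing one variable.

    Compares ``corr(i, k)`` with ``corr(j, k)`` (common index ``k``) given
    ``corr(i, j)``, using the back-transformed average correlation in the
    covariance term.  Returns ``(z, two-sided p)``.
    """
    if n < 4:
        raise ValueError("dependent-correlation z test needs n >= 4")
    z1 = np.arctanh(np.clip(r_ik, -0.999999, 0.999999))
    z2 = np.arctanh(np.clip(r_jk, -0.999999, 0.999999))
    rbar = np.tanh((z1 + z2) / 2.0)
    num = r_ij * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_ij**2)
    c = num / (1 - rbar**2) ** 2
    denom = 2.0 - 2.0 * c
    if denom <= 0:
        # degenerate geometry (e.g. duplicated items with r_ij = 1); the two
        # correlations are then constrained equal and the test is vacuous
        if abs(z1 - z2) < 1e-12:
            return 0.0, 1.0
        denom = 1e-12
    z = (z1 - z2) * np.sqrt((n - 3) / denom)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def goldbricker(
    data: OrdinalPanelDataset,
    alpha: float = 0.01,
    prop_threshold: float = 0.25,
    cor_min: float = 0.50,
) -> pd.DataFrame:
    """Screen item pairs for redundancy (Goldbricker analysis).

    For every pair ``(i, j)`` with ``|r_ij| >= cor_min``, each remaining item
    ``k`` yields a Steiger dependent-correlation test of ``r_ik`` vs
    ``r_jk``.  The pair is flagged redundant when the proportion of
    significant differences (at ``alpha``) falls below ``prop_threshold`` —
    i.e. the two items relate to the rest of the network interchangeably.

    Returns a table with one row per screened pair: zero-order correlation,
    proportion of significantly different correlations, and the flag.
    """
    if data.n < 30:
        raise ValueError("Goldbricker needs n >= 30")
    X = data.responses.astype(float)
    R = np.corrcoef(X, rowvar=False)
    p = data.p
    rows = []
    for i, j in combinations(range(p), 2):
        if abs(R[i, j]) < cor_min:
            continue
        n_sig = 0
        others = [k for k in range(p) if k not in (i, j)]
        for k in others:
            _, pval = steiger_z(R[i, k], R[j, k], R[i, j], data.n)
            n_sig += pval < alpha
        prop = n_sig / len(others) if others else 0.0
        rows.append(
            {
                "item_a": data.item_labels[i],
                "item_b": data.item_labels[j],
                "zero_order_r": R[i, j],
                "prop_significant": prop,
                "redundant": prop < prop_threshold,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=["item_a", "item_b", "zero_order_r", "prop_significant", "redundant"],
    )
    report.attrs["params"] = {
        "alpha": alpha,
        "prop_threshold": prop_threshold,
        "cor_min": cor_min,
        "note": "alpha/prop_threshold are conventional defaults",
    }
    return report


def npn_scores(X: np.ndarray) -> np.ndarray:
    """Shrunken-ECDF Gaussianization of each column of ``X``.

    Mid-ranks ``r`` map to ``Phi^{-1}(r / (n + 1))``, Winsorized at
    ``delta_n = 1 / (4 n^{1/4} sqrt(pi log n))``, then each column is centred
    and scaled to unit (ddof=0) variance.  Strictly monotone in the ranks.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    flat = np.ptp(X, axis=0) == 0
    if np.any(flat):
        raise ValueError(f"zero-variance column(s): {np.flatnonzero(flat)}")
    delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
    ranks = rankdata(X, method="average", axis=0)  # mid-ranks for ties
    u = np.clip(ranks / (n + 1.0), delta, 1.0 - delta)
    z = ndtri(u)
    z = z - z.mean(axis=0)
    return z / z.std(axis=0, ddof=0)


def nonparanormal_transform(data: OrdinalPanelDataset) -> GaussianScores:
    """Apply the nonparanormal transform to every item of a wave."""
    return GaussianScores(
        scores=npn_scores(data.responses),
        item_labels=list(data.item_labels),
        source_wave=data.wave_id,
        communities=dict(data.community_labels),
    )
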