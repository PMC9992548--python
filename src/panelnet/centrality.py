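"""Expected influence, bridge expected influence and node predictability.

Expected influence keeps edge signs (unlike strength): the one-step value of
a node is the signed sum of its edge weights, and the two-step value adds the
edge-weighted one-step values of its neighbours.  Bridge expected influence
restricts the same sums to edges crossing community boundaries, quantifying
how much a symptom transmits activation *between* disorders.  Predictability
is the variance of a node explained by its network neighbours.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .communities import CommunityPartition
from .estimation import WeightedNetwork
from .preprocessing import GaussianScores


def expected_influence(net: WeightedNetwork, steps: int = 1) -> pd.Series:
    """One- or two-step expected influence per node.

    ``EI1(i) = sum_j w_ij``;  ``EI2(i) = EI1(i) + sum_j w_ij * EI1(j)``.
    """
    if steps not in (1, 2):
        raise ValueError("steps must be 1 or 2")
    W = net.weights
    ei1 = W.sum(axis=1)
    values = ei1 if steps == 1 else ei1 + W @ ei1
    return pd.Series(values, index=net.node_labels, name=f"EI{steps}")


def _community_vector(net: WeightedNetwork, partition) -> np.ndarray:
    if isinstance(partition, CommunityPartition):
        mapping = partition.membership
    else:
        mapping = dict(partition)
    missing = [v for v in net.node_labels if v not in mapping]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing}")
    return np.asarray([mapping[v] for v in net.node_labels], dtype=object)


def bridge_expected_influence(
    net: WeightedNetwork,
    partition: CommunityPartition | dict,
    steps: int = 1,
) -> pd.Series:
    """Bridge expected influence: EI restricted to cross-community edges."""
    if steps not in (1, 2):
        raise ValueError("steps must be 1 or 2")
    comm = _community_vector(net, partition)
    cross = comm[:, None] != comm[None, :]
    Wb = np.where(cross, net.weights, 0.0)
    bei1 = Wb.sum(axis=1)
    values = bei1 if steps == 1 else bei1 + Wb @ bei1
    return pd.Series(values, index=net.node_labels, name=f"BEI{steps}")


def predictability(scores: GaussianScores, net: WeightedNetwork) -> pd.Series:
    """Per-node R^2 of the OLS regression on its nonzero-edge neighbours.

    Nodes without neighbours get 0.  Rank-deficient neighbour blocks are
    handled by the minimum-norm solution with a warning (collinear columns
    contribute nothing extra to the fit).
    """
    if list(scores.item_labels) != list(net.node_labels):
        raise ValueError("scores and network have different node labels")
    X = scores.scores
    W = net.weights
    out = np.zeros(net.p)
    for i in range(net.p):
        nbrs = np.flatnonzero(W[i] != 0)
        if nbrs.size == 0:
            continue
        y = X[:, i]
        Z = np.column_stack([np.ones(X.shape[0]), X[:, nbrs]])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            warnings.warn(
                f"collinear neighbours for node {net.node_labels[i]}; "
                "using minimum-norm fit",
                stacklevel=2,
            )
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        tss = np.sum((y - y.mean()) ** 2)
        out[i] = 1.0 - np.sum(resid**2) / tss if tss > 0 else 0.0
    return pd.Series(out, index=net.node_labels, name="predictability")


def centrality_table(
    net: WeightedNetwork,
    partition: CommunityPartition | dict,
    scores: GaussianScores | None = None,
) -> pd.DataFrame:
    """EI1/EI2/BEI1/BEI2 (raw and z-scored) plus predictability per node."""
    table = pd.DataFrame(
        {
            "EI1": expected_influence(net, 1),
            "EI2": expected_influence(net, 2),
            "BEI1": bridge_expected_influence(net, partition, 1),
            "BEI2": bridge_expected_influence(net, partition, 2),
        }
    )
    for col in ["EI1", "EI2", "BEI1", "BEI2"]:
        sd = table[col].std(ddof=1)
        table[f"{col}_z"] = (
            (table[col] - table[col].mean()) / sd if sd > 0 else 0.0
        )
    if scores is not None:
        table["predictability"] = predictability(scores, net)
    comm = _community_vector(net, partition)
    table["community"] = comm
    return table
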