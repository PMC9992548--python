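"""Permutation-based comparison of two networks and similarity summaries.

The network comparison test (NCT) asks whether two independently sampled
groups share one network: rows are pooled, group labels permuted, and both
networks re-estimated per permutation with the full estimation pipeline.
Test statistics are the maximum absolute edge difference M (structure) and
the absolute global-strength difference S; per-edge and per-node expected
influence differences are tested the same way with Holm correction.

Similarity is summarized by correlating the vectorized adjacency matrices
and the centrality vectors of the two networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import expected_influence
from .datasets import OrdinalPanelDataset
from .estimation import (
    EstimatorConfig,
    WeightedNetwork,
    estimate_network,
    estimate_pcor,
)


@dataclass
class NCTResult:
    """Outcome of the permutation network comparison test."""

    observed_M: float
    observed_S: float
    p_M: float
    p_S: float
    edge_table: pd.DataFrame  # per-edge observed diff, raw and Holm p
    centrality_table: pd.DataFrame  # per-node EI1 diff, raw and Holm p
    n_permutations: int
    seed: int
    network_a: WeightedNetwork | None = None
    network_b: WeightedNetwork | None = None

    def to_json_payload(self) -> dict:
        return {
            "observed_M": self.observed_M,
            "observed_S": self.observed_S,
            "p_M": self.p_M,
            "p_S": self.p_S,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = (m - rank) * p[idx]
        running = max(running, min(val, 1.0))
        adj[idx] = running
    return adj


def _perm_pvalue(perm_stats: np.ndarray, observed: float) -> float:
    """Monte-Carlo p with the +1 convention (never exactly 0)."""
    return float((1 + np.sum(perm_stats >= observed)) / (1 + perm_stats.size))


def network_structure_test(
    data_a: OrdinalPanelDataset,
    data_b: OrdinalPanelDataset,
    n_perm: int = 1000,
    seed: int = 0,
    config: EstimatorConfig | None = None,
    keep_networks: bool = True,
) -> NCTResult:
    """Permutation test of network equality between two groups.

    Both groups must share the item set.  Per permutation the pooled rows are
    reassigned to two groups of the original sizes and both networks
    re-estimated with ``config``; p-values use the +1 convention.  Per-edge
    p-values are Holm-corrected across edges, per-node expected-influence
    p-values across nodes.
    """
    if data_a.item_labels != data_b.item_labels:
        raise ValueError("groups have different item sets")
    cfg = config or EstimatorConfig()

    def _estimate(responses: np.ndarray, est_seed: int) -> WeightedNetwork:
        ds = OrdinalPanelDataset(
            responses=responses,
            item_labels=list(data_a.item_labels),
            community_labels=dict(data_a.community_labels),
            wave_id="perm",
            reverse_coded=dict(data_a.reverse_coded),
            n_categories=data_a.n_categories,
        )
        local = EstimatorConfig(**{**cfg.__dict__, "seed": est_seed})
        return estimate_network(ds, local)

    net_a = _estimate(data_a.responses, cfg.seed)
    net_b = _estimate(data_b.responses, cfg.seed)

    diff = net_a.weights - net_b.weights
    iu = np.triu_indices(net_a.p, 1)
    obs_edge = np.abs(diff[iu])
    observed_M = float(obs_edge.max())
    observed_S = abs(net_a.global_strength() - net_b.global_strength())
    obs_ei = np.abs(
        expected_influence(net_a, 1).to_numpy()
        - expected_influence(net_b, 1).to_numpy()
    )

    pooled = np.vstack([data_a.responses, data_b.responses])
    n_a = data_a.n
    rng = np.random.default_rng(seed)
    perm_M = np.empty(n_perm)
    perm_S = np.empty(n_perm)
    perm_edge = np.empty((n_perm, obs_edge.size))
    perm_ei = np.empty((n_perm, net_a.p))
    for b in range(n_perm):
        order = rng.permutation(pooled.shape[0])
        pa, _ = estimate_pcor(pooled[order[:n_a]], cfg)
        pb, _ = estimate_pcor(pooled[order[n_a:]], cfg)
        d = pa - pb
        perm_edge[b] = np.abs(d[iu])
        perm_M[b] = perm_edge[b].max()
        perm_S[b] = abs(np.abs(pa[iu]).sum() - np.abs(pb[iu]).sum())
        perm_ei[b] = np.abs(pa.sum(axis=1) - pb.sum(axis=1))

    edge_p_raw = np.array(
        [_perm_pvalue(perm_edge[:, e], obs_edge[e]) for e in range(obs_edge.size)]
    )
    ei_p_raw = np.array(
        [_perm_pvalue(perm_ei[:, i], obs_ei[i]) for i in range(net_a.p)]
    )
    edge_table = pd.DataFrame(
        {
            "node_a": [data_a.item_labels[i] for i in iu[0]],
            "node_b": [data_a.item_labels[j] for j in iu[1]],
            "observed_diff": diff[iu],
            "p_raw": edge_p_raw,
            "p_holm": holm_adjust(edge_p_raw),
        }
    )
    centrality_table = pd.DataFrame(
        {
            "node": data_a.item_labels,
            "observed_diff": obs_ei,
            "p_raw": ei_p_raw,
            "p_holm": holm_adjust(ei_p_raw),
        }
    )
    return NCTResult(
        observed_M=observed_M,
        observed_S=float(observed_S),
        p_M=_perm_pvalue(perm_M, observed_M),
        p_S=_perm_pvalue(perm_S, observed_S),
        edge_table=edge_table,
        centrality_table=centrality_table,
        n_permutations=n_perm,
        seed=seed,
        network_a=net_a if keep_networks else None,
        network_b=net_b if keep_networks else None,
    )


@dataclass
class SimilarityReport:
    """Correlations between two networks' adjacencies and centralities."""

    adjacency: pd.DataFrame  # rows: pearson/spearman; cols: r, p
    centrality: pd.DataFrame  # per centrality index: r, p

    def to_json_payload(self) -> dict:
        return {
            "adjacency": self.adjacency.to_dict(orient="index"),
            "centrality": self.centrality.to_dict(orient="index"),
        }


def _safe_corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def adjacency_correlation(
    net_a: WeightedNetwork, net_b: WeightedNetwork
) -> SimilarityReport:
    """Correlate upper-triangle weights and centrality vectors of two nets.

    Constant vectors make the correlation undefined; those entries are
    reported as NaN rather than raising.
    """
    if net_a.node_labels != net_b.node_labels:
        raise ValueError("networks have different node labels")
    xa, xb = net_a.upper_triangle(), net_b.upper_triangle()
    adjacency = pd.DataFrame(
        [
            dict(zip(("r", "p"), _safe_corr(xa, xb, "pearson"))),
            dict(zip(("r", "p"), _safe_corr(xa, xb, "spearman"))),
        ],
        index=["pearson", "spearman"],
    )
    rows = {}
    for steps in (1, 2):
        ca = expected_influence(net_a, steps).to_numpy()
        cb = expected_influence(net_b, steps).to_numpy()
        rows[f"EI{steps}"] = dict(zip(("r", "p"), _safe_corr(ca, cb, "pearson")))
    centrality = pd.DataFrame.from_dict(rows, orient="index")
    return SimilarityReport(adjacency=adjacency, centrality=centrality)
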