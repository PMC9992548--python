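"""Community structure: spinglass partitions and weighted clique percolation.

Two complementary views of community structure are used on symptom networks:

* a *partition* from the spinglass algorithm — simulated annealing of a
  signed Potts Hamiltonian in which positive within-community weight is
  rewarded against a configuration null and negative within-community weight
  penalized; restarted many times, keeping the minimum-Hamiltonian
  configuration;
* *overlapping* communities from the weighted clique percolation method
  (CFinder): a k-clique is retained when the geometric mean of its absolute
  edge weights (its "intensity") reaches a threshold I; retained cliques
  sharing k-1 nodes chain into communities, and nodes belonging to more than
  one community are the "percolated" bridge symptoms.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field
from itertools import combinations

import igraph as ig
import numpy as np

from .estimation import WeightedNetwork


@dataclass
class CommunityPartition:
    """Hard partition of the nodes with the (signed) Hamiltonian achieved."""

    membership: dict[str, int]
    hamiltonian: float
    n_runs: int
    seed: int

    def labels_for(self, node_labels: list[str]) -> np.ndarray:
        return np.array([self.membership[v] for v in node_labels])

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def as_community_map(self) -> dict[str, str]:
        return {v: f"community{c}" for v, c in self.membership.items()}


@dataclass
class OverlapCommunities:
    """Clique-percolation communities (node sets, possibly overlapping)."""

    communities: list[list[str]]
    membership_counts: dict[str, int]
    k: int
    intensity_threshold: float
    cliques: list[tuple[tuple[str, ...], float]] = field(default_factory=list)

    @property
    def percolated_nodes(self) -> list[str]:
        """Nodes in at least two communities (overlapping symptoms)."""
        return sorted(v for v, c in self.membership_counts.items() if c >= 2)

    def to_json_payload(self) -> dict:
        return {
            "k": self.k,
            "intensity_threshold": self.intensity_threshold,
            "communities": self.communities,
            "membership_counts": self.membership_counts,
            "percolated_nodes": self.percolated_nodes,
        }


def signed_hamiltonian(
    weights: np.ndarray,
    membership: np.ndarray,
    gamma: float = 1.0,
    gamma_minus: float = 1.0,
) -> float:
    """Signed Potts Hamiltonian with configuration null models.

    ``H = -sum_in (w+ - gamma * s+_i s+_j / 2m+) + sum_in (|w-| -
    gamma_minus * s-_i s-_j / 2m-)`` over within-community pairs, where the
    positive and negative layers each get their own strength-product null.
    Lower is better.
    """
    W = np.asarray(weights, dtype=float)
    membership = np.asarray(membership)
    same = membership[:, None] == membership[None, :]
    np.fill_diagonal(same, False)

    H = 0.0
    for sign in (1, -1):
        layer = np.where(np.sign(W) == sign, np.abs(W), 0.0)
        two_m = layer.sum()  # = 2m for a symmetric matrix
        if two_m == 0:
            continue
        strength = layer.sum(axis=1)
        null = np.outer(strength, strength) / two_m
        g = gamma if sign == 1 else gamma_minus
        inner = (layer[same].sum() - g * null[same].sum()) / 2.0
        H += -inner if sign == 1 else inner
    return float(H)


def _spinglass_component(
    sub_w: np.ndarray, gamma: float, rng_seed: int
) -> np.ndarray:
    """One igraph spinglass run on a connected weighted (signed) subnetwork."""
    p = sub_w.shape[0]
    iu = np.triu_indices(p, 1)
    mask = sub_w[iu] != 0
    edges = list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
    weights = sub_w[iu][mask].tolist()
    g = ig.Graph(n=p, edges=edges)
    has_negative = any(w < 0 for w in weights)
    _pyrandom.seed(rng_seed)  # python-igraph draws from the stdlib RNG
    clustering = g.community_spinglass(
        weights=weights,
        spins=min(p, 25),
        start_temp=1.0,
        stop_temp=0.01,
        cool_fact=0.99,
        gamma=gamma,
        implementation="negative" if has_negative else "original",
    )
    return np.asarray(clustering.membership)


def _canonical(membership: np.ndarray) -> tuple[int, ...]:
    """Relabel communities by order of first appearance."""
    seen: dict[int, int] = {}
    out = []
    for c in membership:
        if c not in seen:
            seen[c] = len(seen)
        out.append(seen[c])
    return tuple(out)


def spinglass_partition(
    net: WeightedNetwork,
    n_spins: int = 500,
    gamma: float = 1.0,
    seed: int = 0,
) -> CommunityPartition:
    """Minimum-Hamiltonian spinglass partition over ``n_spins`` restarts.

    The underlying annealer only handles connected graphs, so it runs per
    connected component of the nonzero-edge graph (isolated nodes become
    singleton communities); the Hamiltonian is evaluated on the full
    network.  Ties across restarts break toward the lexicographically
    smallest canonical labeling, making the result deterministic given
    ``seed``.
    """
    W = net.weights
    p = net.p
    if not np.any(W[np.triu_indices(p, 1)] != 0):
        raise ValueError("spinglass needs at least one nonzero edge")

    adj = (W != 0).astype(int)
    g_full = ig.Graph.Adjacency(adj.tolist(), mode="undirected")
    components = list(g_full.connected_components())

    best: tuple[float, tuple[int, ...]] | None = None
    for run in range(n_spins):
        membership = np.zeros(p, dtype=int)
        next_label = 0
        for comp in components:
            comp = list(comp)
            if len(comp) == 1:
                membership[comp[0]] = next_label
                next_label += 1
                continue
            if len(comp) == 2:
                # the annealer loops forever on 2-node graphs; the optimum
                # is immediate (merge a positive dyad, split a negative one)
                a, b = comp
                together = W[a, b] > 0
                membership[a] = next_label
                membership[b] = next_label if together else next_label + 1
                next_label += 1 if together else 2
                continue
            sub_w = W[np.ix_(comp, comp)]
            sub_m = _spinglass_component(
                sub_w, gamma, rng_seed=(seed * 100003 + run * 131 + comp[0])
            )
            for node, c in zip(comp, sub_m):
                membership[node] = next_label + int(c)
            next_label += int(sub_m.max()) + 1
        canon = _canonical(membership)
        H = signed_hamiltonian(W, np.asarray(canon), gamma=gamma)
        cand = (H, canon)
        if best is None or cand < best:
            best = cand

    H, canon = best
    return CommunityPartition(
        membership={net.node_labels[i]: canon[i] for i in range(p)},
        hamiltonian=H,
        n_runs=n_spins,
        seed=seed,
    )


def clique_intensity(net: WeightedNetwork, nodes) -> float:
    """Geometric mean of absolute edge weights over a complete subgraph.

    Raises ``ValueError`` naming the first missing pair if ``nodes`` do not
    form a clique in the nonzero-edge graph.
    """
    idx = {v: i for i, v in enumerate(net.node_labels)}
    members = [idx[v] for v in nodes]
    logs = []
    for a, b in combinations(range(len(members)), 2):
        w = net.weights[members[a], members[b]]
        if w == 0:
            raise ValueError(
                f"nodes do not form a clique: missing edge "
                f"({list(nodes)[a]}, {list(nodes)[b]})"
            )
        logs.append(np.log(abs(w)))
    return float(np.exp(np.mean(logs)))


def clique_percolation(
    net: WeightedNetwork, k: int = 4, intensity: float = 0.08
) -> OverlapCommunities:
    """Weighted clique percolation (CFinder) communities.

    Enumerates all k-cliques of the nonzero-edge graph, keeps those with
    intensity >= ``intensity``, links cliques sharing k-1 nodes, and returns
    the node unions of the resulting clique-graph components.
    """
    if k < 3:
        raise ValueError("clique percolation needs k >= 3")
    import networkx as nx

    G = net.to_graph()
    kcliques: list[frozenset] = []
    for clique in nx.enumerate_all_cliques(G):
        if len(clique) > k:
            break
        if len(clique) == k:
            kcliques.append(frozenset(clique))
    retained = [
        c for c in kcliques if clique_intensity(net, sorted(c)) >= intensity
    ]

    # union-find over cliques sharing k-1 nodes
    parent = list(range(len(retained)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(range(len(retained)), 2):
        if len(retained[a] & retained[b]) == k - 1:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

    groups: dict[int, set] = {}
    for i, cl in enumerate(retained):
        groups.setdefault(find(i), set()).update(cl)
    communities = sorted(
        (sorted(nodes) for nodes in groups.values()), key=lambda c: (len(c), c)
    )
    counts = {v: 0 for v in net.node_labels}
    for comm in communities:
        for v in comm:
            counts[v] += 1
    return OverlapCommunities(
        communities=[list(c) for c in communities],
        membership_counts=counts,
        k=k,
        intensity_threshold=intensity,
        cliques=[
            (tuple(sorted(c)), clique_intensity(net, sorted(c))) for c in retained
        ],
    )
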