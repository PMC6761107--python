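"""Random-walk (Walktrap) community detection for coexpression networks.

Implements the Pons-Latapy agglomerative algorithm from first principles:
short lazy random walks of length ``t`` (each vertex carries a self-loop of
weight equal to its strength, so the walk is aperiodic and invariant to
weight rescaling) define per-node probability vectors ``P^t_i``; the
distance between communities C1, C2 is

    r^2(C1, C2) = sum_k (P^t_{C1 k} - P^t_{C2 k})^2 / d(k)

with ``P^t_C`` the average walk vector over the community and ``d(k)`` the
(weighted) node degree.  Adjacent communities are merged greedily by the
smallest Ward-style increase

    delta_sigma(C1, C2) = (1/n) * |C1||C2| / (|C1| + |C2|) * r^2(C1, C2)

and the partition with maximal modularity along the merge dendrogram is
returned.  Connected components are processed independently; ties are broken
by the lexicographically smallest community-id pair so repeated runs are
identical.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import ValidationError
from . import stats as _stats

__all__ = ["ClusterAssignment", "walktrap_clusters", "cluster_size_summary", "compare_size_distributions"]


@dataclass(frozen=True)
class ClusterAssignment:
    """A hard partition of network nodes into communities."""

    membership: dict[str, int]
    sizes: list[int]
    modularity: float
    merges: tuple[tuple[int, int, int, float], ...]  # (cid_a, cid_b, new_cid, delta_sigma)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def members(self, cluster_id: int) -> list[str]:
        return sorted(n for n, c in self.membership.items() if c == cluster_id)


def _component_dendrogram(
    nodes: list[str], adj: np.ndarray, steps: int
) -> tuple[list[tuple[int, int, int, float]], np.ndarray]:
    """Run the agglomeration on one connected component.

    Returns the merge list (local community ids; leaves are 0..n-1) and the
    strength vector — enough to replay modularity along the dendrogram.
    """
    n = len(nodes)
    strength = adj.sum(axis=1)
    # lazy walk: a self-loop of weight d(i) per vertex (P' = (P+I)/2) makes
    # the walk aperiodic and scale-invariant, following the reference
    # formulation; community distances then use the looped degrees
    lazy = adj + np.diag(strength)
    d = lazy.sum(axis=1)
    P = lazy / d[:, None]
    Pt = np.linalg.matrix_power(P, steps)
    inv_d = 1.0 / d

    # community state, keyed by integer id (leaves 0..n-1, merged n, n+1, ...)
    vec: dict[int, np.ndarray] = {i: Pt[i] for i in range(n)}
    size: dict[int, int] = {i: 1 for i in range(n)}
    # inter-community total edge weight (for modularity replay and adjacency)
    nbr: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    ii, jj = np.nonzero(np.triu(adj, k=1))
    for a, b in zip(ii.tolist(), jj.tolist()):
        nbr[a][b] = adj[a, b]
        nbr[b][a] = adj[a, b]

    def delta(c1: int, c2: int) -> float:
        r2 = float(np.sum((vec[c1] - vec[c2]) ** 2 * inv_d))
        return size[c1] * size[c2] / (size[c1] + size[c2]) * r2 / n

    heap: list[tuple[float, int, int]] = []
    for a in range(n):
        for b in nbr[a]:
            if a < b:
                heapq.heappush(heap, (delta(a, b), a, b))

    alive = set(range(n))
    merges: list[tuple[int, int, int, float]] = []
    next_id = n
    while len(alive) > 1 and heap:
        dsig, c1, c2 = heapq.heappop(heap)
        if c1 not in alive or c2 not in alive or c2 not in nbr[c1]:
            continue
        new = next_id
        next_id += 1
        vec[new] = (size[c1] * vec[c1] + size[c2] * vec[c2]) / (size[c1] + size[c2])
        size[new] = size[c1] + size[c2]
        combined: dict[int, float] = {}
        for c in (c1, c2):
            for other, w in nbr[c].items():
                if other in (c1, c2):
                    continue
                combined[other] = combined.get(other, 0.0) + w
        nbr[new] = combined
        for other, w in combined.items():
            nbr[other].pop(c1, None)
            nbr[other].pop(c2, None)
            nbr[other][new] = w
        merges.append((c1, c2, new, dsig))
        alive.discard(c1)
        alive.discard(c2)
        alive.add(new)
        for c in (c1, c2):
            vec.pop(c, None)
            nbr.pop(c, None)
        for other in sorted(combined):
            a, b = min(new, other), max(new, other)
            heapq.heappush(heap, (delta(a, b), a, b))
    return merges, strength


def _best_cut(
    merges: list[tuple[int, int, int, float]],
    n_leaves: int,
    inter_weight: list[float],
    strengths: np.ndarray,
    two_m: float,
) -> tuple[list[set[int]], float]:
    """Replay merges, tracking modularity; return the best partition of leaves."""
    members: dict[int, set[int]] = {i: {i} for i in range(n_leaves)}
    tot: dict[int, float] = {i: float(strengths[i]) for i in range(n_leaves)}
    q = -float(np.sum((strengths / two_m) ** 2))  # singleton partition (no intra edges)
    best_q, best_level = q, 0
    qs = [q]
    for level, (c1, c2, new, _), e12 in zip(range(1, len(merges) + 1), merges, inter_weight):
        q += 2.0 * e12 / two_m - 2.0 * tot[c1] * tot[c2] / two_m**2
        members[new] = members.pop(c1) | members.pop(c2)
        tot[new] = tot.pop(c1) + tot.pop(c2)
        qs.append(q)
        if q > best_q + 1e-12:
            best_q, best_level = q, level
    # replay to the chosen level
    members = {i: {i} for i in range(n_leaves)}
    for c1, c2, new, _ in merges[:best_level]:
        members[new] = members.pop(c1) | members.pop(c2)
    return list(members.values()), best_q


def walktrap_clusters(net: nx.Graph, steps: int = 4, use_weights: bool = True) -> ClusterAssignment:
    """Cluster a network by the Walktrap random-walk agglomerative method.

    Parameters
    ----------
    net:
        Undirected network; edge weights may be signed correlations.
    steps:
        Random-walk length ``t`` (default 4, the conventional choice).
    use_weights:
        Use |weight| as walk transition weights; otherwise treat the
        network as unweighted.
    """
    if steps < 1:
        raise ValidationError(f"walk length must be >=1, got {steps}")
    if net.number_of_nodes() == 0:
        raise ValidationError("cannot cluster an empty network")

    # global modularity normalization over the whole graph
    def _w(u, v):
        return abs(net[u][v].get("weight", 1.0)) if use_weights else 1.0

    two_m = 2.0 * sum(_w(u, v) for u, v in net.edges())

    cluster_sets: list[tuple[str, set[str]]] = []  # (min node, member set), for stable ids
    modularity = 0.0
    merges_global: list[tuple[int, int, int, float]] = []

    for comp in nx.connected_components(net):
        nodes = sorted(comp)
        if len(nodes) == 1:
            cluster_sets.append((nodes[0], set(nodes)))
            continue
        idx = {v: k for k, v in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)))
        for u, v in net.subgraph(comp).edges():
            w = _w(u, v)
            adj[idx[u], idx[v]] = w
            adj[idx[v], idx[u]] = w
        merges, strengths = _component_dendrogram(nodes, adj, steps)
        # inter-community weight between the two merged communities at each step
        inter = _replay_inter_weights(len(nodes), adj, merges)
        parts, q = _best_cut(merges, len(nodes), inter, strengths, two_m)
        modularity += q
        for part in parts:
            names = {nodes[i] for i in part}
            cluster_sets.append((min(names), names))
        merges_global.extend(merges)

    cluster_sets.sort(key=lambda t: t[0])
    membership = {v: cid for cid, (_, names) in enumerate(cluster_sets) for v in sorted(names)}
    sizes = [len(names) for _, names in cluster_sets]
    return ClusterAssignment(membership, sizes, float(modularity), tuple(merges_global))


def _replay_inter_weights(
    n_leaves: int, adj: np.ndarray, merges: list[tuple[int, int, int, float]]
) -> list[float]:
    """Edge weight between the two communities joined at each merge step."""
    members: dict[int, np.ndarray] = {
        i: np.eye(1, n_leaves, i, dtype=bool)[0] for i in range(n_leaves)
    }
    out = []
    for c1, c2, new, _ in merges:
        m1, m2 = members.pop(c1), members.pop(c2)
        out.append(float(adj[np.ix_(m1, m2)].sum()))
        members[new] = m1 | m2
    return out


def cluster_size_summary(ca: ClusterAssignment, small_cutoff: int = 10) -> tuple[int, int, int, list[int]]:
    """Count clusters below/at-or-above the size cutoff.

    Returns ``(n_clusters, n_small, n_large, sizes)`` where small means
    size strictly below ``small_cutoff``.
    """
    sizes = list(ca.sizes)
    n_small = sum(1 for s in sizes if s < small_cutoff)
    return len(sizes), n_small, len(sizes) - n_small, sizes


def compare_size_distributions(a: list[int], b: list[int]) -> "_stats.MannWhitneyResult":
    """Two-sided Mann-Whitney comparison of two cluster-size distributions."""
    if not a or not b:
        raise ValidationError("size lists must be nonempty")
    return _stats.mann_whitney_u(a, b)
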