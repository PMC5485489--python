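"""Independent brute-force oracles for the topology metrics.

Everything here is written from the definitions using plain Python BFS and
exhaustive enumeration — deliberately sharing no code path with the package
or with networkx's centrality implementations.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations


def bfs_distances(adj: dict, source) -> dict:
    """Hop counts from source over an adjacency-set mapping."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def to_adj(edges, nodes=()) -> dict:
    adj: dict = {v: set() for v in nodes}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def enumerate_shortest_paths(adj: dict, s, t) -> list:
    """All shortest s→t paths by depth-limited DFS along decreasing
    distance-to-t."""
    dist_t = bfs_distances(adj, t)
    if s not in dist_t:
        return []
    paths = []

    def walk(u, path):
        if u == t:
            paths.append(path)
            return
        for w in adj[u]:
            if dist_t.get(w, -1) == dist_t[u] - 1:
                walk(w, path + [w])

    walk(s, [s])
    return paths


def brute_betweenness(adj: dict) -> dict:
    """Btwn(v) = Σ over unordered pairs {s,t} of σ_st(v)/σ_st, endpoints
    excluded, by explicit path enumeration."""
    nodes = sorted(adj, key=str)
    btwn = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = enumerate_shortest_paths(adj, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for p in paths:
            for v in p[1:-1]:
                btwn[v] += 1.0 / sigma
    return btwn


def brute_clustering(adj: dict) -> dict:
    """2 · (edges among neighbors) / (k(k−1)); zero when k < 2."""
    out = {}
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(sorted(nbrs, key=str), 2)
                    if b in adj[a])
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def brute_eccentricity(adj: dict) -> dict:
    """max_u d(v, u); requires a connected graph."""
    out = {}
    n = len(adj)
    for v in adj:
        dist = bfs_distances(adj, v)
        assert len(dist) == n, "eccentricity oracle needs a connected graph"
        out[v] = max(dist.values())
    return out


def brute_average_distance(adj: dict, diameter: int | None = None) -> dict:
    """Mean distance to the other n−1 nodes, unreachable pairs → diameter."""
    n = len(adj)
    if diameter is None:
        finite_ecc = []
        for comp_nodes in _components(adj):
            if len(comp_nodes) < 2:
                continue
            sub = {v: adj[v] & comp_nodes for v in comp_nodes}
            finite_ecc.extend(brute_eccentricity(sub).values())
        diameter = max(finite_ecc, default=0)
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        out[v] = (sum(dist.values()) + (n - len(dist)) * diameter) / (n - 1)
    return out


def _components(adj: dict) -> list:
    seen: set = set()
    comps = []
    for v in adj:
        if v in seen:
            continue
        comp = set(bfs_distances(adj, v))
        seen |= comp
        comps.append(comp)
    return comps


def brute_coreness(adj: dict) -> dict:
    """Coreness by checking k-core membership for every k via pruning."""

    def k_core_nodes(k: int) -> set:
        alive = {v: set(nbrs) for v, nbrs in adj.items()}
        changed = True
        while changed:
            changed = False
            for v in list(alive):
                if len(alive[v]) < k:
                    for w in alive[v]:
                        alive[w].discard(v)
                    del alive[v]
                    changed = True
        return set(alive)

    max_deg = max((len(nbrs) for nbrs in adj.values()), default=0)
    cores = {k: k_core_nodes(k) for k in range(max_deg + 2)}
    out = {}
    for v in adj:
        out[v] = max(k for k in cores if v in cores[k])
    return out


def brute_modularity(edges, partition: dict) -> float:
    """Direct double-sum of [A_ij − k_i k_j / 2m] δ(c_i, c_j) / 2m."""
    adj = to_adj(edges, partition.keys())
    nodes = sorted(partition, key=str)
    deg = {v: len(adj[v]) for v in nodes}
    two_m = sum(deg.values())
    q = 0.0
    for i in nodes:
        for j in nodes:
            if partition[i] != partition[j]:
                continue
            a_ij = 1.0 if j in adj[i] else 0.0
            q += a_ij - deg[i] * deg[j] / two_m
    return q / two_m
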