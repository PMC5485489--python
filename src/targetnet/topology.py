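"""Per-node topological indices of the interaction network.

Conventions (all for simple undirected graphs):

* betweenness  Btwn(v) = Σ_{s≠v≠t} σ_st(v)/σ_st over unordered pairs {s,t},
  endpoints excluded (Brandes accumulation; exactly equal to shortest-path
  enumeration);
* normalized betweenness  NB(v) = (Btwn(v) − min) / (max − min), all zero
  when the raw map is constant;
* eigenvector centrality: nonnegative leading eigenvector of the adjacency
  matrix with unit Euclidean norm, together with the leading eigenvalue λ;
* eccentricity  ε(v) = max_u d(v, u), diameter D_G = max_v ε(v);
* average distance  l(v) = (1/(n−1)) Σ_{u≠v} d(v, u), where an unreachable
  pair contributes D_G (the network-diameter substitution; on a connected
  graph this is the plain mean shortest distance);
* local clustering  2·e_N(v) / (k_v (k_v − 1)), defined as 0 for k_v < 2;
* coreness(v) = largest k such that v survives iterative pruning of nodes
  of degree < k (i.e. v is in the k-core but not the (k+1)-core).
"""

from __future__ import annotations

from collections import Counter
from typing import Hashable, Mapping, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network_io import LabeledProteome

__all__ = [
    "degree_map",
    "clustering_map",
    "betweenness_map",
    "normalize_betweenness",
    "eigenvector_centrality",
    "shortest_path_lengths",
    "eccentricity_map",
    "EccentricityResult",
    "average_distance_map",
    "coreness_map",
    "k_core_subgraph",
    "profile_table",
]


def degree_map(net: nx.Graph) -> dict:
    """Degree k_i of every node."""
    return dict(net.degree())


def clustering_map(net: nx.Graph) -> dict:
    """Local clustering coefficient; 0 for nodes of degree < 2."""
    return nx.clustering(net)


def betweenness_map(net: nx.Graph) -> dict:
    """Raw (unnormalized) betweenness over unordered pairs, endpoints
    excluded."""
    return nx.betweenness_centrality(net, normalized=False)


def normalize_betweenness(raw: Mapping[Hashable, float]) -> dict:
    """Min-max normalization of a betweenness map.

    A constant map (max == min) normalizes to all zeros.
    """
    if not raw:
        raise ValueError("cannot normalize an empty betweenness map")
    values = list(raw.values())
    lo, hi = min(values), max(values)
    if hi == lo:
        return {v: 0.0 for v in raw}
    span = hi - lo
    return {v: (b - lo) / span for v, b in raw.items()}


def eigenvector_centrality(
    net: nx.Graph, tolerance: float = 1e-10, max_iterations: int = 1000
) -> tuple[dict, float]:
    """Leading eigenvector of the adjacency matrix by power iteration.

    Iterates ``x ← (A + I) x`` from the all-ones vector with Euclidean
    renormalization; the identity shift makes the iteration matrix primitive
    on a connected graph (plain iteration on A oscillates on bipartite
    graphs), without changing the leading eigenvector.  Convergence is
    declared when successive iterates differ by less than *tolerance* in
    max-norm and the Rayleigh residual ``‖Ax − λx‖∞`` is below
    ``10 * tolerance``.

    Returns the nonnegative unit-norm score map and λ (Rayleigh quotient of
    A, i.e. the greatest adjacency eigenvalue).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net):
        raise ValueError("eigenvector centrality requires a connected network; "
                         "run on the largest connected component")
    nodes = list(net.nodes())
    a = nx.to_scipy_sparse_array(net, nodelist=nodes, dtype=float, format="csr")
    x = np.ones(len(nodes)) / np.sqrt(len(nodes))
    for _ in range(max_iterations):
        y = a @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:  # edgeless graph: A = 0, x is already the fixed point
            break
        y /= norm
        ax = a @ y
        lam = float(y @ ax)
        if np.max(np.abs(y - x)) < tolerance and np.max(
            np.abs(ax - lam * y)
        ) < 10 * tolerance:
            return dict(zip(nodes, y)), lam
        x = y
    if net.number_of_edges() == 0:
        return dict(zip(nodes, x)), 0.0
    raise RuntimeError(
        f"power iteration did not converge within {max_iterations} iterations"
    )


def shortest_path_lengths(net: nx.Graph, source: Hashable) -> dict:
    """BFS hop counts from *source*; unreachable nodes are absent."""
    if source not in net:
        raise KeyError(f"source {source!r} not in network")
    return dict(nx.single_source_shortest_path_length(net, source))


class EccentricityResult(NamedTuple):
    """Eccentricity map with its two summary values."""

    eccentricity: dict
    diameter: int
    mode: int


def eccentricity_map(net: nx.Graph) -> EccentricityResult:
    """ε(v) for every node, the diameter D_G = max ε, and the modal ε.

    Requires a connected network (run on the LCC).  The mode's ties are
    broken toward the smaller value.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net):
        raise ValueError(
            "eccentricity is undefined on a disconnected network; extract the "
            "largest connected component first"
        )
    ecc = nx.eccentricity(net)
    diameter = max(ecc.values())
    counts = Counter(ecc.values())
    top = max(counts.values())
    mode = min(k for k, c in counts.items() if c == top)
    return EccentricityResult(ecc, diameter, mode)


def _component_diameter(net: nx.Graph) -> int:
    """Max finite eccentricity over all components (the D_G fallback for a
    disconnected graph)."""
    best = 0
    for comp in nx.connected_components(net):
        if len(comp) < 2:
            continue
        sub = net.subgraph(comp)
        best = max(best, max(nx.eccentricity(sub).values()))
    return best


def average_distance_map(net: nx.Graph, diameter: int | None = None) -> dict:
    """Mean shortest distance l(v) from each node to the other n−1 nodes.

    Unreachable pairs contribute the network diameter D_G.  On a connected
    graph the substitution is inactive and l(v) is the ordinary mean
    distance.  For a disconnected graph D_G defaults to the maximum finite
    eccentricity over components unless supplied explicitly.  A single-node
    network has no defined l and maps to NaN.
    """
    n = net.number_of_nodes()
    out: dict = {}
    if n == 0:
        return out
    if n == 1:
        return {v: float("nan") for v in net.nodes()}
    if diameter is None:
        if nx.is_connected(net):
            diameter = 0  # never used
        else:
            diameter = _component_diameter(net)
    for v in net.nodes():
        dist = nx.single_source_shortest_path_length(net, v)
        total = sum(dist.values())  # d(v,v)=0 contributes nothing
        total += (n - len(dist)) * diameter  # unreachable → D_G
        out[v] = total / (n - 1)
    return out


def coreness_map(net: nx.Graph) -> dict:
    """Coreness by iterative pruning: largest k with v in the k-core."""
    if any(True for _ in nx.selfloop_edges(net)):
        raise ValueError("coreness requires a simple graph (self-loops found)")
    return nx.core_number(net)


def k_core_subgraph(net: nx.Graph, k: int) -> nx.Graph:
    """The k-core: maximal subgraph of minimum degree ≥ k."""
    return nx.k_core(net, k)


def profile_table(
    net: nx.Graph,
    labels: LabeledProteome | None = None,
    partition: Mapping[Hashable, int] | None = None,
    eigen_tolerance: float = 1e-10,
) -> pd.DataFrame:
    """Assemble the full per-node topology profile as a DataFrame.

    One row per node with columns: label, degree, betweenness, nb,
    eigenvector, clustering, eccentricity, avg_distance, coreness and
    (when a partition is given) community.  Requires a connected network.
    """
    nodes = sorted(net.nodes(), key=str)
    deg = degree_map(net)
    btwn = betweenness_map(net)
    nb = normalize_betweenness(btwn)
    eig, _lam = eigenvector_centrality(net, tolerance=eigen_tolerance)
    clust = clustering_map(net)
    ecc = eccentricity_map(net)
    avg = average_distance_map(net)
    core = coreness_map(net)
    df = pd.DataFrame(
        {
            "label": [labels.label_of(v) if labels else "" for v in nodes],
            "degree": [deg[v] for v in nodes],
            "betweenness": [btwn[v] for v in nodes],
            "nb": [nb[v] for v in nodes],
            "eigenvector": [eig[v] for v in nodes],
            "clustering": [clust[v] for v in nodes],
            "eccentricity": [ecc.eccentricity[v] for v in nodes],
            "avg_distance": [avg[v] for v in nodes],
            "coreness": [core[v] for v in nodes],
        },
        index=pd.Index(nodes, name="id"),
    )
    if partition is not None:
        df["community"] = [partition[v] for v in nodes]
    return df
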