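"""Synthetic labeled interactomes with planted structure.

The generator emulates, at desk scale, the statistical structure a real
drug-target interactome analysis rests on:

* a degree-corrected planted-partition network: community blocks with a
  tunable intra/inter edge-weight ratio, expected degrees drawn from a
  truncated power law (heavy-tailed degree distribution with a long tail);
* a small labeled target fraction (about 1% of nodes by default, matching
  the scale of curated target sets), with targets concentrated in a few
  designated communities at controlled enrichment levels and, crucially,
  with the target *degree distribution matched to non-targets* by
  stratified sampling within degree deciles — the central null finding
  (targets are not hubs) holds by construction;
* per-protein chemical-physical feature tables (39 columns by default)
  with class-conditional Gaussian structure: targets shifted by an effect
  size Δ on an informative subset, everything else pure noise; a small
  hidden-positive contingent inside PT1 models the not-yet-annotated true
  targets a predictor should recover.

Everything is deterministic for a fixed spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network_io import LabeledProteome

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_network",
    "plant_target_labels",
    "generate_feature_table",
    "generate_dataset",
    "tiny_fixture",
    "TinyFixture",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters of the generator.

    Defaults emulate the structure of a curated human interactome analysis
    scaled to 3,000 nodes: mean degree ≈ 11.6, power-law degree exponent
    2.5, ten communities with an 8:1 intra/inter edge-weight ratio, a 1.2%
    target fraction concentrated in three communities (together holding
    roughly two-thirds of the targets), 10.5% of pending proteins carrying
    a 39-column feature table, and an 8.5% hidden-positive rate inside PT1.
    """

    n_nodes: int = 3000
    n_communities: int = 10
    community_sizes: tuple | None = None  # default: equal split
    mean_degree: float = 11.6
    #: power-law exponent of the expected-degree distribution; ``None``
    #: switches off the degree correction (homogeneous planted partition).
    degree_exponent: float | None = 2.5
    intra_inter_ratio: float = 8.0
    target_fraction: float = 0.012
    n_targets: int | None = None  # overrides target_fraction when set
    #: community index (0-based) -> planted enrichment rd; unlisted
    #: communities share the remaining targets in proportion to size.
    relative_risk: Mapping[int, float] = field(
        default_factory=lambda: {0: 3.0, 1: 2.0, 2: 1.5}
    )
    coreness_levels: tuple | None = None  # restrict targets to these shells
    featured_fraction: float = 0.105  # PT1 share of non-targets
    n_features: int = 39
    n_informative: int = 8
    effect_size: float = 1.0
    noise_scale: float = 1.0
    hidden_target_fraction: float = 0.085  # planted positives inside PT1

    def sizes(self) -> tuple:
        if self.community_sizes is not None:
            sizes = tuple(self.community_sizes)
            if sum(sizes) != self.n_nodes:
                raise ValueError("community sizes must sum to n_nodes")
            return sizes
        base, extra = divmod(self.n_nodes, self.n_communities)
        return tuple(
            base + (1 if i < extra else 0) for i in range(self.n_communities)
        )

    def resolved_n_targets(self) -> int:
        n = (
            self.n_targets
            if self.n_targets is not None
            else int(round(self.target_fraction * self.n_nodes))
        )
        if n <= 0:
            raise ValueError("the spec must plant at least one target")
        if n >= self.n_nodes:
            raise ValueError("cannot plant targets on every node")
        return n


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset."""

    partition: dict = field(default_factory=dict)  # node -> community (0-based)
    target_ids: tuple = ()
    enriched_communities: tuple = ()  # (community, planted rd) pairs
    per_community_targets: dict = field(default_factory=dict)
    informative_features: tuple = ()
    hidden_positive_ids: tuple = ()  # PT1 proteins carrying the target signal
    augmented_edges: tuple = ()  # edges added to connect stray components


def _node_name(i: int) -> str:
    return f"P{i:05d}"


def _truncated_power_law(rng, n, exponent, xmin=1.0, xmax=None):
    """Inverse-CDF sample from p(x) ∝ x^-exponent on [xmin, xmax]."""
    if xmax is None:
        xmax = max(10.0 * xmin, n ** 0.5)
    a = 1.0 - exponent
    u = rng.random(n)
    lo, hi = xmin ** a, xmax ** a
    return (lo + u * (hi - lo)) ** (1.0 / a)


def generate_network(
    spec: SyntheticSpec, seed: int
) -> tuple[nx.Graph, SyntheticTruth]:
    """Degree-corrected planted-partition graph, guaranteed connected.

    Expected degrees follow a truncated power law; a pair (i, j) is joined
    with probability proportional to θ_i θ_j, boosted by the intra/inter
    ratio inside a block, globally scaled to the requested mean degree.
    If the raw draw is disconnected, each stray component is tied into the
    giant component by a single random edge (recorded in the truth).
    """
    sizes = spec.sizes()
    n = spec.n_nodes
    rng = np.random.default_rng(seed)
    comm = np.repeat(np.arange(len(sizes)), sizes)
    if spec.degree_exponent is None:
        theta = np.ones(n)
    else:
        theta = _truncated_power_law(rng, n, spec.degree_exponent)
    if theta.max() * spec.mean_degree / theta.mean() > n:
        raise ValueError("infeasible spec: an expected degree exceeds n")
    iu, ju = np.triu_indices(n, k=1)
    s = theta[iu] * theta[ju]
    s = s * np.where(comm[iu] == comm[ju], spec.intra_inter_ratio, 1.0)
    target_edges = n * spec.mean_degree / 2.0
    p = np.clip(s * (target_edges / s.sum()), 0.0, 1.0)
    keep = rng.random(p.size) < p
    g = nx.Graph()
    names = [_node_name(i) for i in range(n)]
    g.add_nodes_from(names)
    g.add_edges_from((names[a], names[b]) for a, b in zip(iu[keep], ju[keep]))
    augmented = []
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    if len(comps) > 1:
        giant = sorted(comps[0])
        for comp in comps[1:]:
            u = sorted(comp)[rng.integers(len(comp))]
            v = giant[rng.integers(len(giant))]
            g.add_edge(u, v)
            augmented.append((u, v))
    truth = SyntheticTruth(
        partition={names[i]: int(comm[i]) for i in range(n)},
        augmented_edges=tuple(augmented),
    )
    return g, truth


def _largest_remainder(real_counts: np.ndarray, total: int) -> np.ndarray:
    """Round nonnegative reals to integers preserving the exact total."""
    floors = np.floor(real_counts).astype(int)
    short = total - floors.sum()
    if short > 0:
        order = np.argsort(-(real_counts - floors), kind="stable")
        floors[order[:short]] += 1
    elif short < 0:  # defensive; cannot occur when Σ real == total
        order = np.argsort(real_counts - floors, kind="stable")
        floors[order[: -short]] -= 1
    return floors


def _decile_stratified_pick(rng, pool: list, degrees: Mapping, edges: np.ndarray,
                            count: int) -> list:
    """Pick *count* nodes from *pool* matching the global degree profile.

    Allocation across global degree-decile strata is proportional to the
    stratum occupancy of the pool itself (so the picked set mirrors the
    pool's degree mix, which in turn mirrors the network's); shortfalls in
    a stratum spill over to the remaining pool at random.
    """
    pool = sorted(pool)
    strata: dict[int, list] = {}
    for v in pool:
        b = int(np.searchsorted(edges, degrees[v], side="right")) - 1
        strata.setdefault(b, []).append(v)
    bins = sorted(strata)
    occup = np.array([len(strata[b]) for b in bins], dtype=float)
    alloc = _largest_remainder(occup * (count / occup.sum()), count)
    picked: list = []
    for b, k in zip(bins, alloc):
        k = min(int(k), len(strata[b]))
        if k > 0:
            picked.extend(rng.choice(strata[b], size=k, replace=False).tolist())
    remaining = count - len(picked)
    if remaining > 0:
        rest = sorted(set(pool) - set(picked))
        picked.extend(rng.choice(rest, size=remaining, replace=False).tolist())
    return picked


def plant_target_labels(
    net: nx.Graph,
    partition: Mapping[str, int],
    spec: SyntheticSpec,
    seed: int,
) -> tuple[LabeledProteome, SyntheticTruth]:
    """Plant target labels with controlled community enrichment.

    For each community c with a stated enrichment rd = ρ_c, the planted
    target count d_c solves  d_c / (n_c − d_c) = ρ_c · |D| / |PT|,  so the
    community's realized enrichment statistic equals ρ_c in expectation by
    construction; the remaining targets spread over unlisted communities
    in proportion to size (whose rd consequently sits slightly below 1 —
    the enrichment ratios of a partition cannot all exceed their weighted
    average of 1).  Within a community, targets are drawn by stratified
    sampling over global degree deciles, so the target degree distribution
    matches the non-target one.  When ``spec.coreness_levels`` is set the
    candidate pool is further restricted to those coreness shells.
    """
    n = net.number_of_nodes()
    n_targets = spec.resolved_n_targets()
    if n_targets > n:
        raise ValueError("more targets requested than nodes available")
    rng = np.random.default_rng(seed)
    nodes_by_comm: dict[int, list] = {}
    for v, c in partition.items():
        nodes_by_comm.setdefault(c, []).append(v)
    comms = sorted(nodes_by_comm)
    n_pending = n - n_targets
    odds = n_targets / n_pending
    pinned = {c: r for c, r in spec.relative_risk.items() if c in nodes_by_comm}
    real_counts = {}
    for c, rho in pinned.items():
        if rho < 0:
            raise ValueError("relative risk must be nonnegative")
        nc = len(nodes_by_comm[c])
        real_counts[c] = nc * rho * odds / (1.0 + rho * odds)
    pinned_total = sum(real_counts.values())
    if pinned_total > n_targets:
        raise ValueError(
            "unsatisfiable planting: enriched communities alone require "
            f"{pinned_total:.1f} targets but only {n_targets} are planted; "
            "lower the relative risks or raise the target count"
        )
    rest_comms = [c for c in comms if c not in pinned]
    rest_sizes = np.array([len(nodes_by_comm[c]) for c in rest_comms], dtype=float)
    remainder = n_targets - pinned_total
    if rest_comms:
        for c, r in zip(rest_comms, remainder * rest_sizes / rest_sizes.sum()):
            real_counts[c] = r
    elif remainder > 0.5:
        raise ValueError("unsatisfiable planting: no community left to absorb "
                         "the remaining targets")
    order = sorted(real_counts)
    counts = _largest_remainder(
        np.array([real_counts[c] for c in order]), n_targets
    )
    degrees = dict(net.degree())
    deg_values = np.array(list(degrees.values()), dtype=float)
    edges = np.quantile(deg_values, np.linspace(0, 1, 11))
    edges[0] -= 1e-9  # include the minimum in the first decile
    targets: list = []
    per_comm: dict[int, int] = {}
    for c, d_c in zip(order, counts):
        d_c = int(d_c)
        per_comm[c] = d_c
        if d_c == 0:
            continue
        pool = nodes_by_comm[c]
        if spec.coreness_levels is not None:
            core = nx.core_number(net)
            allowed = set(spec.coreness_levels)
            pool = [v for v in pool if core[v] in allowed]
            if len(pool) < d_c:
                raise ValueError(
                    f"unsatisfiable planting: community {c} has only "
                    f"{len(pool)} nodes in coreness shells "
                    f"{sorted(allowed)} but needs {d_c} targets"
                )
        targets.extend(_decile_stratified_pick(rng, pool, degrees, edges, d_c))
    target_set = set(targets)
    pending = sorted(set(net.nodes()) - target_set)
    n_feat = int(round(spec.featured_fraction * len(pending)))
    pt1 = set(rng.choice(pending, size=n_feat, replace=False).tolist())
    labels = LabeledProteome(
        targets=target_set,
        pending_featured=pt1,
        pending_unfeatured=set(pending) - pt1,
    )
    truth = SyntheticTruth(
        partition=dict(partition),
        target_ids=tuple(sorted(target_set)),
        enriched_communities=tuple(sorted(pinned.items())),
        per_community_targets=per_comm,
    )
    return labels, truth


def generate_feature_table(
    labels: LabeledProteome,
    spec: SyntheticSpec,
    seed: int,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Class-conditional Gaussian feature table for D ∪ PT1.

    Targets (and a hidden-positive subset of PT1) have mean Δ on the first
    ``n_informative`` columns; all other entries are N(0, noise²).  Row
    order is sorted by identifier, so the table is bit-identical across
    runs for a fixed seed.
    """
    if spec.effect_size < 0:
        raise ValueError("effect size must be nonnegative")
    rng = np.random.default_rng(seed)
    d_ids = sorted(labels.targets)
    pt1_ids = sorted(labels.pending_featured)
    n_hidden = int(round(spec.hidden_target_fraction * len(pt1_ids)))
    hidden = set(rng.choice(pt1_ids, size=n_hidden, replace=False).tolist()) \
        if n_hidden else set()
    ids = sorted(d_ids + pt1_ids)
    x = rng.normal(0.0, spec.noise_scale, size=(len(ids), spec.n_features))
    informative = tuple(range(spec.n_informative))
    signal_rows = [
        i for i, v in enumerate(ids) if v in labels.targets or v in hidden
    ]
    for i in signal_rows:
        x[i, list(informative)] += spec.effect_size
    cols = [f"prop_{j + 1:02d}" for j in range(spec.n_features)]
    df = pd.DataFrame(x, index=pd.Index(ids, name="id"), columns=cols)
    truth = SyntheticTruth(
        target_ids=tuple(d_ids),
        informative_features=tuple(cols[j] for j in informative),
        hidden_positive_ids=tuple(sorted(hidden)),
    )
    return df, truth


def generate_dataset(
    spec: SyntheticSpec, seed: int
) -> tuple[nx.Graph, LabeledProteome, pd.DataFrame, SyntheticTruth]:
    """Full bundle: network + labels + features + merged truth.

    Sub-seeds for the three stages are derived from *seed* so the stages
    stay independently reproducible.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    net, truth_net = generate_network(spec, sub[0])
    labels, truth_lab = plant_target_labels(net, truth_net.partition, spec, sub[1])
    features, truth_feat = generate_feature_table(labels, spec, sub[2])
    truth = SyntheticTruth(
        partition=truth_net.partition,
        target_ids=truth_lab.target_ids,
        enriched_communities=truth_lab.enriched_communities,
        per_community_targets=truth_lab.per_community_targets,
        informative_features=truth_feat.informative_features,
        hidden_positive_ids=truth_feat.hidden_positive_ids,
        augmented_edges=truth_net.augmented_edges,
    )
    return net, labels, features, truth


_TINY_EDGES = (
    # community A: a dense 10-node cluster (ring + chords)
    ("N01", "N02"), ("N02", "N03"), ("N03", "N04"), ("N04", "N05"),
    ("N05", "N06"), ("N06", "N07"), ("N07", "N08"), ("N08", "N09"),
    ("N09", "N10"), ("N10", "N01"), ("N01", "N03"), ("N02", "N04"),
    ("N05", "N08"), ("N06", "N09"), ("N01", "N05"), ("N02", "N07"),
    ("N03", "N06"), ("N04", "N08"),
    # community B: a dense 10-node cluster
    ("N11", "N12"), ("N12", "N13"), ("N13", "N14"), ("N14", "N15"),
    ("N15", "N16"), ("N16", "N17"), ("N17", "N18"), ("N18", "N19"),
    ("N19", "N20"), ("N20", "N11"), ("N11", "N13"), ("N12", "N14"),
    ("N15", "N18"), ("N16", "N19"), ("N11", "N15"), ("N13", "N17"),
    # single bridge between the clusters
    ("N10", "N11"),
    # a short pendant tail off community B
    ("N20", "N21"), ("N21", "N22"), ("N22", "N23"), ("N23", "N24"),
)

_TINY_TARGETS = ("N02", "N04", "N06", "N08")
_TINY_FEATURED_PENDING = ("N12", "N14", "N16", "N18", "N21", "N22", "N11",
                          "N13", "N15", "N17")


@dataclass
class TinyFixture:
    """A deterministic 24-node bundle for unit tests and documentation."""

    net: nx.Graph
    labels: LabeledProteome
    features: pd.DataFrame
    partition: dict  # hand-assigned ground-truth communities


def tiny_fixture() -> TinyFixture:
    """Hand-built connected 24-node network with labels and features.

    Two dense 10-node clusters joined by one bridge plus a 4-node pendant
    tail; 4 targets concentrated in the first cluster; 10 featured pending
    proteins; 39 seeded Gaussian features with effect size 2 on the first
    five columns.  Every metric is small enough to verify by exhaustive
    enumeration.
    """
    g = nx.Graph()
    g.add_edges_from(_TINY_EDGES)
    labels = LabeledProteome(
        targets=set(_TINY_TARGETS),
        pending_featured=set(_TINY_FEATURED_PENDING),
        pending_unfeatured=set(g.nodes()) - set(_TINY_TARGETS)
        - set(_TINY_FEATURED_PENDING),
    )
    spec = SyntheticSpec(
        n_nodes=24,
        n_features=39,
        n_informative=5,
        effect_size=2.0,
        hidden_target_fraction=0.0,
    )
    features, _ = generate_feature_table(labels, spec, seed=20240)
    partition = {v: (0 if int(v[1:]) <= 10 else 1) for v in g.nodes()}
    return TinyFixture(net=g, labels=labels, features=features,
                       partition=partition)
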