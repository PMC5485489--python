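# targetnet

Topology-based analysis of drug targets in protein–protein interaction
(PPI) networks.

Known drug targets are a tiny, precious subset of the interactome (on the
order of 1% of proteins), and whether they occupy distinctive positions in
the PPI network is a long-standing question in systems pharmacology.
`targetnet` implements a complete desk-scale analysis of that question for
any labeled interaction network:

* **Topology profiling** — per-protein degree `k_i`, betweenness
  `Btwn(v) = Σ_{s≠v≠t} σ_st(v)/σ_st` and its min–max normalization `NB`,
  eigenvector centrality `x = (1/λ) A x`, local clustering coefficient,
  eccentricity `ε(v)`, mean shortest distance `l(v)` with the
  network-diameter substitution for unreachable pairs, and coreness from
  k-core decomposition.
* **Community structure** — modularity
  `Q = (1/2m) Σ_{ij} [A_ij − k_i k_j/2m] δ(c_i, c_j)` and Louvain-style
  maximization; per-community target enrichment
  `rd(i) = D(i)/PT(i)` (shares of the target set vs. the pending set), with
  `rd(i) > 1` flagging a *target-like* community; per-coreness-level
  enrichment ratios `rc_D(k)`, `rc_PT(k)` against the global target ratio.
* **Knockout experiments** — delete the target set, re-extract the largest
  connected component, and quantify the change in any metric distribution
  with summary statistics and the maximum ECDF gap.
* **Candidate prediction** — naive-Bayes scoring over community and
  coreness (fixed 50% prior) to select a reliable *negative* set from the
  featured pending proteins, a linear-kernel SVM on 39 chemical-physical
  properties, stratified 10-fold cross-validation (accuracy, PPV, NPV from
  the pooled confusion matrix), and candidate calling by decision sign;
  plus a classifier × feature-set benchmark harness.
* **Synthetic data** — a degree-corrected planted-partition generator with
  controlled target enrichment, degree-matched target placement, and
  class-conditional Gaussian feature tables, so the whole pipeline is
  testable without any database downloads.

## Worked example

```python
import targetnet as tn
from targetnet.topology import coreness_map

fx = tn.tiny_fixture()              # 24-node network, 4 targets, features
part = tn.detect_communities(fx.net, seed=0, min_report_size=5)
print("Q =", round(part.q, 4), "sizes:", part.sizes)
print(tn.community_enrichment(part, fx.labels)[
    ["size", "n_targets", "rd", "target_like"]].round(3))
```

prints

```
Q = 0.5237 sizes: {1: 10, 2: 9, 3: 5}
           size  n_targets     rd  target_like
community
1            10          4  3.333         True
2             9          0  0.000        False
3             5          0  0.000        False
```

All four targets sit in community 1, whose enrichment `rd = (4/4)/(6/20) =
3.33 > 1` marks it target-like; the other communities hold no targets.
The coreness table tells the same story from the layer structure — the
targets live in the innermost 3-core (`rc_D(3) = (4/8)/(4/24) = 3`):

```python
print(tn.coreness_enrichment(coreness_map(fx.net), fx.labels)[
    ["size", "n_targets", "rc_d", "target_dominated"]].round(3))
#           size  n_targets  rc_d  target_dominated
# coreness
# 1            4          0   0.0             False
# 2           12          0   0.0             False
# 3            8          4   3.0              True
```

Removing the targets and re-profiling quantifies their structural role:

```python
ko = tn.knockout_experiment(fx.net, fx.labels, metrics=["degree"])
r = ko["degree"]
print(r.before_mean, r.after_mean, r.gap)   # 3.25 2.632 0.259
```

The same stages run from the shell — `targetnet build | profile |
communities | enrich | knockout | predict | simulate | run` — with
`targetnet run config.cfg` chaining them from a flat key=value file into
TSV/JSON artifacts plus a manifest (every output header records the seed
and config hash; reruns are byte-identical).

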