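# Methods

This note records the models, conventions and design choices behind
`targetnet`, in the order the pipeline applies them.

## The analysis graph

The network is a simple undirected graph `G = (V, E)` of opaque protein
identifiers with adjacency matrix `A ∈ {0,1}^{n×n}`. Edge-list ingestion
drops self-loops and collapses duplicate pairs in either orientation, and
every analysis runs on the largest connected component (LCC) — curated
interactomes are incomplete, and isolated nodes or two-protein fragments
say more about missing evidence than about biology. LCC ties are broken by
the lexicographically smallest member, so extraction is deterministic.

Labels partition the proteome into known targets `D`, featured pending
proteins `PT1` (those with a chemical-physical property vector) and
unfeatured pending proteins `PT2`. The global ratios `DR = |D|/|P|` and
`PR = |PT|/|P|` (with `P = D ∪ PT1 ∪ PT2`) are the baselines for every
enrichment statistic. Coverage accounting reports used/original counts per
category as percentages rounded to one decimal.

## Topological indices

* **Betweenness** sums `σ_st(v)/σ_st` over unordered pairs with endpoints
  excluded (Brandes accumulation). The normalization
  `NB(v) = (Btwn(v) − min)/(max − min)` makes the pair-orientation
  convention irrelevant downstream; a constant raw map normalizes to all
  zeros rather than dividing by zero.
* **Eigenvector centrality** is computed by power iteration on `A + I`
  from the all-ones vector with Euclidean renormalization. The identity
  shift matters: plain iteration on `A` oscillates on bipartite graphs
  (±λ are both extreme eigenvalues), while `A + I` is primitive on any
  connected graph and has the same Perron vector. Convergence requires
  both a max-norm step difference below the tolerance (default 1e-10,
  at most 1000 iterations) and a Rayleigh residual `‖Ax − λx‖∞ <
  10·tolerance`; λ is the Rayleigh quotient of `A`. Non-convergence is an
  error naming the iteration count.
* **Average distance** `l(v)` is the mean over the other `n − 1` nodes
  (the standard average-path-length denominator), with unreachable pairs
  contributing the network diameter `D_G`. On a connected graph the rule
  is inactive and `l` equals the plain mean distance — tested explicitly.
  On a disconnected graph `D_G` defaults to the maximum finite
  eccentricity over components (the analysis graph is connected, so this
  only affects general reuse).
* **Clustering** for degree < 2 is defined as 0, so group means are
  computable over all nodes.
* **Eccentricity** requires a connected graph; the map is reported with
  its maximum (the diameter) and its mode (ties toward the smaller
  value), because knockout effects show up as modal shifts.
* **Coreness** is the largest k for which a node survives iterative
  pruning of degree-< k nodes.

## Communities and enrichment

Modularity follows the standard degree-preserving null form and is
evaluated exactly by the per-community regrouping
`Q = Σ_c [L_c/m − (deg_c/2m)²]`. Detection is Louvain-style greedy
multi-level maximization, deterministic for a fixed seed; detected
communities are relabeled 1..K by decreasing size (ties by smallest
member) and the "main" communities are those of at least
`min_report_size` nodes (default 50), pooling the long tail of small
communities out of the enrichment report.

Community enrichment uses shares of each class: `D(i) = i_D/|D|`,
`PT(i) = i_PT/|PT|`, `rd(i) = D(i)/PT(i)`. Because `Σ_i PT(i)·rd(i) = 1`,
the rd values of a partition average to 1 under PT-share weights — a
community can only be target-like (`rd > 1`, strictly) at the expense of
others. `rd` is +∞ when a community holds targets but no pending
proteins, and 0 in the opposite case. "PT" always means `PT1 ∪ PT2`.

Coreness enrichment works per occupied coreness level. The report carries
the shell shares `p_k` (each class's shares summing to 1 over levels) and
the ratios `rc_D(k)` and `rc_PT(k)`, defined as the within-level class
proportion over the global baseline (`DR` resp. `PR`) — equivalently the
shell share divided by the level's share of all nodes. `rc_D(k) > 1`
(strict) flags a target-dominated level. Levels are
coreness-exactly-k shells by default because the target concentration of
interest lives in distinct bins; a cumulative (k-core membership) variant
is exposed behind a flag.

## Knockout experiments

`knockout_experiment` removes the target set, re-restricts to the LCC
(the same rule as the original preprocessing, applied consistently), and
recomputes each requested metric. Because visual distribution comparisons
are not assertable, the quantitative contract is the two-sample
Kolmogorov–Smirnov statistic — the maximum vertical gap between the
before/after ECDFs, which is 0 exactly when the distributions coincide
and needs no distributional assumptions. Integer-valued metrics also
report the modal shift.

## Candidate prediction

Because no curated non-target set exists, the negative class is
bootstrapped from topology: a categorical naive Bayes over community
membership and coreness, with add-one smoothing over the levels observed
in the whole network and a fixed 50% target prior, scores every PT1
protein; the `floor(0.5·|PT1|)` lowest-posterior proteins become the
negative set (ties at the cut broken by identifier). Target likelihoods
are estimated from `D`; non-target likelihoods from all pending proteins
(`PT1 ∪ PT2`) — the contamination of that set by unknown true targets is
exactly what the subsequent selection of the *lowest*-scoring half guards
against. Community membership is used as the per-protein realization of
modularity structure.

The classifier is a linear-kernel SVM with unit regularization (C = 1) on
the 39 standardized chemical-physical properties; standardization is fit
on training folds only (a leakage guard). Evaluation is stratified
10-fold cross-validation with a pooled held-out confusion matrix;
accuracy, PPV `TP/(TP+FP)` and NPV `TN/(TN+FN)` are properties computed
from that stored matrix, so reported metrics can always be re-derived
exactly; a metric with a zero denominator is reported absent. Candidates
are the PT1 proteins outside the negative set with a positive decision
value (no calibration or threshold tuning).

The benchmark harness runs any of {naive Bayes, linear SVM, logistic
regression, decision tree} over named feature sets of the topology
profile — by default the eight topological features {degree, betweenness,
eigenvector, average distance, eccentricity, clustering, community,
coreness} against the three target-characteristic features
{eccentricity, community, coreness}. It balances classes (all targets vs.
an equal-size seeded sample of pending proteins) so that the chance level
of accuracy is 0.5 and cells are comparable across rows.

## Synthetic data: what it emulates, and what it does not

The generator produces a degree-corrected planted-partition graph:
expected degrees are drawn from a truncated power law (default exponent
2.5, truncation at √n) and pair probabilities are proportional to
`θ_i θ_j`, boosted by an 8:1 intra/inter factor inside blocks and scaled
to a mean degree of 11.6 — the degree scale of curated human
interactomes. A degree-corrected block model was chosen over preferential
attachment because community structure and the degree tail must be
controlled independently. Setting `degree_exponent=None` gives a
homogeneous planted partition. Stray components are tied into the giant
component with single recorded edges so the output is connected.

Defaults emulate the published structure of a curated drug-target
interactome at 3,000-node scale: a 1.2% target fraction, three enriched
communities at planted rd of 3, 2 and 1.5 (together holding roughly
two-thirds of the targets), 10.5% of pending proteins featured (PT1), 39
features with 8 informative ones, and an 8.5% hidden-positive rate
inside PT1 modeling not-yet-annotated true targets.

Target planting pins each community with a stated enrichment ρ to the
count solving `d_c/(n_c − d_c) = ρ · |D|/|PT|` (largest-remainder
rounding), which makes the realized `rd` equal ρ in expectation by
construction; remaining targets spread over unpinned communities by size,
whose rd then sits slightly below 1, as the weighted-average identity
requires. A naive multinomial weighting of communities by `size·ρ` would
bias the realized rd noticeably below ρ (≈ 3.6 for ρ = 4 at a 7% target
fraction), because a density ratio is not the odds ratio that rd
measures. Within a community, targets are drawn by stratified sampling
over global degree deciles, so the target degree distribution matches the
non-target one *by construction* — the central null finding (targets are
not hubs) is a property of the study conditions, not an accident of
sampling. An optional constraint restricts targets to stated coreness
shells.

Feature tables are class-conditional Gaussians: targets (and hidden
positives) shifted by Δ on the informative columns, unit noise elsewhere.

What passing tests on these data do **not** show: real interactomes have
correlated, non-Gaussian physicochemical properties, assortativity and
motif structure beyond a block model, and study-specific curation biases;
false-positive interaction models are deliberately out of scope. Results
on synthetic data validate the *machinery* (estimators recover what was
planted; nulls planted by construction stay null), not biological claims.

## Numerical and reporting choices

* All randomness flows through `numpy.random.default_rng` seeds;
  sub-seeds are derived with `SeedSequence.spawn`, and identical
  spec + seed reproduce bit-identical outputs.
* Deterministic tie-breaks throughout: LCC ties and negative-set cut ties
  by identifier, community relabeling by size then smallest member, modal
  values toward the smaller level.
* Pipeline TSVs print floats with `%.10g`; every artifact header names
  the seed and a hash of the analysis-relevant configuration (output
  location excluded), and the manifest records package version, seed and
  input checksums — no timestamps, so reruns are byte-identical.
* Degenerate inputs are contracts, not crashes: empty networks map to
  empty results where meaningful (LCC, edge-list round-trip), and
  undefined quantities (average distance on a singleton, NPV with no
  negative calls, coverage with a zero denominator) are reported absent.

## Test-study problem sizes

Oracle-equivalence tests run exhaustive brute-force checks on 200 random
graphs of up to 12 nodes (betweenness, clustering, coreness, distances)
and dense eigendecompositions on 50 connected graphs of up to 30 nodes.
Recovery studies use n = 3000 with 200 targets (enrichment), the default
3000-node study conditions (knockout null), 6×50-node blocks at a 5:1
mixing ratio and mean degree 20 (community recovery — modularity
detection needs density well above the detectability threshold at this
block size, which the ≥ 0.9 NMI configuration provides), and 1000-sample
balanced feature sets (prediction calibration), each averaged over 10–20
seeds.

## Known limitations

* Exact betweenness and all-pairs distances are O(nm); the pipeline is
  desk-scale (tens of thousands of nodes at most), with no approximate
  sampling variants.
* Louvain maximization is a heuristic: community labels are arbitrary
  (only enrichment structure is comparable across runs) and the Q
  guarantee is only relative to the trivial partition.
* Metrics are unweighted and undirected by design; confidence-scored or
  directed interactomes are out of scope.
* The naive-Bayes negative selector assumes community and coreness are
  conditionally independent given the class; violations soften the
  posterior ranking but the downstream SVM sees only the selected set.
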