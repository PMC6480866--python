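# Methods

## The synthetic study generator

Raw data from the OIT experiments this pipeline is designed around are not
publicly deposited, so the package ships a generator that emulates their
statistical structure and carries known ground truth for validation. The
generator is first-class, tested code: its defaults *are* the study
conditions under which everything else is validated.

### Generative model

Each animal belongs to one of five treatment arms — sham, sensitized,
sensitized+FOS diet, sensitized+OIT, sensitized+OIT+FOS — encoded as three
binary flags (sensitized, diet, oit); arms are equally sized. Features are
organized in five latent blocks: clinical, antibody, scfa, cytokine, cell.
For an animal with flags f and latent block vector u ~ N(0, Σ):

    x_j = λ_j (u_b(j) + m_b(j)(f)) + ε_j,     ε_j ~ N(0, σ_j²)

where b(j) is feature j's block, λ_j its loading, and m_b(f) the additive
treatment shift of block b (sum of per-flag effects, in latent units).
Relative-scale features are reported as exp(x_j) · batch_e — log-normal,
positive-skewed, with a per-experiment multiplicative batch factor, as for
titers, cytokine and SCFA assays. Body temperature is the one
absolute-scale feature: reported as 37.2 °C + x_j in degrees Celsius, with
a *negative* loading (−0.4 °C per latent unit) so that clinical severity
drives an anaphylactic temperature drop; it receives no batch factor.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| loadings λ | cycle 0.45–0.60 (scfa block 0.72–0.92) | see calibration note below |
| residual σ | 1.2 log-units (0.75 °C for temperature) | immunoassay spread |
| effects m | e.g. sensitized: clinical +4.5, antibody +6.0; OIT: clinical −3.0; diet: clinical −2.4, scfa −1.0/+0 | order-of-magnitude fold-changes (IgE > 20× on sensitization), ~1.8 °C anaphylactic drop partially rescued by OIT/diet |
| block coupling Σ | clinical–antibody 0.5, clinical–cytokine 0.3, cytokine–cell 0.4, clinical–scfa **0.8 (CMA) / 0.0 (PNA)** | antibodies track clinical severity; the scfa contrast is the analysis target |
| batch scales | CMA (1.0, 1.8, 0.6); PNA (1.0, 1.5) | strong enough that pooling without per-experiment normalization would be visibly wrong |
| panel | CMA 66 features / 3 experiments / 6 per arm (90 animals); PNA 33 / 2 / 7 (70 animals); ~20-feature shared core; one experiment lacks a few panel features | matches the study sizes the pipeline is meant for and exercises the merge-on-intersection rule |

**Calibration note.** The loading/noise/effect scales were set jointly, at
generator-design time, to a regime with two properties: (i) treatment
flags carry most of the information about any single marker (the
Bayes-optimal AUC for the mMCP-1 tertile given *all* other network
variables exceeds the flags-only ceiling by only ~0.03), which is the
regime a treatment-rooted expert DAG assumes; and (ii) within-block
Spearman correlations stay at 0.2–0.4, enough for the feature network to
recover blocks. Strong residual marker–marker correlation and a
treatments-only DAG are mutually inconsistent modeling assumptions; the
generator deliberately sits where the modeled structure is approximately
right.

**The scfa contrast.** In the CMA flavour the scfa block receives
treatment effects aligned with the clinical axis plus latent coupling 0.8,
so its features are topologically near the clinical cluster; in the PNA
flavour it receives neither, making it an isolated, internally coherent
cluster. This emulates a correlational contrast between the two disease
models, not SCFA metabolism: the generator makes no mechanistic claim
about fiber fermentation, and the association sign was chosen so the
contrast is visible under signed similarity (see below).

### What the generator does not emulate

No longitudinal (multi-timepoint) structure; no assay-specific dynamic
ranges, detection limits, or censoring; no missing values by default; no
heavy-tailed outliers; no within-arm covariates (age, weight, cage).
Passing tests therefore demonstrate correctness of the *procedures* under
a plausible correlation/treatment structure — not robustness to every
pathology of real immunoassay data.

### Oracles

`oracle_bayes_auc` estimates the Bayes-optimal Hand–Till AUC for a
discretized target by Monte Carlo: simulate n_mc samples, discretize
target and predictor markers into quantile levels, estimate
P(target level | joint predictor configuration) by empirical frequencies,
and score those posteriors. At the default n_mc = 20000 the estimate is
stable to ±0.02 across seeds. It is the ceiling for any fitted network
predicting from the same discretized variables.

## Preprocessing

* **Min-max normalization** maps each relative feature onto [0, 1] *within
  each experiment*, before pooling, so relative assays become comparable
  across experiments; absolute features (temperature) pass through
  unchanged. A constant relative feature is an error, not a silent 0.
* **Pool-and-merge** concatenates experiments on the intersection of their
  feature panels; features present in only some experiments are discarded
  (similarity between features observed on disjoint animals is
  undefined). Provenance is kept in an `experiment_id` column.
* **Discretization** (Hartemink): quantile-bin each feature into 10
  initial levels, then reduce to L = 3 by collapsing adjacent bins,
  each collapse chosen to maximize the summed pairwise mutual information
  (nats, empirical frequencies) with all other features. Two
  implementation refinements: when the joint space of breakpoint subsets
  is small (≤ 2000 combinations, e.g. 12-sample toy tables) the optimum
  is found by exhaustive enumeration; otherwise the greedy collapse is
  followed by a deterministic coordinate-ascent sweep (per feature,
  re-select the best subset of its initial breakpoints given the others)
  to a fixed point. Both stay inside the family of quantile-subset
  discretizations and are rank-based, hence invariant to monotone
  transforms. Caveat: for mutually *independent* features the MI
  objective is sampling noise and no greedy scheme reliably tracks the
  global optimum — nor does the choice matter there.
* **Tertiles** use nearest-rank quantiles with ties assigned to the lower
  class, so tied values always share a label and the split is
  deterministic.
* L = 3 for every node (the target is evaluated on tertiles; other marker
  nodes default to the same, configurable). Missing values: pairwise
  deletion for MI, listwise for network fitting.

## Bayesian network track

* **Structure** is never learned. The default expert DAG has the three
  treatment flags as roots and every marker (sIgE, sIgG1, ear swelling,
  mMCP-1, body temperature) as a child of all three roots — the design
  semantics of a controlled experiment, with no invented marker–marker
  biology. Fully overridable via YAML. The temperature node is the
  absolute-scale body-temperature reading; its *low* level corresponds to
  the anaphylactic drop.
* **Fitting**: CPT entry = (count + α) / (row total + α·L); α defaults to
  0 (pure maximum likelihood), with parent configurations never observed
  falling back to the uniform distribution.
* **Inference** is exact by enumeration of the joint (≤ a dozen nodes —
  cheap, and avoids approximation error entirely). Zero-probability
  evidence raises `ImpossibleEvidenceError`.
* **Prediction** conditions on all non-target network nodes. Rows whose
  evidence combination is impossible under the unsmoothed fitted joint
  (which occurs on transfer data) receive a uniform posterior rather than
  an error — a documented scoring fallback, configurable to raise.
* **Transfer** evaluation applies the *training* discretization map to the
  second model's pooled (per-experiment-normalized) data: a trained
  network's thresholds are part of the model and travel with it.
* **Hand–Till AUC** is computed from average ranks (ties ½) per ordered
  class pair, averaged per unordered pair and over pairs. Classes absent
  from the truth labels raise by default; transfer scoring skips those
  pairs explicitly.

## Topological track

* Similarity is **signed** Spearman ρ by default ("nearest" = most
  positively correlated); an absolute-value mode is available since
  whether anti-correlated features should count as near is a modeling
  choice. Consequence of the signed default: an inversely-coded feature
  (body temperature) tends to become an isolated node.
* k = ceil(ln n) (natural log, ceiling for integrality, clamped to
  [1, n−1]): kNN graphs become connected at k on the order of log n. The
  90-animal pooled study gives k = 5.
* Top-k ties break lexicographically by feature name; edges are
  unweighted for modularity; Louvain resolution defaults to 1; the
  partition seed defaults to 0 and is recorded. Cluster-to-cluster
  distance is the minimum pairwise node distance.
* Prioritization: multi-source BFS from the clinical features; rank
  ascending by distance (name as tie-break); no path ⇒ *unrelated*;
  identical closed neighborhoods within a cluster ⇒ *redundant*.

## Numerical and engineering choices

CPT rows are validated to sum to 1 within 1e-12; inference matches
brute-force enumeration to better than 1e-9 (tested on random networks).
All simulation flows through `numpy.random.default_rng` with per-experiment
streams spawned from a single seed; Louvain uses a seeded sweep order.
Artifacts (JSON with sorted keys, CSV, YAML, GraphML) are byte-identical
across reruns of the same config+seed; manifests record a config hash,
seed, and stage-by-stage row/feature counts, and contain no timestamps.

Problem sizes used by the test suite and the acceptance script — chosen as
the smallest sizes at which the asymptotic statements are comfortably
visible: large-study checks use 200 animals per arm over 2 experiments
(2000 animals), the Bayes-ceiling Monte Carlo uses 20000 draws, planted
2×8-feature blocks use 200 samples, and the discretization optimality toys
use 12 samples × 3 features so exhaustive search is feasible.

## Known limitations

* The default DAG's prediction for a childless target reduces to its
  parent configuration; sibling markers contribute nothing by
  construction. With strong residual marker correlations a richer
  structure would be needed, and the internal AUC would sit further below
  the all-variable Bayes ceiling.
* Exact inference by enumeration scales exponentially in node count; the
  implementation guards nothing beyond practicality (~12 nodes).
* The greedy+refined discretization is optimal only within the family of
  subsets of the initial quantile breakpoints, and only coordinate-wise
  at large panel sizes.
* Cross-model transfer assumes the marker panels share the network's node
  set; no imputation of absent markers is attempted.
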