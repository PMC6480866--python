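# oitnet

Network-based biomarker prioritization for oral immunotherapy (OIT)
studies of food allergy.

Murine OIT experiments — cow's-milk allergy (CMA) and peanut allergy (PNA)
models with fructo-oligosaccharide (scFOS/lcFOS) dietary support — measure
dozens of immune parameters per animal across several independent
experiments: clinical challenge readouts (ear swelling, anaphylaxis shock
scores, body temperature, mucosal mast cell protease-1), allergen-specific
antibodies, short-chain fatty acids (SCFA), cytokine release, and leukocyte
phenotypes. Two questions follow: *does a compact probabilistic model of
treatment → marker relationships transfer across allergy models*, and
*which of the many measured parameters are actually informative about the
clinical outcome* (and which are redundant or unrelated, and could be
dropped from future panels)?

`oitnet` implements both analysis tracks as a tested, reusable pipeline,
driven by a synthetic-study generator that emulates the statistical
structure of such experiments (correlated latent assay blocks, treatment
arms, log-normal assay scales, per-experiment batch effects, partially
overlapping feature panels) and provides ground-truth oracles so that every
step can be validated quantitatively. It is aimed at computational
biologists who want to run, audit, or extend this style of analysis.

## The two tracks

**Discrete Bayesian network.** Relative-scale features are min-max
normalized per experiment, experiments are pooled, and continuous markers
are discretized into L = 3 levels by a mutual-information-preserving
quantile collapse (Hartemink's algorithm). Over the expert-specified DAG —
treatment roots (sensitized, diet, OIT) pointing at marker nodes
(specific IgE and IgG1, ear swelling, mMCP-1, body temperature) — the
joint factorizes as

    P(X1..Xn) = prod_i P(Xi | pa(Xi)),

with conditional probability tables fitted by maximum likelihood. Exact
inference by joint enumeration answers what-if queries (e.g. "all animals
sensitized and given OIT") and yields per-sample posteriors for the mMCP-1
tertile, scored with the Hand–Till multiclass AUC

    M = 2 / (c(c-1)) * sum_{i<j} A(i, j),

where A(i, j) averages the two one-vs-one rank AUCs of classes i and j.
Transfer evaluation scores the trained network on the *other* allergy
model, discretized with the training breakpoints.

**Topological feature network.** Features are nodes; similarity is
Spearman's rank correlation over the pooled samples; edges follow the
mutual k-nearest-neighbor rule with k = ceil(ln n); clusters come from
multilevel modularity (Louvain) optimization. Candidate biomarkers are
ranked by their shortest-path distance to the nearest clinical outcome
feature; features with no path are flagged *unrelated*, and same-cluster
features with identical closed neighborhoods are flagged *redundant*.

## Worked example

```bash
python analysis/01_simulate_studies.py --seed 0   # CMA: 90 animals / 66 features, PNA: 70 / 33
python analysis/02_bayesnet_analysis.py --seed 0
python analysis/03_network_prioritization.py --seed 0
```

The network analysis prints the what-if scenario table (probabilities in
percent, one column per scenario) and the evaluation summary:

```
internal Hand-Till AUC (mMCP-1 tertile, CMA): 0.767
transfer Hand-Till AUC (CMA-trained network on PNA): 0.721
P(high mMCP-1): 16.7% under sensitization, 0.0% after adding OIT (decrease)
```

The internal AUC says the fitted network ranks the held-in animals'
mMCP-1 tertiles far better than chance (0.5); the transfer AUC shows the
CMA-trained network still ranks PNA animals well, i.e. the treatment →
marker structure is shared between the models. The scenario line is the
what-if contrast: conditioning on OIT on top of sensitization lowers the
probability of the highest mast-cell-activity tertile.

The prioritization step prints, per study, the non-clinical features
closest to the clinical outcomes, the unrelated features, and the
SCFA-to-clinical distance:

```
== CMA study ==  SCFA block to clinical features: 1 hops
== PNA study ==  SCFA block to clinical features: 2 hops
```

reflecting the generated contrast: the SCFA block is coupled to the
clinical severity axis in the CMA flavour and decoupled in the PNA
flavour, so it sits closer to the clinic in the CMA network.

A `oitnet` command-line interface wraps the same steps
(`oitnet simulate | bn-train | bn-eval | scenarios | tda | report`).

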