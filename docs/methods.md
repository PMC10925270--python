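# Methods

## The model

A **graph-structured neural network (GSNN)** predicts perturbation responses
under the constraints of a directed biological network 𝒢 with three node
roles. *Input nodes* (drugs and per-cell 'omic features; in-degree 0) carry
the stimulus and the cellular context. *Function nodes* (proteins and RNAs;
in- and out-degree ≥ 1, cycles allowed) are molecular entities whose
behavior is learned. *Output nodes* (measured genes; out-degree 0, in-degree
exactly 1, fed by the matching RNA node) carry the predicted readout.

The hidden representation lives on the **edges** of 𝒢. Each function node n
with in-degree D_in(n) and out-degree D_out(n) is a one-hidden-layer neural
map from its incoming-edge values to its outgoing-edge values with C_n hidden
channels; no parameters are shared between function nodes, so each
interaction's behavior is learned separately. One GSNN layer applies all node
maps at once — a sparse gather (E → ΣC_n), per-node layer normalization, an
ELU nonlinearity, optional dropout on hidden channels, and a sparse scatter
(ΣC_n → E) — and adds the previous edge state (a residual connection). L
stacked layers propagate signal exactly L function-node hops; the residual
stream models signal latency by letting contributions accumulate across
depth. Weights of node n are initialized from Normal(0, 2/D_in(n)) (kaiming)
or Normal(0, 2/(D_in(n)+D_out(n))) (xavier), using the graph degrees as fan
values. Training minimizes mean squared error over output nodes with Adam and
small batches; normalization is per node (layer norm), never per batch,
because batch statistics are unreliable at the batch sizes this architecture
requires.

Two structural guarantees follow from the construction and are enforced by
tests: the sparse implementation is exactly the masked dense linear model
(agreement with an explicit dense masked-matrix oracle to ≤ 1e-5), and an
output's gradient with respect to a non-ancestor input is exactly zero.

### Numerical and design choices

* **Input persistence.** Edges leaving input nodes are written by no function
  node, so the residual stream holds them at the encoded stimulus at every
  layer. This is equivalent to re-clamping the inputs each layer; injecting
  the stimulus only at layer 0 would be an alternative reading, but clamping
  keeps the drug "present" for the whole forward pass and avoids
  double-counting through the residual.
* **Layer normalization with one channel.** Normalizing a single value is
  degenerate (it always yields zero and would sever the node's signal), so
  nodes with C_n = 1 — possible when channels scale with degree — skip the
  normalization and keep only the learnable scale/shift.
* **Degree-scaled channels.** With `scale_channels_by_degree`,
  C_n = max(1, min(C, max(D_in, D_out))): low-degree entities get simpler
  functions. The clamp form is one realization of "scale channels by degree";
  any monotone rule would do.
* **Parameter sharing.** With `share_layer_params` the weight blocks are
  reused at every layer but the normalization scale/shift stays per layer:
  activation statistics are depth-dependent even when the transformation is
  shared.
* **Inert nodes.** Randomized control graphs can leave a function node with
  no incoming or no outgoing edge; such nodes are skipped by the model (they
  can compute nothing) and tolerated by validation in non-strict mode.
* **Gradients.** All training (GSNN, baseline network, explainer mask,
  viability head) runs on the package's own vectorized reverse-mode autodiff
  core (`gsnn.autodiff`) over numpy arrays, with sparse-matrix linear maps
  for the gather/scatter and an Adam optimizer. Gradient correctness is
  checked against finite differences indirectly through the dense-oracle and
  faithfulness tests.

## Graph construction and randomization

`build_subgraph` reduces raw interaction tables to a pathway-focused graph:
(1) the protein-space is the union of proteins in the requested pathways;
(2) the rna-space is every RNA reachable from the protein-space through at
most `rna_descendant_depth` regulatory edges (TF→RNA, miRNA→RNA, RNA→protein
chains; depth 1 = direct targets, depth 0 = empty); (3) drugs with ≥ 1
retained target join; (4) outputs are the rna-space ∩ assay-measurable genes;
(5) all edges with both endpoints retained are kept; (6) each measurable RNA
gains one output node; (7) drugs whose descendants cover less than
`drug_prune_fraction` (default 0.25) of the outputs are removed — such drugs
are over-constrained by the prior knowledge and cannot influence most
predictions; (8) proteins/RNAs with no downstream output are removed; (9)
'omic input nodes are attached for retained entities (expression reaches both
the protein and the RNA node when both exist). A final fixpoint cleanup drops
function nodes that received no regulator, drug, or 'omic input (they cannot
compute anything), cascades, and re-checks the drug-coverage invariant; the
builder therefore always returns a valid graph or raises. Drug pruning counts
descendants on the pre-'omics graph, and 'omics never resurrect pruned
entities.

`randomize_graph` is the negative control for the value of curated wiring:
input, function, and output edges are resampled independently — input edges
keep their source, output edges keep their destination, function edges redraw
both endpoints uniformly among function nodes — conserving per-class edge
counts exactly while destroying individual degrees. Self-loops are resampled
away unless the original graph contained self-edges.

## Data handling

Drug concentration c (μM) is encoded as
`x = -(log10(c + ε) - log10(ε)) / log10(ε)` with ε = 1e-6: zero maps to zero,
1 μM maps to ~1, and the map is log-linear over the assay-relevant range.
'Omic values pass through unchanged (the fixture generator standardizes them;
real-data scaling is left to the caller). The cell-agnostic encoding zeroes
every non-drug input and is the ablation that removes cellular context.
Cross-validation splits **(drug, cell line) pairs**, not observations —
train 60% / validation 20% / test 20%, floor rounding with the remainder to
train — so test performance measures imputation of unseen drug–cell
combinations.

## Evaluation

Performance is the mean Pearson correlation ρ̄: per output gene across
observations, averaged over genes with defined variance (constant columns are
skipped and counted). Two methods are compared by a two-sided paired t-test
across folds with Bonferroni adjustment (p × number of planned comparisons,
capped at 1); a zero-variance, zero-mean difference is flagged invalid rather
than given a p-value, and a constant nonzero difference reports a divergent t
with p = 0. Grouped local performance drops groups under 5 observations in
any fold and controls FDR by Benjamini–Hochberg or Benjamini–Yekutieli
(threshold 0.1). Grid search selects by validation ρ̄ within each fold and
touches the test partition exactly once, for the selected configuration. The
baseline is a two-hidden-layer fully connected network with ELU and batch
normalization; early stopping for all models is by validation ρ̄ with
patience 10.

## Explainer

Given an observation x and a baseline x_b (same cell, zero dose, for
drug-response questions), the explainer learns per-edge logits θ whose
sigmoid is the edge-inclusion probability. Each iteration draws B = 8
binary-concrete masks m = σ((θ + logistic noise)/τ), runs the masked forward
— after the initial state and after every layer, edge e's state becomes
m_e·state + (1−m_e)·(baseline activation) — and minimizes
MSE(f(x) − f(x_b), masked output − f(x_b)) + β·max(0, Σm − E_free) + γ‖θ‖².
Pinning excluded edges to the baseline activations rather than zero matters:
edges carry endogenous, context-driven signal even without drug, and zeroing
them would not represent removal. The temperature anneals geometrically from
5.0 to 0.5; masks start near-full (prior 0.9) and the size penalty prunes
uninvolved edges. The penalty is hinged at the free-edge budget so masks
smaller than the budget are not rewarded. The logits are optimized with Adam
(plain gradient steps were markedly less stable on fixtures at comparable
learning rates). Boundary identities are exact: an all-ones mask reproduces
f(x), an all-zeros mask reproduces f(x_b). The reported
`variance_retained` is 1 − MSE(hard mask at 0.5)/Var(target). Replicate runs
differ only in mask noise; averaging replicate scores reduces their variance,
so the averaged scores correlate across repeats at least as well as raw ones.

## Viability head and prioritization

Cell viability in [0, 1] is modeled as Beta(a, b) with (a, b) predicted from
the *frozen* expression model's output by a single linear layer per ensemble
member through softplus(·) + 1e-6; members differ in initialization and data
order and are mixed uniformly. Training minimizes the Beta negative
log-likelihood with labels clipped into (1e-4, 1 − 1e-4).

For prioritization, p_sens(drug) = P(mean viability over target lines <
mean viability over background lines), estimated by Monte Carlo: each round
samples one ensemble member per line and one Beta draw from it. Draws are
seeded per (seed, line), so swapping target and background sets maps p_sens
to exactly 1 − p_sens. Rankings sort by p_sens (ties broken by drug name) and
are evaluated against indication labels by AUROC with a permutation null
(p = fraction of `n_null` score permutations with AUROC ≥ observed). The
ranking dose defaults to 1 μM (transformed value ≈ 1); the dose is a free
parameter of the analysis, not of the method.

## Synthetic data: what it emulates and what it does not

The generator emits interaction tables (drug→protein, PPI with cycles,
TF→RNA, miRNA→RNA, RNA→protein translation, two overlapping pathway labels),
per-cell standardized 'omic values, and responses simulated through a known
graph: every function node computes tanh(Σ w·inputs) with fixed random
weights (magnitudes near 1 so signal survives several hops), states update
synchronously for 10 steps (cycles unrolled, matching the depth regime the
model is used in), and Gaussian noise (σ = 0.1 by default) is added to
outputs. Cellular context enters through the 'omic inputs, so responses are
cell-dependent. This reproduces the *shape* of perturbation data — graded
log-dose response, context modulation, pathway-local signal flow — but not
the noise structure, scale, or topology of any real assay; passing tests
demonstrate correctness and recoverability of planted structure at desk
scale, not real-data performance.

Problem sizes are chosen so every harness runs on one CPU in minutes: the
default fixture has ~60 nodes and ~100 observations; the benchmark preset for
the true-vs-random comparison has ~125 nodes, ~300 edges, and 620
observations over 20 cell lines and 3 doses; the planted-path instance has
13 edges and 36 observations over 12 cell lines.

Planted constructions:

* **Planted path.** Exactly one drug→protein→…→RNA→output path carries the
  drug effect; a disjoint decoy chain is driven only by 'omics. Drug-sourced
  edge weights are doubled and 'omic weights halved so the drug effect is not
  drowned by context saturation of the tanh — the instance exists to make
  recovery well-posed, and masking the planted edges to baseline removes the
  drug effect exactly, for any parameter values, by construction.
* **Planted selective drug.** The first drug's stimulus is amplified (gain 2)
  in the designated target lines and zeroed elsewhere. Mean viability is a
  logistic function of a fixed linear readout of the noiseless expression
  state, anti-aligned with the planted drug's mean response in target lines:
  expression that "looks like" the planted response drives viability down.
  A linear functional of absolute expression is used (rather than a per-cell
  response shift) because the viability head sees only predicted expression —
  a label depending on each cell's own baseline would not be identifiable
  from the head's inputs. Planted rows are clipped (target ≤ 0.30,
  background ≥ 0.70) so the selective-cytotoxicity margin ≥ 0.3 holds even
  where the simulated response is weak.

## Known limitations

* The compute core is numpy-based and single-threaded; it is sized for
  fixture-scale graphs (hundreds of edges), not genome-scale networks.
* The simulator's node functions are stateless saturating maps; it has no
  time axis, no assay artifacts, and no distribution shift between data
  sources, so calibration results on fixtures are optimistic.
* Output nodes accept exactly one regulator edge; interaction tables implying
  multiple regulators of one measured gene are rejected rather than merged.
* The explainer scores edges only; node- or feature-level attribution is out
  of scope.
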