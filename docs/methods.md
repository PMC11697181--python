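# Methods

## Model

SGCD scores each gene of an attributed interaction network with the
probability of being a cancer driver. It combines two branches before a
linear two-class head with a single log-softmax:

1. **RS graph encoder.** With `Ã = D̃^{-1/2}(A+I)D̃^{-1/2}` (D̃ = D + I;
   isolated nodes get `Ã_ii = 1`), the input projection is `r⁰ = X W⁰` and
   each of the `L` layers computes `ReLU(concat[Ã r, Ã(Ã r)])`. Concatenation
   rather than summation keeps the 1-hop and 2-hop aggregates in separate
   coordinates, which is the mechanism that avoids blurring a node's
   representation with dissimilar neighbors in heterophilic graphs. Layer
   width doubles per layer (`dim r^l = 2^l d`); each layer output is projected
   by a head matrix `W^l` to a common width `d_h` and the `L` projections are
   concatenated into `h_G` (width `L·d_h`). `Ã²` is never materialized — the
   2-hop term is two successive sparse products.
2. **Bimodal extractor.** `h_BI = α·MLP_A(A) + β·MLP_X(X)`, where each MLP has
   one ReLU hidden layer of width `d` with biases and maps to width `L·d_h`.
   `MLP_A` consumes the raw binary adjacency rows (not `Ã`), so the topology
   modality is embedded independently of message passing.

Prediction: `logp = log_softmax((h_G + h_BI) W′)`; the driver probability is
`exp(logp[:,1])`. The loss is binary cross-entropy summed over labeled genes,
evaluated as the negative log-likelihood of the class log-probabilities
(identical algebraically, stable numerically; probabilities are clamped at
1e-12 inside the standalone loss function). Unlabeled genes receive scores
but contribute no loss.

A formulation detail: applying a log-softmax both to `h_G` and again at the
prediction head would compose two log-softmaxes and break the probabilistic
reading of the loss, so the encoder applies none by default; the
`eq5_logsoftmax` config flag restores the literal stacked variant for
comparison. "Number of hops = 2" is read as L = 2 RS layers; since every
layer already mixes 1- and 2-hop aggregates, the default receptive field is
4 hops.

## Defaults

| parameter | default | meaning |
|---|---|---|
| hidden_dim d | 64 | width of `r⁰` and of MLP hidden layers |
| num_layers L | 2 | RS layers ("hops") |
| head_dim d_h | 64 | per-layer head projection width |
| alpha | 0.0204 | weight of the topology embedding `h_A` |
| beta | 0.001 | weight of the omics embedding `h_X` |
| learning_rate | 0.0149 | Adam step size |
| weight_decay | 5e-5 | L2 decay folded into the gradient |
| epochs | 30 | full-batch steps, no early stopping |

The optimizer is Adam (the optimizer itself is not pinned by the published
operating point; adaptive moments are the standard choice for this model
family). All linear maps written as bare matrix products (`W⁰`, `W^l`, `W′`)
carry no bias; the MLPs do. Initialization is Glorot-uniform, biases zero,
fully determined by the seed. Training aborts with a diagnostic if the loss
becomes non-finite.

Everything runs on a small reverse-mode autodiff engine over numpy +
scipy.sparse (`sgcd.autodiff`) written for exactly this pipeline: dense and
fixed-pattern sparse matrix products, pointwise nonlinearities, gather /
segment-sum, and row-wise log-softmax, plus an Adam implementation. Float64
throughout; the test suite checks every operation against central
differences and the whole forward pass against an independent dense,
loop-based oracle (tolerance 1e-6).

## Evaluation protocol

Labeled genes are split 75/25 with stratification (stratified k-fold CV is
available as a utility; reported metrics use the single held-out split).
Metrics: AUPRC (average precision — primary under rare positives), AUROC,
and F1/accuracy at threshold 0.5 on the driver probability. Robustness
experiments retrain a fresh model per perturbation rate and seed; feature
masking zeroes an exact count `round(rate·n·f)` of entries sampled without
replacement (a row-masking mode exists behind a flag), edge deletion removes
an exact count of undirected edges. Ablation variants: `full`; `rs_only`
(α=β=0); `rs_mlpA` (β=0); `rs_mlpX` (α=0); `bimodal_only` (graph-encoder
branch zeroed). The internal plain-GCN reference (2-layer, symmetrically
normalized sum aggregation, same training budget) exists solely as the
comparison point for heterophily experiments.

## Explainer

For gene *i*, the local computation subgraph is its 2L-hop ego network. A
raw mask value per undirected edge (tied across both directions) and per
feature dimension is optimized with Adam to minimize the negative
log-probability of the model's *own* predicted class under masked inputs,
plus regularizers: `size_coeff · Σ σ(mask)` and `entropy_coeff · mean
entropy(σ(mask))` for edges, and analogous terms for the feature mask
(defaults 0.005 / 1.0 for edges, 1.0/f / 0.1 for features; 100 steps at
learning rate 0.01, the values of the original mask-learning formulation).
The sigmoid mask multiplies the *fixed* normalized messages of the subgraph;
the masked graph is deliberately not renormalized, because renormalization
largely cancels a uniform mask shrinkage and empirically removes the
optimization's ability to discriminate edges. `MLP_A` sees full-width
adjacency rows with masked values on within-subgraph entries. For subgraphs
with on the order of 10³ edges, a stronger compression (mask learning rate
0.05, size coefficient 0.05) separates edges much more reliably and is what
the planted-edge benchmark uses.

Modules are extracted by keeping the top-k edges by mask value (default
k = 10; an absolute sigmoid threshold θ is available) and restricting to the
connected component containing the gene; if nothing survives, the module is
the singleton {gene}. Module profiles are means over module nodes of
PageRank (damping 0.85), clustering coefficient, degree centrality and
normalized betweenness, computed on the module subgraph by default (a flag
computes them on the module's nodes within the full network instead).
Singleton convention: (1, 0, 0, 0). Group consistency is operationalized as
the within-group populations of pairwise cosine similarities between
profiles compared by Welch's t-test; zero-vector profiles are excluded with
a warning. High-order modules union-merge any modules sharing at least
`min_shared` genes, transitively.

## Synthetic data

The generator emulates the shape of a pan-cancer driver-gene dataset: a
sparse undirected network with controllable edge homophily, rare positives,
and bounded per-gene features (default f = 64, min-max scaled per column).

* **Topology.** Labels are drawn at the requested prevalence; edges come from
  a two-block model whose within/between probabilities are solved in closed
  form so the expected edge homophily equals the target at the requested mean
  degree (infeasible combinations raise an error stating the feasible range).
  Realized homophily concentrates within ~0.01 of target at n = 2000.
  Optional per-node propensity weights add degree heterogeneity (off by
  default so property tests are clean).
* **Features.** The first `n_informative` (default 8) columns are
  class-conditional Gaussians with means separated by `effect_size` (default
  1.0) in units of `noise_sd` (default 1.0); the rest are noise. Defaults
  were chosen to emulate moderately separable omics summaries.
* **Planted explanations.** For explainer benchmarks, selected nodes get a
  designated neighbor rewired into a leaf carrying a high value in a
  designated feature column, and both are labeled positive (all other labels
  cleared). Adjacency to a high-signal node is then exactly equivalent to
  being planted, so the label rule is identifiable and the designated edge is
  the unique path carrying the signal. Non-leaf sources were tried first and
  rejected: their extra neighbors are negatives with high-signal neighbors,
  the rule becomes unidentifiable, and the model memorizes instead of
  learning it.

What passing tests on these fixtures do *not* show: real PPI networks have
correlated, heavy-tailed degrees, overlapping pathway structure and
feature-topology dependence that the independent two-block model lacks, and
real multi-omics features are not Gaussian. Results on the fixtures
demonstrate mechanism (heterophily handling, explanation recovery,
calibration), not clinical performance.

## Known behavior at the main study conditions

The main study fixture (n = 2000, prevalence 0.1, edge homophily 0.1, mean
degree 10, 80% of genes labeled) is *extremely* heterophilic: those two
constraints force ~90% of edges to be cross-class, which concentrates ~45
cross-edges on each positive versus ~6 on each negative. Two consequences,
both visible in the experiment output:

* Every SGCD variant with topology access saturates near test AUPRC 1.0
  (degree alone separates the classes), while the plain sum-aggregation GCN
  reaches roughly 0.6–0.8 — the heterophily advantage is large, but the
  *differences among* SGCD variants degenerate to ranking-noise ties of order
  1e-4, so the strict ablation ordering is not resolvable at these
  conditions.
* Feature masking barely moves the curve (the topology signal survives any
  feature masking rate), so the robustness curve is flat at the ceiling and
  its strict monotonicity is likewise decided by ~1e-3 noise. A flat curve
  also cannot be escaped by switching fixtures: with label-uncorrelated
  topology the RS encoder attenuates a gene's own features by ~1/(deg+1)
  (there is no pure self channel, and β = 0.001 makes `MLP_X` negligible), so
  purely feature-driven fixtures score near chance at every rate.

## Limitations

* Transductive full-batch training only; no minibatching, no GPU.
* `MLP_A`'s input width is n, so the topology branch does not transfer to
  unseen nodes and can memorize small fixtures (visible in the planted-edge
  benchmark design).
* Two classes only; per-cancer-type models and multi-class outputs are out of
  scope, as are attention/diffusion mechanisms.
* The explainer optimizes one gene at a time; batch explanation amortization
  is not implemented.
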