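# sgcd

Driver-gene prioritization on heterophilic gene–gene interaction networks
with a simplified graph neural network (SGCD), plus post-hoc dissection of
explanatory gene modules.

## The problem

Cancer driver genes are rare positives in large protein–protein interaction
(PPI) networks, and the networks are *heterophilic*: interacting genes often
belong to different classes, so the edge homophily ratio (the fraction of
edges joining same-class nodes) is low. Classical graph convolutions sum a
node's neighborhood, which blurs the representation of a node whose neighbors
mostly belong to the other class. This package implements, trains, evaluates
and explains a model built for that regime, and ships a synthetic-data
generator so every experiment runs end to end without external downloads.

## The model

Given a network with symmetric binary adjacency `A` (n genes) and per-gene
feature matrix `X ∈ R^{n×f}` (multi-omics summaries scaled to [0,1]), the
symmetrically normalized operator is

```
Ã = D̃^{-1/2} (A + I) D̃^{-1/2},   D̃ = D + I.
```

**Representation-separation (RS) encoder.** Starting from `r⁰ = X W⁰`, each
layer *concatenates* the 1-hop and 2-hop aggregates instead of summing them:

```
r^{l+1} = ReLU( [ Ã r^l , Ã(Ã r^l) ] )          (width doubles per layer)
h_G     = [ r¹W¹ , … , r^L W^L ]                 (L = 2 layers by default)
```

**Bimodal feature extractor.** Two independent 2-layer perceptrons embed each
node's raw adjacency row (topology modality) and its feature vector (omics
modality):

```
h_BI = α · MLP_A(A) + β · MLP_X(X),   α = 0.0204, β = 0.001.
```

**Prediction.** `p = log softmax( (h_G + h_BI) W′ )`, trained with summed
binary cross-entropy over labeled genes (Adam, lr 0.0149, weight decay 5e-5,
30 epochs, full batch).

**Gene modules.** For a chosen gene, continuous masks over the edges of its
local computation subgraph and over feature dimensions are optimized to keep
the model's predicted class likely while size/entropy regularizers shrink the
masks; thresholding the edge mask and keeping the connected component around
the gene yields its explanatory *gene module*, which is profiled with
PageRank, clustering coefficient, degree and betweenness centrality, and can
be merged with other modules sharing genes into high-order modules.

Because no GPU deep-learning stack is assumed, the forward/backward passes
run on a small reverse-mode autodiff engine over numpy and scipy.sparse
(`sgcd.autodiff`).

## Worked example

```
$ sgcd simulate --n 2000 --homophily 0.1 --prevalence 0.1 --seed 7 --out-dir fixture
fixture written to fixture
$ sgcd train --edges fixture/edges.tsv --features fixture/features.tsv \
             --pos fixture/pos.txt --neg fixture/neg.txt --seed 7 --out-dir run
final training loss: 0.0490
$ sgcd predict --edges fixture/edges.tsv --features fixture/features.tsv \
               --checkpoint run/model.npz --pos fixture/pos.txt \
               --neg fixture/neg.txt --out-dir run
wrote run/predictions.tsv
$ sgcd evaluate --predictions run/predictions.tsv --pos fixture/pos.txt \
                --neg fixture/neg.txt --subset run/test_genes.txt --out-dir run
{"auprc": 1.0, "auroc": 1.0, "f1": 0.9876543209876543, "acc": 0.9975}
```

The fixture is a 2000-gene network with edge homophily 0.1 and 10% positives;
training uses a stratified 75/25 split. `predictions.tsv` ranks every gene by
its driver probability; `metrics.json` holds AUPRC (the primary metric under
rare positives), AUROC, and F1/accuracy at the 0.5 threshold, here computed
on the 400 held-out test genes. At these strongly heterophilic conditions the
positive class is close to separable (see `docs/methods.md` for why), so the
held-out AUPRC is at or near 1.0, while a plain 2-layer sum-aggregation GCN
trained with the same budget reaches roughly 0.6–0.8 depending on the seed.

Other subcommands: `sgcd ablate` (architecture variants), `sgcd robustness`
(feature-masking / edge-deletion perturbation curves), `sgcd explain`
(per-gene module JSON + edge lists).

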