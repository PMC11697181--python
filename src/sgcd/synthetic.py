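"""Synthetic attributed networks with controllable edge homophily.

Emulates the data shape of a driver-gene study — a sparse undirected
gene–gene interaction network with rare positives, 64-dimensional per-gene
feature vectors min-max scaled to [0, 1] — while making the two quantities
the model cares about controllable: the edge homophily of the network and
the class separation of the features.

Edges come from a two-block stochastic block model whose within- and
between-class edge probabilities are solved analytically so that the
*expected* edge homophily equals the target at the requested prevalence and
mean degree.  Optionally, labels of selected nodes can be rewired to depend
deterministically on one designated neighbor's designated feature, planting
a known explanatory edge for explainer benchmarks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .graph_io import GeneNetwork, LabelSet, minmax_columns

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_network",
    "generate_features",
    "generate_dataset",
    "plant_explanations",
    "label_set",
    "write_fixture",
    "load_truth",
]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n: int = 2000
    prevalence: float = 0.1
    target_homophily: float = 0.1
    mean_degree: float = 10.0
    feature_dim: int = 64
    n_informative: int = 8
    effect_size: float = 1.0
    noise_sd: float = 1.0
    labeled_fraction: float = 0.8
    degree_heterogeneity: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.prevalence <= 0.5):
            raise ValueError("prevalence must be in (0, 0.5]")
        if not (0.0 <= self.target_homophily <= 1.0):
            raise ValueError("target_homophily must be in [0, 1]")
        if self.mean_degree >= self.n - 1:
            raise ValueError("mean_degree must be < n - 1")
        if not (0 <= self.n_informative <= self.feature_dim):
            raise ValueError("n_informative must be <= feature_dim")


@dataclass
class GroundTruth:
    """Complete labels plus planted explanatory structure."""

    labels: np.ndarray  # 0/1 per node
    signal_edges: list[tuple[int, int]] = field(default_factory=list)
    informative_dims: list[int] = field(default_factory=list)
    signal_dim: int | None = None
    planted_nodes: list[int] = field(default_factory=list)


def _block_probs(spec: SyntheticSpec, n_pos: int, n_neg: int) -> tuple[float, float]:
    """Solve for (p_in, p_out) giving the target expected edge homophily."""
    within_pairs = n_pos * (n_pos - 1) / 2 + n_neg * (n_neg - 1) / 2
    between_pairs = n_pos * n_neg
    total_edges = spec.n * spec.mean_degree / 2.0
    p_in = spec.target_homophily * total_edges / within_pairs
    p_out = (1.0 - spec.target_homophily) * total_edges / between_pairs
    if p_in > 1.0 or p_out > 1.0:
        h_max = within_pairs / total_edges
        h_min = 1.0 - between_pairs / total_edges
        raise ValueError(
            "infeasible homophily target: feasible range is "
            f"[{max(h_min, 0.0):.4f}, {min(h_max, 1.0):.4f}] at this n, "
            "prevalence and mean_degree"
        )
    return p_in, p_out


def _sample_pairs_within(rng, members: np.ndarray, p: float) -> list[tuple[int, int]]:
    m = members.size
    n_pairs = m * (m - 1) // 2
    if n_pairs == 0 or p <= 0:
        return []
    k = rng.binomial(n_pairs, min(p, 1.0))
    if k == 0:
        return []
    iu, ju = np.triu_indices(m, k=1)
    chosen = rng.choice(n_pairs, size=k, replace=False)
    return list(zip(members[iu[chosen]], members[ju[chosen]]))


def _sample_pairs_between(rng, a: np.ndarray, b: np.ndarray, p: float) -> list[tuple[int, int]]:
    n_pairs = a.size * b.size
    if n_pairs == 0 or p <= 0:
        return []
    k = rng.binomial(n_pairs, min(p, 1.0))
    if k == 0:
        return []
    chosen = rng.choice(n_pairs, size=k, replace=False)
    return list(zip(a[chosen // b.size], b[chosen % b.size]))


def generate_network(spec: SyntheticSpec) -> tuple[GeneNetwork, GroundTruth]:
    """Draw labels at the given prevalence and edges from the calibrated SBM."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    n_pos = int(round(spec.prevalence * n))
    labels = np.zeros(n, dtype=np.int64)
    pos_idx = rng.choice(n, size=n_pos, replace=False)
    labels[pos_idx] = 1
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    p_in, p_out = _block_probs(spec, pos.size, neg.size)

    edges: list[tuple[int, int]] = []
    edges += _sample_pairs_within(rng, pos, p_in)
    edges += _sample_pairs_within(rng, neg, p_in)
    edges += _sample_pairs_between(rng, pos, neg, p_out)

    if spec.degree_heterogeneity:
        # thin edges by per-node propensity to induce a heavy-ish tail
        w = rng.lognormal(mean=0.0, sigma=0.75, size=n)
        w /= w.mean()
        keep_p = np.clip([np.sqrt(w[u] * w[v]) for u, v in edges], 0.0, 1.0)
        keep = rng.random(len(edges)) < keep_p
        edges = [e for e, k in zip(edges, keep) if k]

    gene_ids = [f"G{i:05d}" for i in range(n)]
    if edges:
        eu = np.array([e[0] for e in edges], dtype=np.intp)
        ev = np.array([e[1] for e in edges], dtype=np.intp)
        rows = np.concatenate([eu, ev])
        cols = np.concatenate([ev, eu])
        adj = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
        adj.data[:] = 1.0
    else:
        adj = sp.csr_matrix((n, n), dtype=np.float64)
    net = GeneNetwork(gene_ids=gene_ids, adjacency=adj)
    truth = GroundTruth(labels=labels)
    return net, truth


def generate_features(network: GeneNetwork, truth: GroundTruth,
                      spec: SyntheticSpec) -> GeneNetwork:
    """Class-conditional Gaussian features, min-max rescaled to [0, 1].

    The first `n_informative` columns (recorded in the ground truth) have
    class means separated by `effect_size` (in units of `noise_sd`); the rest
    are pure noise.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n, f = network.n, spec.feature_dim
    X = rng.normal(0.0, spec.noise_sd, size=(n, f))
    info = list(range(spec.n_informative))
    X[:, info] += np.outer(truth.labels, np.full(len(info), spec.effect_size))
    network.features = minmax_columns(X)
    truth.informative_dims = info
    return network


def plant_explanations(network: GeneNetwork, truth: GroundTruth,
                       k_signal: int = 10, seed: int = 0,
                       signal_dim: int | None = None,
                       reset_labels: bool = True) -> GroundTruth:
    """Plant nodes whose positive label is caused by a single neighbor edge.

    For each planted node v a neighbor u is designated and rewired into a
    leaf attached only to v, u's entry in the signal feature column is raised
    to 1, and u and v are labeled positive; every other node's signal entry
    stays near 0.  Being adjacent to a high-signal node is then exactly
    equivalent to being a planted node, so the label rule is identifiable
    from the data, v's label is a deterministic function of u's signal
    feature exceeding 0.5 (zeroing it flips the label), and the (v, u) edge
    is the unique path carrying the signal — it is recorded as a ground-truth
    signal edge so explanation quality can be scored.

    With `reset_labels` (default) the block-model labels are cleared first,
    making planted pairs the only positives.  Nodes of degree 0 cannot be
    planted and are skipped with a warning.
    """
    if network.features is None:
        raise ValueError("generate features before planting explanations")
    rng = np.random.default_rng(seed)
    n = network.n
    dim = int(signal_dim) if signal_dim is not None else network.f - 1
    adj = network.adjacency.tolil(copy=True)
    if reset_labels:
        truth.labels = np.zeros(n, dtype=np.int64)
    candidates = rng.permutation(n)
    planted: list[int] = []
    signal_edges: list[tuple[int, int]] = []
    used: set[int] = set()
    # background: push the signal column toward 0 so only designated
    # neighbors carry it
    network.features[:, dim] = 0.05 * rng.random(n)
    for v in candidates:
        if len(planted) == k_signal:
            break
        v = int(v)
        if v in used:
            continue
        neigh = [int(u) for u in adj.rows[v] if int(u) not in used and int(u) != v]
        # v needs a spare neighbor besides the one sacrificed as the source
        if len(neigh) < 2:
            if not adj.rows[v]:
                logger.warning("node %d has degree 0; cannot plant, skipped", v)
            continue
        u = int(rng.choice(neigh))
        for w in list(adj.rows[u]):
            if w != v:
                adj[u, w] = 0
                adj[w, u] = 0
        network.features[u, dim] = 1.0
        truth.labels[v] = 1
        truth.labels[u] = 1
        planted.append(v)
        signal_edges.append((v, u))
        used.update((v, u))
    network.adjacency = adj.tocsr()
    network.adjacency.eliminate_zeros()
    truth.signal_edges = signal_edges
    truth.planted_nodes = planted
    truth.signal_dim = dim
    return truth


def label_set(network: GeneNetwork, truth: GroundTruth,
              labeled_fraction: float, seed: int,
              always_include: list[int] | None = None) -> LabelSet:
    """Reveal a random fraction of the ground-truth labels as a LabelSet."""
    rng = np.random.default_rng(seed + 2)
    n = network.n
    k = int(round(labeled_fraction * n))
    revealed = set(int(i) for i in rng.choice(n, size=k, replace=False))
    if always_include:
        revealed.update(int(i) for i in always_include)
    pos = {network.gene_ids[i] for i in revealed if truth.labels[i] == 1}
    neg = {network.gene_ids[i] for i in revealed if truth.labels[i] == 0}
    return LabelSet(positives=pos, negatives=neg)


def generate_dataset(spec: SyntheticSpec) -> tuple[GeneNetwork, GroundTruth, LabelSet]:
    """Network + features + revealed labels in one call (no planting)."""
    net, truth = generate_network(spec)
    generate_features(net, truth, spec)
    labels = label_set(net, truth, spec.labeled_fraction, spec.seed)
    return net, truth, labels


def write_fixture(directory, network: GeneNetwork, truth: GroundTruth,
                  spec: SyntheticSpec | None = None,
                  labels: LabelSet | None = None) -> Path:
    """Write edges.tsv, features.tsv, pos.txt, neg.txt and truth.json."""
    from .graph_io import write_edge_list, write_features, write_labels

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_edge_list(d / "edges.tsv", network)
    if network.features is not None:
        write_features(d / "features.tsv", network)
    if labels is None and spec is not None:
        labels = label_set(network, truth, spec.labeled_fraction, spec.seed)
    if labels is not None:
        write_labels(d / "pos.txt", d / "neg.txt", labels)
    payload = {
        "labels": truth.labels.tolist(),
        "gene_ids": network.gene_ids,
        "signal_edges": [list(map(int, e)) for e in truth.signal_edges],
        "informative_dims": list(map(int, truth.informative_dims)),
        "signal_dim": truth.signal_dim,
        "planted_nodes": list(map(int, truth.planted_nodes)),
        "spec": asdict(spec) if spec else None,
    }
    with open(d / "truth.json", "w") as fh:
        json.dump(payload, fh)
    return d


def load_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        labels=np.asarray(payload["labels"], dtype=np.int64),
        signal_edges=[tuple(e) for e in payload["signal_edges"]],
        informative_dims=payload["informative_dims"],
        signal_dim=payload["signal_dim"],
        planted_nodes=payload["planted_nodes"],
    )
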