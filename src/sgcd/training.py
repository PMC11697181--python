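"""Training loop, splits, metrics, ablations and robustness experiments.

Training is full-batch gradient descent with Adam adaptive moments on the
summed binary cross-entropy over labeled genes, for a fixed number of epochs
(no early stopping).  Metrics follow the usual imbalanced node-classification
protocol: AUPRC (average precision) as the primary metric, AUROC, and F1 /
accuracy at a 0.5 threshold on the driver probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import autodiff as ad
from .graph_io import GeneNetwork, LabelSet, symmetric_normalize
from .model import (
    GeneScores,
    ModelConfig,
    ModelParams,
    init_params,
    model_logp,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "MetricReport",
    "PerturbationSpec",
    "stratified_split",
    "stratified_folds",
    "train_model",
    "evaluate",
    "perturb_features",
    "perturb_edges",
    "robustness_experiment",
    "ablation_run",
    "train_gcn_baseline",
    "predictions_table",
]


@dataclass
class SplitSpec:
    train_fraction: float = 0.75
    n_folds: int = 5
    stratified: bool = True  # always on
    seed: int = 0


@dataclass
class MetricReport:
    auprc: float
    auroc: float
    f1: float
    acc: float

    def as_dict(self) -> dict[str, float]:
        return {"auprc": self.auprc, "auroc": self.auroc,
                "f1": self.f1, "acc": self.acc}


@dataclass
class PerturbationSpec:
    mode: str = "feature_mask"  # or "edge_delete"
    rates: tuple[float, ...] = (0.25, 0.50, 0.75, 0.90)
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self):
        if self.mode not in ("feature_mask", "edge_delete"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if any(not 0.0 <= r <= 1.0 for r in self.rates):
            raise ValueError("rates must lie in [0, 1]")


def _sorted_labeled(labels: LabelSet) -> tuple[list[str], np.ndarray]:
    symbols = sorted(labels.labeled())
    return symbols, labels.y(symbols)


def stratified_split(labels: LabelSet, spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Deterministic stratified train/test split of the labeled symbols."""
    symbols, y = _sorted_labeled(labels)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least 2 samples per class to split")
    train, test = train_test_split(
        symbols, train_size=spec.train_fraction, stratify=y,
        random_state=spec.seed,
    )
    return list(train), list(test)


def stratified_folds(labels: LabelSet, spec: SplitSpec) -> list[tuple[list[str], list[str]]]:
    """Stratified k-fold assignments over the labeled symbols."""
    symbols, y = _sorted_labeled(labels)
    if min(np.bincount(y, minlength=2)) < spec.n_folds:
        raise ValueError("too few samples per class for the requested folds")
    skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True,
                          random_state=spec.seed)
    symbols_arr = np.array(symbols)
    return [
        (symbols_arr[tr].tolist(), symbols_arr[te].tolist())
        for tr, te in skf.split(symbols_arr, y)
    ]


def train_model(network: GeneNetwork, labels: LabelSet, config: ModelConfig,
                train_symbols: list[str] | None = None,
                variant: str = "full",
                ) -> tuple[ModelParams, list[float]]:
    """Fit SGCD by full-batch Adam on the summed BCE over training genes."""
    if network.features is None:
        raise ValueError("network features not loaded")
    if train_symbols is None:
        train_symbols = sorted(labels.labeled())
    idx = network.index_of(train_symbols)
    y = labels.y(train_symbols)
    params = init_params(config, f=network.f, n=network.n, seed=config.seed)
    history: list[float] = []
    if config.epochs == 0:
        return params, history
    A_norm = symmetric_normalize(network)
    opt = ad.Adam(params.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    onehot = _onehot(y)
    for epoch in range(config.epochs):
        opt.zero_grad()
        logp = model_logp(A_norm, network.adjacency, network.features,
                          params, config, variant=variant)
        picked = ad.gather_rows(logp, idx)
        # sum of log-probabilities of the true classes, negated
        nll = ad.scale(ad.tsum(ad.mul(picked, onehot)), -1.0)
        loss = float(nll.data)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"NaN/inf loss at epoch {epoch}; check inputs and learning rate"
            )
        nll.backward()
        opt.step()
        history.append(loss)
    return params, history


def _onehot(y: np.ndarray) -> np.ndarray:
    out = np.zeros((y.size, 2))
    out[np.arange(y.size), y] = 1.0
    return out


def score_network(network: GeneNetwork, params: ModelParams,
                  config: ModelConfig, variant: str = "full") -> GeneScores:
    A_norm = symmetric_normalize(network)
    logp = model_logp(A_norm, network.adjacency, network.features,
                      params, config, variant=variant)
    return GeneScores(logp=logp.data)


def evaluate(driver_prob: np.ndarray, truth: np.ndarray) -> MetricReport:
    """Metric report for probability scores against 0/1 ground truth."""
    truth = np.asarray(truth, dtype=np.int64)
    driver_prob = np.asarray(driver_prob, dtype=np.float64)
    if truth.min() == truth.max():
        raise ValueError("evaluation requires both classes in the test set")
    pred = (driver_prob >= 0.5).astype(np.int64)
    return MetricReport(
        auprc=float(average_precision_score(truth, driver_prob)),
        auroc=float(roc_auc_score(truth, driver_prob)),
        f1=float(f1_score(truth, pred, zero_division=0)),
        acc=float(accuracy_score(truth, pred)),
    )


def train_and_evaluate(network: GeneNetwork, labels: LabelSet,
                       config: ModelConfig, split: SplitSpec,
                       variant: str = "full") -> MetricReport:
    train_syms, test_syms = stratified_split(labels, split)
    params, _ = train_model(network, labels, config, train_syms, variant=variant)
    scores = score_network(network, params, config, variant=variant)
    test_idx = network.index_of(test_syms)
    return evaluate(scores.driver_prob[test_idx], labels.y(test_syms))


def perturb_features(X: np.ndarray, rate: float, seed: int,
                     row_mask: bool = False) -> np.ndarray:
    """Zero exactly round(rate * count) entries (or rows), without replacement."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = X.copy()
    if row_mask:
        k = int(round(rate * X.shape[0]))
        rows = rng.choice(X.shape[0], size=k, replace=False)
        out[rows] = 0.0
    else:
        k = int(round(rate * X.size))
        flat = rng.choice(X.size, size=k, replace=False)
        out.flat[flat] = 0.0
    return out


def perturb_edges(network: GeneNetwork, rate: float, seed: int) -> GeneNetwork:
    """Delete exactly round(rate * |E|) undirected edges; node set unchanged."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = network.edge_array()
    m = edges.shape[0]
    k = int(round(rate * m))
    keep = np.ones(m, dtype=bool)
    if k:
        keep[rng.choice(m, size=k, replace=False)] = False
    kept = edges[keep]
    n = network.n
    if kept.size:
        rows = np.concatenate([kept[:, 0], kept[:, 1]])
        cols = np.concatenate([kept[:, 1], kept[:, 0]])
        adj = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    else:
        adj = sp.csr_matrix((n, n), dtype=np.float64)
    return GeneNetwork(gene_ids=list(network.gene_ids), adjacency=adj,
                       features=None if network.features is None
                       else network.features.copy())


def robustness_experiment(network: GeneNetwork, labels: LabelSet,
                          config: ModelConfig, pspec: PerturbationSpec,
                          split: SplitSpec | None = None) -> pd.DataFrame:
    """Train and evaluate a fresh model per (rate, seed); rate 0 is included."""
    split = split or SplitSpec(seed=config.seed)
    rates = sorted(set([0.0, *pspec.rates]))
    rows = []
    for rate in rates:
        for seed in pspec.seeds:
            net = network
            if rate > 0:
                if pspec.mode == "feature_mask":
                    net = GeneNetwork(
                        gene_ids=list(network.gene_ids),
                        adjacency=network.adjacency.copy(),
                        features=perturb_features(network.features, rate, seed),
                    )
                else:
                    net = perturb_edges(network, rate, seed)
                    net.features = network.features.copy()
            cfg = ModelConfig(**{**config.__dict__, "seed": seed})
            report = train_and_evaluate(net, labels, cfg,
                                        SplitSpec(seed=seed, n_folds=split.n_folds,
                                                  train_fraction=split.train_fraction))
            rows.append({"mode": pspec.mode, "rate": rate, "seed": seed,
                         **report.as_dict()})
    return pd.DataFrame(rows)


def ablation_run(network: GeneNetwork, labels: LabelSet, config: ModelConfig,
                 variant: str, split: SplitSpec | None = None) -> MetricReport:
    """Train and evaluate one architectural variant.

    rs_only drops the bimodal extractor (alpha = beta = 0); rs_mlpA keeps
    only the topology perceptron; rs_mlpX only the omics perceptron;
    bimodal_only zeroes the graph-encoder branch; full uses everything.
    """
    from .model import VARIANTS

    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; one of {sorted(VARIANTS)}")
    split = split or SplitSpec(seed=config.seed)
    return train_and_evaluate(network, labels, config, split, variant=variant)


# ---------------------------------------------------------------------------
# Internal plain-GCN baseline.  A standard 2-layer symmetric-normalized
# sum-aggregation network used only as a reference point in heterophily
# experiments; it is not any published model.
# ---------------------------------------------------------------------------

def _gcn_logp(A_norm_op, X, W1, b1, W2) -> ad.Tensor:
    h = ad.relu(ad.add(A_norm_op.matmul(ad.matmul(X, W1)), b1))
    return ad.log_softmax(A_norm_op.matmul(ad.matmul(h, W2)))


def train_gcn_baseline(network: GeneNetwork, labels: LabelSet,
                       config: ModelConfig,
                       train_symbols: list[str] | None = None,
                       ) -> tuple[GeneScores, list[float]]:
    """Train the internal vanilla GCN with the same budget; return all scores."""
    from .model import SparseOperator, _glorot

    if train_symbols is None:
        train_symbols = sorted(labels.labeled())
    idx = network.index_of(train_symbols)
    y = labels.y(train_symbols)
    rng = np.random.default_rng(config.seed)
    d = config.hidden_dim
    W1 = ad.Tensor(_glorot(rng, network.f, d), requires_grad=True)
    b1 = ad.Tensor(np.zeros(d), requires_grad=True)
    W2 = ad.Tensor(_glorot(rng, d, 2), requires_grad=True)
    op = SparseOperator.from_scipy(symmetric_normalize(network).matrix)
    X = network.features
    opt = ad.Adam([W1, b1, W2], lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    history: list[float] = []
    onehot = _onehot(y)
    for _ in range(config.epochs):
        opt.zero_grad()
        logp = _gcn_logp(op, X, W1, b1, W2)
        picked = ad.gather_rows(logp, idx)
        nll = ad.scale(ad.tsum(ad.mul(picked, onehot)), -1.0)
        history.append(float(nll.data))
        nll.backward()
        opt.step()
    logp = _gcn_logp(op, X, W1, b1, W2)
    return GeneScores(logp=logp.data), history


def predictions_table(network: GeneNetwork, scores: GeneScores,
                      labels: LabelSet | None = None) -> pd.DataFrame:
    """gene, driver_prob, rank (1 = highest), label (1/0/NA)."""
    prob = scores.driver_prob
    order = np.argsort(-prob, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, len(order) + 1)
    lab = []
    for g in network.gene_ids:
        if labels is None:
            lab.append(pd.NA)
        elif g in labels.positives:
            lab.append(1)
        elif g in labels.negatives:
            lab.append(0)
        else:
            lab.append(pd.NA)
    return pd.DataFrame({
        "gene": network.gene_ids,
        "driver_prob": prob,
        "rank": rank,
        "label": pd.array(lab, dtype="Int64"),
    })
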