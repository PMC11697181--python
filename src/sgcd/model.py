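"""The SGCD forward computation.

Two branches are combined additively before a linear prediction head:

* a graph encoder whose layers perform *representation separation* (RS):
  each layer concatenates the 1-hop aggregate ``A~ r`` and the 2-hop
  aggregate ``A~ (A~ r)`` instead of summing them, so that in heterophilic
  networks dissimilar neighbors do not blur the central node's embedding
  (layer width doubles per layer);
* a bimodal feature extractor: two independent 2-layer perceptrons embedding
  each node's raw adjacency row (topology modality, ``MLP_A``) and its omics
  feature vector (``MLP_X``), combined as ``alpha * h_A + beta * h_X``.

A single log-softmax is applied at the prediction head so that the two-class
log-probabilities are well defined for the binary cross-entropy loss; the
``eq5_logsoftmax`` flag additionally applies a log-softmax to the graph
encoder output for comparison with the literal stacked formulation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor
from .graph_io import GeneNetwork, LabelSet, NormalizedAdjacency, symmetric_normalize

__all__ = [
    "ModelConfig",
    "ModelParams",
    "GeneScores",
    "SparseOperator",
    "init_params",
    "rs_layer",
    "graph_encoder",
    "bimodal_extract",
    "predict",
    "predict_logp",
    "model_logp",
    "bce_loss",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
    "VARIANTS",
]

CHECKPOINT_SCHEMA = 1

# ablation variants: (use graph-encoder branch, use alpha, use beta)
VARIANTS = {
    "full": (True, True, True),
    "rs_only": (True, False, False),
    "rs_mlpA": (True, True, False),
    "rs_mlpX": (True, False, True),
    "bimodal_only": (False, True, True),
}


@dataclass
class ModelConfig:
    """Hyperparameters of SGCD.

    Defaults are the published operating point: hidden dimension 64, two RS
    layers ("hops"), topology coefficient alpha = 0.0204, omics coefficient
    beta = 0.001, learning rate 0.0149, weight decay 5e-5, 30 epochs.
    """

    hidden_dim: int = 64
    num_layers: int = 2
    head_dim: int = 64
    alpha: float = 0.0204
    beta: float = 0.001
    learning_rate: float = 0.0149
    weight_decay: float = 5e-5
    epochs: int = 30
    seed: int = 0
    eq5_logsoftmax: bool = False

    def __post_init__(self):
        if min(self.hidden_dim, self.num_layers, self.head_dim) < 1:
            raise ValueError("hidden_dim, num_layers, head_dim must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")


@dataclass
class GeneScores:
    """Per-gene two-class log-probabilities and driver probability."""

    logp: np.ndarray  # (n, 2)

    @property
    def driver_prob(self) -> np.ndarray:
        return np.exp(self.logp[:, 1])


@dataclass
class ModelParams:
    """All trainable matrices, keyed by name.

    Shape ledger (f features, d hidden, d_h head width, L layers, n nodes):
    W0 (f, d); W{l} (2^l * d, d_h) for l = 1..L; MLP_A n -> d -> L*d_h;
    MLP_X f -> d -> L*d_h; Wprime (L*d_h, 2).
    """

    tensors: dict[str, Tensor]
    n: int
    f: int
    config: ModelConfig = field(repr=False, default=None)

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def parameters(self) -> list[Tensor]:
        return list(self.tensors.values())

    def copy(self) -> "ModelParams":
        t = {k: Tensor(v.data.copy(), requires_grad=v.requires_grad)
             for k, v in self.tensors.items()}
        return ModelParams(tensors=t, n=self.n, f=self.f, config=self.config)


class SparseOperator:
    """A sparse matrix with a fixed pattern and (optionally) tensor values."""

    def __init__(self, rows, cols, shape, vals):
        self.rows = np.asarray(rows, dtype=np.intp)
        self.cols = np.asarray(cols, dtype=np.intp)
        self.shape = tuple(shape)
        self.vals = vals  # ndarray or Tensor

    @classmethod
    def from_scipy(cls, m) -> "SparseOperator":
        coo = m.tocoo()
        return cls(coo.row, coo.col, m.shape, coo.data.astype(np.float64))

    def matmul(self, x) -> Tensor:
        return ad.spmm(self.rows, self.cols, self.shape, self.vals, x)


def _as_operator(a) -> SparseOperator:
    if isinstance(a, SparseOperator):
        return a
    if isinstance(a, NormalizedAdjacency):
        return SparseOperator.from_scipy(a.matrix)
    if sp.issparse(a):
        return SparseOperator.from_scipy(a)
    return SparseOperator.from_scipy(sp.csr_matrix(np.asarray(a)))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(config: ModelConfig, f: int, n: int, seed: int | None = None) -> ModelParams:
    """Deterministic Glorot-uniform initialization; biases start at zero."""
    if f < 1 or n < 1:
        raise ValueError("f and n must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    d, dh, L = config.hidden_dim, config.head_dim, config.num_layers
    out_w = L * dh
    t: dict[str, Tensor] = {}

    def par(name: str, arr: np.ndarray) -> None:
        t[name] = Tensor(arr, requires_grad=True)

    par("W0", _glorot(rng, f, d))
    for layer in range(1, L + 1):
        par(f"W{layer}", _glorot(rng, (2**layer) * d, dh))
    par("A_W1", _glorot(rng, n, d))
    par("A_b1", np.zeros(d))
    par("A_W2", _glorot(rng, d, out_w))
    par("A_b2", np.zeros(out_w))
    par("X_W1", _glorot(rng, f, d))
    par("X_b1", np.zeros(d))
    par("X_W2", _glorot(rng, d, out_w))
    par("X_b2", np.zeros(out_w))
    par("Wprime", _glorot(rng, out_w, 2))
    return ModelParams(tensors=t, n=n, f=f, config=config)


def rs_layer(A_norm, r) -> Tensor:
    """One representation-separation layer: ReLU(concat([A~ r, A~^2 r])).

    The 2-hop term is computed as two successive sparse products; the square
    of the normalized adjacency is never materialized.  Output width is twice
    the input width.
    """
    op = _as_operator(A_norm)
    r = ad.as_tensor(r)
    if op.shape[1] != r.shape[0]:
        raise ValueError(
            f"dimension mismatch: operator expects {op.shape[1]} rows, "
            f"got {r.shape[0]}"
        )
    r1 = op.matmul(r)
    r2 = op.matmul(r1)
    return ad.relu(ad.concat([r1, r2], axis=1))


def graph_encoder(A_norm, X, params: ModelParams, config: ModelConfig) -> Tensor:
    """Concatenated per-layer head projections of the RS stack.

    r^(0) = X W0; each RS layer doubles the width; layer l output is
    projected by W^(l) to head_dim and the L projections are concatenated.
    """
    if config.num_layers < 1:
        raise ValueError("num_layers must be >= 1")
    op = _as_operator(A_norm)
    r = ad.matmul(X, params["W0"])
    heads = []
    for layer in range(1, config.num_layers + 1):
        r = rs_layer(op, r)
        heads.append(ad.matmul(r, params[f"W{layer}"]))
    h_G = ad.concat(heads, axis=1)
    if config.eq5_logsoftmax:
        h_G = ad.log_softmax(h_G)
    return h_G


def bimodal_extract(A, X, params: ModelParams, config: ModelConfig,
                    use_alpha: bool = True, use_beta: bool = True) -> Tensor:
    """alpha * MLP_A(adjacency rows) + beta * MLP_X(feature rows).

    `A` is the raw binary adjacency (not the normalized operator).  Both
    perceptrons have one ReLU hidden layer of width hidden_dim and biases.
    """
    alpha = config.alpha if use_alpha else 0.0
    beta = config.beta if use_beta else 0.0
    n_rows = ad.as_tensor(X).shape[0]
    terms = []
    if alpha != 0.0:
        op = _as_operator(A)
        hidden = ad.relu(ad.add(op.matmul(params["A_W1"]), params["A_b1"]))
        h_A = ad.add(ad.matmul(hidden, params["A_W2"]), params["A_b2"])
        terms.append(ad.scale(h_A, alpha))
    if beta != 0.0:
        hidden = ad.relu(ad.add(ad.matmul(X, params["X_W1"]), params["X_b1"]))
        h_X = ad.add(ad.matmul(hidden, params["X_W2"]), params["X_b2"])
        terms.append(ad.scale(h_X, beta))
    if not terms:
        width = params["Wprime"].shape[0]
        return Tensor(np.zeros((n_rows, width)))
    out = terms[0]
    for t in terms[1:]:
        out = ad.add(out, t)
    return out


def predict_logp(h_G, h_BI, params: ModelParams) -> Tensor:
    """Log-softmax over the two-class output of (h_G + h_BI) W'."""
    h_G, h_BI = ad.as_tensor(h_G), ad.as_tensor(h_BI)
    if h_G.shape != h_BI.shape:
        raise ValueError(f"shape mismatch: h_G {h_G.shape} vs h_BI {h_BI.shape}")
    logits = ad.matmul(ad.add(h_G, h_BI), params["Wprime"])
    return ad.log_softmax(logits)


def predict(h_G, h_BI, params: ModelParams) -> GeneScores:
    return GeneScores(logp=predict_logp(h_G, h_BI, params).data)


def model_logp(A_norm, A_raw, X, params: ModelParams, config: ModelConfig,
               variant: str = "full") -> Tensor:
    """Full differentiable pipeline; `variant` selects ablation branches."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; one of {sorted(VARIANTS)}")
    use_graph, use_alpha, use_beta = VARIANTS[variant]
    h_BI = bimodal_extract(A_raw, X, params, config, use_alpha, use_beta)
    if use_graph:
        h_G = graph_encoder(A_norm, X, params, config)
    else:
        h_G = Tensor(np.zeros(h_BI.shape))
    return predict_logp(h_G, h_BI, params)


def bce_loss(scores: GeneScores, y: np.ndarray, idx: np.ndarray | None = None) -> float:
    """Binary cross-entropy summed over labeled nodes.

    Computed as negative log-likelihood on the class log-probabilities (for a
    two-class softmax, log(1 - p) is exactly logp[:, 0]); probabilities are
    clamped to [1e-12, 1 - 1e-12].
    """
    y = np.asarray(y, dtype=np.int64)
    if y.size == 0:
        raise ValueError("bce_loss requires at least one labeled node")
    logp = scores.logp if idx is None else scores.logp[np.asarray(idx, dtype=np.intp)]
    if logp.shape[0] != y.size:
        raise ValueError("label vector does not match score rows")
    logp = np.maximum(logp, np.log(1e-12))
    return float(-np.sum(logp[np.arange(y.size), y]))


def forward(network: GeneNetwork, labels: LabelSet, params: ModelParams,
            config: ModelConfig, variant: str = "full") -> tuple[GeneScores, float]:
    """Score every gene and evaluate the loss over the labeled ones."""
    network.validate()
    if network.features is None:
        raise ValueError("network features not loaded")
    A_norm = symmetric_normalize(network)
    logp = model_logp(A_norm, network.adjacency, network.features, params,
                      config, variant=variant)
    scores = GeneScores(logp=logp.data)
    labeled = sorted(labels.labeled())
    idx = network.index_of(labeled)
    y = labels.y(labeled)
    return scores, bce_loss(scores, y, idx)


def save_checkpoint(path, params: ModelParams) -> None:
    """Single-file archive of all parameter matrices plus config metadata."""
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "n": params.n,
        "f": params.f,
        "config": asdict(params.config) if params.config else None,
    }
    arrays = {k: v.data for k, v in params.tensors.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> ModelParams:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema: {meta.get('schema')}")
        tensors = {k: Tensor(z[k], requires_grad=True)
                   for k in z.files if k != "__meta__"}
    cfg = ModelConfig(**meta["config"]) if meta["config"] else None
    return ModelParams(tensors=tensors, n=meta["n"], f=meta["f"], config=cfg)
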