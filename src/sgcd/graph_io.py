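"""Loading, validation and alignment of gene networks, features and labels.

Gene symbols are opaque, case-sensitive strings.  The network is an
undirected, simple graph stored as a symmetric sparse binary adjacency with a
zero diagonal; self-loops enter only inside the symmetric normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "LabelSet",
    "NormalizedAdjacency",
    "load_network",
    "load_features",
    "load_labels",
    "symmetric_normalize",
    "homophily_ratio",
    "write_edge_list",
    "write_features",
    "write_labels",
    "to_graphml",
]


@dataclass
class GeneNetwork:
    """An attributed gene–gene interaction network.

    Attributes
    ----------
    gene_ids
        Ordered unique gene symbols; row/column order of everything else.
    adjacency
        n x n symmetric binary CSR matrix with zero diagonal.
    features
        n x f float matrix in [0, 1], or ``None`` until features are loaded.
    """

    gene_ids: list[str]
    adjacency: sp.csr_matrix
    features: np.ndarray | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene symbols in gene_ids")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    @property
    def f(self) -> int:
        if self.features is None:
            raise ValueError("features not set")
        return self.features.shape[1]

    def index_of(self, symbols) -> np.ndarray:
        return np.array([self._index[s] for s in symbols], dtype=np.intp)

    def edge_array(self) -> np.ndarray:
        """Undirected edges as an (m, 2) array of indices with u < v."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return np.column_stack([coo.row, coo.col]).astype(np.intp)

    def validate(self) -> None:
        a = self.adjacency
        if a.shape != (self.n, self.n):
            raise ValueError("adjacency shape does not match gene_ids")
        if abs(a - a.T).nnz != 0:
            raise ValueError("adjacency is not symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency has nonzero diagonal")
        if self.features is not None and self.features.shape[0] != self.n:
            raise ValueError("feature rows do not match gene_ids")


@dataclass
class LabelSet:
    """Disjoint positive (driver) and negative gene symbol sets."""

    positives: set[str]
    negatives: set[str]

    def __post_init__(self):
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(
                f"positive/negative label sets overlap: {sorted(overlap)}"
            )

    def labeled(self) -> set[str]:
        return self.positives | self.negatives

    def y(self, symbols) -> np.ndarray:
        """0/1 vector over `symbols` (all of which must be labeled)."""
        out = np.empty(len(symbols), dtype=np.int64)
        for i, s in enumerate(symbols):
            if s in self.positives:
                out[i] = 1
            elif s in self.negatives:
                out[i] = 0
            else:
                raise KeyError(f"symbol {s!r} is unlabeled")
        return out


@dataclass
class NormalizedAdjacency:
    """The symmetrically normalized operator D~^{-1/2} (A + I) D~^{-1/2}."""

    matrix: sp.csr_matrix


class EdgeListParseError(ValueError):
    pass


def load_network(edge_list_path, min_confidence: float | None = None) -> GeneNetwork:
    """Read a 2-3 column edge list into an undirected simple graph.

    Columns are whitespace/tab separated: gene_a, gene_b and an optional
    numeric confidence.  Lines starting with '#' are skipped.  Reversed and
    duplicate pairs collapse to one undirected edge; self-edges are
    discarded.  When `min_confidence` is given, rows with confidence below it
    are dropped before the graph is built.
    """
    edges: dict[tuple[str, str], None] = {}
    with open(edge_list_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise EdgeListParseError(
                    f"{edge_list_path}: line {lineno}: expected >=2 columns"
                )
            a, b = parts[0], parts[1]
            if min_confidence is not None:
                if len(parts) < 3:
                    raise EdgeListParseError(
                        f"{edge_list_path}: line {lineno}: confidence column "
                        "required when min_confidence is set"
                    )
                try:
                    conf = float(parts[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"{edge_list_path}: line {lineno}: bad confidence "
                        f"{parts[2]!r}"
                    ) from exc
                if conf < min_confidence:
                    continue
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            edges.setdefault(key, None)
    if not edges:
        raise ValueError(f"{edge_list_path}: no edges after filtering")
    # first-appearance order of endpoints of kept edges
    gene_ids: list[str] = []
    seen: set[str] = set()
    for a, b in edges:
        for g in (a, b):
            if g not in seen:
                seen.add(g)
                gene_ids.append(g)
    index = {g: i for i, g in enumerate(gene_ids)}
    rows, cols = [], []
    for a, b in edges:
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
    n = len(gene_ids)
    adj = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    return GeneNetwork(gene_ids=gene_ids, adjacency=adj)


def load_features(table_path, network: GeneNetwork, apply_minmax: bool = True) -> GeneNetwork:
    """Attach per-gene features from a TSV/CSV table (header, symbol first).

    Rows are aligned to ``network.gene_ids``; network genes absent from the
    table receive zero vectors (logged).  Table genes absent from the network
    are ignored.  With `apply_minmax`, each feature column is rescaled to
    [0, 1]; constant columns map to 0.
    """
    df = pd.read_csv(table_path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{table_path}: feature table must have f >= 1 columns")
    symbols = df.iloc[:, 0].astype(str).tolist()
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{table_path}: non-numeric feature cell: {exc}") from exc
    f = values.shape[1]
    X = np.zeros((network.n, f), dtype=np.float64)
    present = np.zeros(network.n, dtype=bool)
    for sym, row in zip(symbols, values):
        idx = network._index.get(sym)
        if idx is not None:
            X[idx] = row
            present[idx] = True
    n_missing = int((~present).sum())
    if n_missing:
        logger.warning(
            "%d network genes missing from feature table; filled with zeros",
            n_missing,
        )
    if apply_minmax:
        X = minmax_columns(X)
    network.features = X
    return network


def minmax_columns(X: np.ndarray) -> np.ndarray:
    """Column-wise (x - min) / (max - min); constant columns map to 0."""
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    rng = hi - lo
    out = np.zeros_like(X, dtype=np.float64)
    nz = rng > 0
    out[:, nz] = (X[:, nz] - lo[nz]) / rng[nz]
    return out


def load_labels(pos_path, neg_path, network: GeneNetwork) -> LabelSet:
    """Read positive/negative gene lists (one symbol per line) and align."""

    def read(path) -> set[str]:
        with open(path) as fh:
            return {ln.strip() for ln in fh if ln.strip()}

    pos, neg = read(pos_path), read(neg_path)
    overlap = pos & neg
    if overlap:
        raise ValueError(f"labels overlap between files: {sorted(overlap)}")
    known = set(network.gene_ids)
    dropped = len(pos - known) + len(neg - known)
    if dropped:
        logger.warning("%d labeled symbols absent from the network; dropped", dropped)
    return LabelSet(positives=pos & known, negatives=neg & known)


def symmetric_normalize(network: GeneNetwork) -> NormalizedAdjacency:
    """A~ = D~^{-1/2} (A + I) D~^{-1/2} with D~ = D + I.

    Isolated nodes get A~_ii = 1.
    """
    n = network.n
    a_hat = network.adjacency + sp.identity(n, format="csr")
    deg = np.asarray(a_hat.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return NormalizedAdjacency(matrix=(D @ a_hat @ D).tocsr())


def homophily_ratio(network: GeneNetwork, labels: LabelSet) -> float:
    """Edge homophily: the same-class fraction among fully labeled edges."""
    cls: dict[int, int] = {}
    for s in labels.positives:
        cls[network._index[s]] = 1
    for s in labels.negatives:
        cls[network._index[s]] = 0
    same = total = 0
    for u, v in network.edge_array():
        cu, cv = cls.get(int(u)), cls.get(int(v))
        if cu is None or cv is None:
            continue
        total += 1
        same += int(cu == cv)
    if total == 0:
        raise ValueError("homophily ratio undefined: no fully labeled edges")
    return same / total


def write_edge_list(path, network: GeneNetwork) -> None:
    with open(path, "w") as fh:
        for u, v in network.edge_array():
            fh.write(f"{network.gene_ids[u]}\t{network.gene_ids[v]}\n")


def write_features(path, network: GeneNetwork) -> None:
    if network.features is None:
        raise ValueError("features not set")
    cols = [f"feat_{j}" for j in range(network.f)]
    df = pd.DataFrame(network.features, columns=cols)
    df.insert(0, "gene", network.gene_ids)
    df.to_csv(path, sep="\t", index=False)


def write_labels(pos_path, neg_path, labels: LabelSet) -> None:
    with open(pos_path, "w") as fh:
        fh.write("".join(f"{s}\n" for s in sorted(labels.positives)))
    with open(neg_path, "w") as fh:
        fh.write("".join(f"{s}\n" for s in sorted(labels.negatives)))


def to_graphml(path, network: GeneNetwork, labels: LabelSet | None = None) -> None:
    """Export the assembled network for external inspection."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(network.gene_ids)
    for u, v in network.edge_array():
        g.add_edge(network.gene_ids[u], network.gene_ids[v])
    if labels is not None:
        for s in network.gene_ids:
            if s in labels.positives:
                g.nodes[s]["label"] = 1
            elif s in labels.negatives:
                g.nodes[s]["label"] = 0
    nx.write_graphml(g, path)
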