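"""Post-hoc explanation of gene predictions and gene-module dissection.

For a chosen gene, continuous masks over the edges of its local computation
subgraph and over the feature dimensions are optimized so that the masked
inputs still yield the model's own predicted class with high probability,
under size and entropy regularizers that push the masks toward a small,
near-binary explanatory subgraph.  Thresholding the optimized edge mask and
restricting to the connected component around the gene yields its *gene
module*; modules are then profiled with standard graph metrics and merged
into high-order modules when they share genes.

The local computation subgraph is the 2L-hop ego network (each RS layer
touches two hops).  Edge masks are tied across the two directions of each
undirected interaction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cosine as cosine_distance
from scipy.stats import ttest_ind

from . import autodiff as ad
from .autodiff import Tensor
from .graph_io import GeneNetwork
from .model import ModelConfig, ModelParams, SparseOperator, model_logp
from .training import score_network

logger = logging.getLogger(__name__)

__all__ = [
    "ExplanationMask",
    "GeneModule",
    "ModuleMetricProfile",
    "explain_node",
    "extract_module",
    "module_metrics",
    "compare_module_consistency",
    "merge_modules",
    "write_module",
]


@dataclass
class ExplanationMask:
    """Optimized masks for one gene's local computation subgraph."""

    node: int  # global index of the explained gene
    sub_nodes: np.ndarray  # global indices of the ego subgraph
    edge_index: np.ndarray  # (m, 2) global undirected pairs, u < v
    edge_mask: np.ndarray  # raw (pre-sigmoid) value per undirected edge
    feature_mask: np.ndarray  # raw value per feature dimension
    target_class: int
    objective: list[float] = field(default_factory=list)

    @property
    def edge_importance(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.edge_mask))

    @property
    def feature_importance(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.feature_mask))


@dataclass
class GeneModule:
    """Thresholded connected explanatory subgraph around a center gene."""

    center: str
    nodes: set[str]
    edges: set[tuple[str, str, float]]
    theta: float | None = None
    centers: tuple[str, ...] = ()

    def gene_set(self) -> set[str]:
        return set(self.nodes)


@dataclass
class ModuleMetricProfile:
    mean_pagerank: float
    mean_clustering: float
    mean_degree_centrality: float
    mean_betweenness: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.mean_pagerank, self.mean_clustering,
                         self.mean_degree_centrality, self.mean_betweenness])


def _ego_nodes(adj, start: int, hops: int) -> np.ndarray:
    frontier = {int(start)}
    seen = {int(start)}
    for _ in range(hops):
        nxt = set()
        for u in frontier:
            nxt.update(int(v) for v in adj.indices[adj.indptr[u]:adj.indptr[u + 1]])
        nxt -= seen
        seen |= nxt
        frontier = nxt
        if not frontier:
            break
    return np.array(sorted(seen), dtype=np.intp)


def _entropy_mean(s: Tensor) -> Tensor:
    ent = ad.scale(
        ad.add(ad.mul(s, ad.log(s, eps=1e-12)),
               ad.mul(ad.sub(Tensor(np.ones(s.shape)), s),
                      ad.log(ad.sub(Tensor(np.ones(s.shape)), s), eps=1e-12))),
        -1.0,
    )
    return ad.scale(ad.tsum(ent), 1.0 / max(s.data.size, 1))


def explain_node(network: GeneNetwork, params: ModelParams, config: ModelConfig,
                 node_id, steps: int = 100, lr: float = 0.01,
                 size_coeff: float = 0.005, entropy_coeff: float = 1.0,
                 feat_size_coeff: float = 1.0, feat_entropy_coeff: float = 0.1,
                 seed: int = 0) -> ExplanationMask:
    """Optimize edge and feature masks around one gene.

    The objective is the negative log-probability of the model's own
    predicted class for the gene under masked inputs, plus mask-size and
    mask-entropy regularizers (coefficients follow the original GNNExplainer
    formulation).  The edge mask is shared between the two directions of each
    undirected interaction; the masked graph is renormalized on every step.
    """
    if network.features is None:
        raise ValueError("network features not loaded")
    center = node_id if isinstance(node_id, (int, np.integer)) \
        else network._index[node_id]
    center = int(center)
    rng = np.random.default_rng(seed)
    adj = network.adjacency.tocsr()

    # model's own prediction for the gene on the unmasked graph
    full_scores = score_network(network, params, config)
    target = int(np.argmax(full_scores.logp[center]))

    hops = 2 * config.num_layers
    sub = _ego_nodes(adj, center, hops)
    local = {int(g): i for i, g in enumerate(sub)}
    ns = sub.size
    center_local = local[center]

    sub_adj = adj[sub][:, sub].tocsr()
    sub_coo = sub_adj.tocoo()
    within = sub_coo.row < sub_coo.col
    eu = sub_coo.row[within].astype(np.intp)  # local endpoints, u < v
    ev = sub_coo.col[within].astype(np.intp)
    m_edges = eu.size
    if m_edges == 0:
        logger.warning("gene %s is isolated in its computation subgraph; "
                       "edge mask is empty", node_id)

    edge_mask = Tensor(0.1 * rng.standard_normal(m_edges), requires_grad=True)
    feat_mask = Tensor(0.1 * rng.standard_normal(network.f), requires_grad=True)

    # Fixed symmetric normalization of the subgraph; the mask multiplies the
    # normalized messages (GNNExplainer semantics) rather than triggering a
    # renormalization, so that shrinking a mask genuinely attenuates the
    # corresponding message.
    deg = np.asarray(sub_adj.sum(axis=1)).ravel() + 1.0
    c_fix = 1.0 / np.sqrt(deg)
    dir_rows = np.concatenate([eu, ev])
    dir_cols = np.concatenate([ev, eu])
    norm_fix = c_fix[dir_rows] * c_fix[dir_cols]  # A~ value per directed edge
    diag = np.arange(ns, dtype=np.intp)
    diag_fix = 1.0 / deg  # unmasked self-loop values A~_ii
    diag_tensor = Tensor(diag_fix)
    diag_col = np.arange(ns, dtype=np.intp)
    X_sub = network.features[sub]

    # MLP_A consumes full-width adjacency rows of the subgraph nodes, with
    # the mask applied to entries whose both endpoints lie in the subgraph.
    rows_csr = adj[sub].tocoo()
    a_rows = rows_csr.row.astype(np.intp)          # local row index
    a_cols = rows_csr.col.astype(np.intp)          # global column index
    in_sub = np.array([c in local for c in a_cols])
    edge_id = {}
    for k in range(m_edges):
        edge_id[(int(eu[k]), int(ev[k]))] = k
        edge_id[(int(ev[k]), int(eu[k]))] = k
    within_pos = np.flatnonzero(in_sub)
    within_ids = np.array(
        [edge_id[(int(a_rows[p]), local[int(a_cols[p])])] for p in within_pos],
        dtype=np.intp,
    )
    ones_base = np.ones(a_rows.size)

    opt = ad.Adam([edge_mask, feat_mask], lr=lr)
    history: list[float] = []
    for _ in range(max(steps, 0)):
        opt.zero_grad()
        s = ad.sigmoid(edge_mask)
        fs = ad.sigmoid(feat_mask)
        vals_dir = ad.concat([s, s], axis=0) if m_edges else Tensor(np.zeros(0))
        norm_vals = ad.mul(vals_dir, norm_fix)
        A_norm = SparseOperator(
            np.concatenate([dir_rows, diag]),
            np.concatenate([dir_cols, diag_col]),
            (ns, ns),
            ad.concat([norm_vals, diag_tensor], axis=0),
        )
        masked_row_vals = ad.scatter_into(ones_base, within_pos,
                                          ad.take(s, within_ids)) \
            if m_edges else Tensor(ones_base)
        A_raw = SparseOperator(a_rows, a_cols, (ns, network.n), masked_row_vals)
        X_masked = ad.mul(Tensor(X_sub), fs)

        logp = model_logp(A_norm, A_raw, X_masked, params, config)
        obj = ad.scale(_pick(logp, center_local, target), -1.0)
        if m_edges:
            obj = ad.add(obj, ad.scale(ad.tsum(s), size_coeff))
            obj = ad.add(obj, ad.scale(_entropy_mean(s), entropy_coeff))
        obj = ad.add(obj, ad.scale(ad.tsum(fs),
                                   feat_size_coeff / max(network.f, 1)))
        obj = ad.add(obj, ad.scale(_entropy_mean(fs), feat_entropy_coeff))
        history.append(float(obj.data))
        obj.backward()
        opt.step()

    return ExplanationMask(
        node=center,
        sub_nodes=sub,
        edge_index=np.column_stack([sub[eu], sub[ev]]).astype(np.intp)
        if m_edges else np.zeros((0, 2), dtype=np.intp),
        edge_mask=edge_mask.data.copy(),
        feature_mask=feat_mask.data.copy(),
        target_class=target,
        objective=history,
    )


def _pick(logp: Tensor, row: int, col: int) -> Tensor:
    """logp[row, col] as a length-1 tensor."""
    picked = ad.gather_rows(logp, np.array([row]))
    onehot = np.zeros((1, logp.shape[1]))
    onehot[0, col] = 1.0
    return ad.tsum(ad.mul(picked, onehot))


def extract_module(mask: ExplanationMask, network: GeneNetwork,
                   theta: float | None = None, top_k: int | None = 10) -> GeneModule:
    """Threshold the edge mask and keep the component containing the center.

    Either an absolute sigmoid threshold `theta` or a `top_k` edge count may
    be given (top-k is the default mode).  If nothing survives, the module is
    the singleton {center}.
    """
    if theta is None and top_k is None:
        raise ValueError("give theta or top_k")
    center_sym = network.gene_ids[mask.node]
    imp = mask.edge_importance
    if theta is not None:
        keep = np.flatnonzero(imp >= theta)
    else:
        k = min(top_k, imp.size)
        keep = np.argsort(-imp, kind="stable")[:k]
    g = nx.Graph()
    g.add_node(center_sym)
    for k_ in keep:
        u, v = mask.edge_index[k_]
        g.add_edge(network.gene_ids[u], network.gene_ids[v],
                   importance=float(imp[k_]))
    if center_sym not in g or g.degree(center_sym) == 0:
        comp = {center_sym}
        if imp.size:
            warnings.warn("no retained edge touches the center; "
                          "returning singleton module")
    else:
        comp = nx.node_connected_component(g, center_sym)
    edges = {
        (a, b, g.edges[a, b]["importance"])
        for a, b in g.subgraph(comp).edges
    }
    return GeneModule(center=center_sym, nodes=set(comp), edges=edges,
                      theta=theta, centers=(center_sym,))


def _module_graph(module: GeneModule, network: GeneNetwork | None,
                  within_full_network: bool) -> nx.Graph:
    if within_full_network:
        if network is None:
            raise ValueError("network required for within_full_network mode")
        g = nx.Graph()
        g.add_nodes_from(module.nodes)
        idx = network.index_of(sorted(module.nodes))
        sub = network.adjacency[idx][:, idx].tocoo()
        syms = sorted(module.nodes)
        for r, c in zip(sub.row, sub.col):
            if r < c:
                g.add_edge(syms[r], syms[c])
        return g
    g = nx.Graph()
    g.add_nodes_from(module.nodes)
    g.add_edges_from((a, b) for a, b, _ in module.edges)
    return g


def module_metrics(module: GeneModule, network: GeneNetwork | None = None,
                   within_full_network: bool = False) -> ModuleMetricProfile:
    """Mean PageRank (damping 0.85), clustering, degree and betweenness
    centrality over the module's nodes.

    Computed on the module subgraph by default, or on the module's nodes
    within the full network when `within_full_network` is set.  A singleton
    module profiles as (1, 0, 0, 0).
    """
    if not module.nodes:
        raise ValueError("empty module")
    g = _module_graph(module, network, within_full_network)
    if g.number_of_nodes() == 1:
        return ModuleMetricProfile(1.0, 0.0, 0.0, 0.0)
    pr = nx.pagerank(g, alpha=0.85)
    cl = nx.clustering(g)
    dc = nx.degree_centrality(g)
    bc = nx.betweenness_centrality(g, normalized=True)
    mean = lambda d: float(np.mean(list(d.values())))
    return ModuleMetricProfile(mean(pr), mean(cl), mean(dc), mean(bc))


def compare_module_consistency(group_a: list[ModuleMetricProfile],
                               group_b: list[ModuleMetricProfile],
                               ) -> tuple[float, float]:
    """Welch t-test between the within-group pairwise cosine similarities."""

    def similarities(group) -> np.ndarray:
        vecs = [p.as_vector() for p in group]
        kept = [v for v in vecs if np.linalg.norm(v) > 0]
        if len(kept) < len(vecs):
            warnings.warn("degenerate zero-vector profiles excluded")
        if len(kept) < 2:
            raise ValueError("need >= 2 non-degenerate profiles per group")
        sims = []
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                sims.append(1.0 - cosine_distance(kept[i], kept[j]))
        return np.array(sims)

    sa, sb = similarities(group_a), similarities(group_b)
    t, p = ttest_ind(sa, sb, equal_var=False)
    return float(t), float(p)


def merge_modules(modules: list[GeneModule], min_shared: int = 3) -> list[GeneModule]:
    """Union-merge modules sharing >= min_shared genes (transitively)."""
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    parent = list(range(len(modules)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(modules)):
        for j in range(i + 1, len(modules)):
            if len(modules[i].gene_set() & modules[j].gene_set()) >= min_shared:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(len(modules)):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        base = modules[members[0]]
        if len(members) == 1:
            out.append(base)
            continue
        nodes = set().union(*(modules[i].nodes for i in members))
        edges = set().union(*(modules[i].edges for i in members))
        centers = tuple(modules[i].center for i in members)
        out.append(GeneModule(center=base.center, nodes=nodes, edges=edges,
                              theta=base.theta, centers=centers))
    return out


def write_module(path, module: GeneModule,
                 profile: ModuleMetricProfile | None = None) -> None:
    """JSON dump of a module (plus a sibling .tsv edge list)."""
    payload = {
        "center": module.center,
        "centers": list(module.centers),
        "nodes": sorted(module.nodes),
        "edges": sorted([a, b, w] for a, b, w in module.edges),
        "theta": module.theta,
    }
    if profile is not None:
        payload["metrics"] = {
            "mean_pagerank": profile.mean_pagerank,
            "mean_clustering": profile.mean_clustering,
            "mean_degree_centrality": profile.mean_degree_centrality,
            "mean_betweenness": profile.mean_betweenness,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    tsv = str(path)
    tsv = tsv[: -len(".json")] + ".tsv" if tsv.endswith(".json") else tsv + ".tsv"
    with open(tsv, "w") as fh:
        for a, b, w in sorted(module.edges):
            fh.write(f"{a}\t{b}\t{w:.6f}\n")
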