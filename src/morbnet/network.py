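"""SVD embedding and cosine patient-similarity graph construction.

The count matrix is embedded with randomized truncated SVD (retaining the
smallest number of components whose cumulative explained variance reaches the
target, default 50%, capped at 41).  Patient similarity is the cosine between
embedded vectors; edges below the similarity threshold (default 0.35) are
dropped, each node's neighbor count is capped (#ceilnb, default 8000, weakest
edges removed first), and finally all weights are shifted so the minimum is
zero, as the MCL manual recommends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD

log = logging.getLogger(__name__)


@dataclass
class EmbeddingConfig:
    variance_target: float = 0.50
    max_components: int = 41
    svd_iterations: int = 10
    seed: int = 42

    def __post_init__(self):
        if not 0 < self.variance_target <= 1:
            raise ValueError("variance_target must be in (0, 1]")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")


@dataclass
class NetworkConfig:
    edge_threshold: float = 0.35
    neighbor_ceiling: int = 8000
    shift_to_zero: bool = True

    def __post_init__(self):
        if not -1 <= self.edge_threshold <= 1:
            raise ValueError("edge_threshold must be in [-1, 1]")
        if self.neighbor_ceiling < 1:
            raise ValueError("neighbor_ceiling must be >= 1")


class SimilarityGraph:
    """Weighted undirected patient graph stored as (u, v, w) edge arrays.

    Edges are canonical (u < v, positional indices into ``nodes``); no
    self-edges.  ``provenance`` logs the transforms applied.
    """

    def __init__(self, nodes, u, v, w, provenance=None):
        self.nodes = np.asarray(nodes)
        u = np.asarray(u, dtype=np.int64)
        v = np.asarray(v, dtype=np.int64)
        if (u == v).any():
            raise ValueError("self-edges are not allowed")
        lo, hi = np.minimum(u, v), np.maximum(u, v)
        order = np.lexsort((hi, lo))
        self.u = lo[order]
        self.v = hi[order]
        self.w = np.asarray(w, dtype=float)[order]
        self.provenance = list(provenance or [])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.w)

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(d, self.u, 1)
        np.add.at(d, self.v, 1)
        return d

    def to_csr(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency matrix."""
        n = self.n_nodes
        a = sp.coo_matrix(
            (
                np.concatenate([self.w, self.w]),
                (np.concatenate([self.u, self.v]), np.concatenate([self.v, self.u])),
            ),
            shape=(n, n),
        )
        return a.tocsr()

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(zip(self.u.tolist(), self.v.tolist(), self.w.tolist()))
        return g

    def copy(self) -> "SimilarityGraph":
        return SimilarityGraph(self.nodes, self.u, self.v, self.w, self.provenance)

    def edge_set(self) -> set:
        return set(zip(self.u.tolist(), self.v.tolist()))


def fit_embedding(m, cfg: EmbeddingConfig | None = None):
    """Randomized truncated SVD of the count matrix.

    Returns ``(embedding, explained_variance_fractions)`` where the number of
    retained components is the smallest k with cumulative explained variance
    >= ``variance_target``, capped at ``max_components`` and at
    ``min(rows, cols) - 1``.
    """
    cfg = cfg or EmbeddingConfig()
    values = m.values if hasattr(m, "values") else m
    if sp.issparse(values):
        values = values.tocsr().astype(float)
    else:
        values = np.asarray(values, dtype=float)
    rows, cols = values.shape
    if rows < 2 or cols < 2:
        raise ValueError("matrix must have at least 2 rows and 2 columns")
    nnz = values.nnz if sp.issparse(values) else np.count_nonzero(values)
    if nnz == 0:
        raise ValueError("degenerate all-zero matrix")
    k_max = min(cfg.max_components, min(rows, cols) - 1)
    svd = TruncatedSVD(
        n_components=k_max,
        algorithm="randomized",
        n_iter=cfg.svd_iterations,
        random_state=cfg.seed,
    )
    emb = svd.fit_transform(values)
    cumvar = np.cumsum(svd.explained_variance_ratio_)
    above = np.nonzero(cumvar >= cfg.variance_target)[0]
    k = int(above[0]) + 1 if len(above) else k_max
    return emb[:, :k], svd.explained_variance_ratio_[:k]


def cosine_graph(embedding, cfg: NetworkConfig | None = None, nodes=None,
                 block_size: int = 2000) -> SimilarityGraph:
    """All-pairs cosine similarity graph, thresholded.

    Edge (i, j) is present iff cosine(v_i, v_j) >= ``edge_threshold`` and
    i != j; the weight is the cosine.  Zero-norm rows produce no edges and
    remain isolated.  Computed block-wise; results are independent of the
    block size.
    """
    cfg = cfg or NetworkConfig()
    x = np.asarray(embedding, dtype=float)
    n = x.shape[0]
    if nodes is None:
        nodes = np.arange(n)
    norms = np.linalg.norm(x, axis=1)
    safe = norms > 0
    xn = np.zeros_like(x)
    xn[safe] = x[safe] / norms[safe, None]

    us, vs, ws = [], [], []
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        sims = xn[start:stop] @ xn.T
        ii, jj = np.nonzero(sims >= cfg.edge_threshold)
        gi = ii + start
        keep = gi < jj  # upper triangle only, no self-edges
        us.append(gi[keep])
        vs.append(jj[keep])
        ws.append(sims[ii[keep], jj[keep]])
    u = np.concatenate(us) if us else np.array([], dtype=int)
    v = np.concatenate(vs) if vs else np.array([], dtype=int)
    w = np.concatenate(ws) if ws else np.array([], dtype=float)
    w = np.clip(w, -1.0, 1.0)
    return SimilarityGraph(nodes, u, v, w, provenance=[f"cosine>= {cfg.edge_threshold}"])


def ceil_neighbors(g: SimilarityGraph, c: int) -> SimilarityGraph:
    """Cap each node's neighbor count at ``c`` (the #ceilnb transform).

    Nodes are processed in decreasing order of their initial degree (ties by
    node index); for a node over the ceiling, incident edges are deleted in
    increasing-weight order (ties by neighbor index) until its degree is
    <= c.  Deletion is mutual.  The result has max degree <= c.
    """
    if c < 1:
        raise ValueError("neighbor ceiling must be >= 1")
    deg = g.degrees()
    if (deg <= c).all():
        return g
    # adjacency as dict-of-dict for deterministic mutual deletion
    adj: list[dict] = [dict() for _ in range(g.n_nodes)]
    for a, b, wt in zip(g.u.tolist(), g.v.tolist(), g.w.tolist()):
        adj[a][b] = wt
        adj[b][a] = wt
    order = sorted(range(g.n_nodes), key=lambda i: (-deg[i], i))
    for node in order:
        if len(adj[node]) <= c:
            continue
        incident = sorted(adj[node].items(), key=lambda kv: (kv[1], kv[0]))
        n_drop = len(adj[node]) - c
        for nbr, _wt in incident[:n_drop]:
            del adj[node][nbr]
            del adj[nbr][node]
    u, v, w = [], [], []
    for a in range(g.n_nodes):
        for b, wt in adj[a].items():
            if a < b:
                u.append(a)
                v.append(b)
                w.append(wt)
    out = SimilarityGraph(g.nodes, u, v, w, provenance=g.provenance + [f"ceilnb {c}"])
    return out


def shift_weights(g: SimilarityGraph) -> SimilarityGraph:
    """Shift all edge weights so the minimum is 0.0 (topology unchanged)."""
    if g.n_edges == 0:
        raise ValueError("cannot shift weights of an edgeless graph")
    mn = g.w.min()
    if g.w.max() == mn:
        log.warning("uniform edge weights: shift produces all-zero weights; "
                    "clustering degenerates to connectivity")
    out = SimilarityGraph(g.nodes, g.u, g.v, g.w - mn, provenance=g.provenance + ["shift0"])
    return out


def build_similarity_graph(embedding, net_cfg: NetworkConfig | None = None, nodes=None
                           ) -> SimilarityGraph:
    """threshold -> ceilnb -> shift, in the documented order."""
    cfg = net_cfg or NetworkConfig()
    g = cosine_graph(embedding, cfg, nodes=nodes)
    g = ceil_neighbors(g, cfg.neighbor_ceiling)
    if cfg.shift_to_zero and g.n_edges > 0:
        g = shift_weights(g)
    return g


def write_abc(g: SimilarityGraph, path) -> None:
    """MCL "abc" format: tab-separated `source target weight` lines."""
    with open(path, "w") as fh:
        for a, b, wt in zip(g.u, g.v, g.w):
            fh.write(f"{g.nodes[a]}\t{g.nodes[b]}\t{wt:.10g}\n")


def read_abc(path, nodes=None) -> SimilarityGraph:
    """Read an abc edge list; ``nodes`` fixes the node universe (isolated
    nodes are otherwise unrepresentable in abc format)."""
    src, dst, wts = [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            src.append(parts[0])
            dst.append(parts[1])
            wts.append(float(parts[2]) if len(parts) > 2 else 1.0)
    if nodes is None:
        nodes = np.array(sorted(set(src) | set(dst)))
    else:
        nodes = np.asarray(nodes)
    pos = {str(n): i for i, n in enumerate(map(str, nodes))}
    u = np.array([pos[str(s)] for s in src], dtype=int)
    v = np.array([pos[str(d)] for d in dst], dtype=int)
    return SimilarityGraph(nodes, u, v, np.array(wts), provenance=["read_abc"])
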