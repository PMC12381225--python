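"""Markov Cluster (MCL) algorithm with pre-inflation and prune/select/recover.

MCL simulates flow on a graph by alternating expansion (squaring a
column-stochastic matrix) and inflation (entrywise power followed by column
renormalization).  Flow concentrates inside dense regions; the idempotent
limit matrix is block structured and clusters are read off its attractor
systems.  The implementation mirrors the mcl program's resource scheme:
entries below 1/P are pruned, at most S entries are kept per column, and if
the retained column mass falls below pct% the largest R entries of the
pre-prune column are restored.  Exact parity with the C implementation's
adaptive pruning is not promised; equivalence with a dense no-pruning
iteration is the correctness contract (and is tested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

log = logging.getLogger(__name__)


@dataclass
class MCLParams:
    pre_inflation: float = 0.5
    inflation: float = 2.0
    prune_threshold_inverse: int = 7000  # prune entries < 1/7000
    select_number: int = 800
    recover_number: int = 900
    recover_pct: float = 90.0
    max_iterations: int = 100
    convergence_tol: float = 1e-8
    add_self_loops: bool = True

    def __post_init__(self):
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.pre_inflation <= 0:
            raise ValueError("pre_inflation must be > 0")
        if self.select_number > self.recover_number:
            raise ValueError("select_number must be <= recover_number")


@dataclass
class Clustering:
    """Partition of nodes into size-ranked clusters plus an unclustered rest.

    ``assignment`` holds a cluster index per node, -1 for unclustered.  After
    :func:`finalize_clustering`, indices are size ranks (0 -> "C1", the
    largest).
    """

    node_ids: np.ndarray
    assignment: np.ndarray  # int, -1 = unclustered
    min_size_applied: int = 0
    labels: list = field(default_factory=list)  # label per cluster index

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids)
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        if len(self.node_ids) != len(self.assignment):
            raise ValueError("node_ids and assignment must align")
        if not self.labels:
            self.labels = [str(k) for k in range(self.n_clusters)]

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.max()) + 1 if (self.assignment >= 0).any() else 0

    @property
    def n_unclustered(self) -> int:
        return int((self.assignment < 0).sum())

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment[self.assignment >= 0], minlength=self.n_clusters)

    def membership_labels(self, unclustered_as_singletons: bool = True) -> np.ndarray:
        """Integer labels usable by partition metrics; unclustered nodes get
        unique labels (their own singleton clusters) when requested."""
        out = self.assignment.copy()
        if unclustered_as_singletons:
            k = self.n_clusters
            un = np.nonzero(out < 0)[0]
            out[un] = k + np.arange(len(un))
        return out

    def members(self, k: int) -> np.ndarray:
        return self.node_ids[self.assignment == k]

    def to_frame(self):
        import pandas as pd

        lab = np.array(
            [self.labels[a] if a >= 0 else "unclustered" for a in self.assignment], dtype=object
        )
        return pd.DataFrame({"patient_id": self.node_ids, "cluster": lab})


def build_stochastic_matrix(g, p: MCLParams | None = None) -> sp.csc_matrix:
    """Column-stochastic flow matrix from a similarity graph.

    Adds a self-loop per node with weight equal to the node's maximum incident
    weight (1.0 for isolated nodes), applies the pre-inflation exponent to all
    entries, and normalizes columns.  Columns that would be all-zero (a node
    whose every weight is 0 after the shift, with loops off) become absorbing
    via a unit diagonal.
    """
    p = p or MCLParams()
    a = g.to_csr().astype(float) if hasattr(g, "to_csr") else sp.csr_matrix(g, dtype=float)
    n = a.shape[0]
    if p.add_self_loops:
        max_w = np.zeros(n)
        if a.nnz:
            max_w = np.asarray(a.max(axis=0).todense()).ravel()
        loop = np.where(max_w > 0, max_w, 1.0)
        a = a + sp.diags(loop)
    t = a.tocsc()
    t.data = np.power(t.data, p.pre_inflation)
    return _normalize_columns(t)


def _normalize_columns(t: sp.csc_matrix) -> sp.csc_matrix:
    t = t.tocsc()
    sums = np.asarray(t.sum(axis=0)).ravel()
    empty = sums == 0
    if empty.any():
        # absorbing unit diagonal for empty columns
        idx = np.nonzero(empty)[0]
        t = t + sp.coo_matrix((np.ones(len(idx)), (idx, idx)), shape=t.shape).tocsc()
        sums = np.asarray(t.sum(axis=0)).ravel()
    inv = sp.diags(1.0 / sums)
    return (t @ inv).tocsc()


def _prune_columns(t: sp.csc_matrix, p: MCLParams) -> sp.csc_matrix:
    """Threshold / select / recover scheme, column by column, then renormalize."""
    t = t.tocsc()
    t.sort_indices()
    pre_mass = np.asarray(t.sum(axis=0)).ravel()
    thr = 1.0 / p.prune_threshold_inverse

    data, indices, indptr = t.data, t.indices, t.indptr
    new_data, new_indices, new_indptr = [], [], [0]
    recover_frac = p.recover_pct / 100.0
    for j in range(t.shape[1]):
        lo, hi = indptr[j], indptr[j + 1]
        col_d = data[lo:hi]
        col_i = indices[lo:hi]
        keep = col_d >= thr
        kept_d, kept_i = col_d[keep], col_i[keep]
        if len(kept_d) > p.select_number:
            order = np.argsort(-kept_d, kind="stable")[: p.select_number]
            order.sort()
            kept_d, kept_i = kept_d[order], kept_i[order]
        if pre_mass[j] > 0 and kept_d.sum() < recover_frac * pre_mass[j]:
            # restore the largest pre-prune entries, up to recover_number
            r = min(p.recover_number, len(col_d))
            order = np.argsort(-col_d, kind="stable")[:r]
            order.sort()
            kept_d, kept_i = col_d[order], col_i[order]
        new_data.append(kept_d)
        new_indices.append(kept_i)
        new_indptr.append(new_indptr[-1] + len(kept_d))
    out = sp.csc_matrix(
        (
            np.concatenate(new_data) if new_data else np.array([]),
            np.concatenate(new_indices) if new_indices else np.array([], dtype=int),
            np.array(new_indptr),
        ),
        shape=t.shape,
    )
    return _normalize_columns(out)


def mcl_iterate(t: sp.csc_matrix, p: MCLParams | None = None):
    """Run expansion/inflation with pruning to (near-)idempotence.

    Returns ``(limit_matrix, converged, n_iterations)``.  Convergence is
    max absolute entrywise change between successive iterates below
    ``convergence_tol``.
    """
    p = p or MCLParams()
    t = t.tocsc()
    converged = False
    it = 0
    for it in range(1, p.max_iterations + 1):
        prev = t
        t = (t @ t).tocsc()  # expansion
        t = _prune_columns(t, p)
        t.data = np.power(t.data, p.inflation)  # inflation
        t = _normalize_columns(t)
        t = _prune_columns(t, p)
        change = abs(t - prev).max() if (t - prev).nnz else 0.0
        if change < p.convergence_tol:
            converged = True
            break
    if not converged:
        log.warning("MCL did not converge in %d iterations", p.max_iterations)
    return t, converged, it


def mcl_iterate_dense(t, p: MCLParams | None = None):
    """Dense no-pruning reference iteration (oracle for small graphs)."""
    p = p or MCLParams()
    t = np.asarray(t.todense() if sp.issparse(t) else t, dtype=float)
    converged = False
    it = 0
    for it in range(1, p.max_iterations + 1):
        prev = t
        t = t @ t
        t = np.power(t, p.inflation)
        t = t / t.sum(axis=0, keepdims=True)
        if np.abs(t - prev).max() < p.convergence_tol:
            converged = True
            break
    return t, converged, it


def extract_clusters(limit, node_ids=None, tol: float = 1e-8) -> Clustering:
    """Read clusters off the (near-)idempotent limit matrix.

    Attractors are nodes with diagonal entry > tol; attractors sharing flow
    form one attractor system (connected components over the attractor
    submatrix); every other node joins the system receiving its largest
    flow, ties broken by the smallest attractor index in the system.
    """
    t = sp.csc_matrix(limit)
    n = t.shape[0]
    if node_ids is None:
        node_ids = np.arange(n)
    diag = t.diagonal()
    attractors = np.nonzero(diag > tol)[0]
    if len(attractors) == 0:  # degenerate; treat every node as its own cluster
        return Clustering(node_ids, np.arange(n))

    # attractor systems: connected components over flow among attractors
    sub = t[attractors][:, attractors]
    sub = (abs(sub) + abs(sub.T)) > tol
    n_sys, sys_label = connected_components(sub, directed=False)
    # canonical system order: by smallest attractor index
    first = np.full(n_sys, n)
    for a_pos, s in enumerate(sys_label):
        first[s] = min(first[s], attractors[a_pos])
    sys_rank = np.argsort(np.argsort(first, kind="stable"), kind="stable")
    sys_label = sys_rank[sys_label]

    assignment = np.full(n, -1, dtype=np.int64)
    assignment[attractors] = sys_label

    coo = t.tocoo()
    # flow of column j into each attractor system
    flow = np.zeros((0,))
    att_sys = np.full(n, -1)
    att_sys[attractors] = sys_label
    mask = att_sys[coo.row] >= 0
    rows_sys = att_sys[coo.row[mask]]
    cols = coo.col[mask]
    vals = coo.data[mask]
    n_sys_total = sys_label.max() + 1
    flow = np.zeros((n, n_sys_total))
    np.add.at(flow, (cols, rows_sys), vals)
    undecided = np.nonzero(assignment < 0)[0]
    for j in undecided:
        fj = flow[j]
        if fj.max() <= tol:
            continue  # no flow to any attractor; resolved below
        best = np.nonzero(fj == fj.max())[0]
        assignment[j] = best.min()  # system ids already ranked by smallest attractor
    # leftovers (no flow to any attractor): own singleton clusters
    leftover = np.nonzero(assignment < 0)[0]
    next_label = int(n_sys_total)
    for j in leftover:
        assignment[j] = next_label
        next_label += 1
    return Clustering(np.asarray(node_ids), assignment)


def finalize_clustering(c: Clustering, min_size: int = 500) -> Clustering:
    """Drop clusters below ``min_size`` (members flagged unclustered, not
    deleted) and relabel the rest C1..Ck by decreasing size, ties by smallest
    original cluster index."""
    sizes = c.cluster_sizes()
    keep = np.nonzero(sizes >= min_size)[0]
    order = sorted(keep, key=lambda k: (-sizes[k], k))
    remap = {old: new for new, old in enumerate(order)}
    assignment = np.array(
        [remap.get(a, -1) if a >= 0 else -1 for a in c.assignment], dtype=np.int64
    )
    labels = [f"C{i + 1}" for i in range(len(order))]
    return Clustering(c.node_ids, assignment, min_size_applied=min_size, labels=labels)


def cluster_graph(g, params: MCLParams | None = None, min_size: int = 500) -> Clustering:
    """Full MCL stage: stochastic matrix -> iterate -> extract -> finalize."""
    params = params or MCLParams()
    t = build_stochastic_matrix(g, params)
    limit, _conv, _it = mcl_iterate(t, params)
    raw = extract_clusters(limit, node_ids=getattr(g, "nodes", None), tol=params.convergence_tol)
    return finalize_clustering(raw, min_size=min_size)


def write_clustering(c: Clustering, tsv_path, mcl_path=None) -> None:
    """TSV (patient_id <tab> cluster) and optional mcl line-per-cluster file."""
    c.to_frame().to_csv(tsv_path, sep="\t", index=False)
    if mcl_path is not None:
        with open(mcl_path, "w") as fh:
            for k in range(c.n_clusters):
                fh.write("\t".join(map(str, c.members(k))) + "\n")
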