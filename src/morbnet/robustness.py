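"""Clustering robustness: graph perturbation and partition-distance metrics.

The reference clustering is compared against clusterings of perturbed graphs:
edge dilution (each edge deleted independently with probability alpha, alpha
in [0, 0.5]) and degree-preserving shuffling (double-edge swaps, preserving
the node set, edge count and exact degree sequence).  Deviation is quantified
with the variation of information VI = H(a) + H(b) - 2 I(a; b) (natural
logarithms) and van Dongen's split-join distance
d = 2n - sum_A max_B |A ∩ B| - sum_B max_A |A ∩ B|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcl import Clustering, MCLParams, cluster_graph
from .network import SimilarityGraph

log = logging.getLogger(__name__)


@dataclass
class PerturbationConfig:
    alpha_grid: tuple = (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5)
    n_replicates: int = 20
    modes: tuple = ("delete", "shuffle")
    seed: int = 0

    def __post_init__(self):
        if any(not 0 <= a <= 0.5 for a in self.alpha_grid):
            raise ValueError("alpha values must lie in [0, 0.5]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def perturb_delete(g: SimilarityGraph, alpha: float, seed: int) -> SimilarityGraph:
    """Delete each edge independently with probability alpha; nodes retained."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(g.n_edges) >= alpha
    return SimilarityGraph(
        g.nodes, g.u[keep], g.v[keep], g.w[keep],
        provenance=g.provenance + [f"delete alpha={alpha}"],
    )


def perturb_shuffle(g: SimilarityGraph, seed: int, swaps_per_edge: int = 10) -> SimilarityGraph:
    """Degree-preserving randomization via repeated double-edge swaps.

    Node set, edge count and the exact degree sequence are preserved; edge
    weights are reassigned by a random permutation of the original weight
    multiset.  Graphs admitting no valid swap are returned unchanged with a
    warning.
    """
    import networkx as nx

    if g.n_edges < 2:
        log.warning("shuffle: fewer than 2 edges, returning graph unchanged")
        return g.copy()
    rng = np.random.default_rng(seed)
    nxg = g.to_networkx()
    try:
        nx.double_edge_swap(
            nxg,
            nswap=swaps_per_edge * g.n_edges,
            max_tries=100 * swaps_per_edge * g.n_edges,
            seed=int(rng.integers(2**31)),
        )
    except nx.NetworkXError as exc:
        log.warning("shuffle: no valid swap (%s), returning graph unchanged", exc)
        return g.copy()
    except nx.NetworkXAlgorithmError:
        log.warning("shuffle: swap budget exhausted before target; using partial shuffle")
    edges = np.array(nxg.edges(), dtype=np.int64)
    w = rng.permutation(g.w)
    return SimilarityGraph(
        g.nodes, edges[:, 0], edges[:, 1], w, provenance=g.provenance + ["shuffle"]
    )


def _as_labels(c, unclustered_as_singletons: bool = True) -> np.ndarray:
    if isinstance(c, Clustering):
        return c.membership_labels(unclustered_as_singletons)
    return np.asarray(c)


def _align(a, b, restrict_common: bool = False):
    la = _as_labels(a)
    lb = _as_labels(b)
    if isinstance(a, Clustering) and isinstance(b, Clustering):
        ids_a = list(map(str, a.node_ids))
        ids_b = list(map(str, b.node_ids))
        if ids_a != ids_b:
            common = sorted(set(ids_a) & set(ids_b))
            pos_a = {n: i for i, n in enumerate(ids_a)}
            pos_b = {n: i for i, n in enumerate(ids_b)}
            la = la[[pos_a[n] for n in common]]
            lb = lb[[pos_b[n] for n in common]]
    if len(la) != len(lb):
        raise ValueError("partitions must cover the same node set")
    return la, lb


def _contingency(la: np.ndarray, lb: np.ndarray) -> np.ndarray:
    _, ia = np.unique(la, return_inverse=True)
    _, ib = np.unique(lb, return_inverse=True)
    m = np.zeros((ia.max() + 1, ib.max() + 1))
    np.add.at(m, (ia, ib), 1.0)
    return m


def variation_of_information(a, b, base: float = math.e) -> float:
    """VI between two partitions (log base configurable; default nats)."""
    la, lb = _align(a, b)
    n = len(la)
    if n == 0:
        return 0.0
    m = _contingency(la, lb) / n
    pa = m.sum(axis=1)
    pb = m.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ha = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
        hb = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
        nz = m > 0
        mi = np.sum(m[nz] * (np.log(m[nz]) - np.log(np.outer(pa, pb)[nz])))
    vi = ha + hb - 2.0 * mi
    # clip fp noise: any genuine difference on n nodes gives VI >> 1e-12
    if vi < 1e-12:
        vi = 0.0
    return float(vi / math.log(base))


def split_join_distance(a, b) -> int:
    """van Dongen split-join distance between two partitions."""
    la, lb = _align(a, b)
    n = len(la)
    if n == 0:
        return 0
    m = _contingency(la, lb)
    return int(round(2 * n - m.max(axis=1).sum() - m.max(axis=0).sum()))


@dataclass
class ComparisonResult:
    vi: float
    split_join: int
    n_common_nodes: int


def compare_clusterings(a, b) -> ComparisonResult:
    la, lb = _align(a, b)
    return ComparisonResult(
        vi=variation_of_information(la, lb),
        split_join=split_join_distance(la, lb),
        n_common_nodes=len(la),
    )


def robustness_sweep(
    g: SimilarityGraph,
    reference: Clustering,
    cfg: PerturbationConfig | None = None,
    mcl_params: MCLParams | None = None,
    min_size: int = 500,
) -> pd.DataFrame:
    """Perturb, re-cluster and compare against the reference clustering.

    Returns a long-format table (mode, alpha, replicate, vi, split_join,
    n_clusters).  Delete mode at alpha=0 leaves the graph unchanged and the
    pipeline is deterministic, so that cell is computed once and replicated.
    """
    cfg = cfg or PerturbationConfig()
    mcl_params = mcl_params or MCLParams()
    rows = []
    seed_stream = np.random.default_rng(cfg.seed)

    def run(perturbed):
        c = cluster_graph(perturbed, mcl_params, min_size=min_size)
        r = compare_clusterings(reference, c)
        return r, c

    if "delete" in cfg.modes:
        for alpha in cfg.alpha_grid:
            if alpha == 0.0:
                r, c = run(g)
                for rep in range(cfg.n_replicates):
                    rows.append(("delete", alpha, rep, r.vi, r.split_join, c.n_clusters))
                continue
            for rep in range(cfg.n_replicates):
                seed = int(seed_stream.integers(2**31))
                r, c = run(perturb_delete(g, alpha, seed))
                rows.append(("delete", alpha, rep, r.vi, r.split_join, c.n_clusters))
    if "shuffle" in cfg.modes:
        for rep in range(cfg.n_replicates):
            seed = int(seed_stream.integers(2**31))
            r, c = run(perturb_shuffle(g, seed))
            rows.append(("shuffle", float("nan"), rep, r.vi, r.split_join, c.n_clusters))
    return pd.DataFrame(
        rows, columns=["mode", "alpha", "replicate", "vi", "split_join", "n_clusters"]
    )
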