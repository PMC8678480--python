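"""Random walk with restart over the ceRNA network.

Each triplet contributes three undirected edges (lncRNA-miRNA,
miRNA-mRNA, lncRNA-mRNA); the union over triplets is a simple graph.
The walker iterates

    p <- (1 - r) * W^T p + r * p0

with W the column-normalized adjacency, p0 uniform over the seed genes
present in the network, and restart probability r (default 0.7, the
published setting). Iteration stops when the L1 change drops below the
tolerance; for graphs up to 2000 nodes the result is cross-checked
against the closed-form solve p = r (I - (1-r) W^T)^{-1} p0. The top-k
visitation probabilities (default k=30) define the hub set, ties at the
k-th value included.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cerna import CeRNATriplet

__all__ = [
    "build_network",
    "RandomWalkRestart",
    "random_walk_restart",
    "extract_hub_subnets",
]

_SOLVE_LIMIT = 2000


def build_network(triplets: list[CeRNATriplet]) -> nx.Graph:
    """Union of the three within-triplet edges over all triplets."""
    g = nx.Graph()
    for t in triplets:
        g.add_node(t.lncrna, cls="lncRNA")
        g.add_node(t.mirna, cls="miRNA")
        g.add_node(t.mrna, cls="mRNA")
        g.add_edge(t.lncrna, t.mirna)
        g.add_edge(t.mirna, t.mrna)
        g.add_edge(t.lncrna, t.mrna)
    return g


class RandomWalkRestart(BaseEstimator):
    """RWR node prioritization.

    Attributes
    ----------
    probabilities_ : Series node -> stationary visitation probability.
    ranking_ : node list, highest probability first (ties: node id).
    hubs_ : top-k node set (ties at the k-th value included).
    effective_k_ : len(hubs_), >= top_k when tied.
    n_iter_ : iterations to convergence.
    """

    def __init__(
        self,
        restart_prob: float = 0.7,
        tol: float = 1e-10,
        max_iter: int = 10_000,
        top_k: int = 30,
    ):
        self.restart_prob = restart_prob
        self.tol = tol
        self.max_iter = max_iter
        self.top_k = top_k

    def fit(self, network: nx.Graph, seeds) -> "RandomWalkRestart":
        r = self.restart_prob
        if not (0 < r <= 1):
            raise ValueError("restart_prob must be in (0, 1]")
        nodes = sorted(network.nodes)
        if not nodes:
            raise ValueError("empty network")
        index = {n: i for i, n in enumerate(nodes)}
        seeds = list(dict.fromkeys(seeds))
        inside = [s for s in seeds if s in index]
        dropped = [s for s in seeds if s not in index]
        if dropped:
            warnings.warn(f"{len(dropped)} seed(s) not in network; dropped")
        if not inside:
            raise ValueError("no seed gene overlaps the network")
        n = len(nodes)
        a = nx.to_numpy_array(network, nodelist=nodes)
        colsum = a.sum(axis=0)
        w = np.divide(a, colsum, out=np.zeros_like(a), where=colsum > 0)
        p0 = np.zeros(n)
        p0[[index[s] for s in inside]] = 1.0 / len(inside)
        # zero-degree columns would leak mass: park the walker on the
        # restart distribution instead
        dangling = colsum == 0
        p = p0.copy()
        for it in range(1, self.max_iter + 1):
            spread = w @ p + p0 * float(p[dangling].sum())
            p_new = (1 - r) * spread + r * p0
            delta = float(np.abs(p_new - p).sum())
            p = p_new
            if delta < self.tol:
                break
        self.n_iter_ = it

        if n <= _SOLVE_LIMIT:
            wd = w + np.outer(p0, dangling.astype(float))
            exact = r * np.linalg.solve(np.eye(n) - (1 - r) * wd, p0)
            if float(np.abs(exact - p).max()) > 1e-6:
                raise RuntimeError("iterative RWR diverged from the linear solve")
            self.solve_residual_ = float(np.abs(exact - p).max())

        probs = pd.Series(p, index=nodes, name="visitation_probability")
        self.probabilities_ = probs
        order = sorted(nodes, key=lambda x: (-probs[x], x))
        self.ranking_ = order
        k = min(self.top_k, n)
        threshold = probs[order[k - 1]]
        hubs = [x for x in order if probs[x] > threshold]
        hubs += [x for x in order if probs[x] == threshold]
        self.hubs_ = set(hubs)
        self.effective_k_ = len(self.hubs_)
        return self


def random_walk_restart(
    network: nx.Graph,
    seeds,
    restart_prob: float = 0.7,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    top_k: int = 30,
) -> RandomWalkRestart:
    return RandomWalkRestart(restart_prob, tol, max_iter, top_k).fit(network, seeds)


def extract_hub_subnets(
    triplets: list[CeRNATriplet], rwr: RandomWalkRestart, k: int | None = None
) -> list[list[CeRNATriplet]]:
    """Triplets fully inside the hub set, grouped into connected subnets.

    A triplet is retained when all three members are hubs (top-k by
    visitation probability; k defaults to the fitted estimator's top_k).
    Retained triplets are grouped by connected component of the network
    they induce; components are ordered by decreasing size, then by
    smallest member id.
    """
    if k is None:
        hubs = rwr.hubs_
    else:
        probs = rwr.probabilities_
        order = rwr.ranking_
        kk = min(k, len(order))
        threshold = probs[order[kk - 1]]
        hubs = {x for x in order if probs[x] >= threshold}
    kept = [t for t in triplets if {t.lncrna, t.mirna, t.mrna} <= hubs]
    if not kept:
        return []
    g = build_network(kept)
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            comp_of[node] = ci
    groups: dict[int, list[CeRNATriplet]] = {}
    for t in kept:
        groups.setdefault(comp_of[t.mirna], []).append(t)
    ordered = sorted(
        groups.values(),
        key=lambda ts: (-len({x for t in ts for x in (t.lncrna, t.mirna, t.mrna)}),
                        min(t.mirna for t in ts)),
    )
    return ordered
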