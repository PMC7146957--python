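"""Markov Clustering (MCL) of a weighted undirected similarity network.

MCL simulates flow on the graph: the column-stochastic transition matrix is
alternately *expanded* (squared — flow spreads along paths) and *inflated*
(raised entrywise to a power r > 1 and renormalized — strong flow is boosted,
weak flow starved) until the matrix is (near-)idempotent.  In the limit
matrix, *attractors* — nodes with positive diagonal mass — emerge, and the
positive entries of each attractor's row name the nodes it has captured.
The inflation exponent r is the granularity dial: larger r yields more,
smaller clusters.

The implementation is dense NumPy; inputs are GO-term networks of at most a
few thousand nodes.  Edge similarity values (not a binarized adjacency) feed
the matrix, a self-loop of weight 1.0 is added to every node for aperiodicity,
entries below a pruning floor are zeroed during inflation, and the result is
always a strict partition of the node set — every term lands in exactly one
cluster, with documented deterministic tie-breaking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import networkx as nx

log = logging.getLogger("goclust.mcl")

DEFAULT_INFLATION = 1.5
DEFAULT_SELF_LOOP = 1.0
DEFAULT_PRUNE = 1e-5
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100

_DIAG_EPS = 1e-8   # diagonal mass above this marks an attractor
_TIE_REL = 1e-9    # relative tolerance for "equal" attractor claims


class TransitionMatrix(NamedTuple):
    """Column-stochastic MCL state plus the node labels indexing it."""

    matrix: np.ndarray
    nodes: tuple


@dataclass(frozen=True)
class ClusterPartition:
    """Strict partition of network nodes: disjoint clusters covering all nodes.

    Clusters are held in a deterministic provisional order (size descending,
    then smallest member accession); final biological ordering and C-labels
    are assigned by the pipeline from gene unions.
    """

    clusters: tuple  # tuple of frozensets
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        seen: set = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster in partition")
            if seen & c:
                raise ValueError("clusters are not disjoint")
            seen |= c

    @property
    def nodes(self) -> frozenset:
        out: set = set()
        for c in self.clusters:
            out |= c
        return frozenset(out)

    def membership(self) -> dict:
        return {n: i for i, c in enumerate(self.clusters) for n in c}


def build_matrix(net: nx.Graph, self_loop: float = DEFAULT_SELF_LOOP) -> TransitionMatrix:
    """Weighted adjacency + self-loops, column-normalized to sum 1."""
    nodes = tuple(sorted(net.nodes))
    if not nodes:
        raise ValueError("network has no nodes")
    index = {n: i for i, n in enumerate(nodes)}
    M = np.zeros((len(nodes), len(nodes)))
    for u, v, data in net.edges(data=True):
        w = float(data.get("weight", 1.0))
        M[index[u], index[v]] = w
        M[index[v], index[u]] = w
    M[np.diag_indices_from(M)] += self_loop
    M /= M.sum(axis=0, keepdims=True)
    return TransitionMatrix(M, nodes)


def expand(M: np.ndarray) -> np.ndarray:
    """Expansion step: square the transition matrix (power 2)."""
    return M @ M


def inflate(M: np.ndarray, r: float, prune: float = DEFAULT_PRUNE) -> np.ndarray:
    """Inflation step: entrywise power r, prune tiny entries, renormalize."""
    if r <= 1.0:
        raise ValueError(f"inflation must be > 1, got {r}")
    out = np.power(M, r)
    out[out < prune] = 0.0
    colsum = out.sum(axis=0, keepdims=True)
    # a column can never be fully pruned: its max entry is >= 1/n >> prune,
    # but guard against pathological inputs anyway
    colsum[colsum == 0.0] = 1.0
    return out / colsum


def iterate(M: np.ndarray, inflation: float, max_iter: int = DEFAULT_MAX_ITER,
            tol: float = DEFAULT_TOL, prune: float = DEFAULT_PRUNE):
    """Alternate expand/inflate until the max absolute entry change < tol."""
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = inflate(expand(M), inflation, prune=prune)
        change = float(np.max(np.abs(new - M)))
        log.debug("mcl iteration %d: max change %.3e", it, change)
        M = new
        if change < tol:
            converged = True
            break
    if not converged:
        log.warning("MCL did not converge within %d iterations; "
                    "extracting clusters from the last iterate", max_iter)
    return M, converged, it


def extract_clusters(tm: TransitionMatrix, gene_counts: dict | None = None,
                     converged: bool = True, n_iter: int = 0) -> ClusterPartition:
    """Read a strict partition off a (near-)idempotent MCL iterate.

    Attractors are nodes with positive diagonal mass; each attractor claims
    the nodes with positive entries in its row.  A node claimed by several
    attractors goes to the one with the largest entry; exact ties go to the
    attractor whose unambiguous cluster holds more total test-set genes, and
    a remaining tie to the lexicographically smallest attractor accession.
    Unclaimed nodes (possible only in non-converged iterates) become
    singletons.
    """
    M, nodes = tm
    n = len(nodes)
    gene_counts = gene_counts or {}
    attractors = [i for i in range(n) if M[i, i] > _DIAG_EPS]

    claims: list[list] = [[] for _ in range(n)]  # per node: (weight, attractor)
    for i in attractors:
        row = M[i]
        for j in np.nonzero(row > 0.0)[0]:
            claims[j].append((float(row[j]), i))

    assigned = [-1] * n
    ambiguous = []
    for j in range(n):
        if not claims[j]:
            continue
        best = max(w for w, _ in claims[j])
        tied = [i for w, i in claims[j] if w >= best * (1.0 - _TIE_REL)]
        if len(tied) == 1:
            assigned[j] = tied[0]
        else:
            ambiguous.append((j, tied))

    totals = {i: 0 for i in attractors}
    for j, a in enumerate(assigned):
        if a >= 0:
            totals[a] += gene_counts.get(nodes[j], 0)
    for j, tied in ambiguous:
        tied.sort(key=lambda i: (-totals[i], nodes[i]))
        assigned[j] = tied[0]

    groups: dict[int, set] = {}
    for j, a in enumerate(assigned):
        if a < 0:
            groups[-(j + 1)] = {nodes[j]}  # unclaimed: singleton
        else:
            groups.setdefault(a, set()).add(nodes[j])

    clusters = sorted((frozenset(g) for g in groups.values()),
                      key=lambda c: (-len(c), min(c)))
    return ClusterPartition(tuple(clusters), converged=converged, n_iter=n_iter)


def mcl(net: nx.Graph, inflation: float = DEFAULT_INFLATION,
        max_iter: int = DEFAULT_MAX_ITER, tol: float = DEFAULT_TOL,
        self_loop: float = DEFAULT_SELF_LOOP,
        prune: float = DEFAULT_PRUNE) -> ClusterPartition:
    """Cluster ``net`` by Markov Clustering into a strict node partition."""
    if inflation <= 1.0:
        raise ValueError(f"inflation must be > 1, got {inflation}")
    tm = build_matrix(net, self_loop=self_loop)
    limit, converged, n_iter = iterate(tm.matrix, inflation, max_iter=max_iter,
                                       tol=tol, prune=prune)
    gene_counts = {
        node: len(data["term"].genes) if "term" in data else 0
        for node, data in net.nodes(data=True)
    }
    part = extract_clusters(TransitionMatrix(limit, tm.nodes),
                            gene_counts=gene_counts,
                            converged=converged, n_iter=n_iter)
    # sanity: strict partition over exactly the input nodes
    assert part.nodes == frozenset(net.nodes)
    return part
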