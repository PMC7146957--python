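"""Gene-set similarity networks over enriched GO terms.

Two GO terms are similar when their test-set gene members overlap.  The
Jaccard coefficient JC = |A∩B| / |A∪B| suits similarly sized terms; the
overlap coefficient OC = |A∩B| / min(|A|, |B|) saturates when one gene set
contains the other and is the better redundancy detector for terms of very
different sizes.  The network keeps every term as a node and stores an edge
exactly when the chosen coefficient reaches the cutoff (inclusive).

Before the network is built the term list is *trimmed*: terms annotated to
more than ``max_size`` genes in the reference annotation are too broad to
describe a specific function ("biological regulation" covers many thousands
of genes in a typical plant or animal annotation) and are removed.
"""

from __future__ import annotations

import logging
from itertools import combinations

import networkx as nx

from .enrichment import EnrichmentList

log = logging.getLogger("goclust.simnet")

METRICS = ("JC", "OC")


def jaccard(A, B) -> float:
    """|A∩B| / |A∪B| for non-empty gene sets."""
    if not A or not B:
        raise ValueError("jaccard undefined for empty gene sets")
    A, B = set(A), set(B)
    return len(A & B) / len(A | B)


def overlap_coeff(A, B) -> float:
    """|A∩B| / min(|A|, |B|) for non-empty gene sets."""
    if not A or not B:
        raise ValueError("overlap coefficient undefined for empty gene sets")
    A, B = set(A), set(B)
    return len(A & B) / min(len(A), len(B))


_METRIC_FN = {"JC": jaccard, "OC": overlap_coeff}


def similarity(A, B, metric: str = "OC") -> float:
    try:
        fn = _METRIC_FN[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}") from None
    return fn(A, B)


def trim_terms(elist: EnrichmentList, max_size: int, keep=None, graph=None) -> EnrichmentList:
    """Drop overly broad terms (n > max_size, strict), then filter namespaces.

    Terms whose source dialect carries no ``n`` cannot be judged and are kept.
    ``keep``/``graph`` forward to :func:`goclust.enrichment.filter_namespaces`.
    """
    if max_size < 1:
        raise ValueError(f"max_size must be >= 1, got {max_size}")
    kept = []
    for term in elist:
        if term.n is not None and term.n > max_size:
            log.info("trimmed %s (n=%d > %d)", term.go_id, term.n, max_size)
            continue
        kept.append(term)
    out = EnrichmentList(terms=tuple(kept), source_dialect=elist.source_dialect,
                         source_path=elist.source_path)
    if keep is not None:
        from .enrichment import filter_namespaces
        if graph is None:
            raise ValueError("namespace filtering requires an ontology graph")
        out = filter_namespaces(out, graph, keep)
    return out


def build_network(elist: EnrichmentList, metric: str = "OC",
                  cutoff: float = 0.5) -> nx.Graph:
    """All-pairs similarity graph; an edge is stored iff weight >= cutoff.

    Every term becomes a node (isolated terms stay in the graph); node
    attribute ``term`` carries the :class:`EnrichedTerm`.  Graph attributes
    ``metric`` and ``cutoff`` record how the network was built.
    """
    if metric not in _METRIC_FN:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    fn = _METRIC_FN[metric]
    G = nx.Graph(metric=metric, cutoff=cutoff)
    for term in elist:
        G.add_node(term.go_id, term=term)
    for a, b in combinations(elist, 2):
        w = fn(a.genes, b.genes)
        if w >= cutoff and w > 0.0:
            G.add_edge(a.go_id, b.go_id, weight=w)
    return G


def write_edge_table(G: nx.Graph, path, header_lines=()) -> None:
    """TAB-separated edge list: term_A, term_B, weight, metric."""
    metric = G.graph.get("metric", "?")
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("term_A\tterm_B\tweight\tmetric\n")
        for a, b, w in sorted((min(u, v), max(u, v), d["weight"])
                              for u, v, d in G.edges(data=True)):
            fh.write(f"{a}\t{b}\t{w:.6g}\t{metric}\n")
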