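"""Reconstruct the GO hierarchy restricted to one cluster's members.

Ancestor/descendant relations among the member terms are computed in the
*full* ontology (intermediate terms outside the cluster still mediate
reachability), restricted to member pairs, then transitively reduced over
the members so the drawing stays readable: an edge implied by two other
member edges is dropped.  Remaining edges are tagged ``direct`` when the
parent is an immediate parent of the child in the ontology, ``transitive``
when the connection runs only through non-member intermediates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .ontology import OntologyGraph

log = logging.getLogger("goclust.hierarchy")

DIRECT = "direct"
TRANSITIVE = "transitive"


@dataclass(frozen=True)
class ClusterHierarchy:
    """Member accessions plus (parent, child, tag) edges; a forest-shaped DAG."""

    nodes: tuple               # member accessions, sorted
    edges: tuple               # (parent, child, tag) sorted

    def tagged(self, tag: str) -> tuple:
        return tuple((p, c) for p, c, t in self.edges if t == tag)


def cluster_hierarchy(graph: OntologyGraph, members,
                      relations=("is_a",)) -> ClusterHierarchy:
    """Ancestor relation among ``members``, transitively reduced and tagged.

    ``members`` may be a :class:`goclust.pipeline.GOCluster` or any iterable
    of accessions.  Members absent from the ontology are excluded with a
    warning.
    """
    if hasattr(members, "accessions"):
        members = members.accessions
    relations = tuple(relations)

    resolved = []
    for acc in members:
        try:
            canonical = graph.resolve(acc)
        except KeyError:
            log.warning("%s not in ontology; excluded from hierarchy", acc)
            continue
        if graph.terms[canonical].obsolete:
            log.warning("%s is obsolete; excluded from hierarchy", canonical)
            continue
        resolved.append(canonical)
    resolved = sorted(set(resolved))
    mset = set(resolved)

    anc = {m: graph.ancestors(m, relations) for m in resolved}
    pairs = {(p, c) for c in resolved for p in (anc[c] & mset)}

    # transitive reduction over members only: drop (p, c) when some member m
    # sits strictly between them (p ancestor of m, m ancestor of c)
    reduced = {
        (p, c) for (p, c) in pairs
        if not any(m != p and m != c and m in anc[c] and p in anc[m]
                   for m in mset)
    }

    edges = []
    for p, c in sorted(reduced):
        term = graph.terms[c]
        immediate: set = set()
        if "is_a" in relations:
            immediate |= term.parents_is_a
        if "part_of" in relations:
            immediate |= term.parents_part_of
        tag = DIRECT if p in immediate else TRANSITIVE
        edges.append((p, c, tag))
    return ClusterHierarchy(nodes=tuple(resolved), edges=tuple(edges))
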