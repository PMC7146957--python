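"""End-to-end clustering pipeline and sub-clustering.

The full run is: resolve input terms against the ontology → trim overly broad
terms → build the thresholded gene-set-overlap network → Markov Clustering →
order clusters by the number of distinct genes they cover → pick candidate
representative terms per cluster.  Everything is deterministic: identical
inputs and parameters give byte-identical downstream outputs.

Sub-clustering re-runs trim → network → MCL on the members of selected
clusters only, typically with a tighter term-size cutoff and higher
granularity, to expose distinct functional themes hidden inside one large
cluster.  Members removed by the tighter trim are reported separately as
"not passed" rather than silently lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, asdict

import networkx as nx

from .enrichment import EnrichedTerm, EnrichmentList, filter_namespaces
from .ontology import OntologyGraph, UnknownTermError
from . import mcl_core as _mcl
from . import simnet

log = logging.getLogger("goclust.pipeline")


class EmptyRunError(ValueError):
    """No terms survive trimming/filtering."""


@dataclass(frozen=True)
class Params:
    """Full parameter record for one clustering run.

    ``metric`` — gene-set similarity coefficient, JC or OC (default OC, the
    better redundancy detector for disproportionately sized terms).
    ``cutoff`` — minimum similarity for a network edge (inclusive).
    ``inflation`` — MCL granularity; larger values give more, smaller clusters.
    ``max_size`` — trim terms annotated to more than this many genes in the
    reference annotation.
    ``namespaces`` — ontology namespaces to keep (None = all three).
    """

    metric: str = "OC"
    cutoff: float = 0.5
    inflation: float = 1.5
    max_size: int = 3500
    namespaces: tuple | None = None
    self_loop: float = _mcl.DEFAULT_SELF_LOOP
    prune: float = _mcl.DEFAULT_PRUNE
    tol: float = _mcl.DEFAULT_TOL
    max_iter: int = _mcl.DEFAULT_MAX_ITER
    seed: int = 42  # figure layout seed only; the clustering itself has no randomness

    def validate(self) -> "Params":
        if self.metric not in simnet.METRICS:
            raise ValueError(f"metric must be one of {simnet.METRICS}")
        if not (0.0 <= self.cutoff <= 1.0):
            raise ValueError(f"cutoff must be in [0, 1], got {self.cutoff}")
        if self.inflation <= 1.0:
            raise ValueError(f"inflation must be > 1, got {self.inflation}")
        if self.max_size < 1:
            raise ValueError(f"max_size must be >= 1, got {self.max_size}")
        return self

    def as_dict(self) -> dict:
        d = asdict(self)
        d["namespaces"] = list(self.namespaces) if self.namespaces else "all"
        return d


@dataclass(frozen=True)
class GOCluster:
    """One ordered, labeled cluster of enriched GO terms."""

    label: str
    members: tuple  # EnrichedTerm, sorted by (p_value, go_id)
    representatives: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.members:
            raise ValueError("cluster must have at least one member")

    @property
    def gene_union(self) -> frozenset:
        out: set = set()
        for t in self.members:
            out |= t.genes
        return frozenset(out)

    @property
    def accessions(self) -> tuple:
        return tuple(t.go_id for t in self.members)


@dataclass(frozen=True)
class ClusteringResult:
    """Ordered clusters plus the network and provenance they came from."""

    clusters: tuple  # GOCluster, ordered C1, C2, ...
    network: nx.Graph
    params: Params
    depths: dict            # go_id -> ontology depth
    ontology_version: str | None = None
    dropped: tuple = ()     # (go_id, reason) rows excluded before clustering
    trimmed: tuple = ()     # EnrichedTerm removed by the size trim

    def cluster(self, label: str) -> GOCluster:
        for c in self.clusters:
            if c.label == label:
                return c
        raise KeyError(f"no cluster labeled {label!r}")

    @property
    def terms(self) -> tuple:
        return tuple(t for c in self.clusters for t in c.members)


@dataclass(frozen=True)
class SubclusterResult:
    """Sub-groups of one parent cluster plus the terms the tighter trim removed."""

    parent_label: str
    clusters: tuple
    network: nx.Graph
    params: Params
    not_passed: tuple  # EnrichedTerm with n above the sub-run max_size


# -- ordering and representatives -------------------------------------------

def _sorted_members(terms) -> tuple:
    return tuple(sorted(terms, key=lambda t: (t.p_value, t.go_id)))


def order_clusters(partition: _mcl.ClusterPartition, terms_by_id: dict) -> tuple:
    """Sort clusters by gene-union size (desc) and assign labels C1, C2, ...

    Ties break by member count (desc), then by the smallest member accession,
    so labels are reproducible.
    """
    raw = []
    for cluster in partition.clusters:
        members = _sorted_members(terms_by_id[acc] for acc in cluster)
        union: set = set()
        for t in members:
            union |= t.genes
        raw.append((len(union), len(members), min(cluster), members))
    raw.sort(key=lambda r: (-r[0], -r[1], r[2]))
    return tuple(
        GOCluster(label=f"C{i}", members=members)
        for i, (_, _, _, members) in enumerate(raw, start=1)
    )


def select_representatives(cluster: GOCluster, net: nx.Graph) -> dict:
    """Candidate representative terms for one cluster.

    ``most_genes`` — largest test-set gene count x; ``smallest_p`` — smallest
    enrichment p-value; ``highest_degree`` — most within-cluster network
    neighbours.  One term may carry several tags.  Ties break toward smaller
    p-value, then smaller accession.
    """
    members = cluster.members
    acc_set = set(cluster.accessions)

    def degree(t):
        if t.go_id not in net:
            return 0
        return sum(1 for nb in net.neighbors(t.go_id) if nb in acc_set)

    most_genes = min(members, key=lambda t: (-t.x, t.p_value, t.go_id))
    smallest_p = min(members, key=lambda t: (t.p_value, -t.x, t.go_id))
    highest_degree = min(members, key=lambda t: (-degree(t), t.p_value, t.go_id))
    return {
        "most_genes": most_genes.go_id,
        "smallest_p": smallest_p.go_id,
        "highest_degree": highest_degree.go_id,
    }


def _attach_representatives(clusters, net) -> tuple:
    return tuple(
        replace(c, representatives=select_representatives(c, net))
        for c in clusters
    )


# -- main run ----------------------------------------------------------------

def _resolve_terms(elist: EnrichmentList, graph: OntologyGraph):
    """Canonicalize accessions, take namespaces from the ontology, drop
    unknown/obsolete terms with a warning."""
    kept, dropped = [], []
    seen: dict[str, EnrichedTerm] = {}
    for term in elist:
        try:
            canonical = graph.resolve(term.go_id)
        except UnknownTermError:
            log.warning("%s not found in ontology; dropped", term.go_id)
            dropped.append((term.go_id, "not in ontology"))
            continue
        oterm = graph.terms[canonical]
        if oterm.obsolete:
            log.warning("%s is obsolete in the ontology; dropped", canonical)
            dropped.append((term.go_id, "obsolete"))
            continue
        norm = replace(term, go_id=canonical, namespace=oterm.namespace)
        prev = seen.get(canonical)
        if prev is not None:
            # alt-id collision onto one canonical term
            keep = norm if norm.p_value < prev.p_value else prev
            log.warning("%s duplicated after alt-id resolution; kept p=%g",
                        canonical, keep.p_value)
            seen[canonical] = keep
        else:
            seen[canonical] = norm
            kept.append(canonical)
    out = EnrichmentList(terms=tuple(seen[a] for a in kept),
                         source_dialect=elist.source_dialect,
                         source_path=elist.source_path)
    return out, tuple(dropped)


def run(elist: EnrichmentList, graph: OntologyGraph,
        params: Params | None = None, **overrides) -> ClusteringResult:
    """Full clustering run: trim → similarity network → MCL → order → label."""
    params = replace(params or Params(), **overrides).validate()

    resolved, dropped = _resolve_terms(elist, graph)
    before_trim = resolved.by_id()
    trimmed_list = simnet.trim_terms(resolved, params.max_size)
    trimmed_out = tuple(before_trim[a] for a in before_trim
                        if a not in trimmed_list.by_id())
    if params.namespaces:
        trimmed_list = filter_namespaces(trimmed_list, graph, params.namespaces)
    if not len(trimmed_list):
        raise EmptyRunError(
            "no terms left after trimming/filtering; consider a larger "
            f"max_size (currently {params.max_size}) or more namespaces"
        )

    net = simnet.build_network(trimmed_list, metric=params.metric,
                               cutoff=params.cutoff)
    partition = _mcl.mcl(net, inflation=params.inflation,
                         max_iter=params.max_iter, tol=params.tol,
                         self_loop=params.self_loop, prune=params.prune)
    clusters = order_clusters(partition, trimmed_list.by_id())
    clusters = _attach_representatives(clusters, net)
    depths = {t.go_id: graph.depth(t.go_id) for t in trimmed_list}
    return ClusteringResult(
        clusters=clusters, network=net, params=params, depths=depths,
        ontology_version=graph.data_version, dropped=dropped,
        trimmed=trimmed_out,
    )


def subcluster(result: ClusteringResult, labels, graph: OntologyGraph,
               **overrides) -> dict:
    """Re-cluster the members of selected clusters into sub-groups.

    ``overrides`` may change ``max_size``, ``cutoff`` and ``inflation``
    (and any other :class:`Params` field); unset parameters are inherited
    from the parent run.  Returns ``{parent_label: SubclusterResult}`` with
    sub-groups labeled ``C<k>-1``, ``C<k>-2``, ... ordered by gene union.
    """
    if isinstance(labels, str):
        labels = [labels]
    sub_params = replace(result.params, **overrides).validate()
    out: dict[str, SubclusterResult] = {}
    for label in labels:
        parent = result.cluster(label)  # raises KeyError on unknown label
        elist = EnrichmentList(terms=_sorted_members(parent.members),
                               source_dialect="memory",
                               source_path=f"cluster:{label}")
        trimmed = simnet.trim_terms(elist, sub_params.max_size)
        passed_ids = set(trimmed.by_id())
        not_passed = tuple(t for t in parent.members if t.go_id not in passed_ids)
        if not len(trimmed):
            log.warning("%s: no members pass max_size=%d; no sub-groups",
                        label, sub_params.max_size)
            out[label] = SubclusterResult(
                parent_label=label, clusters=(), network=nx.Graph(),
                params=sub_params, not_passed=not_passed)
            continue
        net = simnet.build_network(trimmed, metric=sub_params.metric,
                                   cutoff=sub_params.cutoff)
        partition = _mcl.mcl(net, inflation=sub_params.inflation,
                             max_iter=sub_params.max_iter, tol=sub_params.tol,
                             self_loop=sub_params.self_loop,
                             prune=sub_params.prune)
        clusters = order_clusters(partition, trimmed.by_id())
        clusters = tuple(
            replace(c, label=f"{label}-{i}")
            for i, c in enumerate(clusters, start=1)
        )
        clusters = _attach_representatives(clusters, net)
        out[label] = SubclusterResult(
            parent_label=label, clusters=clusters, network=net,
            params=sub_params, not_passed=not_passed)
    return out
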