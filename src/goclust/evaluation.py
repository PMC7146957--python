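"""Cluster-quality evaluation via within-cluster similarity distributions.

A well-formed cluster has mostly high pairwise gene-set similarities between
its member terms.  For each cluster, *all* member pairs are re-scored with
the run's similarity coefficient — including pairs below the network cutoff,
so terms with no or small overlaps show up as zeros — and summarized as the
proportion of pairwise similarities at or above a threshold (default 0.5)
together with the empirical cumulative distribution for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import simnet
from .pipeline import GOCluster


@dataclass(frozen=True)
class ClusterCohesion:
    """Within-cluster pairwise similarity distribution for one cluster.

    ``p_above`` is the fraction of pairwise similarities >= ``threshold``
    (the boundary counts), or ``None`` for singleton clusters where no pair
    exists — deliberately distinct from 0 or 1.
    """

    label: str
    pairwise_sims: tuple      # sorted ascending, one value per unordered pair
    threshold: float
    metric: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairwise_sims)

    @property
    def p_above(self) -> float | None:
        if not self.pairwise_sims:
            return None
        hits = sum(1 for s in self.pairwise_sims if s >= self.threshold)
        return hits / len(self.pairwise_sims)


def cohesion(cluster: GOCluster, metric: str = "OC",
             threshold: float = 0.5) -> ClusterCohesion:
    """Recompute all pairwise member similarities and the >= threshold share."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    members = cluster.members
    sims = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            sims.append(simnet.similarity(members[i].genes, members[j].genes,
                                          metric=metric))
    return ClusterCohesion(label=cluster.label,
                           pairwise_sims=tuple(sorted(sims)),
                           threshold=threshold, metric=metric)


def cumulative_curve(coh: ClusterCohesion) -> tuple:
    """Empirical CDF as sorted (similarity, fraction <= similarity) pairs."""
    sims = coh.pairwise_sims
    if not sims:
        raise ValueError(f"cluster {coh.label} has no pairs; CDF undefined")
    n = len(sims)
    out = []
    for i, s in enumerate(sims, start=1):
        if out and out[-1][0] == s:
            out[-1] = (s, i / n)
        else:
            out.append((s, i / n))
    return tuple(out)


def evaluate_clusters(result, metric: str | None = None,
                      threshold: float = 0.5) -> tuple:
    """Cohesion of every cluster in a run, with the run's own metric by default."""
    metric = metric or result.params.metric
    return tuple(cohesion(c, metric=metric, threshold=threshold)
                 for c in result.clusters)
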