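"""Serialization and plotting of clustering results.

Every figure has a machine-readable companion table written next to it
(``<figure>.tsv``); tests and downstream scripts read the companions, never
pixels.  All tables carry ``#``-prefixed provenance header lines recording
the run parameters, the ontology data-version and the tool version, and all
text outputs are byte-deterministic given inputs, parameters and the layout
seed.

SIF files ("source TAB interaction TAB target") plus the node/edge attribute
tables are directly importable into Cytoscape.
"""

from __future__ import annotations

import math

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np

from . import __version__
from . import simnet
from .evaluation import ClusterCohesion, cumulative_curve
from .hierarchy import ClusterHierarchy, DIRECT

# deterministic SVG output: no timestamps, stable element ids
matplotlib.rcParams["svg.hashsalt"] = "goclust"

PVAL_SHADE_CAP = 10.0  # -log10(p) cap so extreme p-values do not saturate


# -- provenance headers -------------------------------------------------------

def provenance_lines(params=None, ontology_version=None, extra=()) -> list:
    lines = [f"goclust {__version__}"]
    if ontology_version:
        lines.append(f"ontology data-version: {ontology_version}")
    if params is not None:
        d = params.as_dict()
        lines.append("parameters: " + ", ".join(f"{k}={d[k]}" for k in sorted(d)))
    lines.extend(extra)
    return lines


def _write_table(path, header_lines, columns, rows) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _fmt_p(p: float) -> str:
    return "%.6g" % p


def _shade(p: float) -> float:
    """Monotone p-value shade in [0, 1]: 0 for p=1, 1 at/beyond the cap."""
    return min(-math.log10(p), PVAL_SHADE_CAP) / PVAL_SHADE_CAP


def _label_sort_key(label: str):
    # "C2" -> (2,); "C1-10" -> (1, 10): numeric, not lexicographic
    return tuple(int(x) for x in label[1:].split("-"))


# -- tables -------------------------------------------------------------------

def write_cluster_table(result, graph, path) -> None:
    """Per-term table: accession, description, namespace, depth, p, x, n,
    cluster label and representative tags; ordered by cluster then p-value."""
    rows = []
    for cluster in result.clusters:
        tag_by_acc: dict = {}
        for tag, acc in sorted(cluster.representatives.items()):
            tag_by_acc.setdefault(acc, []).append(tag)
        for t in cluster.members:  # members already sorted by (p, accession)
            rows.append((
                t.go_id, t.description, t.namespace,
                result.depths.get(t.go_id, ""),
                _fmt_p(t.p_value), t.x, t.n if t.n is not None else "",
                cluster.label, ",".join(tag_by_acc.get(t.go_id, [])),
            ))
    _write_table(
        path,
        provenance_lines(result.params, result.ontology_version),
        ["GO_ID", "Description", "Namespace", "Depth", "P_value", "x", "n",
         "Cluster", "Representative"],
        rows,
    )


def _rep_cell(cluster, tag, by_id) -> str:
    t = by_id[cluster.representatives[tag]]
    n = t.n if t.n is not None else "NA"
    return f"{t.go_id} {t.description} (x={t.x}, n={n}, p={_fmt_p(t.p_value)})"


def write_summary(result, path) -> None:
    """One row per cluster: label, member count, distinct genes covered, and
    the three candidate representative terms."""
    rows = []
    for cluster in result.clusters:
        by_id = {t.go_id: t for t in cluster.members}
        rows.append((
            cluster.label, len(cluster.members), len(cluster.gene_union),
            _rep_cell(cluster, "most_genes", by_id),
            _rep_cell(cluster, "smallest_p", by_id),
            _rep_cell(cluster, "highest_degree", by_id),
        ))
    _write_table(
        path,
        provenance_lines(result.params, result.ontology_version),
        ["Cluster", "Terms", "Genes", "Rep_most_genes", "Rep_smallest_p",
         "Rep_highest_degree"],
        rows,
    )


def write_cohesion_table(cohesions, path, params=None,
                         ontology_version=None) -> None:
    rows = [
        (c.label,
         # member count m from pair count m(m-1)/2; singletons have 0 pairs
         int((1 + math.isqrt(1 + 8 * c.n_pairs)) // 2) if c.n_pairs else 1,
         c.n_pairs,
         "NA" if c.p_above is None else "%.6g" % c.p_above)
        for c in cohesions
    ]
    _write_table(path, provenance_lines(params, ontology_version),
                 ["Cluster", "Members", "Pairs", "P_above"], rows)


def write_hierarchy_table(hier: ClusterHierarchy, graph, path, params=None) -> None:
    rows = [
        (p, c, tag, graph.depth(p), graph.depth(c))
        for p, c, tag in hier.edges
    ]
    _write_table(path,
                 provenance_lines(params, graph.data_version),
                 ["Parent", "Child", "Link", "Parent_depth", "Child_depth"],
                 rows)


# -- SIF / Cytoscape ----------------------------------------------------------

def write_sif(obj, path, kind: str = "similarity") -> None:
    """Cytoscape simple-interaction-format export.

    ``kind="similarity"`` takes a network (interaction ``sim``; isolated
    nodes become single-column lines); ``kind="hierarchy"`` takes a
    :class:`ClusterHierarchy` (interactions ``isa_direct``/``isa_indirect``).
    """
    lines = []
    if kind == "similarity":
        G: nx.Graph = obj
        connected: set = set()
        for a, b in sorted((min(u, v), max(u, v)) for u, v in G.edges):
            lines.append(f"{a}\tsim\t{b}")
            connected |= {a, b}
        for node in sorted(set(G.nodes) - connected):
            lines.append(node)
    elif kind == "hierarchy":
        hier: ClusterHierarchy = obj
        linked: set = set()
        for p, c, tag in hier.edges:
            interaction = "isa_direct" if tag == DIRECT else "isa_indirect"
            lines.append(f"{p}\t{interaction}\t{c}")
            linked |= {p, c}
        for node in sorted(set(hier.nodes) - linked):
            lines.append(node)
    else:
        raise ValueError(f"unknown SIF kind {kind!r}")
    if not lines:
        raise ValueError("nothing to export: empty network/hierarchy")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def write_edge_attributes(G: nx.Graph, path, params=None,
                          ontology_version=None) -> None:
    simnet.write_edge_table(G, path,
                            header_lines=provenance_lines(params, ontology_version))


def write_node_attributes(result, path) -> None:
    rows = []
    for cluster in result.clusters:
        for t in cluster.members:
            rows.append((t.go_id, t.description, cluster.label, t.x,
                         _fmt_p(t.p_value)))
    _write_table(path, provenance_lines(result.params, result.ontology_version),
                 ["GO_ID", "Description", "Cluster", "x", "P_value"], rows)


# -- figure helpers -----------------------------------------------------------

def _cluster_colors(n: int) -> list:
    cmap = plt.get_cmap("tab20" if n > 10 else "tab10")
    return [matplotlib.colors.to_hex(cmap(i % cmap.N)) for i in range(n)]


def _heatmap_order(result) -> list:
    """Terms grouped by cluster; within a cluster by within-cluster degree
    (descending), ties by accession."""
    order = []
    for cluster in result.clusters:
        accs = set(cluster.accessions)
        def deg(t):
            if t.go_id not in result.network:
                return 0
            return sum(1 for nb in result.network.neighbors(t.go_id) if nb in accs)
        order.extend(sorted(cluster.members, key=lambda t: (-deg(t), t.go_id)))
    return order


def plot_heatmap(result, path) -> None:
    """All-pairs similarity heatmap with cluster-contiguous ordering.

    Companion ``<path>.tsv`` holds the exact cell values (threshold ignored,
    so between-cluster similarities are visible)."""
    terms = _heatmap_order(result)
    n = len(terms)
    metric = result.params.metric
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = simnet.similarity(terms[i].genes, terms[j].genes,
                                                  metric=metric)
    ids = [t.go_id for t in terms]
    _write_table(str(path) + ".tsv",
                 provenance_lines(result.params, result.ontology_version),
                 ["GO_ID"] + ids,
                 [(ids[i], *("%.6g" % v for v in M[i])) for i in range(n)])

    fig, ax = plt.subplots(figsize=(max(4, n * 0.12), max(4, n * 0.12)))
    im = ax.imshow(M, cmap="viridis", vmin=0, vmax=1, interpolation="nearest")
    # delineate cluster blocks
    pos = 0
    for cluster in result.clusters[:-1]:
        pos += len(cluster.members)
        ax.axhline(pos - 0.5, color="white", lw=0.8)
        ax.axvline(pos - 0.5, color="white", lw=0.8)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"{metric} similarity, {len(result.clusters)} clusters")
    fig.colorbar(im, ax=ax, shrink=0.7, label=metric)
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def plot_network(result, path, seed: int | None = None) -> None:
    """Force-directed network: node size ∝ x, edge width ∝ similarity, one
    color per cluster, node shade darker for smaller p-values.  The layout
    seed is fixed so output is reproducible; companion ``<path>.tsv`` holds
    the per-node visual encodings."""
    seed = result.params.seed if seed is None else seed
    G = result.network
    colors = _cluster_colors(len(result.clusters))
    node_info = {}
    for ci, cluster in enumerate(result.clusters):
        for t in cluster.members:
            node_info[t.go_id] = (t, cluster.label, colors[ci])

    rows = []
    for cluster in result.clusters:
        for t in cluster.members:
            _, label, color = node_info[t.go_id]
            rows.append((t.go_id, t.x, label, _fmt_p(t.p_value), color,
                         "%.6g" % _size(t.x), "%.6g" % _shade(t.p_value)))
    _write_table(str(path) + ".tsv",
                 provenance_lines(result.params, result.ontology_version),
                 ["GO_ID", "x", "Cluster", "P_value", "Color", "Size", "Shade"],
                 rows)

    pos = nx.spring_layout(G, seed=seed, weight="weight")
    fig, ax = plt.subplots(figsize=(8, 8))
    widths = [2.5 * d["weight"] for _, _, d in G.edges(data=True)]
    nx.draw_networkx_edges(G, pos, ax=ax, width=widths, edge_color="#bbbbbb")
    for node in G.nodes:
        t, label, color = node_info[node]
        rgba = matplotlib.colors.to_rgba(color)
        shade = 0.25 + 0.75 * _shade(t.p_value)  # lighter = larger p
        face = tuple(1 - shade * (1 - c) for c in rgba[:3])
        ax.scatter(*pos[node], s=_size(t.x), color=face, edgecolors=color,
                   linewidths=1.2, zorder=3)
    ax.set_axis_off()
    ax.set_title(f"{len(G)} terms, {len(result.clusters)} clusters "
                 f"({result.params.metric} >= {result.params.cutoff})")
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def _size(x: int) -> float:
    return 30.0 + 8.0 * x  # strictly increasing in x


def plot_cohesion(cohesions, path, params=None, ontology_version=None) -> None:
    """One empirical-CDF curve per cluster; legend shows each cluster's
    P(>= threshold).  Companion ``<path>.tsv`` holds the curves long-format."""
    curves = {}
    for coh in cohesions:
        if coh.n_pairs:
            curves[coh.label] = (coh, cumulative_curve(coh))
    if not curves:
        raise ValueError("no multi-member cluster to plot")
    rows = []
    for label in sorted(curves, key=_label_sort_key):
        coh, curve = curves[label]
        for s, frac in curve:
            rows.append((label, "%.6g" % s, "%.6g" % frac))
    _write_table(str(path) + ".tsv",
                 provenance_lines(params, ontology_version),
                 ["Cluster", "Similarity", "Cumulative_fraction"], rows)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    threshold = next(iter(curves.values()))[0].threshold
    for label in sorted(curves, key=_label_sort_key):
        coh, curve = curves[label]
        xs = [0.0] + [s for s, _ in curve] + [1.0]
        ys = [0.0] + [f for _, f in curve] + [1.0]
        ax.step(xs, ys, where="post",
                label=f"{label}: P(>={threshold:g}) = {coh.p_above:.2f}")
    ax.axvline(threshold, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("similarity index")
    ax.set_ylabel("cumulative fraction of pairs")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def plot_hierarchy(hier: ClusterHierarchy, result, graph, path) -> None:
    """Layered hierarchy drawing: rows by ontology depth, direct links black,
    transitive links grey; node size ∝ x, shade darker for smaller p.
    Companion ``<path>.tsv`` is the tagged edge table."""
    write_hierarchy_table(hier, graph, str(path) + ".tsv", params=result.params)

    terms = {t.go_id: t for c in result.clusters for t in c.members}
    depths = {acc: graph.depth(acc) for acc in hier.nodes}
    by_depth: dict[int, list] = {}
    for acc in hier.nodes:
        by_depth.setdefault(depths[acc], []).append(acc)
    pos = {}
    for d, accs in by_depth.items():
        for i, acc in enumerate(sorted(accs)):
            pos[acc] = (i - (len(accs) - 1) / 2.0, -d)

    fig, ax = plt.subplots(figsize=(8, 6))
    for p, c, tag in hier.edges:
        color = "black" if tag == DIRECT else "#999999"
        (x0, y0), (x1, y1) = pos[p], pos[c]
        ax.annotate("", xy=(x1, y1), xytext=(x0, y0),
                    arrowprops=dict(arrowstyle="-|>", color=color, lw=1.2))
    for acc in hier.nodes:
        t = terms.get(acc)
        size = _size(t.x) if t else 30.0
        shade = 0.25 + 0.75 * _shade(t.p_value) if t else 0.5
        face = (1 - shade * 0.8, 1 - shade * 0.5, 1 - shade * 0.2)
        ax.scatter(*pos[acc], s=size, color=face, edgecolors="black",
                   linewidths=0.8, zorder=3)
        ax.annotate(acc, pos[acc], textcoords="offset points", xytext=(0, 8),
                    ha="center", fontsize=6)
    ax.set_axis_off()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
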