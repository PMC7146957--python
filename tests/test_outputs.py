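"""Tables, SIF exports and figure companion files."""

import pytest

from goclust import evaluation, hierarchy, outputs, pipeline
from goclust.pipeline import run, subcluster
from conftest import make_term, make_list
import oracles


def read_table(path):
    """Parse a TSV with '#' provenance lines into (header_lines, rows)."""
    header_lines, rows = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                header_lines.append(line)
            elif line:
                rows.append(line.split("\t"))
    return header_lines, rows[0], rows[1:]


@pytest.fixture()
def result(loaded_single):
    graph, elist = loaded_single
    return run(elist, graph), graph


class TestClusterTable:
    def test_rows_and_labels(self, result, tmp_path):
        res, graph = result
        path = tmp_path / "clusters.tsv"
        outputs.write_cluster_table(res, graph, path)
        prov, header, rows = read_table(path)
        assert len(rows) == sum(len(c.members) for c in res.clusters)
        labels = {r[header.index("Cluster")] for r in rows}
        assert labels == {c.label for c in res.clusters}
        assert any("data-version" in line for line in prov)

    def test_rows_sorted_by_cluster_then_p(self, result, tmp_path):
        res, graph = result
        path = tmp_path / "clusters.tsv"
        outputs.write_cluster_table(res, graph, path)
        _, header, rows = read_table(path)
        ci, pi = header.index("Cluster"), header.index("P_value")
        key = [(r[ci], float(r[pi])) for r in rows]
        assert key == sorted(key)

    def test_depth_column_from_ontology(self, result, tmp_path):
        res, graph = result
        path = tmp_path / "clusters.tsv"
        outputs.write_cluster_table(res, graph, path)
        _, header, rows = read_table(path)
        gi, di = header.index("GO_ID"), header.index("Depth")
        for r in rows:
            assert int(r[di]) == graph.depth(r[gi])

    def test_singleton_run(self, chain_obo_graph, tmp_path):
        res = run(make_list([make_term("GO:0000002", ["a"])]), chain_obo_graph)
        path = tmp_path / "one.tsv"
        outputs.write_cluster_table(res, chain_obo_graph, path)
        _, header, rows = read_table(path)
        assert len(rows) == 1
        assert rows[0][header.index("Cluster")] == "C1"

    def test_rerun_is_byte_identical(self, result, tmp_path):
        res, graph = result
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        outputs.write_cluster_table(res, graph, p1)
        outputs.write_cluster_table(res, graph, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestSummary:
    def test_row_per_cluster_in_order(self, result, tmp_path):
        res, graph = result
        path = tmp_path / "summary.tsv"
        outputs.write_summary(res, path)
        _, header, rows = read_table(path)
        assert [r[0] for r in rows] == [c.label for c in res.clusters]
        gi = header.index("Genes")
        assert [int(r[gi]) for r in rows] == \
            [len(c.gene_union) for c in res.clusters]

    def test_subcluster_labels_rendered(self, loaded_two_level, tmp_path):
        graph, elist = loaded_two_level
        res = run(elist, graph)
        sres = subcluster(res, ["C1"], graph, max_size=2000, inflation=1.8)["C1"]
        view = pipeline.ClusteringResult(
            clusters=sres.clusters, network=sres.network, params=sres.params,
            depths={}, ontology_version=graph.data_version)
        path = tmp_path / "sub.tsv"
        outputs.write_summary(view, path)
        _, _, rows = read_table(path)
        assert [r[0] for r in rows] == ["C1-1", "C1-2"]


class TestSif:
    def test_similarity_sif_with_isolated_nodes(self, tmp_path):
        a = make_term("GO:0000001", ["g1", "g2"])
        b = make_term("GO:0000002", ["g1", "g2"])
        c = make_term("GO:0000003", ["h1"])
        from goclust.simnet import build_network
        net = build_network(make_list([a, b, c]), cutoff=0.5)
        path = tmp_path / "net.sif"
        outputs.write_sif(net, path, kind="similarity")
        lines = path.read_text().splitlines()
        assert "GO:0000001\tsim\tGO:0000002" in lines
        assert "GO:0000003" in lines  # single-column isolated node

    def test_hierarchy_sif_interaction_types(self, chain_obo_graph, tmp_path):
        hier = hierarchy.ClusterHierarchy(
            nodes=("GO:0000001", "GO:0000002", "GO:0000005"),
            edges=(("GO:0000001", "GO:0000002", "direct"),
                   ("GO:0000002", "GO:0000005", "transitive")))
        path = tmp_path / "hier.sif"
        outputs.write_sif(hier, path, kind="hierarchy")
        lines = path.read_text().splitlines()
        assert lines == ["GO:0000001\tisa_direct\tGO:0000002",
                         "GO:0000002\tisa_indirect\tGO:0000005"]

    def test_node_attribute_rowcount(self, result, tmp_path):
        res, graph = result
        path = tmp_path / "nodes.tsv"
        outputs.write_node_attributes(res, path)
        _, _, rows = read_table(path)
        assert len(rows) == len(res.network)

    def test_unknown_kind(self, result, tmp_path):
        with pytest.raises(ValueError):
            outputs.write_sif(result[0].network, tmp_path / "x.sif", kind="foo")


class TestHeatmap:
    def test_companion_matrix_equals_allpairs_oracle(self, result, tmp_path):
        res, graph = result
        path = tmp_path / "heatmap.svg"
        outputs.plot_heatmap(res, path)
        _, header, rows = read_table(str(path) + ".tsv")
        ids = header[1:]
        terms = {t.go_id: t for c in res.clusters for t in c.members}
        expected = oracles.edge_set_reference(
            [terms[i] for i in ids], res.params.metric, cutoff=0.0)
        for r in rows:
            src = r[0]
            for col, val in zip(ids, r[1:]):
                want = 1.0 if src == col else expected.get(
                    tuple(sorted((src, col))), 0.0)
                assert float(val) == pytest.approx(want, abs=1e-6)

    def test_cluster_blocks_contiguous(self, result, tmp_path):
        res, graph = result
        path = tmp_path / "heatmap.svg"
        outputs.plot_heatmap(res, path)
        _, header, _ = read_table(str(path) + ".tsv")
        member_label = {t.go_id: c.label for c in res.clusters
                        for t in c.members}
        seq = [member_label[i] for i in header[1:]]
        # labels appear in one contiguous stretch each
        assert len({(a, b) for a, b in zip(seq, seq[1:]) if a != b}) == \
            len(set(seq)) - 1

    def test_singleton_matrix(self, chain_obo_graph, tmp_path):
        res = run(make_list([make_term("GO:0000002", ["a"])]), chain_obo_graph)
        path = tmp_path / "h.svg"
        outputs.plot_heatmap(res, path)
        _, header, rows = read_table(str(path) + ".tsv")
        assert len(rows) == 1 and len(header) == 2

    def test_companion_deterministic(self, result, tmp_path):
        res, graph = result
        p1, p2 = tmp_path / "h1.svg", tmp_path / "h2.svg"
        outputs.plot_heatmap(res, p1)
        outputs.plot_heatmap(res, p2)
        assert (tmp_path / "h1.svg.tsv").read_bytes() == \
            (tmp_path / "h2.svg.tsv").read_bytes()


class TestNetworkPlot:
    def test_visual_encodings_in_companion(self, result, tmp_path):
        res, graph = result
        path = tmp_path / "net.svg"
        outputs.plot_network(res, path)
        _, header, rows = read_table(str(path) + ".tsv")
        xi, si = header.index("x"), header.index("Size")
        pi, shi = header.index("P_value"), header.index("Shade")
        ci = header.index("Color")
        # size strictly increases with x
        pairs = sorted((int(r[xi]), float(r[si])) for r in rows)
        for (x1, s1), (x2, s2) in zip(pairs, pairs[1:]):
            if x2 > x1:
                assert s2 > s1
        # equal p-values -> equal shades; shade monotone in -log10 p
        by_p = {}
        for r in rows:
            by_p.setdefault(float(r[pi]), set()).add(float(r[shi]))
        assert all(len(v) == 1 for v in by_p.values())
        ps = sorted(by_p)
        shades = [next(iter(by_p[p])) for p in ps]
        assert shades == sorted(shades, reverse=True)
        # one color per cluster
        colors = {r[ci] for r in rows}
        assert len(colors) == len(res.clusters)


class TestCohesionOutputs:
    def test_companion_matches_curves(self, result, tmp_path):
        res, graph = result
        cohs = evaluation.evaluate_clusters(res)
        path = tmp_path / "cohesion.svg"
        outputs.plot_cohesion(cohs, path, params=res.params)
        _, header, rows = read_table(str(path) + ".tsv")
        for coh in cohs:
            if not coh.n_pairs:
                continue
            got = [(float(r[1]), float(r[2])) for r in rows if r[0] == coh.label]
            expected = [(pytest.approx(s), pytest.approx(f))
                        for s, f in evaluation.cumulative_curve(coh)]
            assert got == expected

    def test_table_reports_na_for_singletons(self, chain_obo_graph, tmp_path):
        res = run(make_list([make_term("GO:0000002", ["a"]),
                             make_term("GO:0000003", ["b"])]), chain_obo_graph)
        cohs = evaluation.evaluate_clusters(res)
        path = tmp_path / "cohesion.tsv"
        outputs.write_cohesion_table(cohs, path, params=res.params)
        _, header, rows = read_table(path)
        assert all(r[header.index("P_above")] == "NA" for r in rows)


class TestHierarchyPlot:
    def test_chain_renders_two_direct_edges(self, chain_obo_graph, tmp_path,
                                            loaded_single):
        graph, elist = loaded_single
        res = run(elist, graph)
        from goclust.ontology import OntologyGraph, OntologyTerm
        g = chain_obo_graph
        hier = hierarchy.cluster_hierarchy(
            g, ["GO:0000001", "GO:0000002", "GO:0000003"])
        path = tmp_path / "hier.svg"
        outputs.plot_hierarchy(hier, res, g, path)
        _, header, rows = read_table(str(path) + ".tsv")
        assert [r[header.index("Link")] for r in rows] == ["direct", "direct"]
        di = header.index("Child_depth")
        assert [int(r[di]) for r in rows] == [1, 2]

    def test_skip_level_renders_transitive(self, chain_obo_graph, tmp_path,
                                           loaded_single):
        graph, elist = loaded_single
        res = run(elist, graph)
        hier = hierarchy.cluster_hierarchy(chain_obo_graph,
                                           ["GO:0000001", "GO:0000003"])
        path = tmp_path / "hier.svg"
        outputs.plot_hierarchy(hier, res, chain_obo_graph, path)
        _, header, rows = read_table(str(path) + ".tsv")
        assert [r[header.index("Link")] for r in rows] == ["transitive"]
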