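"""Backbone sparsification, clustering, and graph export."""

import networkx as nx
import numpy as np
import pytest

from semharm.backbone import (
    BackboneGraph,
    cluster_graph,
    export_graph,
    read_clusters_tsv,
    read_edge_tsv,
    sparsify_to_backbone,
    write_clusters_tsv,
)
from semharm.embedding import SimilarityMatrix, embed_bank, item_similarity_matrix
from semharm.item_bank import ItemBank, ScaleItem


def _random_fixture(rng, n_backbone=3, n_other=4):
    items = [ScaleItem("BB", str(i), "l", "d") for i in range(n_backbone)]
    items += [ScaleItem("XX", str(i), "l", "d") for i in range(n_other)]
    bank = ItemBank(tuple(items))
    n = len(items)
    raw = rng.uniform(0, 1, size=(n, n))
    raw = (raw + raw.T) / 2
    np.fill_diagonal(raw, 1.0)
    sim = SimilarityMatrix(ids=bank.item_ids, values=raw, normalization="clip01")
    return bank, sim


class TestSparsify:
    def test_single_backbone_item_star(self, rng):
        bank, sim = _random_fixture(rng, n_backbone=1, n_other=3)
        g = sparsify_to_backbone(sim, bank, "BB", include_intra_backbone=False)
        assert len(g.edges) == 3
        assert all(e.target == "BB-0" for e in g.edges)

    def test_edges_equal_argmax_oracle(self, rng):
        for _ in range(50):
            nb = int(rng.integers(1, 5))
            no = int(rng.integers(1, 7))
            bank, sim = _random_fixture(rng, nb, no)
            g = sparsify_to_backbone(sim, bank, "BB", include_intra_backbone=False)
            backbone_ids = [it.item_id for it in bank if it.scale_id == "BB"]
            for e in g.edges:
                i = bank.item_ids.index(e.source)
                best = max(backbone_ids,
                           key=lambda b: sim.values[i, bank.item_ids.index(b)])
                assert e.target == best
                assert e.weight == sim.values[i, bank.item_ids.index(e.target)]

    @pytest.mark.parametrize("intra", [True, False])
    def test_edge_count_law(self, rng, intra):
        for _ in range(20):
            nb = int(rng.integers(2, 5))
            no = int(rng.integers(1, 7))
            bank, sim = _random_fixture(rng, nb, no)
            g = sparsify_to_backbone(sim, bank, "BB", include_intra_backbone=intra)
            assert len(g.edges) == no + (nb if intra else 0)

    def test_every_nonbackbone_item_out_degree_one(self, themed_pipeline):
        cfg, bank, truth, backend = themed_pipeline
        sim = item_similarity_matrix(embed_bank(bank, backend))
        g = sparsify_to_backbone(sim, bank, "TLC")
        non_backbone = [it.item_id for it in bank if it.scale_id != "TLC"]
        out_deg = {n: 0 for n in non_backbone}
        backbone = {it.item_id for it in bank if it.scale_id == "TLC"}
        for e in g.edges:
            if e.source in out_deg:
                out_deg[e.source] += 1
                assert e.target in backbone
        assert all(d == 1 for d in out_deg.values())

    def test_tie_flagged_and_broken_to_earliest(self):
        items = (ScaleItem("BB", "1", "l", "d"), ScaleItem("BB", "2", "l", "d"),
                 ScaleItem("XX", "1", "l", "d"))
        bank = ItemBank(items)
        vals = np.array([[1.0, 0.2, 0.5], [0.2, 1.0, 0.5], [0.5, 0.5, 1.0]])
        sim = SimilarityMatrix(ids=bank.item_ids, values=vals, normalization="clip01")
        g = sparsify_to_backbone(sim, bank, "BB", include_intra_backbone=False)
        assert g.edges[0].target == "BB-1"
        assert g.edges[0].tie

    def test_monotone_stability_under_constant_shift(self, rng):
        bank, sim = _random_fixture(rng, 3, 5)
        shifted = SimilarityMatrix(
            ids=sim.ids, values=(sim.values - 0.4).clip(-1, 1),
            normalization="raw_cosine")
        a = sparsify_to_backbone(sim, bank, "BB")
        b = sparsify_to_backbone(shifted, bank, "BB")
        assert [(e.source, e.target) for e in a.edges] == \
               [(e.source, e.target) for e in b.edges]

    def test_absent_backbone_scale_rejected(self, rng):
        bank, sim = _random_fixture(rng)
        with pytest.raises(ValueError, match="ZZ"):
            sparsify_to_backbone(sim, bank, "ZZ")

    def test_id_mismatch_rejected(self, rng):
        bank, sim = _random_fixture(rng)
        other_bank, _ = _random_fixture(rng, n_backbone=2, n_other=2)
        with pytest.raises(ValueError, match="match"):
            sparsify_to_backbone(sim, other_bank, "BB")


def _graph(nodes, edges, backbone="BB"):
    from semharm.backbone import Edge
    return BackboneGraph(
        nodes=tuple(nodes),
        edges=tuple(Edge(s, t, w) for s, t, w in edges),
        backbone_scale=backbone,
        include_intra_backbone=False,
        node_scale={n: n.split("-")[0] for n in nodes},
        node_label={n: n for n in nodes},
    )


class TestClusterGraph:
    def test_no_edges_gives_singletons(self):
        g = _graph([f"N-{i}" for i in range(5)], [])
        c = cluster_graph(g)
        assert c.n_clusters == 5
        assert sorted(c.labels.values()) == [1, 2, 3, 4, 5]

    def test_two_stars_match_flood_fill(self):
        nodes = ["BB-1", "BB-2", "XX-1", "XX-2", "XX-3", "XX-4"]
        edges = [("XX-1", "BB-1", 0.9), ("XX-2", "BB-1", 0.8),
                 ("XX-3", "BB-2", 0.9), ("XX-4", "BB-2", 0.7)]
        c = cluster_graph(_graph(nodes, edges))
        # independent flood fill
        adj = {n: set() for n in nodes}
        for s, t, _ in edges:
            adj[s].add(t)
            adj[t].add(s)
        seen, comps = set(), []
        for n in nodes:
            if n in seen:
                continue
            stack, comp = [n], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u] - comp)
            seen |= comp
            comps.append(comp)
        assert c.n_clusters == len(comps) == 2
        for comp in comps:
            labels = {c.labels[n] for n in comp}
            assert len(labels) == 1

    def test_labels_ordered_by_size_then_member(self):
        nodes = ["A-1", "A-2", "A-3", "B-1"]
        edges = [("A-2", "A-1", 1.0), ("A-3", "A-1", 1.0)]
        c = cluster_graph(_graph(nodes, edges))
        assert c.labels["A-1"] == 1  # biggest cluster gets label 1
        assert c.labels["B-1"] == 2

    def test_greedy_modularity_runs_and_partitions(self, themed_pipeline):
        cfg, bank, truth, backend = themed_pipeline
        sim = item_similarity_matrix(embed_bank(bank, backend))
        g = sparsify_to_backbone(sim, bank, "TLC")
        c = cluster_graph(g, method="greedy_modularity")
        assert set(c.labels) == set(g.nodes)
        assert c.n_clusters >= 2

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            cluster_graph(_graph(["A-1"], []), method="kmeans")

    def test_synthetic_theme_recovery_far_above_chance(self, themed_pipeline):
        # smoke-level check at one seed; distribution-level recovery bounds
        # live in the acceptance suite
        from sklearn.metrics import adjusted_rand_score
        cfg, bank, truth, backend = themed_pipeline
        sim = item_similarity_matrix(embed_bank(bank, backend))
        g = sparsify_to_backbone(sim, bank, "TLC")
        c = cluster_graph(g)
        ari = adjusted_rand_score(
            [truth[i] for i in bank.item_ids],
            [c.labels[i] for i in bank.item_ids],
        )
        assert ari > 0.5
        # every cluster is anchored by at least one backbone item
        for label in range(1, c.n_clusters + 1):
            assert any(n.startswith("TLC-") for n in c.members(label))


class TestExport:
    def test_edge_tsv_single_edge(self, tmp_path):
        g = _graph(["BB-1", "XX-1"], [("XX-1", "BB-1", 0.75)])
        c = cluster_graph(g)
        p = tmp_path / "edges.tsv"
        export_graph(g, c, p, format="edge_tsv")
        assert len(p.read_text().splitlines()) == 2  # header + one edge

    def test_edge_tsv_round_trip(self, tmp_path, rng):
        bank, sim = _random_fixture(rng, 3, 6)
        g = sparsify_to_backbone(sim, bank, "BB")
        c = cluster_graph(g)
        p = tmp_path / "edges.tsv"
        export_graph(g, c, p, format="edge_tsv")
        back = read_edge_tsv(p)
        assert sorted((e.source, e.target, e.weight) for e in back) == \
               sorted((e.source, e.target, e.weight) for e in g.edges)

    def test_graphml_reimports_with_attributes(self, tmp_path, rng):
        bank, sim = _random_fixture(rng, 2, 4)
        g = sparsify_to_backbone(sim, bank, "BB")
        c = cluster_graph(g)
        p = tmp_path / "g.graphml"
        export_graph(g, c, p, format="graphml")
        back = nx.read_graphml(p)
        assert set(back.nodes) == set(g.nodes)
        for n in back.nodes:
            assert back.nodes[n]["cluster"] == c.labels[n]
            assert back.nodes[n]["scale_id"] == g.node_scale[n]

    def test_clusters_tsv_round_trip(self, tmp_path, rng):
        bank, sim = _random_fixture(rng)
        g = sparsify_to_backbone(sim, bank, "BB")
        c = cluster_graph(g)
        p = tmp_path / "clusters.tsv"
        write_clusters_tsv(c, p)
        back = read_clusters_tsv(p)
        assert dict(back.labels) == dict(c.labels)
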