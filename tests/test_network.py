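"""Similarity graph construction, clustering, and the two-step rule."""

import networkx as nx
import numpy as np

from symtox.align import HitFilter
from symtox.model import AlignmentHit, TrgAnnotation
from symtox.network import (build_graph, cluster_graph,
                            select_trg_neighborhood, write_graph)

from oracles import bfs_within


def hit(q, s, similarity=60.0, coverage=0.8, evalue=1e-20):
    return AlignmentHit(query_id=q, subject_id=s, raw_score=100, bitscore=40,
                        evalue=evalue, percent_identity=similarity / 2,
                        percent_similarity=similarity,
                        query_coverage=coverage, subject_coverage=coverage)


def trg(pid, cls="YD"):
    return TrgAnnotation(protein_id=pid, trg_class=cls)


def test_similarity_threshold_is_strict():
    g = build_graph([hit("a", "b", similarity=25.0)], HitFilter())
    assert g.number_of_edges() == 0
    g = build_graph([hit("a", "b", similarity=25.01)], HitFilter())
    assert g.number_of_edges() == 1


def test_identical_proteins_form_complete_component():
    hits = [hit(f"p{i}", f"p{j}", 100.0)
            for i in range(5) for j in range(5) if i != j]
    g = build_graph(hits, HitFilter())
    assert g.number_of_edges() == 10  # K5, reciprocal hits collapsed


def test_reciprocal_hits_keep_better_evalue():
    g = build_graph([hit("a", "b", evalue=1e-10),
                     hit("b", "a", evalue=1e-30)], HitFilter())
    assert g.edges["a", "b"]["evalue"] == 1e-30


def test_chain_forms_single_cluster_and_singletons_stand_alone():
    g = build_graph([hit("a", "b"), hit("b", "c")], HitFilter())
    g.add_node("z", annotation="", genome="", trg_class="")
    clusters = cluster_graph(g)
    assert clusters["a"] == clusters["b"] == clusters["c"]
    assert clusters["z"] != clusters["a"]


def test_clustering_matches_union_find_oracle():
    for seed in range(25):
        rng = np.random.default_rng(seed)
        g = nx.Graph()
        g.add_nodes_from(f"n{i}" for i in range(50))
        for i in range(50):
            for j in range(i + 1, 50):
                if rng.random() < 0.05:
                    g.add_edge(f"n{i}", f"n{j}", similarity=50.0,
                               evalue=1e-10)
        clusters = cluster_graph(g)
        # naive union-find
        parent = {n: n for n in g.nodes}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for u, v in g.edges:
            parent[find(u)] = find(v)
        for u in g.nodes:
            for v in g.nodes:
                assert (find(u) == find(v)) == (clusters[u] == clusters[v])


def test_cluster_chain_selected_to_depth_two():
    # cluster-level chain T - A - B - C; T contains the only TRG
    g = nx.Graph()
    edges = [("t1", "t2"), ("a1", "a2"), ("b1", "b2"), ("c1", "c2"),
             ("t2", "a1"), ("a2", "b1"), ("b2", "c1")]
    for u, v in edges:
        g.add_edge(u, v, similarity=50.0, evalue=1e-10)
    for n in g.nodes:
        g.nodes[n]["annotation"] = n[0].upper()
    clusters = {"t1": "T", "t2": "T", "a1": "A", "a2": "A",
                "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
    hood = select_trg_neighborhood(g, clusters, [trg("t1")], max_steps=2)
    assert hood.selected == {"T": 0, "A": 1, "B": 2}
    assert "C" not in hood.selected
    assert hood.names["T"] == "T"


def test_isolated_non_trg_cluster_excluded():
    g = nx.Graph()
    g.add_edge("t1", "t2", similarity=50.0, evalue=1e-10)
    g.add_edge("x1", "x2", similarity=50.0, evalue=1e-10)
    clusters = {"t1": "T", "t2": "T", "x1": "X", "x2": "X"}
    hood = select_trg_neighborhood(g, clusters, [trg("t1")], 2)
    assert set(hood.selected) == {"T"}


def test_max_steps_zero_selects_only_trg_clusters():
    g = nx.Graph()
    g.add_edge("t1", "a1", similarity=50.0, evalue=1e-10)
    clusters = {"t1": "T", "a1": "A"}
    hood = select_trg_neighborhood(g, clusters, [trg("t1")], 0)
    assert set(hood.selected) == {"T"}


def test_selection_monotone_in_max_steps():
    rng = np.random.default_rng(3)
    g = nx.gnp_random_graph(40, 0.08, seed=3)
    g = nx.relabel_nodes(g, {i: f"p{i}" for i in range(40)})
    clusters = {n: f"C{rng.integers(10)}" for n in g.nodes}
    annotations = [trg("p0"), trg("p7")]
    prev = set()
    for steps in (0, 1, 2, 3):
        hood = select_trg_neighborhood(g, clusters, annotations, steps)
        assert prev <= set(hood.selected)
        prev = set(hood.selected)


def test_no_trg_nodes_gives_empty_selection():
    g = nx.Graph()
    g.add_edge("a", "b", similarity=50.0, evalue=1e-10)
    hood = select_trg_neighborhood(g, {"a": "A", "b": "A"}, [], 2)
    assert hood.selected == {}


def test_edge_filter_idempotent_rebuild():
    hits = [hit("a", "b", 60.0), hit("b", "c", 30.0), hit("c", "d", 24.0)]
    g1 = build_graph(hits, HitFilter())
    rebuilt_hits = [hit(u, v, g1.edges[u, v]["similarity"],
                        evalue=g1.edges[u, v]["evalue"])
                    for u, v in g1.edges]
    g2 = build_graph(rebuilt_hits, HitFilter())
    assert set(g1.edges) == set(g2.edges)


def test_graph_serialisation_lists_nodes_and_edges(tmp_path):
    g = build_graph([hit("a", "b")], HitFilter())
    clusters = cluster_graph(g)
    path = tmp_path / "net.tsv"
    write_graph(g, clusters, str(path))
    text = path.read_text()
    assert "node\ta" in text and "edge\ta\tb" in text


def test_random_instances_match_bfs_oracle():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n_clusters = 8
        g = nx.Graph()
        nodes = [f"p{i}" for i in range(30)]
        g.add_nodes_from(nodes)
        clusters = {n: f"C{rng.integers(n_clusters)}" for n in nodes}
        for i in range(30):
            for j in range(i + 1, 30):
                if rng.random() < 0.06:
                    g.add_edge(nodes[i], nodes[j], similarity=50.0,
                               evalue=1e-10)
        trg_nodes = [n for n in nodes if rng.random() < 0.1]
        hood = select_trg_neighborhood(g, clusters,
                                       [trg(n) for n in trg_nodes], 2)
        adjacency: dict[str, set[str]] = {}
        for u, v in g.edges:
            cu, cv = clusters[u], clusters[v]
            if cu != cv:
                adjacency.setdefault(cu, set()).add(cv)
                adjacency.setdefault(cv, set()).add(cu)
        seeds = {clusters[n] for n in trg_nodes}
        assert hood.selected == bfs_within(adjacency, seeds, 2)
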