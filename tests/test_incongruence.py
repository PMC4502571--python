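"""Homology network, trees, patristic distances and incongruence calls."""

import numpy as np
import pytest

from lgtscan import PipelineConfig, read_newick, write_newick
from lgtscan.incongruence import (Cluster, build_homology_graph, build_tree,
                                  call_incongruent_leaves,
                                  connected_components,
                                  extract_supported_subtrees,
                                  patristic_distances,
                                  poisson_distance_matrix)

from conftest import make_hit


def bfs_components(nodes, edges):
    """Independent BFS connected-components oracle."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen, comps = set(), []
    for start in nodes:
        if start in seen:
            continue
        comp, queue = {start}, [start]
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def pathwalk_patristic(tree, a, b):
    """Independent patristic oracle: walk root-to-leaf paths and sum
    branch lengths below the divergence point."""
    def path_to(label):
        leaf = next(l for l in tree.leaf_node_iter()
                    if l.taxon.label == label)
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path[::-1]

    pa, pb = path_to(a), path_to(b)
    i = 0
    while i < min(len(pa), len(pb)) and pa[i] is pb[i]:
        i += 1
    return (sum(n.edge.length for n in pa[i:])
            + sum(n.edge.length for n in pb[i:]))


class TestHomologyGraph:
    def edge_hit(self, **kw):
        d = dict(query_id="a", subject_id="b", pct_identity=70.0,
                 aln_len=60, evalue=1e-5, q_len=100)
        d.update(kw)
        return make_hit(**d)

    def test_inclusive_boundaries_admit_edge(self):
        g = build_homology_graph([self.edge_hit()])
        assert g.has_edge("a", "b")

    @pytest.mark.parametrize("kw", [
        {"pct_identity": 69.9}, {"aln_len": 59}, {"evalue": 2e-5}])
    def test_below_any_threshold_no_edge(self, kw):
        g = build_homology_graph([self.edge_hit(**kw)])
        assert g.number_of_edges() == 0

    def test_duplicate_hits_keep_best_evalue(self):
        g = build_homology_graph([self.edge_hit(evalue=1e-6),
                                  self.edge_hit(evalue=1e-9)])
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["evalue"] == 1e-9

    def test_self_hits_ignored(self):
        g = build_homology_graph([self.edge_hit(subject_id="a")])
        assert g.number_of_edges() == 0


class TestConnectedComponents:
    def test_two_clusters(self):
        import networkx as nx
        g = nx.Graph([("a", "b"), ("b", "c"), ("d", "e")])
        clusters, singles = connected_components(g)
        assert [c.members for c in clusters] == [
            frozenset("abc"), frozenset("de")]
        assert singles == []

    def test_empty_graph(self):
        import networkx as nx
        assert connected_components(nx.Graph()) == ([], [])

    def test_matches_bfs_oracle_on_random_graphs(self):
        import networkx as nx
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            nodes = [f"n{i}" for i in range(n)]
            edges = [(nodes[int(rng.integers(n))], nodes[int(rng.integers(n))])
                     for _ in range(int(rng.integers(0, 2 * n)))]
            edges = [(u, v) for u, v in edges if u != v]
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            clusters, singles = connected_components(g)
            got = {c.members for c in clusters} | {frozenset({s})
                                                   for s in singles}
            assert got == bfs_components(nodes, edges)

    def test_partition_property(self):
        import networkx as nx
        g = nx.Graph([("a", "b"), ("c", "d"), ("d", "e")])
        g.add_node("z")
        clusters, singles = connected_components(g)
        all_members = [m for c in clusters for m in c.members] + singles
        assert sorted(all_members) == sorted(g.nodes)


class TestBuildTree:
    def test_identical_sequences_star(self):
        t = build_tree({"A": "MKLV" * 30, "B": "MKLV" * 30,
                        "C": "MKLV" * 30})
        d = patristic_distances(t)
        assert d.values.max() == pytest.approx(0.0, abs=1e-9)

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            build_tree({"A": "MK", "B": "MK"})

    def test_nj_recovers_additive_topology(self):
        """Sequences built so true distances are additive: NJ groups the
        two close pairs."""
        rng = np.random.default_rng(11)
        L = 600
        root = rng.integers(0, 20, L)

        def mutate(codes, n_sub):
            out = codes.copy()
            pos = rng.choice(L, size=n_sub, replace=False)
            out[pos] = (out[pos] + rng.integers(1, 20, n_sub)) % 20
            return out

        left = mutate(root, 120)
        right = mutate(root, 120)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        seqs = {"A": left, "B": mutate(left, 15), "C": right,
                "D": mutate(right, 15)}
        prot = {k: "".join(aa[i] for i in v) for k, v in seqs.items()}
        t = build_tree(prot)
        d = patristic_distances(t)
        assert d.at["A", "B"] < d.at["A", "C"]
        assert d.at["C", "D"] < d.at["A", "C"]

    def test_external_newick_path_equivalent(self, tmp_path):
        text = "((A:0.1,B:0.2)90:0.05,C:0.3);"
        p = tmp_path / "ext.nwk"
        p.write_text(text)
        t = build_tree({}, method=str(p))
        d = patristic_distances(t)
        assert d.at["A", "B"] == pytest.approx(0.3)

    def test_bootstrap_support_on_clear_split(self):
        rng = np.random.default_rng(3)
        L = 400
        aa = "ACDEFGHIKLMNPQRSTVWY"
        root = rng.integers(0, 20, L)

        def mutate(codes, n_sub):
            out = codes.copy()
            pos = rng.choice(L, size=n_sub, replace=False)
            out[pos] = (out[pos] + rng.integers(1, 20, n_sub)) % 20
            return out

        left, right = mutate(root, 150), mutate(root, 150)
        prot = {"A": left, "B": mutate(left, 8), "C": right,
                "D": mutate(right, 8), "E": mutate(right, 8)}
        prot = {k: "".join(aa[i] for i in v) for k, v in prot.items()}
        t = build_tree(prot, bootstrap=30, seed=5)
        from lgtscan.core_io import node_support
        supports = [node_support(n) for n in t.preorder_node_iter()
                    if not n.is_leaf() and n is not t.seed_node]
        assert any(s is not None and s >= 90 for s in supports)

    def test_poisson_correction_values(self):
        # 10 % differing sites -> -ln(0.9)
        dm = poisson_distance_matrix({"A": "K" * 100,
                                      "B": "K" * 90 + "R" * 10})
        assert dm.at["A", "B"] == pytest.approx(-np.log(0.9))


class TestSubtreeExtraction:
    def tree_with_supported_clade(self, n_big=30, n_small=15, support=90):
        big = ",".join(f"L{i}:0.1" for i in range(n_big))
        small = ",".join(f"S{i}:0.1" for i in range(n_small))
        return read_newick(f"(({small}){support}:0.2,({big})40:0.2);")

    def test_supported_clade_extracted(self):
        cfg = PipelineConfig(subtree_max_leaves=20)
        clusters = extract_supported_subtrees(
            self.tree_with_supported_clade(), cfg)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [15, 30]
        supported = next(c for c in clusters if len(c.members) == 15)
        assert supported.iteration == 1
        assert {m for m in supported.members} == {f"S{i}"
                                                  for i in range(15)}

    def test_small_tree_returned_whole(self):
        t = read_newick("((A:1,B:1)50:1,C:1);")
        clusters = extract_supported_subtrees(t, PipelineConfig())
        assert [c.members for c in clusters] == [frozenset("ABC")]

    def test_unsupported_tree_rebuilt_then_warned(self, caplog):
        import logging
        cfg = PipelineConfig(subtree_max_leaves=20)
        calls = []

        def rebuild(members):
            calls.append(list(members))
            return self.tree_with_supported_clade(support=40)

        with caplog.at_level(logging.WARNING, logger="lgtscan"):
            clusters = extract_supported_subtrees(
                self.tree_with_supported_clade(support=40), cfg,
                rebuild=rebuild, _max_iterations=2)
        assert len(calls) == 1
        assert any(len(c.members) > cfg.subtree_max_leaves
                   for c in clusters)
        assert "indivisible" in caplog.text

    def test_no_support_values_raises(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        cfg = PipelineConfig(subtree_max_leaves=2)
        with pytest.raises(ValueError, match="support"):
            extract_supported_subtrees(t, cfg)


class TestPatristic:
    def test_path_sums(self):
        t = read_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        d = patristic_distances(t)
        assert d.at["A", "B"] == pytest.approx(0.3)
        assert d.at["A", "C"] == pytest.approx(0.45)
        assert d.at["B", "C"] == pytest.approx(0.55)
        assert (np.diag(d.values) == 0).all()

    def test_matches_pathwalk_oracle_on_random_trees(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(3, 12))
            labels = [f"L{i}" for i in range(n)]
            # random agglomeration with random branch lengths
            parts = [f"{l}:{rng.uniform(0.01, 0.5):.4f}" for l in labels]
            while len(parts) > 1:
                i, j = sorted(rng.choice(len(parts), 2, replace=False),
                              reverse=True)
                a, b = parts.pop(i), parts.pop(j)
                parts.append(f"({a},{b}):{rng.uniform(0.01, 0.5):.4f}")
            tree = read_newick(parts[0] + ";")
            d = patristic_distances(tree)
            for _ in range(5):
                a, b = rng.choice(n, 2, replace=False)
                la, lb = labels[int(a)], labels[int(b)]
                assert d.at[la, lb] == pytest.approx(
                    pathwalk_patristic(tree, la, lb), abs=1e-9)

    def test_four_point_condition(self):
        t = read_newick("((A:0.1,B:0.2):0.1,(C:0.15,D:0.05):0.2);")
        d = patristic_distances(t)
        sums = sorted([d.at["A", "B"] + d.at["C", "D"],
                       d.at["A", "C"] + d.at["B", "D"],
                       d.at["A", "D"] + d.at["B", "C"]])
        assert sums[1] == pytest.approx(sums[2], abs=1e-9)


class TestIncongruenceCalls:
    def run_one(self, distance, neighbor_class="G"):
        t = read_newick(f"((q:{distance / 2},ref1:{distance / 2}):0.1,"
                        "ref2:1.0);")
        classes = {"q": "B", "ref1": neighbor_class, "ref2": "B"}
        origins = {"q": "AU", "ref1": "reference", "ref2": "reference"}
        return call_incongruent_leaves(t, classes, origins,
                                       PipelineConfig())

    def test_out_of_class_within_cutoff_called(self):
        calls, over, reports = self.run_one(0.2)
        assert len(calls) == 1 and over == 0
        call = calls[0]
        assert call.method == "phylogenetic"
        assert call.recipient_class == "B" and call.partner_class == "G"
        assert call.patristic_distance == pytest.approx(0.2)

    def test_out_of_class_beyond_cutoff_tallied(self):
        calls, over, reports = self.run_one(0.35)
        assert calls == [] and over == 1
        assert reports[0].called is False

    def test_same_class_neighbor_no_call(self):
        calls, over, _ = self.run_one(0.01, neighbor_class="B")
        assert calls == [] and over == 0

    @pytest.mark.parametrize("distance,called", [
        (0.29, True), (0.31, False)])
    def test_patristic_boundary(self, distance, called):
        calls, over, _ = self.run_one(distance)
        assert bool(calls) == called

    def test_unlabelled_leaf_excluded(self, caplog):
        import logging
        t = read_newick("((q:0.1,ref1:0.1):0.1,ref2:1.0);")
        classes = {"q": "B", "ref2": "G"}
        origins = {"q": "AU", "ref1": "reference", "ref2": "reference"}
        with caplog.at_level(logging.WARNING, logger="lgtscan"):
            calls, over, _ = call_incongruent_leaves(t, classes, origins)
        assert "no class label" in caplog.text
        # nearest among labelled leaves is ref2 (class G) at 1.2 -> tally
        assert calls == [] and over == 1

    def test_other_community_leaves_not_neighbors(self):
        t = read_newick("((q:0.05,other:0.05):0.1,(sameref:0.6,x:0.1):0.3);")
        classes = {"q": "B", "other": "G", "sameref": "B", "x": "B"}
        origins = {"q": "AU", "other": "DK", "sameref": "reference",
                   "x": "reference"}
        calls, over, reports = call_incongruent_leaves(
            t, classes, origins, PipelineConfig())
        # the DK leaf at 0.1 is ignored; nearest eligible is x (class B)
        focal_q = next(r for r in reports if r.focal_id == "q")
        assert focal_q.nearest_overall_class == "B"
        assert all(c.orf_id != "q" for c in calls)
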