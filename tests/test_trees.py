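"""Rooted trees, edge addressing, network realization and containment."""

import itertools

import numpy as np
import pytest

from hgtmp.trees import (EdgeAddress, HGTEdge, PhyloNetwork, TreeError,
                         contained_trees, is_valid_hgt_edge, parse_newick,
                         realize_network, report_to_string)
from hgtmp.bootstrap import SupportRecord

from conftest import nx_contained_canonicals, random_tree


def addr(*labels):
    return EdgeAddress.of(labels)


class TestParseNewick:
    @pytest.mark.parametrize("text,n_leaves,n_edges", [
        ("((A,B),(C,D));", 4, 6),
        ("(A,B);", 2, 2),
        ("((A,B,C),D);", 4, 5),
    ])
    def test_structure(self, text, n_leaves, n_edges):
        tree = parse_newick(text)
        assert len(tree.leaf_labels) == n_leaves
        assert len(tree.edges()) == n_edges

    def test_polytomy_preserved(self):
        tree = parse_newick("((A,B,C),D);")
        inner = tree.head(addr("A", "B", "C"))
        assert len(inner.children) == 3

    def test_root_trifurcation_accepted(self):
        tree = parse_newick("(A,B,C);")
        assert len(tree.root.children) == 3

    def test_branch_lengths_parsed(self):
        tree = parse_newick("((A:1.5,B:2):0.5,C:3);")
        assert tree.head(addr("A")).length == pytest.approx(1.5)
        assert tree.head(addr("A", "B")).length == pytest.approx(0.5)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((A,B),(A,C));")

    def test_malformed_rejected(self):
        with pytest.raises(TreeError):
            parse_newick("((A,B),(C,D)")

    def test_newick_round_trip(self):
        text = "((A,B),(C,(D,E)));"
        assert parse_newick(parse_newick(text).newick()) == parse_newick(text)


class TestEdgeAddress:
    def test_round_trip_every_edge(self):
        tree = parse_newick("((A,(B,C)),((D,E),F));")
        for e in tree.edges():
            head = tree.head(e)
            assert EdgeAddress.of(tree.clade_of(head)) == e

    def test_unknown_address_raises(self):
        tree = parse_newick("((A,B),C);")
        with pytest.raises(TreeError):
            tree.head(addr("A", "C"))

    def test_restrict_preserves_topology(self):
        tree = parse_newick("((A,(B,C)),((D,E),F));")
        sub = tree.restrict(["A", "B", "D", "E"])
        assert sub == parse_newick("((A,B),(D,E));")


class TestHGTEdgeValidity:
    def test_recipient_ancestor_rejected(self):
        tree = parse_newick("(((A,B),C),D);")
        bad = HGTEdge(addr("A"), addr("A", "B", "C"))
        assert not is_valid_hgt_edge(tree, bad)
        with pytest.raises(TreeError):
            PhyloNetwork(tree, (bad,))

    def test_descendant_source_allowed(self):
        tree = parse_newick("(((A,B),C),D);")
        starred = HGTEdge(addr("A", "B", "C"), addr("A"))
        assert is_valid_hgt_edge(tree, starred)
        PhyloNetwork(tree, (starred,))

    def test_validity_matches_cycle_detection(self, rng):
        """On small trees, the pairwise validity predicate rejects exactly
        the single additions whose realized graph would contain a cycle."""
        for _ in range(10):
            tree = random_tree([f"x{i}" for i in range(6)], rng)
            for src, rcp in itertools.permutations(tree.edges(), 2):
                h = HGTEdge(src, rcp)
                assert is_valid_hgt_edge(tree, h) == \
                    _raw_realize_is_acyclic(tree, h)


def _raw_realize_is_acyclic(tree, h):
    """Cycle check on the split graph built without any validity predicate."""
    import networkx as nx
    g = nx.DiGraph()
    points = {}
    points.setdefault(h.source, []).append("s")
    points.setdefault(h.recipient, []).append("r")
    for node in tree.preorder():
        for child in node.children:
            a = EdgeAddress.of(tree.clade_of(child))
            prev = id(node)
            for pt in points.get(a, []):
                g.add_edge(prev, pt)
                prev = pt
            g.add_edge(prev, id(child))
    g.add_edge("s", "r")
    return nx.is_directed_acyclic_graph(g)


class TestRealizeNetwork:
    def test_no_edges_isomorphic_to_base(self):
        tree = parse_newick("((A,B),(C,D));")
        g = realize_network(PhyloNetwork(tree))
        assert len(g.children) == 7  # 4 leaves + 2 internals + root

    def test_one_edge_adds_two_degree3_nodes(self):
        # mirror of the classic picture: horizontal edge from branch B to
        # branch E creates two new attachment ("rectangular") nodes
        tree = parse_newick("(((a,b),(c,d)),e);")
        h = HGTEdge(addr("a", "b"), addr("e"))
        g = realize_network(PhyloNetwork(tree, (h,)))
        attach = [n for n in g.children
                  if isinstance(n, tuple) and n[0] in ("s", "r")]
        assert len(attach) == 2
        for n in attach:
            deg = len(g.children[n]) + len(g.parents[n])
            assert deg == 3
        assert g.is_acyclic()

    def test_attachment_order_root_to_leaf(self):
        """Two horizontal edges on one base branch attach earlier-inserted
        first (closer to the root)."""
        tree = parse_newick("((A,B),(C,D));")
        h1 = HGTEdge(addr("C", "D"), addr("A"))
        h2 = HGTEdge(addr("C", "D"), addr("B"))
        g = realize_network(PhyloNetwork(tree, (h1, h2)))
        src_edge_chain = g.children[("t", id(tree.root))]
        # the chain below the root towards {C,D} starts at h1's source point
        assert ("s", 0) in src_edge_chain
        assert ("s", 1) not in src_edge_chain
        # h1's attachment continues down the branch to h2's, plus its
        # horizontal edge
        assert set(g.children[("s", 0)]) == {("s", 1), ("r", 0)}

    def test_cycle_reported_for_bad_combination(self):
        tree = parse_newick("((A,B),(C,D));")
        h1 = HGTEdge(addr("A"), addr("C"))
        # recipient ancestor of source: rejected before realization
        with pytest.raises(TreeError):
            PhyloNetwork(tree, (h1, HGTEdge(addr("C"), addr("C", "D"))))


class TestContainedTrees:
    def test_zero_reticulations(self):
        tree = parse_newick("((A,B),(C,D));")
        assert contained_trees(PhyloNetwork(tree)) == [tree]

    def test_single_hgt_two_trees(self):
        """One horizontal edge displays the species tree plus the tree in
        which the recipient clade is re-grafted next to the donor branch."""
        tree = parse_newick("(((a,b),(c,d)),e);")
        net = PhyloNetwork(tree, (HGTEdge(addr("a", "b"), addr("e")),))
        trees = contained_trees(net)
        assert len(trees) == 2
        assert tree in trees
        moved = parse_newick("((((a,b),e),(c,d)));")
        assert parse_newick("(((a,b),e),(c,d));") in trees or moved in trees

    def test_base_tree_always_member(self, rng):
        for _ in range(20):
            tree = random_tree([f"x{i}" for i in range(7)], rng)
            net = _random_network(tree, rng, k=rng.integers(1, 4))
            if net is None:
                continue
            trees = contained_trees(net)
            assert tree in trees
            assert len(trees) <= 2 ** len(net.hgt_edges)

    def test_matches_networkx_oracle(self, rng):
        """Displayed trees equal the independent networkx enumeration on
        random networks with up to 8 leaves and 3 reticulations."""
        checked = 0
        for _ in range(60):
            n = int(rng.integers(4, 9))
            tree = random_tree([f"x{i}" for i in range(n)], rng)
            net = _random_network(tree, rng, k=int(rng.integers(1, 4)))
            if net is None:
                continue
            ours = {t.canonical() for t in contained_trees(net)}
            assert ours == nx_contained_canonicals(net)
            checked += 1
        assert checked >= 30

    def test_descendant_transfer_displays_valid_trees(self):
        tree = parse_newick("(((A,B),C),D);")
        net = PhyloNetwork(tree, (HGTEdge(addr("A", "B", "C"), addr("A")),))
        trees = contained_trees(net)
        assert tree in trees
        for t in trees:
            assert t.leaf_labels == tree.leaf_labels


def _random_network(tree, rng, k):
    edges = tree.edges()
    net = PhyloNetwork(tree)
    for _ in range(k):
        pairs = [(s, r) for s, r in itertools.permutations(edges, 2)
                 if is_valid_hgt_edge(tree, HGTEdge(s, r))
                 and HGTEdge(s, r) not in net.hgt_edges]
        rng.shuffle(pairs)
        for s, r in pairs:
            try:
                net = net.add(HGTEdge(s, r))
                break
            except TreeError:
                continue
    return net if net.hgt_edges else None


class TestEdgeNeighborhood:
    def test_caterpillar_internal_edge(self):
        tree = parse_newick("(((A,B),C),D);")
        x = addr("A", "B")
        dx = tree.edge_neighborhood(x)
        assert dx == {addr("A", "B"), addr("A"), addr("B"), addr("C"),
                      addr("A", "B", "C")}

    def test_root_tail_has_no_parent_term(self):
        tree = parse_newick("((A,B),(C,D));")
        dx = tree.edge_neighborhood(addr("A", "B"))
        assert dx == {addr("A", "B"), addr("C", "D"), addr("A"), addr("B")}

    def test_pendant_edge(self):
        tree = parse_newick("(((A,B),C),D);")
        dx = tree.edge_neighborhood(addr("A"))
        assert dx == {addr("A"), addr("B"), addr("A", "B")}

    def test_contains_self_always(self, rng):
        tree = random_tree([f"x{i}" for i in range(8)], rng)
        for e in tree.edges():
            assert e in tree.edge_neighborhood(e)


class TestReport:
    def _record(self, step, src, rcp, accepted=True):
        return SupportRecord(step=step, edge=HGTEdge(src, rcp), strict=80,
                             relaxed=90, ps_before=100, ps_after=90,
                             accepted=accepted)

    def test_zero_hgt_report(self):
        tree = parse_newick("((A,B),(C,D));")
        text = report_to_string(PhyloNetwork(tree), [])
        lines = text.strip().split("\n")
        assert lines[0].endswith(";")
        assert lines[1].startswith("step\t")
        assert len(lines) == 2

    def test_rows_in_insertion_order(self):
        tree = parse_newick("((A,B),(C,D));")
        recs = [self._record(1, addr("A"), addr("C")),
                self._record(2, addr("B"), addr("D"), accepted=False)]
        net = PhyloNetwork(tree, (HGTEdge(addr("A"), addr("C")),))
        lines = report_to_string(net, recs).strip().split("\n")
        assert lines[2].split("\t")[:3] == ["1", "A", "C"]
        assert lines[3].split("\t")[:3] == ["2", "B", "D"]
        assert lines[3].split("\t")[-1] == "0"
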