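"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately take different routes from the package code:
parsimony by exhaustive enumeration of internal-node labelings, network
containment by networkx subgraph surgery, supports by direct replicate
scans.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from hgtmp.alignment import Alignment
from hgtmp.trees import EdgeAddress, Node, PhyloNetwork, RootedTree

BASES = "ACGT"
BIT = {"A": 1, "C": 2, "G": 4, "T": 8}


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------

def leaf(label: str) -> Node:
    return Node(label)


def join(*children: Node) -> Node:
    node = Node()
    for c in children:
        node.add_child(c)
    return node


def _set_partitions(items: list, min_blocks: int = 2):
    """All partitions of ``items`` into at least ``min_blocks`` blocks."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest, 1) if rest else [[]]:
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def all_rooted_trees(labels: tuple[str, ...]):
    """Every rooted (possibly multifurcating) tree topology on the labels."""
    if len(labels) == 1:
        yield leaf(labels[0])
        return
    for part in _set_partitions(list(labels)):
        if len(part) < 2:
            continue
        for combo in itertools.product(
                *(list(all_rooted_trees(tuple(block))) for block in part)):
            yield join(*(clone_node(c) for c in combo))


def clone_node(node: Node) -> Node:
    new = Node(node.label, node.length)
    for c in node.children:
        new.add_child(clone_node(c))
    return new


def all_binary_rooted_trees(labels: tuple[str, ...]):
    """Every rooted binary topology: each new leaf attaches on any existing
    edge or above the root ((2n-3)!! shapes)."""
    def attach(shape, label):
        yield (shape, label)
        if isinstance(shape, tuple):
            left, right = shape
            for s in attach(left, label):
                yield (s, right)
            for s in attach(right, label):
                yield (left, s)

    def to_node(shape) -> Node:
        if not isinstance(shape, tuple):
            return leaf(shape)
        return join(to_node(shape[0]), to_node(shape[1]))

    shapes = [labels[0]]
    for label in labels[1:]:
        shapes = [s for sh in shapes for s in attach(sh, label)]
    return [to_node(s) for s in shapes]


def random_tree(labels, rng: np.random.Generator,
                polytomy_prob: float = 0.0) -> RootedTree:
    """Random rooted tree by sequential attachment; optional polytomies by
    attaching directly to an internal node."""
    labels = list(labels)
    root = join(leaf(labels[0]), leaf(labels[1]))
    for label in labels[2:]:
        internal = []

        def collect(node):
            internal.append(node)
            for c in node.children:
                if not c.is_leaf:
                    collect(c)
        collect(root)
        if rng.random() < polytomy_prob:
            target = internal[rng.integers(len(internal))]
            target.add_child(leaf(label))
        else:
            nodes = []

            def collect_all(node):
                nodes.append(node)
                for c in node.children:
                    collect_all(c)
            collect_all(root)
            target = nodes[rng.integers(len(nodes))]
            if target is root:
                root = join(root, leaf(label))
            else:
                parent = target.parent
                i = parent.children.index(target)
                pair = join(target, leaf(label))
                parent.children[i] = pair
                pair.parent = parent
    return RootedTree(clone_node(root))


def random_alignment(taxa, n_sites, rng: np.random.Generator,
                     missing_prob: float = 0.0) -> Alignment:
    seqs = {}
    for t in taxa:
        chars = [BASES[rng.integers(4)] if rng.random() >= missing_prob
                 else "-" for _ in range(n_sites)]
        seqs[t] = "".join(chars)
    return Alignment.from_dict(seqs)


# ---------------------------------------------------------------------------
# Parsimony oracle: exhaustive internal labelings
# ---------------------------------------------------------------------------

def brute_force_parsimony(tree: RootedTree, aln: Alignment) -> int:
    """Minimum substitutions over all internal-node state assignments,
    summed over sites.  Missing/ambiguous leaves cost 0 for any compatible
    parent state."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    index = {id(n): i for i, n in enumerate(internals)}
    rows = {t: aln.data[i] for i, t in enumerate(aln.taxa)}
    assigns = np.array(list(itertools.product(range(4),
                                              repeat=len(internals))))
    total = 0
    for site in range(aln.n_sites):
        cost = np.zeros(len(assigns), dtype=np.int64)
        for node in internals:
            a = assigns[:, index[id(node)]]
            for child in node.children:
                if child.is_leaf:
                    mask = int(rows[child.label][site])
                    allowed = np.array([(mask >> b) & 1 for b in range(4)])
                    cost += 1 - allowed[a]
                else:
                    cost += (a != assigns[:, index[id(child)]]).astype(int)
        total += int(cost.min())
    return total


# ---------------------------------------------------------------------------
# Containment oracle: networkx subgraph surgery
# ---------------------------------------------------------------------------

def nx_realized_graph(net: PhyloNetwork) -> tuple[nx.DiGraph, dict]:
    """Independent edge-splitting construction of the realized graph."""
    tree = net.base
    g = nx.DiGraph()
    labels = {}
    points: dict[EdgeAddress, list] = {}
    for i, h in enumerate(net.hgt_edges):
        points.setdefault(h.source, []).append(("s", i))
        points.setdefault(h.recipient, []).append(("r", i))
    for node in tree.preorder():
        nid = ("t", id(node))
        g.add_node(nid)
        if node.is_leaf:
            labels[nid] = node.label
        for child in node.children:
            addr = EdgeAddress.of(tree.clade_of(child))
            prev = nid
            for pt in points.get(addr, []):
                g.add_edge(prev, pt)
                prev = pt
            g.add_edge(prev, ("t", id(child)))
    for i in range(len(net.hgt_edges)):
        g.add_edge(("s", i), ("r", i))
    return g, labels


def nx_contained_canonicals(net: PhyloNetwork) -> set[str]:
    """Canonical topology strings of all displayed trees, via explicit
    incoming-edge choices and degree-2 suppression in networkx."""
    g, labels = nx_realized_graph(net)
    k = len(net.hgt_edges)
    out = set()
    for mask in range(1 << k):
        h = g.copy()
        for i in range(k):
            rnode = ("r", i)
            parents = list(h.predecessors(rnode))
            keep = ("s", i) if (mask >> i) & 1 else \
                next(p for p in parents if p != ("s", i))
            for p in parents:
                if p != keep:
                    h.remove_edge(p, rnode)
        changed = True
        while changed:
            changed = False
            for n in list(h.nodes):
                if n in labels:
                    continue
                if h.out_degree(n) == 0:
                    h.remove_node(n)
                    changed = True
                elif h.in_degree(n) == 1 and h.out_degree(n) == 1:
                    p = next(h.predecessors(n))
                    c = next(h.successors(n))
                    h.remove_node(n)
                    h.add_edge(p, c)
                    changed = True
                elif h.in_degree(n) == 0 and h.out_degree(n) == 1:
                    # unary root: drop it
                    h.remove_node(n)
                    changed = True
        roots = [n for n in h.nodes if h.in_degree(n) == 0]
        assert len(roots) == 1

        def canon(n) -> str:
            if n in labels:
                return labels[n]
            return "(" + ",".join(sorted(canon(c)
                                         for c in h.successors(n))) + ")"
        out.add(canon(roots[0]))
    return out


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
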