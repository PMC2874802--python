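"""Candidate HGT enumeration, best single-edge addition, and parsimony-based
polytomy refinement.

The search is strictly greedy: one horizontal edge is considered at a time,
every ordered pair of base-tree branches is a candidate (horizontal edges are
never split), and a candidate is kept only if the realized graph stays
acyclic given the edges already in the network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .parsimony import fitch_length, network_parsimony
from .trees import (EdgeAddress, HGTEdge, Node, PhyloNetwork, RootedTree,
                    TreeError, is_valid_hgt_edge)

#: polytomies with more children than this are resolved greedily rather than
#: by exhaustive enumeration of binary resolutions
EXHAUSTIVE_POLYTOMY_LIMIT = 7


@dataclass(frozen=True)
class CandidateResult:
    """Outcome of scoring every single-edge addition to a network."""

    best_edges: frozenset  # all HGTEdges attaining best_score
    best_score: int
    baseline_score: int

    def __post_init__(self):
        if self.best_edges and self.best_score > self.baseline_score:
            raise ValueError("best addition cannot score above baseline")


def enumerate_candidates(net: PhyloNetwork) -> list[HGTEdge]:
    """All horizontal edges addable to ``net``: ordered pairs of distinct
    base-tree branches whose recipient is not an ancestor of the source,
    that do not repeat an edge already in the network, and whose addition
    keeps the realized graph acyclic.  Lexicographically sorted."""
    tree = net.base
    existing = set(net.hgt_edges)
    out = []
    for src, rcp in itertools.permutations(tree.edges(), 2):
        h = HGTEdge(src, rcp)
        if h in existing or not is_valid_hgt_edge(tree, h):
            continue
        if net.hgt_edges:
            try:
                net.add(h)
            except TreeError:
                continue
        out.append(h)
    return sorted(out)


def best_single_addition(net: PhyloNetwork, aln: Alignment) -> CandidateResult:
    """Score ``network_parsimony(net + h)`` for every candidate ``h`` and
    return all minimizers together with the baseline score.

    When the data are congruent with the current network the minimizers tie
    with the baseline (adding an edge never helps but never hurts), so
    ``best_edges`` can be large.
    """
    baseline = network_parsimony(net, aln)
    best: list[HGTEdge] = []
    best_score = None
    for h in enumerate_candidates(net):
        score = network_parsimony(net.add(h), aln)
        if best_score is None or score < best_score:
            best, best_score = [h], score
        elif score == best_score:
            best.append(h)
    if best_score is None:  # no candidates (e.g. two-leaf tree fully used)
        return CandidateResult(frozenset(), baseline, baseline)
    return CandidateResult(frozenset(best), min(best_score, baseline),
                           baseline)


# ---------------------------------------------------------------------------
# Polytomy refinement
# ---------------------------------------------------------------------------

def _binary_shapes(k: int):
    """All rooted binary tree shapes on items 0..k-1, as nested pairs.
    (2k-3)!! shapes: each new item attaches on any existing edge or above
    the root."""
    shapes = [0]
    for item in range(1, k):
        grown = []
        for shape in shapes:
            for s in _attach_everywhere(shape, item):
                grown.append(s)
        shapes = grown
    return shapes


def _attach_everywhere(shape, item):
    yield (shape, item)  # above the current root
    if isinstance(shape, tuple):
        left, right = shape
        for s in _attach_everywhere(left, item):
            yield (s, right)
        for s in _attach_everywhere(right, item):
            yield (left, s)


def _shape_to_node(shape, subtrees: list[Node]) -> Node:
    if not isinstance(shape, tuple):
        return subtrees[shape]
    node = Node()
    node.add_child(_shape_to_node(shape[0], subtrees))
    node.add_child(_shape_to_node(shape[1], subtrees))
    return node


def _clone(node: Node) -> Node:
    new = Node(node.label, node.length)
    for c in node.children:
        new.add_child(_clone(c))
    return new


def _resolution_key(node: Node) -> list[tuple[str, ...]]:
    """Sorted list of clades introduced by a resolution; used as the
    deterministic lexicographic tie-break."""
    clades = []

    def walk(n: Node) -> tuple[str, ...]:
        if n.is_leaf:
            return (n.label,)
        labels: tuple[str, ...] = ()
        for c in n.children:
            labels = tuple(sorted(labels + walk(c)))
        clades.append(labels)
        return labels

    walk(node)
    return sorted(clades)


def refine_polytomies(tree: RootedTree, aln: Alignment) -> RootedTree:
    """Resolve every polytomy into the binary arrangement of its children
    that minimizes the tree's parsimony length.

    Polytomies are processed root to leaves, each resolved locally (children
    subtrees kept intact).  Up to :data:`EXHAUSTIVE_POLYTOMY_LIMIT` children
    all binary resolutions are scored exhaustively; larger polytomies are
    resolved by greedy stepwise joining of the best-scoring child pair.
    Score ties are broken by the lexicographically smallest set of
    introduced clades, so the result is deterministic.  Binary trees are
    returned unchanged (up to copying).
    """
    work = tree.copy()
    while True:
        poly = next((n for n in work.preorder() if len(n.children) > 2), None)
        if poly is None:
            return work
        children = [_clone(c) for c in poly.children]
        if len(children) <= EXHAUSTIVE_POLYTOMY_LIMIT:
            candidates = (_shape_to_node(shape, [_clone(c) for c in children])
                          for shape in _binary_shapes(len(children)))
        else:
            candidates = iter([_greedy_resolution(children, poly, work, aln)])
        best = None
        for cand in candidates:
            scored = _with_replacement(work, poly, cand)
            key = (fitch_length(scored, aln), _resolution_key(cand))
            if best is None or key < best[0]:
                best = (key, scored)
        work = best[1]


def _with_replacement(tree: RootedTree, target: Node, new: Node) -> RootedTree:
    def walk(node: Node) -> Node:
        if node is target:
            out = _clone(new)
            out.length = node.length
            return out
        clone = Node(node.label, node.length)
        for c in node.children:
            clone.add_child(walk(c))
        return clone

    return RootedTree(walk(tree.root))


def _greedy_resolution(children: list[Node], poly: Node, tree: RootedTree,
                       aln: Alignment) -> Node:
    """Stepwise grouping for large polytomies: repeatedly join the pair of
    current child groups whose cherry minimizes the tree score."""
    groups = [_clone(c) for c in children]
    while len(groups) > 2:
        best = None
        for i, j in itertools.combinations(range(len(groups)), 2):
            pair = Node()
            pair.add_child(_clone(groups[i]))
            pair.add_child(_clone(groups[j]))
            rest = [ _clone(g) for k, g in enumerate(groups) if k not in (i, j)]
            trial = Node()
            trial.add_child(pair)
            for r in rest:
                trial.add_child(r)
            scored = _with_replacement(tree, poly, trial)
            key = (fitch_length(scored, aln), _resolution_key(trial), (i, j))
            if best is None or key < best[0]:
                best = (key, (i, j))
        i, j = best[1]
        pair = Node()
        pair.add_child(groups[i])
        pair.add_child(groups[j])
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [pair]
    root = Node()
    for g in groups:
        root.add_child(g)
    return root
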