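"""Rooted trees, HGT networks, clade-based edge addressing and newick I/O.

A phylogenetic network is represented here as a species tree plus an ordered
list of directed horizontal (HGT) edges.  Every horizontal edge attaches to
edges of the *base* tree only; attaching realizes two new degree-3 nodes that
split the donor and recipient branches.  The trees *displayed* (contained) by
the network are obtained by keeping one incoming edge per reticulation node
and suppressing the resulting unary nodes.

Edges are addressed by the clade (set of leaf labels) below their head node.
Clades are unique per edge of a tree, are stable across bootstrap replicates
(which all share one species tree), and serialize naturally, so they are used
as the identity of "the same HGT edge" throughout.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy


_logger = logging.getLogger(__name__)


class TreeError(ValueError):
    """Raised for malformed trees, unknown edge addresses or cyclic networks."""


# ---------------------------------------------------------------------------
# Nodes and rooted trees
# ---------------------------------------------------------------------------

class Node:
    """A node of a rooted tree.  Leaves carry a label; edges carry the length
    of the branch above the node (``None`` if absent in the input)."""

    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label: Optional[str] = None,
                 length: Optional[float] = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


@dataclass(frozen=True, order=True)
class EdgeAddress:
    """Identity of a tree edge: the sorted tuple of leaf labels below its head.

    Ordering is lexicographic on the label tuple, which is the deterministic
    tie-break order used everywhere in the package.
    """

    labels: tuple[str, ...]

    @classmethod
    def of(cls, labels: Iterable[str]) -> "EdgeAddress":
        return cls(tuple(sorted(set(labels))))

    @property
    def clade(self) -> frozenset:
        return frozenset(self.labels)

    def __str__(self) -> str:
        return ",".join(self.labels)


@dataclass(frozen=True, order=True)
class HGTEdge:
    """A directed horizontal edge between two species-tree branches.

    ``source`` is the donor branch, ``recipient`` the branch whose subtree
    received the transferred gene.  The recipient must not be an ancestor
    branch of the source (that would realize a directed cycle); the source
    *may* be an ancestor of the recipient — transfers from a branch to its
    own descendant are legitimate under extinction or incomplete sampling.
    """

    source: EdgeAddress
    recipient: EdgeAddress

    def __str__(self) -> str:
        return f"{self.source} -> {self.recipient}"


class RootedTree:
    """A rooted phylogenetic tree with unique leaf labels.

    Polytomies are allowed.  Branch lengths are carried through all topology
    operations but ignored by parsimony scoring.
    """

    def __init__(self, root: Node):
        self.root = root
        self._index()

    # -- construction / indexing ------------------------------------------

    def _index(self) -> None:
        self._clade: dict[Node, frozenset] = {}
        labels: list[str] = []
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf without a label")
                labels.append(node.label)
                self._clade[node] = frozenset((node.label,))
            else:
                if len(node.children) < 2 and node is not self.root:
                    raise TreeError("internal node with a single child")
                clade = frozenset().union(
                    *(self._clade[c] for c in node.children))
                self._clade[node] = clade
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf labels")
        self.leaf_labels: frozenset = frozenset(labels)
        # edge address -> head node; clades are unique per edge in a tree
        self._edge_head: dict[EdgeAddress, Node] = {}
        for node in self.postorder():
            if node is self.root:
                continue
            addr = EdgeAddress.of(self._clade[node])
            if addr in self._edge_head:
                raise TreeError(f"non-unique clade {addr}")
            self._edge_head[addr] = node

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> Iterator[Node]:
        return (n for n in self.postorder() if n.is_leaf)

    # -- edges and addresses ----------------------------------------------

    def edges(self) -> list[EdgeAddress]:
        """All edge addresses, sorted lexicographically."""
        return sorted(self._edge_head)

    def clade_of(self, node: Node) -> frozenset:
        return self._clade[node]

    def head(self, address: EdgeAddress) -> Node:
        try:
            return self._edge_head[address]
        except KeyError:
            raise TreeError(f"no edge with clade {{{address}}} in tree") from None

    def has_edge(self, address: EdgeAddress) -> bool:
        return address in self._edge_head

    def is_ancestor_edge(self, a: EdgeAddress, b: EdgeAddress) -> bool:
        """True if edge ``a`` lies on the path from the root to edge ``b``."""
        return a != b and a.clade > b.clade

    # -- neighborhood D(X) --------------------------------------------------

    def edge_neighborhood(self, x: EdgeAddress) -> set[EdgeAddress]:
        """The source-ambiguity neighborhood D(X) of edge X = (u, v): all
        edges emanating from u or from v, plus the edge incoming into u (if u
        is not the root).  X itself is always a member (it emanates from u)."""
        v = self.head(x)
        u = v.parent
        assert u is not None
        out: set[EdgeAddress] = set()
        for child in u.children:
            out.add(EdgeAddress.of(self._clade[child]))
        for child in v.children:
            out.add(EdgeAddress.of(self._clade[child]))
        if u.parent is not None:
            out.add(EdgeAddress.of(self._clade[u]))
        return out

    # -- serialization ------------------------------------------------------

    def newick(self, lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    s += node.label
            if lengths and node.length is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    def canonical(self) -> str:
        """Topology-only canonical form (children sorted recursively);
        two rooted trees are topologically equal iff their canonicals match."""
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return node.label or ""
            return "(" + ",".join(sorted(fmt(c) for c in node.children)) + ")"

        return fmt(self.root)

    def copy(self) -> "RootedTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return RootedTree(clone(self.root))

    def restrict(self, labels: Iterable[str]) -> "RootedTree":
        """The tree induced on a subset of leaves (unary nodes suppressed,
        branch lengths summed)."""
        keep = frozenset(labels)
        missing = keep - self.leaf_labels
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")

        def prune(node: Node) -> Optional[Node]:
            if node.is_leaf:
                if node.label in keep:
                    return Node(node.label, node.length)
                return None
            kids = [k for k in (prune(c) for c in node.children) if k]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                if child.length is not None and node.length is not None:
                    child.length += node.length
                elif node.length is not None:
                    child.length = node.length
                return child
            new = Node(node.label, node.length)
            for k in kids:
                new.add_child(k)
            return new

        root = prune(self.root)
        if root is None:
            raise TreeError("restriction removes all leaves")
        root.length = None
        return RootedTree(root)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RootedTree):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def __repr__(self) -> str:
        return f"RootedTree({self.newick(lengths=False)!r})"


# ---------------------------------------------------------------------------
# Newick parsing (dendropy does the syntax; we convert)
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> RootedTree:
    """Parse a rooted newick string into a :class:`RootedTree`.

    Polytomies (including an unrooted-style trifurcation at the root) are
    accepted and preserved.  Branch lengths are kept but ignored by all
    parsimony computation.  Duplicate leaf labels are an error.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.is_leaf():
            label = dnode.label
        node = Node(label, dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    if root.is_leaf:
        raise TreeError("tree must have at least two leaves")
    return RootedTree(root)


def read_newick(path) -> RootedTree:
    with open(path) as fh:
        return parse_newick(fh.read())


# ---------------------------------------------------------------------------
# Phylogenetic networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhyloNetwork:
    """A species tree plus an ordered list of horizontal edges.

    The insertion order of ``hgt_edges`` is meaningful: when several
    horizontal edges attach to one base branch, earlier-inserted edges attach
    closer to the root (a fixed deterministic convention).
    """

    base: RootedTree
    hgt_edges: tuple[HGTEdge, ...] = field(default_factory=tuple)

    def __post_init__(self):
        seen = set()
        for h in self.hgt_edges:
            validate_hgt_edge(self.base, h)
            if h in seen:
                raise TreeError(f"duplicate HGT edge {h}")
            seen.add(h)
        shared = len({h.recipient for h in self.hgt_edges})
        if shared < len(self.hgt_edges):
            _logger.debug("multiple horizontal edges share a recipient "
                          "branch; attachments ordered by insertion")
        # acyclicity of the realized graph is the binding constraint
        realize_network(self)

    @property
    def n_reticulations(self) -> int:
        return len(self.hgt_edges)

    def add(self, edge: HGTEdge) -> "PhyloNetwork":
        return PhyloNetwork(self.base, self.hgt_edges + (edge,))


def validate_hgt_edge(tree: RootedTree, h: HGTEdge) -> None:
    """Check a single horizontal edge against the base tree: both endpoints
    must be tree edges, distinct, and the recipient must not be an ancestor
    branch of the source (source-ancestor-of-recipient is allowed)."""
    tree.head(h.source)
    tree.head(h.recipient)
    if h.source == h.recipient:
        raise TreeError(f"source equals recipient: {h}")
    if tree.is_ancestor_edge(h.recipient, h.source):
        raise TreeError(f"recipient is an ancestor of source: {h}")


def is_valid_hgt_edge(tree: RootedTree, h: HGTEdge) -> bool:
    try:
        validate_hgt_edge(tree, h)
    except TreeError:
        return False
    return True


class RealizedGraph:
    """Explicit directed graph of a network: base-tree nodes plus one
    attachment (degree-3) node per horizontal-edge endpoint.

    Node ids: ``("t", node)`` wraps a base-tree node; ``("s", i)`` and
    ``("r", i)`` are the source/recipient attachment points of the i-th
    horizontal edge.  ``lengths[(a, b)]`` carries branch lengths, with
    attachment points spaced evenly along the split branch and horizontal
    edges of length 0.
    """

    def __init__(self):
        self.children: dict = {}
        self.parents: dict = {}
        self.lengths: dict = {}
        self.labels: dict = {}
        self.root = None

    def add_edge(self, a, b, length=None) -> None:
        self.children.setdefault(a, []).append(b)
        self.children.setdefault(b, [])
        self.parents.setdefault(b, []).append(a)
        self.parents.setdefault(a, [])
        self.lengths[(a, b)] = length

    def is_acyclic(self) -> bool:
        indeg = {n: len(p) for n, p in self.parents.items()}
        queue = [n for n, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for c in self.children.get(n, ()):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        return seen == len(self.children)


def realize_network(net: PhyloNetwork) -> RealizedGraph:
    """Build the explicit realized graph of a network, splitting each
    attachment branch into segments.  Raises :class:`TreeError` (naming the
    offending edge) if the horizontal edges jointly create a directed cycle.
    """
    tree = net.base
    # attachment points per base edge, in insertion order (root-ward first)
    points: dict[EdgeAddress, list] = {}
    for i, h in enumerate(net.hgt_edges):
        points.setdefault(h.source, []).append(("s", i))
        points.setdefault(h.recipient, []).append(("r", i))

    g = RealizedGraph()
    g.root = ("t", id(tree.root))
    for node in tree.preorder():
        nid = ("t", id(node))
        g.children.setdefault(nid, [])
        g.parents.setdefault(nid, [])
        if node.is_leaf:
            g.labels[nid] = node.label
        for child in node.children:
            cid = ("t", id(child))
            addr = EdgeAddress.of(tree.clade_of(child))
            chain = points.get(addr, [])
            total = child.length
            seg = (total / (len(chain) + 1)) if total is not None else None
            prev = nid
            for pt in chain:
                g.add_edge(prev, pt, seg)
                prev = pt
            g.add_edge(prev, cid, seg)
    for i, h in enumerate(net.hgt_edges):
        g.add_edge(("s", i), ("r", i), 0.0)
    if not g.is_acyclic():
        raise TreeError(
            "horizontal edges create a directed cycle "
            f"(while adding {net.hgt_edges[-1]})")
    return g


def _displayed_tree(net: PhyloNetwork, g: RealizedGraph,
                    use_horizontal: int) -> RootedTree:
    """The tree displayed under one incoming-edge choice.

    Bit ``i`` of ``use_horizontal`` set means reticulation node ``("r", i)``
    keeps its horizontal parent; otherwise it keeps the vertical one.
    Unary nodes are suppressed with branch lengths summed; if the root is
    left unary it is suppressed too.
    """
    removed_child: dict = {}
    for i in range(len(net.hgt_edges)):
        rnode = ("r", i)
        keep_parent = ("s", i) if (use_horizontal >> i) & 1 else \
            next(p for p in g.parents[rnode] if p != ("s", i))
        for p in g.parents[rnode]:
            if p != keep_parent:
                removed_child.setdefault(p, set()).add(rnode)

    def build(nid, length):
        kids = [c for c in g.children[nid]
                if c not in removed_child.get(nid, ())]
        if not kids:
            if nid in g.labels:
                return Node(g.labels[nid], length)
            return None  # dead attachment stub (no leaves below)
    # NB: recursion depth is bounded by tree height + 2k; fine at desk scale
        built = [b for b in (build(c, g.lengths[(nid, c)]) for c in kids)
                 if b is not None]
        if not built:
            return None
        if len(built) == 1:
            only = built[0]
            if length is not None and only.length is not None:
                only.length += length
            elif length is not None:
                only.length = length
            return only
        node = Node(None, length)
        for b in built:
            node.add_child(b)
        return node

    root = build(g.root, None)
    if root is None or root.is_leaf:
        raise TreeError("degenerate displayed tree")
    root.length = None
    return RootedTree(root)


def contained_trees(net: PhyloNetwork,
                    with_choices: bool = False):
    """The set of trees displayed by the network: one incoming-edge choice
    per reticulation node (2^k combinations), unary suppression, topological
    duplicates removed.  Always contains the base tree (the all-vertical
    choice).  With ``with_choices=True`` returns ``{choice_bitmask: tree}``
    instead of the deduplicated list.
    """
    g = realize_network(net)
    k = len(net.hgt_edges)
    by_choice = {mask: _displayed_tree(net, g, mask) for mask in range(1 << k)}
    if with_choices:
        return by_choice
    unique: dict[str, RootedTree] = {}
    for mask in sorted(by_choice):
        t = by_choice[mask]
        unique.setdefault(t.canonical(), t)
    return list(unique.values())


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ("step", "source_clade", "recipient_clade", "strict_support",
                  "relaxed_support", "ps_before", "ps_after", "accepted")


def write_report(net: PhyloNetwork, records: Sequence, stream) -> None:
    """Write the inference report: the base species tree as newick on the
    first line, then a TSV table of evaluated HGT edges (one row per greedy
    step, in insertion order; the final rejected step included)."""
    stream.write(net.base.newick() + "\n")
    stream.write("\t".join(REPORT_COLUMNS) + "\n")
    for rec in records:
        stream.write("\t".join(str(v) for v in (
            rec.step, rec.edge.source, rec.edge.recipient,
            rec.strict, rec.relaxed, rec.ps_before, rec.ps_after,
            int(rec.accepted))) + "\n")


def report_to_string(net: PhyloNetwork, records: Sequence) -> str:
    buf = io.StringIO()
    write_report(net, records, buf)
    return buf.getvalue()
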