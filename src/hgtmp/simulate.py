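"""Synthetic study generator: birth-death species trees, planted HGT events
with controlled donor-recipient diameter, and K2P sequence evolution.

The generator emulates the study design the inference pipeline is meant for:
50-taxon birth-death species trees (birth 1, death 0), ten genes per tree,
1000-site DNA alignments under the Kimura 2-parameter model with a
transition/transversion rate ratio of 2, and 0-2 horizontal transfers per
gene.  The *diameter* of a transfer is the number of species-tree branches
on the path between donor and recipient branches (sibling pendant branches:
2); a *starred* transfer goes from a branch to one of its own descendants,
which is realizable under extinction or incomplete taxon sampling.

Every event is recorded as a :class:`SimTruth` in clade-level edge
coordinates, so downstream inferences can be scored against the truth
exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from dendropy.model import birthdeath

from .alignment import Alignment
from .trees import (EdgeAddress, HGTEdge, Node, PhyloNetwork, RootedTree,
                    TreeError, contained_trees, is_valid_hgt_edge)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated study (defaults are the study conditions)."""

    n_taxa: int = 50
    birth_rate: float = 1.0
    death_rate: float = 0.0
    n_genes: int = 10
    seq_length: int = 1000
    kappa: float = 2.0           # transition/transversion rate ratio
    n_hgt: int = 1               # transfers per gene (0-2 in the study)
    diameter_range: tuple[int, int] = (2, 10)
    allow_descendant: bool = True
    tree_height: float = 0.5     # expected root-to-tip substitutions/site
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_taxa < 2 or self.seq_length < 1:
            raise ValueError("need at least 2 taxa and 1 site")
        if self.birth_rate <= 0 or self.death_rate < 0 or self.kappa <= 0:
            raise ValueError("rates must be positive (death may be 0)")


@dataclass(frozen=True)
class HGTEvent:
    source: EdgeAddress
    recipient: EdgeAddress
    diameter: int
    starred: bool  # recipient is a descendant branch of the source

    @property
    def edge(self) -> HGTEdge:
        return HGTEdge(self.source, self.recipient)


@dataclass(frozen=True)
class SimTruth:
    gene: str
    events: tuple[HGTEvent, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------

def simulate_species_tree(n_taxa: int = 50, birth_rate: float = 1.0,
                          death_rate: float = 0.0, tree_height: float = 0.5,
                          seed: Optional[int] = None) -> RootedTree:
    """A birth-death species tree with ``n_taxa`` extant leaves labeled
    t1..tn, rescaled so the expected root-to-tip path length equals
    ``tree_height`` substitutions per site.

    With death rate 0 the tree is ultrametric (pure birth).  The process is
    stopped when the n-th lineage is born; all extant tips are then extended
    by one exponential waiting time to the next event, so no pendant branch
    has length zero.
    """
    rng = random.Random(seed)
    dtree = birthdeath.birth_death_tree(
        birth_rate=birth_rate, death_rate=death_rate,
        num_extant_tips=n_taxa, rng=rng,
        is_retain_extinct_tips=False)
    tail = rng.expovariate(n_taxa * (birth_rate + death_rate))

    def convert(dnode) -> Node:
        node = Node(length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        if dnode.is_leaf():
            node.length = (node.length or 0.0) + tail
        return node

    root = convert(dtree.seed_node)
    root.length = None
    for i, leaf in enumerate(_leaves_preorder(root), start=1):
        leaf.label = f"t{i}"
    tree = RootedTree(root)
    depth = _max_depth(root)
    if depth > 0:
        scale = tree_height / depth
        for node in tree.postorder():
            if node.length is not None:
                node.length *= scale
    return tree


def _leaves_preorder(root: Node):
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            yield node
        stack.extend(reversed(node.children))


def _max_depth(root: Node) -> float:
    best = 0.0
    stack = [(root, 0.0)]
    while stack:
        node, d = stack.pop()
        if node.is_leaf:
            best = max(best, d)
        for c in node.children:
            stack.append((c, d + (c.length or 0.0)))
    return best


# ---------------------------------------------------------------------------
# Planting transfers
# ---------------------------------------------------------------------------

def edge_diameter(tree: RootedTree, x: EdgeAddress, y: EdgeAddress) -> int:
    """Number of branches on the species-tree path between edges ``x`` and
    ``y`` (both included): 2 plus the node distance between their nearest
    endpoints.  Sibling pendant branches have diameter 2."""
    depth: dict[int, int] = {}
    parent: dict[int, Node] = {}
    for node in tree.preorder():
        if node.parent is None:
            depth[id(node)] = 0
        else:
            depth[id(node)] = depth[id(node.parent)] + 1
            parent[id(node)] = node.parent

    def nodedist(a: Node, b: Node) -> int:
        d = 0
        while a is not b:
            if depth[id(a)] >= depth[id(b)]:
                a = parent[id(a)]
            else:
                b = parent[id(b)]
            d += 1
        return d

    hx, hy = tree.head(x), tree.head(y)
    ends_x = (hx.parent, hx)
    ends_y = (hy.parent, hy)
    return 2 + min(nodedist(a, b) for a in ends_x for b in ends_y)


def is_descendant_transfer(tree: RootedTree, source: EdgeAddress,
                           recipient: EdgeAddress) -> bool:
    return tree.is_ancestor_edge(source, recipient)


def achievable_diameters(tree: RootedTree,
                         allow_descendant: bool = True) -> dict[int, int]:
    """Diameter -> number of valid ordered donor/recipient pairs."""
    out: dict[int, int] = {}
    for src, rcp, d, _ in _valid_pairs(tree, allow_descendant):
        out[d] = out.get(d, 0) + 1
    return dict(sorted(out.items()))


def _valid_pairs(tree: RootedTree, allow_descendant: bool):
    edges = tree.edges()
    for src in edges:
        for rcp in edges:
            if src == rcp:
                continue
            h = HGTEdge(src, rcp)
            if not is_valid_hgt_edge(tree, h):
                continue
            starred = is_descendant_transfer(tree, src, rcp)
            if starred and not allow_descendant:
                continue
            yield src, rcp, edge_diameter(tree, src, rcp), starred


def plant_hgt_events(tree: RootedTree, k: int,
                     diameter_range: tuple[int, int] = (2, 10),
                     allow_descendant: bool = True,
                     seed: Optional[int] = None,
                     gene: str = "gene") -> SimTruth:
    """Sample ``k`` distinct transfers uniformly among valid donor/recipient
    branch pairs whose diameter lies in ``diameter_range`` (inclusive), such
    that the resulting network is acyclic.  Raises with the achievable
    diameter range if the request cannot be met."""
    if k == 0:
        return SimTruth(gene, ())
    lo, hi = diameter_range
    pool = [(s, r, d, st) for s, r, d, st in _valid_pairs(tree, allow_descendant)
            if lo <= d <= hi]
    if len(pool) < k:
        avail = achievable_diameters(tree, allow_descendant)
        raise TreeError(
            f"cannot plant {k} transfers with diameter in [{lo}, {hi}]; "
            f"achievable diameters: {avail}")
    rng = np.random.default_rng(seed)
    for _ in range(100):  # resample if the combination happens to cycle
        idx = rng.choice(len(pool), size=k, replace=False)
        events = tuple(HGTEvent(pool[i][0], pool[i][1], pool[i][2], pool[i][3])
                       for i in idx)
        try:
            PhyloNetwork(tree, tuple(e.edge for e in events))
        except TreeError:
            continue
        return SimTruth(gene, events)
    raise TreeError("could not find an acyclic transfer combination")


def gene_tree_from_truth(tree: RootedTree, truth: SimTruth) -> RootedTree:
    """The history of the transferred gene: the displayed tree in which every
    planted reticulation takes its horizontal (donor) parent."""
    if not truth.events:
        return tree.copy()
    net = PhyloNetwork(tree, tuple(e.edge for e in truth.events))
    by_choice = contained_trees(net, with_choices=True)
    return by_choice[(1 << len(truth.events)) - 1]


# ---------------------------------------------------------------------------
# K2P sequence evolution
# ---------------------------------------------------------------------------

def k2p_matrix(t: float, kappa: float) -> np.ndarray:
    """K2P transition probability matrix for a branch of length ``t``
    expected substitutions/site; state order A, C, G, T.  Transitions are
    A<->G and C<->T; rates normalized so alpha + 2*beta = 1."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    p_same = 1.0 - p_ts - 2.0 * p_tv
    M = np.full((4, 4), p_tv)
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
        M[i, j] = p_ts
    np.fill_diagonal(M, p_same)
    return M


def evolve_k2p(gene_tree: RootedTree, seq_length: int = 1000,
               kappa: float = 2.0, seed: Optional[int] = None) -> Alignment:
    """Simulate a DNA alignment on ``gene_tree`` under K2P: the root sequence
    is uniform over {A,C,G,T}, sites are i.i.d., and each branch applies its
    closed-form transition matrix."""
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {
        id(gene_tree.root): rng.integers(0, 4, size=seq_length)}
    for node in gene_tree.preorder():
        if node.parent is None:
            continue
        M = k2p_matrix(node.length or 0.0, kappa)
        cum = M.cumsum(axis=1)
        ps = states[id(node.parent)]
        u = rng.random(seq_length)
        states[id(node)] = (u[:, None] > cum[ps]).sum(axis=1)
    masks = np.array([1, 2, 4, 8], dtype=np.uint8)  # A, C, G, T
    leaves = sorted(gene_tree.leaves(), key=lambda n: n.label)
    data = np.stack([masks[states[id(n)]] for n in leaves])
    return Alignment.from_matrix([n.label for n in leaves], data)


# ---------------------------------------------------------------------------
# Whole studies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedGene:
    name: str
    alignment: Alignment
    truth: SimTruth
    gene_tree: RootedTree


@dataclass(frozen=True)
class SimulatedStudy:
    config: SimConfig
    species_tree: RootedTree
    genes: tuple[SimulatedGene, ...]


def simulate_gene(tree: RootedTree, cfg: SimConfig, seed: int,
                  name: str = "gene") -> SimulatedGene:
    truth = plant_hgt_events(tree, cfg.n_hgt, cfg.diameter_range,
                             cfg.allow_descendant, seed=seed, gene=name)
    gtree = gene_tree_from_truth(tree, truth)
    aln = evolve_k2p(gtree, cfg.seq_length, cfg.kappa, seed=seed + 1)
    return SimulatedGene(name, aln, truth, gtree)


def simulate_study(cfg: SimConfig = SimConfig()) -> SimulatedStudy:
    """One full synthetic study: a species tree and ``n_genes`` alignments,
    each with its planted-transfer truth."""
    root_seed = np.random.SeedSequence(cfg.seed)
    tree_seed, *gene_seeds = root_seed.spawn(cfg.n_genes + 1)

    def as_int(ss: np.random.SeedSequence) -> int:
        return int(ss.generate_state(1, dtype=np.uint64)[0] % (1 << 30))

    tree = simulate_species_tree(cfg.n_taxa, cfg.birth_rate, cfg.death_rate,
                                 cfg.tree_height, seed=as_int(tree_seed))
    genes = []
    for i, gs in enumerate(gene_seeds, start=1):
        genes.append(simulate_gene(tree, cfg, seed=as_int(gs) * 2,
                                   name=f"gene{i}"))
    return SimulatedStudy(cfg, tree, tuple(genes))
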