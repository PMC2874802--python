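"""Small parsimony on trees and networks.

``fitch_length`` computes the unweighted parsimony length of a fixed rooted
tree: the minimum number of substitutions over all assignments of states to
internal nodes, summed over sites.  Internally it runs Hartigan's
majority-vote generalization of the Fitch bottom-up pass, which is exact on
arbitrary multifurcations (plain intersect/union accumulation can undercount
on polytomies) and reduces to Fitch at binary nodes.  All sites of a column
are processed at once as numpy bitmask vectors.

``network_parsimony`` scores an HGT network: per block of sites, the best
(minimum) tree score over all trees the network displays; blocks sum.
Adding a horizontal edge can therefore never worsen the score — the displayed
trees of the smaller network are a subset of the larger one's.
"""

from __future__ import annotations

import numpy as np

from .alignment import Alignment
from .trees import PhyloNetwork, RootedTree, contained_trees


def _leaf_rows(tree: RootedTree, aln: Alignment) -> dict[str, np.ndarray]:
    tree_labels = tree.leaf_labels
    aln_labels = set(aln.taxa)
    if tree_labels != aln_labels:
        raise ValueError(
            "tree leaves and alignment taxa differ: "
            f"only-in-tree={sorted(tree_labels - aln_labels)} "
            f"only-in-alignment={sorted(aln_labels - tree_labels)}")
    return {t: aln.data[i] for i, t in enumerate(aln.taxa)}


def site_changes(tree: RootedTree, aln: Alignment) -> np.ndarray:
    """Per-site minimum substitution counts on ``tree`` (int64, length
    ``aln.n_sites``).  ``fitch_length`` is its sum; bootstrap scoring reuses
    it, since a column-resampled replicate only reweights sites."""
    rows = _leaf_rows(tree, aln)
    m = aln.n_sites
    changes = np.zeros(m, dtype=np.int64)
    masks: dict[int, np.ndarray] = {}
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    for node in tree.postorder():
        if node.is_leaf:
            masks[id(node)] = rows[node.label]
            continue
        kids = np.stack([masks.pop(id(c)) for c in node.children])
        # votes per state: how many children admit it at zero extra cost
        votes = ((kids[:, None, :] & bits[None, :, None]) != 0).sum(axis=0)
        top = votes.max(axis=0)
        vu = ((votes == top) * bits[:, None].astype(np.int64)).sum(axis=0)
        masks[id(node)] = vu.astype(np.uint8)
        changes += len(node.children) - top
    return changes


def fitch_length(tree: RootedTree, aln: Alignment) -> int:
    """Parsimony length of a fixed rooted tree (polytomies allowed)."""
    return int(site_changes(tree, aln).sum())


def block_scores(per_site: np.ndarray, aln: Alignment) -> np.ndarray:
    """Sum a per-site change vector within each block."""
    return np.array([per_site[s:e].sum() for s, e in aln.blocks])


def network_parsimony(net: PhyloNetwork, aln: Alignment) -> int:
    """Parsimony length of an HGT network: per block, the minimum tree
    score over all displayed trees; summed over blocks."""
    trees = contained_trees(net)
    per_tree = np.stack([block_scores(site_changes(t, aln), aln)
                         for t in trees])
    return int(per_tree.min(axis=0).sum())


def parsimony_lower_bound(aln: Alignment) -> int:
    """sum_i (c_i - 1) over sites, c_i = number of distinct unambiguous
    states at site i.  No tree or network can score below this."""
    c = aln.site_state_counts()
    return int(np.maximum(c - 1, 0).sum())
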