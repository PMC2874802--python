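"""Column-resampling bootstrap support for HGT edges and the greedy
stopping procedure.

Support of a horizontal edge h : X -> Y inferred on alignment S is measured
by re-running the single-edge-addition analysis on L alignments resampled
(sites with replacement, per block) from S.  With H_i the set of all optimal
edges in replicate i:

* strict support   S(h)  = 100 * |{i : h in H_i}| / L
* relaxed support  S'(h) = 100 * |{i : some (X' -> Y) in H_i, X' in D(X)}| / L

where D(X) is the immediate neighborhood of the source branch (edges out of
its endpoints plus its parent edge).  The relaxation absorbs ambiguity in
the donor only; the recipient must match exactly.

The greedy procedure starts from the species tree, finds the set H of best
single additions, computes b = max_{h in H} S(h), accepts the argmax edge if
b exceeds the threshold (default 70, strict inequality), and stops
otherwise.  One replicate set is drawn per run and re-scored against the
growing network, so step-t supports measure the t-th addition conditioned on
the edges already accepted.

Replicate scoring is exact but never re-runs Fitch per replicate: a
bootstrap replicate is a multiset of original columns, and parsimony is
additive over sites within a block, so each replicate's score of each
candidate tree is a weighted sum of per-site change counts computed once on
the original alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment import Alignment
from .inference import enumerate_candidates
from .parsimony import site_changes
from .trees import (EdgeAddress, HGTEdge, PhyloNetwork, RootedTree,
                    contained_trees)


# ---------------------------------------------------------------------------
# Replicates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateSet:
    """L column-resampled replicates of one alignment, stored as the matrix
    of sampled column indices (each row one replicate, block sizes kept)."""

    source: Alignment
    indices: np.ndarray  # (L, n_sites) int64 column indices into source
    seed: Optional[int]

    @property
    def n_replicates(self) -> int:
        return self.indices.shape[0]

    def replicate(self, i: int) -> Alignment:
        return Alignment(self.source.taxa, self.source.data[:, self.indices[i]],
                         self.source.blocks)

    def __iter__(self):
        return (self.replicate(i) for i in range(self.n_replicates))

    def counts(self) -> np.ndarray:
        """(L, n_sites) multiplicity of each original column per replicate."""
        m = self.source.n_sites
        out = np.zeros((self.n_replicates, m), dtype=np.int64)
        for i in range(self.n_replicates):
            out[i] = np.bincount(self.indices[i], minlength=m)
        return out


def bootstrap_samples(aln: Alignment, n_replicates: int = 100,
                      seed: Optional[int] = None) -> ReplicateSet:
    """Draw ``n_replicates`` bootstrap replicates: within each block, site
    indices are sampled uniformly with replacement, preserving block sizes.
    Reproducible given ``seed``."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    cols = np.concatenate([
        rng.integers(start, end, size=(n_replicates, end - start))
        for start, end in aln.blocks], axis=1)
    return ReplicateSet(aln, cols, seed)


# ---------------------------------------------------------------------------
# Support formulas
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def support_percent(count: int, n: int) -> int:
    return _round_half_up(100.0 * count / n)


def strict_support(h: HGTEdge, replicate_optima: Sequence[set]) -> int:
    """Percentage (0-100, rounded half-up) of replicates whose optimal-edge
    set contains ``h`` exactly."""
    count = sum(1 for H_i in replicate_optima if h in H_i)
    return support_percent(count, len(replicate_optima))


def relaxed_support(h: HGTEdge, replicate_optima: Sequence[set],
                    tree: RootedTree) -> int:
    """Source-relaxed support: a replicate counts (once) if any of its
    optimal edges has the same recipient as ``h`` and a source inside the
    neighborhood D(source(h)) on the species tree."""
    dx = tree.edge_neighborhood(h.source)
    count = 0
    for H_i in replicate_optima:
        if any(e.recipient == h.recipient and e.source in dx for e in H_i):
            count += 1
    return support_percent(count, len(replicate_optima))


def n_accepted_from_supports(supports: Sequence[float],
                             threshold: float = 70) -> int:
    """Number of edges the stopping rule accepts given the per-step support
    sequence: the run of leading values strictly above the threshold (the
    first value at or below it is the rejected step)."""
    n = 0
    for b in supports:
        if b > threshold:
            n += 1
        else:
            break
    return n


# ---------------------------------------------------------------------------
# Greedy inference with the stopping rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StoppingConfig:
    """Configuration of the greedy bootstrap-supported search.

    ``threshold`` is compared strictly (accept when b > threshold).
    ``support_mode`` selects which formula drives acceptance; both are
    always reported.  ``require_improvement`` controls the optimum-set
    convention for replicates in which no candidate strictly improves the
    score: by default such a replicate contributes an empty optimum set
    (nothing was inferred from it).  Setting it to False counts every
    baseline-tying candidate as optimal instead; on alignments highly
    congruent with the current network that inflates the support of all
    candidates at once, so the default is the conservative convention."""

    threshold: float = 70.0
    n_replicates: int = 100
    support_mode: str = "relaxed"  # "strict" | "relaxed"
    max_edges: Optional[int] = None
    require_improvement: bool = True

    def __post_init__(self):
        if not 0 <= self.threshold <= 100:
            raise ValueError("threshold must be in [0, 100]")
        if self.support_mode not in ("strict", "relaxed"):
            raise ValueError("support_mode must be 'strict' or 'relaxed'")


@dataclass(frozen=True)
class SupportRecord:
    """One greedy step: the edge proposed (argmax of support among the
    optimal additions), its supports, scores, and the decision."""

    step: int
    edge: HGTEdge
    strict: int
    relaxed: int
    ps_before: int
    ps_after: int
    accepted: bool
    ambiguity_set: frozenset = field(default_factory=frozenset)
    n_best: int = 1


class _StepScorer:
    """Scores every candidate addition on the original alignment and on all
    replicates at once, via per-site change vectors and one matrix product
    per block.  Per-site vectors are cached across greedy steps by displayed
    tree topology."""

    def __init__(self, aln: Alignment, counts: np.ndarray):
        self.aln = aln
        self.counts = counts.astype(np.float64)
        self._cache: dict[str, np.ndarray] = {}

    def _vector(self, tree: RootedTree) -> np.ndarray:
        key = tree.canonical()
        vec = self._cache.get(key)
        if vec is None:
            vec = site_changes(tree, self.aln)
            self._cache[key] = vec
        return vec

    def score_step(self, net: PhyloNetwork, candidates: list[HGTEdge]):
        aln = self.aln
        base_keys = self._tree_keys(net)
        cand_keys = [self._tree_keys(net.add(h)) for h in candidates]
        order: dict[str, int] = {}
        for keys in [base_keys, *cand_keys]:
            for k in keys:
                order.setdefault(k, len(order))
        W = np.stack([self._cache[k] for k in order])  # (T, m)
        Wf = W.astype(np.float64)

        n_cand, L = len(candidates), self.counts.shape[0]
        orig = np.zeros(n_cand, dtype=np.int64)
        rep = np.zeros((L, n_cand), dtype=np.float64)
        base_orig = 0
        base_rep = np.zeros(L, dtype=np.float64)
        base_idx = [order[k] for k in base_keys]
        cand_idx = [[order[k] for k in keys] for keys in cand_keys]
        for start, end in aln.blocks:
            wsum = W[:, start:end].sum(axis=1)  # (T,)
            M = self.counts[:, start:end] @ Wf[:, start:end].T  # (L, T)
            base_orig += int(wsum[base_idx].min())
            base_rep += M[:, base_idx].min(axis=1)
            for j, idx in enumerate(cand_idx):
                orig[j] += wsum[idx].min()
                rep[:, j] += M[:, idx].min(axis=1)
        return base_orig, base_rep, orig, rep

    def _tree_keys(self, net: PhyloNetwork) -> list[str]:
        keys = []
        for t in contained_trees(net):
            key = t.canonical()
            if key not in self._cache:
                self._cache[key] = site_changes(t, self.aln)
            keys.append(key)
        return keys


def infer_network(tree: RootedTree, aln: Alignment,
                  cfg: StoppingConfig = StoppingConfig(),
                  seed: Optional[int] = None
                  ) -> tuple[PhyloNetwork, list[SupportRecord]]:
    """Greedy bootstrap-supported HGT inference.

    Returns the inferred network and one :class:`SupportRecord` per
    evaluated step, including the final rejected one.  Identical inputs and
    seed give identical results.
    """
    replicates = bootstrap_samples(aln, cfg.n_replicates, seed)
    scorer = _StepScorer(aln, replicates.counts())
    net = PhyloNetwork(tree)
    records: list[SupportRecord] = []
    step = 0
    while cfg.max_edges is None or len(net.hgt_edges) < cfg.max_edges:
        step += 1
        candidates = enumerate_candidates(net)
        if not candidates:
            break
        base_orig, base_rep, orig, rep = scorer.score_step(net, candidates)
        best_score = int(orig.min())
        best_mask = orig == best_score
        # replicate optimal-edge sets as a boolean membership matrix
        rep_min = rep.min(axis=1)
        member = rep == rep_min[:, None]
        if cfg.require_improvement:
            member &= (rep_min < base_rep)[:, None]

        dx_cache: dict[EdgeAddress, set] = {}
        strict_counts = member.sum(axis=0)
        L = member.shape[0]

        def relaxed_of(h: HGTEdge) -> tuple[int, frozenset]:
            dx = dx_cache.get(h.source)
            if dx is None:
                dx = tree.edge_neighborhood(h.source)
                dx_cache[h.source] = dx
            qual = [j for j, c in enumerate(candidates)
                    if c.recipient == h.recipient and c.source in dx]
            hit_rows = member[:, qual].any(axis=1)
            observed = frozenset(
                candidates[j].source for j in qual if member[:, j].any())
            return support_percent(int(hit_rows.sum()), L), observed

        evaluated = []
        for j in np.flatnonzero(best_mask):
            h = candidates[j]
            s = support_percent(int(strict_counts[j]), L)
            r, ambiguity = relaxed_of(h)
            b = r if cfg.support_mode == "relaxed" else s
            evaluated.append((b, h, s, r, ambiguity))
        # argmax of support; ties broken lexicographically on the edge
        evaluated.sort(key=lambda t: (-t[0], t[1]))
        b, h_best, s_best, r_best, amb = evaluated[0]

        accepted = b > cfg.threshold
        records.append(SupportRecord(
            step=step, edge=h_best, strict=s_best, relaxed=r_best,
            ps_before=base_orig, ps_after=best_score, accepted=accepted,
            ambiguity_set=amb, n_best=int(best_mask.sum())))
        if not accepted:
            break
        net = net.add(h_best)
    return net, records


def replicate_optima(tree: RootedTree, aln: Alignment,
                     replicates: ReplicateSet,
                     net: Optional[PhyloNetwork] = None,
                     require_improvement: bool = True) -> list[set]:
    """The per-replicate optimal single-addition edge sets H_i for a given
    network state, computed with the same fast scorer as the greedy loop.
    Mainly for support inspection and testing."""
    net = net if net is not None else PhyloNetwork(tree)
    scorer = _StepScorer(aln, replicates.counts())
    candidates = enumerate_candidates(net)
    _, base_rep, _, rep = scorer.score_step(net, candidates)
    rep_min = rep.min(axis=1)
    member = rep == rep_min[:, None]
    if require_improvement:
        member &= (rep_min < base_rep)[:, None]
    return [{candidates[j] for j in np.flatnonzero(member[i])}
            for i in range(member.shape[0])]
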