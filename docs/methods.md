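# Methods

## The model

A gene that was horizontally transferred has a tree-like history that
disagrees with the species phylogeny in a characteristic way: the recipient
lineage's copy groups with the donor lineage instead of with its vertical
relatives.  We model this by a *phylogenetic network*: a rooted species tree
`ST` augmented with directed horizontal edges, each connecting a donor branch
`X` to a recipient branch `Y`.  Adding an edge splits both branches with a
new degree-3 attachment node and joins the two split points; horizontal
edges are never themselves split by later additions.  A network with `k`
horizontal edges *displays* up to `2^k` trees, one per choice of incoming
edge at each reticulation node (the node of indegree 2 on the recipient
branch), after suppressing the unary nodes that the choice leaves behind.

The parsimony length of a network `N` on an alignment `S` partitioned into
blocks `S^1 … S^k` (one gene = one block throughout) is

    PS(N, S) = Σ_b  min_{T displayed by N}  PS(T, S^b)

where `PS(T, S^b)` is the ordinary (unweighted) small-parsimony length of
tree `T` on block `b`.  Because the displayed trees of `N` are a subset of
those of `N + h`, adding an edge can only preserve or lower the score —
the criterion has no internal complexity penalty, which is exactly why a
stopping rule is needed.

### Scoring a fixed tree

Small parsimony is computed per site by Hartigan's majority-vote bottom-up
pass rather than the binary Fitch intersect/union recurrence: at an internal
node with `c` children, each nucleotide receives one vote from every child
whose optimal state set contains it; with `k` the maximal vote count, the
node's set is the argmax states and the site cost increases by `c − k`.
On binary nodes this is exactly Fitch; on multifurcations it remains exact,
whereas sequential intersect/union can undercount (leaf states A,A,C,C
under a star tree cost 2, not 1).  Gaps, `?`, `N` and IUPAC ambiguity codes
expand to their compatible nucleotide sets and therefore never add cost
(missing data are free); `U` maps to `T`.  Every tree/network score is
bounded below by `Σ_i (c_i − 1)` with `c_i` the number of distinct
unambiguous states at site `i`.

### Bootstrap support of a horizontal edge

Let `H_i` be the set of optimal single-edge additions inferred from the
`i`-th of `ℓ` replicates obtained by resampling sites with replacement
(within each block, preserving block sizes).  For an edge `h : X → Y`:

* strict support  `S(h)  = 100·|{i : h ∈ H_i}| / ℓ`
* relaxed support `S'(h) = 100·|{i : ∃ (X'→Y) ∈ H_i, X' ∈ D(X)}| / ℓ`

`D(X)`, the source neighborhood of branch `X = (u, v)`, contains the edges
out of `u`, the edges out of `v`, and the edge into `u`; `X` is always a
member, so `S'(h) ≥ S(h)`.  Only the source is relaxed: swapping the source
within `D(X)` perturbs the displayed gene tree very locally, whereas moving
the recipient does not, so recipient identity is required to match exactly.
Supports are reported as integers (half-up rounding).

### The greedy search and stopping rule

Starting from `N = ST`: compute the set `H` of single additions minimizing
`PS(N + h, S)`; compute supports for the edges of `H` against the replicate
optima (the replicates are drawn once per run and re-scored against the
growing network, so step-`t` supports are conditional on the `t − 1` edges
already accepted); let `b = max_{h∈H} S'(h)`.  If `b > 70` (strict
inequality; the threshold follows the conventional bootstrap credibility
cutoff) the argmax edge is accepted — ties broken lexicographically on
(source clade, recipient clade) — and the loop repeats; otherwise the
search stops.  Every evaluated step, including the final rejected one, is
recorded with both supports, the score before and after, and the observed
source-ambiguity set.

**Replicate-optimum convention.** A replicate in which *no* candidate
strictly improves the score contributes an empty `H_i` by default.  The
alternative convention — counting every candidate that ties the baseline as
optimal — is available (`require_improvement=False`) but is not the
default, because a congruent replicate then endorses all ~`O(n²)`
candidates simultaneously and the supports of arbitrary edges are inflated
toward 100, defeating the stopping rule on clean alignments.

### Candidate space

Candidates are all ordered pairs of distinct base-tree branches such that
the recipient is not an ancestor branch of the source and the realized
graph (given the edges already accepted) stays acyclic.  A source that is
an ancestor of its recipient is allowed: such "descendant" transfers are
observable under extinction or incomplete taxon sampling.  Edges already in
the network are excluded verbatim; edges sharing one endpoint with them are
not.  When several horizontal edges attach to one base branch, the
earlier-accepted edge attaches closer to the root — an arbitrary but fixed
convention, since no ordering is implied by the model.

### Polytomy refinement

Species trees with unresolved nodes can be refined before the network
search: each polytomy is replaced (root to leaves) by the binary
arrangement of its child subtrees minimizing the tree's parsimony length.
Up to 7 children all `(2c−3)!!` resolutions are scored exhaustively; larger
polytomies are resolved by greedy stepwise joining of the best child pair.
Score ties are broken by the lexicographically smallest set of introduced
clades, so refinement is deterministic.

## Implementation notes

* **Edge identity.** A branch is addressed by the set of leaf labels below
  it.  All bootstrap replicates share the species tree, so clades are
  stable, serializable names that decide "the same edge" across replicates
  and runs.
* **Replicate scoring.** A bootstrap replicate is a multiset of original
  columns, and parsimony is additive over sites within a block.  Per-site
  change vectors are therefore computed once per displayed-tree topology
  (cached across greedy steps) and every replicate×candidate score is a
  single weighted sum, evaluated as one matrix product per block.  This is
  exact — identical to re-running the scorer on each replicate — and is
  verified against the naive route in the tests.
* **Determinism.** All randomness flows from explicit seeds
  (`numpy.random.default_rng` / `random.Random`); candidate lists, tie
  breaks and report rows are sorted, so identical inputs and seed reproduce
  byte-identical reports.
* **Displayed-tree enumeration is exponential in `k`** (`2^k` per candidate
  evaluation).  This is the intended contract at desk scale; acceleration
  techniques for network parsimony (incremental rescoring, bounding) are
  deliberately out of scope.  A `max_edges` cap bounds the greedy depth;
  analyses here use 3–4, since per-gene support sequences rarely stay above
  threshold longer than that.

## The synthetic-data generator

The generator reproduces the study design the method targets:

* **Species trees**: birth-death (birth 1, death 0 ⇒ pure birth,
  ultrametric) with a fixed number of extant taxa (50 by default; the
  scaled-down studies in the tests and the acceptance script use 20 so the
  full bootstrap pipeline runs in minutes on a laptop).  Growth stops when
  the n-th lineage appears and all tips are extended by one exponential
  waiting time, so no pendant branch has length zero.  Heights are rescaled
  so the root-to-tip path is 0.5 expected substitutions/site by default —
  birth-death time units carry no substitution scale of their own, and 0.5
  yields informative but unsaturated 1000-site genes.
* **Transfers**: `k ∈ {0, 1, 2}` donor→recipient branch pairs sampled
  uniformly among valid pairs whose *diameter* — the number of species-tree
  branches on the path between the two branches, both included (sibling
  pendants: 2) — lies in a requested range.  Descendant ("starred")
  transfers are permitted and flagged.  The truth is recorded in clade
  coordinates so inferences can be scored exactly.
* **Sequences**: the transferred gene's history is the displayed tree in
  which every planted reticulation takes its horizontal parent; attachment
  nodes sit at branch midpoints and horizontal edges have length 0.  DNA
  evolves by K2P with transition/transversion rate ratio κ = 2 (rates
  normalized so branch lengths are in expected substitutions/site), root
  state uniform, sites i.i.d., 1000 sites per gene.

What the generator does **not** emulate: rate heterogeneity across sites,
indels, base-composition bias, within-gene recombination breakpoints, and
alignment error.  Passing the synthetic studies therefore demonstrates
correct recovery of the model's own signal, not robustness to real-data
violations of it.

## Behavior under the study conditions

With 20 taxa, 1000 sites and 100 replicates: a single planted transfer of
diameter ≥ 4 is recovered — recipient exact, source within `D` of the true
donor, relaxed support > 70 (usually 100) — in ~9 of 10 runs, and
transfer-free genes are left empty in ~8–10 of 10 runs (the acceptance
script recomputes both rates).  Residual false positives are
diameter-3 moves across internal branches of length ~10⁻³ (about one
expected substitution per gene) — with so little signal the data can
consistently favor the alternative local arrangement, and a bootstrap
cannot distinguish consistent misleading signal from true signal.
Diameter-2 transfers (adjacent branches) are generally *not* detected:
their best-addition improvement is tiny and support stays below threshold.
Both edge regimes are inherent to the parsimony criterion, not artifacts of
the implementation.

## Known limitations

* Strictly greedy, one edge at a time; no simultaneous multi-edge
  optimization and no lookahead.
* Parsimony, not likelihood: no branch lengths, no rate variation; regimes
  that mislead parsimony mislead this method.
* Temporal feasibility is enforced only as acyclicity of the realized
  graph, deliberately, so descendant transfers remain representable.
* Whether two horizontal edges may share a recipient branch is not
  constrained; such configurations are allowed and simply ordered by
  insertion.
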