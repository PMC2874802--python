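"""Model/Results interface to the bootstrap-supported HGT inference.

`HGTParsimonyModel` binds a rooted species tree to a gene alignment (taxa
are intersected automatically, with a warning, when the gene was not
sequenced for every species).  `fit` runs the greedy maximum-parsimony
search with the column-resampling bootstrap stopping rule and returns an
`HGTParsimonyResults` holding the inferred network, per-step support
records, and a printable summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .alignment import Alignment
from .bootstrap import StoppingConfig, SupportRecord, infer_network
from .parsimony import fitch_length, network_parsimony, parsimony_lower_bound
from .trees import (PhyloNetwork, RootedTree, read_newick, report_to_string,
                    write_report)


class HGTParsimonyModel:
    """Maximum-parsimony HGT detection on a fixed species tree.

    Parameters
    ----------
    species_tree
        Rooted species tree; branch lengths, if present, are ignored.
    alignment
        DNA alignment of one gene (or several loci via its block partition).
        Taxa absent from either side are dropped with a warning.
    """

    def __init__(self, species_tree: RootedTree, alignment: Alignment):
        common = species_tree.leaf_labels & set(alignment.taxa)
        if not common:
            raise ValueError("species tree and alignment share no taxa")
        dropped = (species_tree.leaf_labels | set(alignment.taxa)) - common
        if dropped:
            warnings.warn(
                f"restricting analysis to {len(common)} shared taxa "
                f"(dropped: {', '.join(sorted(dropped))})", stacklevel=2)
            if len(common) < 2:
                raise ValueError("fewer than two shared taxa")
            species_tree = species_tree.restrict(common)
            alignment = alignment.restrict(common)
        self.species_tree = species_tree
        self.alignment = alignment

    @classmethod
    def from_files(cls, tree_path, aln_path, fmt: str = "fasta",
                   blocks=None) -> "HGTParsimonyModel":
        tree = read_newick(tree_path)
        aln = Alignment.read(aln_path, fmt=fmt, blocks=blocks)
        return cls(tree, aln)

    # -- plain scores -------------------------------------------------------

    def tree_length(self) -> int:
        """Parsimony length of the species tree itself."""
        return fitch_length(self.species_tree, self.alignment)

    def network_length(self, network: PhyloNetwork) -> int:
        return network_parsimony(network, self.alignment)

    def lower_bound(self) -> int:
        return parsimony_lower_bound(self.alignment)

    # -- fitting ------------------------------------------------------------

    def fit(self, replicates: int = 100, threshold: float = 70.0,
            support: str = "relaxed", seed: Optional[int] = None,
            max_edges: Optional[int] = None,
            require_improvement: bool = True) -> "HGTParsimonyResults":
        """Run the greedy search with the bootstrap stopping rule.

        ``threshold`` is strict: an edge is accepted only when its step
        support exceeds it.  ``support`` ("relaxed" or "strict") selects the
        formula driving acceptance; both are reported.
        """
        cfg = StoppingConfig(threshold=threshold, n_replicates=replicates,
                             support_mode=support, max_edges=max_edges,
                             require_improvement=require_improvement)
        network, records = infer_network(self.species_tree, self.alignment,
                                         cfg, seed=seed)
        return HGTParsimonyResults(self, cfg, seed, network, records)


@dataclass
class HGTParsimonyResults:
    """Result of a greedy bootstrap-supported HGT inference."""

    model: HGTParsimonyModel
    config: StoppingConfig
    seed: Optional[int]
    network: PhyloNetwork
    records: list[SupportRecord]

    @property
    def n_edges(self) -> int:
        return len(self.network.hgt_edges)

    @property
    def step_supports(self) -> list[int]:
        """Per-step driving support values b1, b2, ... (rejected step
        included)."""
        key = self.config.support_mode
        return [getattr(r, "relaxed" if key == "relaxed" else "strict")
                for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "step": r.step,
            "source": str(r.edge.source),
            "recipient": str(r.edge.recipient),
            "strict": r.strict,
            "relaxed": r.relaxed,
            "ps_before": r.ps_before,
            "ps_after": r.ps_after,
            "accepted": r.accepted,
        } for r in self.records]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Bootstrap-supported MP inference of HGT",
            "=" * 55,
            f"taxa: {len(self.model.species_tree.leaf_labels)}   "
            f"sites: {self.model.alignment.n_sites}   "
            f"blocks: {len(self.model.alignment.blocks)}",
            f"replicates: {self.config.n_replicates}   "
            f"threshold: > {self.config.threshold:g}   "
            f"mode: {self.config.support_mode}   seed: {self.seed}",
            f"species-tree parsimony length: "
            f"{self.records[0].ps_before if self.records else self.model.tree_length()}",
            f"accepted HGT edges: {self.n_edges}",
            "",
        ]
        if self.records:
            lines.append(self.to_frame().to_string(index=False))
        return "\n".join(lines) + "\n"

    def report(self) -> str:
        """The machine-readable report: species-tree newick plus the TSV
        table of evaluated edges."""
        return report_to_string(self.network, self.records)

    def write(self, stream) -> None:
        write_report(self.network, self.records, stream)
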