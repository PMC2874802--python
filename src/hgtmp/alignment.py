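"""DNA alignments as bitmask state-set matrices, with FASTA/PHYLIP input.

Each cell holds the set of nucleotides compatible with the observed symbol,
encoded as a 4-bit mask (A=1, C=2, G=4, T=8).  Gaps, ``N`` and ``?`` expand
to the full set {A,C,G,T} — missing data costs nothing under parsimony —
and IUPAC ambiguity codes expand to their usual subsets.  ``U`` maps to T;
case is ignored.

Sites are partitioned into *blocks* (loci): network parsimony picks the best
displayed tree per block.  The default is a single block spanning the whole
alignment (one gene = one block).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO

A, C, G, T = 1, 2, 4, 8
FULL = A | C | G | T

_CODE = {
    "A": A, "C": C, "G": G, "T": T, "U": T,
    "R": A | G, "Y": C | T, "S": G | C, "W": A | T,
    "K": G | T, "M": A | C,
    "B": C | G | T, "D": A | G | T, "H": A | C | T, "V": A | C | G,
    "N": FULL, "-": FULL, "?": FULL, ".": FULL, "X": FULL,
}

_DECODE = {A: "A", C: "C", G: "G", T: "T", FULL: "-"}


class AlignmentError(ValueError):
    pass


def encode_sequence(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq):
        try:
            out[i] = _CODE[ch.upper()]
        except KeyError:
            raise AlignmentError(f"unknown nucleotide symbol {ch!r}") from None
    return out


@dataclass(frozen=True)
class Alignment:
    """taxa x sites state-set matrix with a block partition.

    ``blocks`` are half-open ``(start, end)`` site ranges, 0-based, covering
    all sites disjointly and in order.
    """

    taxa: tuple[str, ...]
    data: np.ndarray  # (n_taxa, n_sites) uint8 bitmasks
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise AlignmentError("data shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        if self.n_sites == 0:
            raise AlignmentError("empty alignment")
        pos = 0
        for start, end in self.blocks:
            if start != pos or end <= start:
                raise AlignmentError("blocks must tile the sites in order")
            pos = end
        if pos != self.n_sites:
            raise AlignmentError("blocks do not cover all sites")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dict(cls, sequences: Mapping[str, str],
                  blocks: Sequence[tuple[int, int]] | None = None
                  ) -> "Alignment":
        taxa = tuple(sequences)
        rows = [encode_sequence(sequences[t]) for t in taxa]
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise AlignmentError("sequences have unequal lengths")
        data = np.vstack(rows)
        return cls(taxa, data,
                   tuple(blocks) if blocks else ((0, data.shape[1]),))

    @classmethod
    def from_matrix(cls, taxa: Sequence[str], data: np.ndarray,
                    blocks: Sequence[tuple[int, int]] | None = None
                    ) -> "Alignment":
        data = np.asarray(data, dtype=np.uint8)
        return cls(tuple(taxa), data,
                   tuple(blocks) if blocks else ((0, data.shape[1]),))

    @classmethod
    def read(cls, path, fmt: str = "fasta",
             blocks: Sequence[tuple[int, int]] | None = None) -> "Alignment":
        """Read an alignment file.  ``fmt``: "fasta" or "phylip"
        (relaxed PHYLIP)."""
        schema = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(fmt)
        if schema is None:
            raise AlignmentError(f"unsupported alignment format {fmt!r}")
        msa = AlignIO.read(str(path), schema)
        return cls.from_dict({rec.id: str(rec.seq) for rec in msa}, blocks)

    # -- basic properties ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def restrict(self, taxa: Iterable[str]) -> "Alignment":
        keep = [t for t in self.taxa if t in set(taxa)]
        if not keep:
            raise AlignmentError("restriction keeps no taxa")
        idx = [self.taxa.index(t) for t in keep]
        return Alignment(tuple(keep), self.data[idx], self.blocks)

    def site_state_counts(self) -> np.ndarray:
        """c_i: number of distinct unambiguous states observed per site
        (gap/ambiguous cells ignored)."""
        counts = np.zeros(self.n_sites, dtype=np.int64)
        determined = np.isin(self.data, (A, C, G, T))
        for state in (A, C, G, T):
            counts += ((self.data == state) & determined).any(axis=0)
        return counts

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """One bootstrap replicate: sample site indices uniformly with
        replacement, independently within each block (block sizes kept)."""
        cols = np.concatenate([
            rng.integers(start, end, size=end - start)
            for start, end in self.blocks])
        return Alignment(self.taxa, self.data[:, cols], self.blocks)

    def to_fasta(self) -> str:
        lines = []
        for i, taxon in enumerate(self.taxa):
            seq = "".join(_DECODE.get(int(v), "N") for v in self.data[i])
            lines.append(f">{taxon}\n{seq}")
        return "\n".join(lines) + "\n"


def parse_block_ranges(text: str, n_sites: int) -> tuple[tuple[int, int], ...]:
    """Parse 1-based inclusive site ranges like ``"1-500,501-1000"`` into the
    internal 0-based half-open block partition."""
    blocks = []
    for part in text.split(","):
        lo, _, hi = part.strip().partition("-")
        start, end = int(lo) - 1, int(hi or lo)
        blocks.append((start, end))
    alignment_check = Alignment(  # reuse the partition validator
        ("x",), np.full((1, n_sites), FULL, dtype=np.uint8), tuple(blocks))
    return alignment_check.blocks
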