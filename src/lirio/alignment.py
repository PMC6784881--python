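"""Multiple-sequence alignment container with FASTA I/O (via Biopython)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Alignment", "AlignmentError"]

DNA_STATES = "ACGT"
PROTEIN_STATES = "ARNDCQEGHILKMFPSTWYV"


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Taxa-labelled character matrix.

    `alphabet` is "dna", "codon" or "protein".  Codon alignments are stored
    as nucleotide strings whose lengths are divisible by 3.
    """

    names: list[str]
    sequences: list[str]
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if len(self.names) != len(self.sequences):
            raise AlignmentError("names/sequences length mismatch")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("duplicate taxon names")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        if self.alphabet == "codon" and self.n_sites % 3 != 0:
            raise AlignmentError("codon alignment length not divisible by 3")

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence(self, name: str) -> str:
        try:
            return self.sequences[self.names.index(name)]
        except ValueError:
            raise KeyError(name) from None

    def subset(self, names: list[str]) -> "Alignment":
        return Alignment(list(names), [self.sequence(n) for n in names], self.alphabet)

    def state_indices(self) -> np.ndarray:
        """Matrix of state indices (n_taxa x n_sites); -1 for gap/ambiguity."""
        states = PROTEIN_STATES if self.alphabet == "protein" else DNA_STATES
        lut = np.full(256, -1, dtype=np.int64)
        for i, c in enumerate(states):
            lut[ord(c)] = i
        if self.alphabet != "protein":
            lut[ord("U")] = states.index("T")
        raw = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_taxa, self.n_sites)
        return lut[raw]

    # -- I/O -----------------------------------------------------------
    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=n, description="")
            for n, s in zip(self.names, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, alphabet: str = "dna") -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records], alphabet)
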