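"""In-frame codon alignment container.

A :class:`CodonAlignment` is the unit every estimator in this package
consumes: a gap-aware matrix of codon states over named taxa.  Codons are
stored as integer indices into the 61 sense codons of the universal code;
``-1`` marks a missing codon (gap or ambiguity), which every likelihood
treats as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import CODON_NUC, codons_to_indices, indices_to_codons


@dataclass
class CodonAlignment:
    taxa: list[str]
    codons: np.ndarray  # (n_taxa, n_codons) int64, -1 = missing

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype=np.int64)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codon matrix shape does not match taxa")
        if self.n_codons == 0:
            raise ValueError("empty alignment")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self.taxa.index(taxon)]

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(list(taxa), self.codons[idx].copy())

    def nucleotides(self) -> np.ndarray:
        """(n_taxa, 3*n_codons) nucleotide indices (0..3, -1 missing)."""
        out = np.full((self.n_taxa, 3 * self.n_codons), -1, dtype=np.int64)
        present = self.codons >= 0
        for p in range(3):
            col = out[:, p::3]
            col[present] = CODON_NUC[self.codons[present], p]
        return out

    def sequences(self) -> dict[str, str]:
        return {
            t: indices_to_codons(self.codons[i]) for i, t in enumerate(self.taxa)
        }

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "CodonAlignment":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("sequences differ in length; not an alignment")
        mat = np.stack([codons_to_indices(seqs[t]) for t in taxa])
        return cls(taxa, mat)

    @classmethod
    def read_fasta(cls, path: str | Path) -> "CodonAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences({r.id: str(r.seq) for r in recs})

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=taxon, description="")
            for taxon, seq in self.sequences().items()
        ]
        SeqIO.write(records, str(path), "fasta")
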