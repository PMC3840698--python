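"""Universal genetic code tables for codon-model machinery.

The codon state space is the 61 sense codons of the standard (universal)
genetic code; stop codons are never part of the state space, matching the
convention of codon substitution models used for coding sequence (CDS)
analysis.  All tables are precomputed at import time as numpy arrays so the
rate-matrix construction and simulation code can stay fully vectorised.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}

_standard = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_standard.stop_codons)

#: the 61 sense codons, lexicographic order (codeml's "universal code" order)
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid (one letter) encoded by each sense codon
CODON_AA: tuple[str, ...] = tuple(str(Seq(c).translate()) for c in SENSE_CODONS)

#: codon index -> (i, j, k) nucleotide indices at the three positions
CODON_NUC = np.array(
    [[NUC_INDEX[b] for b in c] for c in SENSE_CODONS], dtype=np.int64
)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _classify_pair(a: str, b: str) -> tuple[int, bool, bool]:
    """Number of differing positions, and for single-step pairs whether the
    change is a transition and whether it is synonymous."""
    diffs = [p for p in range(3) if a[p] != b[p]]
    if len(diffs) != 1:
        return len(diffs), False, False
    p = diffs[0]
    is_ti = (a[p], b[p]) in _TRANSITIONS
    is_syn = CODON_AA[CODON_INDEX[a]] == CODON_AA[CODON_INDEX[b]]
    return 1, is_ti, is_syn


# Pairwise structure matrices over the 61-codon space:
#   SINGLE_STEP[i, j]  True iff codons differ at exactly one position
#   IS_TRANSITION[i, j] the single differing position is a transition
#   IS_SYNONYMOUS[i, j] the single-step change preserves the amino acid
SINGLE_STEP = np.zeros((N_CODONS, N_CODONS), dtype=bool)
IS_TRANSITION = np.zeros((N_CODONS, N_CODONS), dtype=bool)
IS_SYNONYMOUS = np.zeros((N_CODONS, N_CODONS), dtype=bool)
for _i, _a in enumerate(SENSE_CODONS):
    for _j, _b in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        nd, ti, syn = _classify_pair(_a, _b)
        if nd == 1:
            SINGLE_STEP[_i, _j] = True
            IS_TRANSITION[_i, _j] = ti
            IS_SYNONYMOUS[_i, _j] = syn


def codons_to_indices(seq: str) -> np.ndarray:
    """Encode an in-frame nucleotide string as codon indices.

    Codons containing gaps or ambiguity characters (anything outside ACGT),
    map to -1 and are treated as missing data downstream.

    Raises ValueError if the sequence length is not a multiple of 3 or an
    ungapped codon is a stop codon.
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not a multiple of 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3]
        if codon in CODON_INDEX:
            out[k // 3] = CODON_INDEX[codon]
        elif codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon {k // 3 + 1}")
        else:
            out[k // 3] = -1
    return out


def indices_to_codons(idx: np.ndarray) -> str:
    """Decode codon indices back to a nucleotide string (-1 -> '---')."""
    return "".join(SENSE_CODONS[i] if i >= 0 else "---" for i in idx)


def translate(seq: str) -> str:
    """Translate an in-frame CDS; stops at the first stop codon is an error
    handled by the caller (Biopython semantics: '*' appears in the output)."""
    return str(Seq(seq).translate())
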