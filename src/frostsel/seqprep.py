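"""CDS hygiene and ortholog-set construction.

Ortholog sets are anchored on *Brachypodium distachyon*: for every other
species, a gene joins the set of anchor gene ``a`` iff it is ``a``'s best
similarity hit in that species AND ``a`` is the gene's best hit among all
anchor genes (reciprocal best hit, no score threshold).  Similarity is
computed internally — per-site protein identity for equal-length
translations, a global Needleman–Wunsch-style alignment score otherwise.

Composition rule for a usable set: at least one of {wheat, barley}
(Hordeeae), at least one of {Lolium, Festuca} (Poeae), the anchor, rice,
and at least one PACMAD outgroup — so the smallest passing set has 5 taxa.

A set is labelled LTI (low-temperature induced) iff its barley member or
its *L. perenne* member appears in the LTI gene table; evidence from other
species does not count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .genetic_code import translate
from .topology import (
    ANCHOR_SPECIES,
    BARLEY,
    BRACHYPODIUM,
    HORDEEAE,
    LOLIUM,
    OUTGROUPS,
    POEAE,
    RICE,
)

_VALID_BASES = frozenset("ACGT")


@dataclass
class CdsRecord:
    """One in-frame coding sequence with its translation."""

    id: str
    species: str
    sequence: str
    protein: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.protein and len(self.sequence) % 3 == 0:
            self.protein = translate(self.sequence).rstrip("*")


def filter_cds(
    records: list[CdsRecord], return_reasons: bool = False
):
    """Keep records whose protein starts with M, is at least 30 amino acids
    long, and whose nucleotide sequence contains only unambiguous A/C/G/T
    codons.  Sequences whose length is not a multiple of 3, or that contain
    an internal stop, are rejected with a reason code."""
    kept: list[CdsRecord] = []
    reasons: dict[str, str] = {}
    for rec in records:
        reason = _reject_reason(rec)
        if reason is None:
            kept.append(rec)
        else:
            reasons[rec.id] = reason
    if return_reasons:
        return kept, reasons
    return kept


def _reject_reason(rec: CdsRecord) -> str | None:
    if len(rec.sequence) % 3 != 0:
        return "length_not_multiple_of_3"
    if not set(rec.sequence) <= _VALID_BASES:
        return "ambiguous_codon"
    protein = rec.protein or translate(rec.sequence).rstrip("*")
    if "*" in protein:
        return "internal_stop"
    if not protein.startswith("M"):
        return "no_start_codon"
    if len(protein) < 30:
        return "too_short"
    return None


# -- similarity scoring -------------------------------------------------

_aligner = Align.PairwiseAligner(
    mode="global", match_score=1.0, mismatch_score=0.0,
    open_gap_score=-1.0, extend_gap_score=-0.5,
)


def similarity_score(protein_a: str, protein_b: str) -> float:
    """Symmetric protein similarity: fraction identity for equal lengths
    (vectorised Hamming), otherwise a global alignment score normalised by
    the longer length."""
    if len(protein_a) == len(protein_b):
        a = np.frombuffer(protein_a.encode(), dtype="S1")
        b = np.frombuffer(protein_b.encode(), dtype="S1")
        return float((a == b).mean())
    score = _aligner.score(protein_a, protein_b)
    return float(score) / max(len(protein_a), len(protein_b))


def compute_similarity_scores(
    anchor_records: list[CdsRecord],
    species_records: list[CdsRecord],
) -> pd.DataFrame:
    """All-vs-all anchor/species similarity table with both search
    directions (the internal score is symmetric, so directions agree)."""
    rows = []
    for a in anchor_records:
        for g in species_records:
            s = similarity_score(a.protein, g.protein)
            rows.append((a.id, g.species, g.id, s, "anchor_to_species"))
            rows.append((a.id, g.species, g.id, s, "species_to_anchor"))
    return pd.DataFrame(
        rows, columns=["anchor_id", "species", "gene_id", "score", "direction"]
    )


@dataclass
class OrthologSet:
    """Putative ortholog set anchored on one *B. distachyon* gene;
    at most one member per species (the anchor included)."""

    anchor_id: str
    members: dict[str, str] = field(default_factory=dict)  # species -> gene id
    is_lti: bool = False

    def __post_init__(self) -> None:
        self.members.setdefault(ANCHOR_SPECIES, self.anchor_id)

    @property
    def species_present(self) -> frozenset[str]:
        return frozenset(self.members)


def _best_hit(group: pd.DataFrame, id_col: str) -> str:
    """Top-scoring id; ties broken by lexicographic id (deterministic)."""
    best = group[group["score"] == group["score"].max()]
    return str(best[id_col].min())


def reciprocal_best_hits(scores: pd.DataFrame) -> dict[str, dict[str, str]]:
    """RBH membership from a directional score table.

    ``scores`` columns: anchor_id, species, gene_id, score, direction
    (``anchor_to_species`` / ``species_to_anchor``).  No score threshold is
    applied.  Species whose table lacks either direction are excluded from
    the affected sets.  Output: anchor_id -> {species -> gene_id}.
    """
    fwd = scores[scores["direction"] == "anchor_to_species"]
    rev = scores[scores["direction"] == "species_to_anchor"]
    # best gene per (anchor, species), forward search
    best_gene = {
        key: _best_hit(grp, "gene_id")
        for key, grp in fwd.groupby(["anchor_id", "species"], sort=True)
    }
    # best anchor per (species, gene), reverse search
    best_anchor = {
        key: _best_hit(grp, "anchor_id")
        for key, grp in rev.groupby(["species", "gene_id"], sort=True)
    }
    out: dict[str, dict[str, str]] = {}
    for (anchor, species), gene in sorted(best_gene.items()):
        if best_anchor.get((species, gene)) == anchor:
            out.setdefault(anchor, {})[species] = gene
    return out


def build_ortholog_sets(
    records_by_species: dict[str, list[CdsRecord]],
) -> list[OrthologSet]:
    """Compute internal similarity scores and assemble one RBH ortholog set
    per anchor-species gene."""
    anchors = records_by_species.get(ANCHOR_SPECIES, [])
    if not anchors:
        raise ValueError(f"no {ANCHOR_SPECIES} (anchor) records")
    tables = [
        compute_similarity_scores(anchors, recs)
        for sp, recs in sorted(records_by_species.items())
        if sp != ANCHOR_SPECIES and recs
    ]
    membership = (
        reciprocal_best_hits(pd.concat(tables, ignore_index=True))
        if tables else {}
    )
    sets = []
    for a in sorted(anchors, key=lambda r: r.id):
        members = dict(membership.get(a.id, {}))
        members[ANCHOR_SPECIES] = a.id
        sets.append(OrthologSet(anchor_id=a.id, members=members))
    return sets


def composition_filter(ortholog_set: OrthologSet | frozenset[str]) -> bool:
    """Minimum taxon composition: >=1 Hordeeae species, >=1 Poeae species,
    the anchor, rice, and >=1 PACMAD outgroup (passing floor: 5 taxa)."""
    present = (
        ortholog_set if isinstance(ortholog_set, (set, frozenset))
        else ortholog_set.species_present
    )
    return (
        any(sp in present for sp in HORDEEAE)
        and any(sp in present for sp in POEAE)
        and BRACHYPODIUM in present
        and RICE in present
        and any(sp in present for sp in OUTGROUPS)
    )


def label_lti(
    ortholog_set: OrthologSet,
    lti_table: set[tuple[str, str]] | pd.DataFrame,
) -> bool:
    """LTI iff the set's barley member or *L. perenne* member is listed.

    ``lti_table`` maps (species, gene_id) -> LTI; a DataFrame needs columns
    ``species`` and ``gene_id``.
    """
    if isinstance(lti_table, pd.DataFrame):
        lti_table = set(zip(lti_table["species"], lti_table["gene_id"]))
    for sp in (BARLEY, LOLIUM):
        gene = ortholog_set.members.get(sp)
        if gene is not None and (sp, gene) in lti_table:
            return True
    return False
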