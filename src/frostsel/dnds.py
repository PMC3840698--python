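"""Pairwise dN/dS estimation and per-lineage rate tables.

dS and dN are substitutions per synonymous / nonsynonymous site.  Each
species-to-outgroup pair is fitted by maximum likelihood on the two-taxon
tree under the single-omega codon model; the fitted distance ``t`` (expected
substitutions per codon) is then decomposed:

    rho_S = synonymous fraction of substitution flux under the fitted Q
    f_S   = synonymous fraction under the same Q with omega := 1
            (the synonymous "site" fraction of the mutation process)

    dS = t * rho_S / (3 * f_S)        dN = t * (1 - rho_S) / (3 * (1 - f_S))

which makes dN/dS equal the fitted omega exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .alignment import CodonAlignment
from .codonmodel import CodonModel, f3x4
from .genetic_code import codons_to_indices
from .markov import SpectralQ
from .nucphylo import GeneTree, outgroup_distance
from .topology import OUTGROUPS

_T_MAX = 20.0
MIN_CODONS = 30


@dataclass(frozen=True)
class PairwiseDnds:
    t: float
    kappa: float
    omega: float
    dN: float
    dS: float
    saturated: bool = False


def estimate_pairwise_dnds(
    seq_a, seq_b, pi: np.ndarray
) -> PairwiseDnds:
    """ML fit of (t, kappa, omega) for one sequence pair and the dS/dN
    decomposition.  Sequences are codon index arrays or in-frame strings;
    codons missing in either sequence are excluded pairwise.

    A pair whose distance estimate hits the upper bound is flagged
    ``saturated`` and reported at the bound value.
    """
    a = seq_a if isinstance(seq_a, np.ndarray) else codons_to_indices(seq_a)
    b = seq_b if isinstance(seq_b, np.ndarray) else codons_to_indices(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    if a.size < MIN_CODONS:
        raise ValueError(f"need >= {MIN_CODONS} shared codons, got {a.size}")

    counts = np.bincount(61 * a + b, minlength=61 * 61).reshape(61, 61)
    if np.all(a == b):
        return PairwiseDnds(t=0.0, kappa=1.0, omega=1.0, dN=0.0, dS=0.0)

    def neg_ll(x: np.ndarray) -> float:
        t, kappa, omega = np.exp(x)
        model = CodonModel(kappa=kappa, omega=omega, pi=pi)
        P = SpectralQ(model.rate_matrix(), model.pi).probs(t)
        joint = model.pi[:, None] * P
        with np.errstate(divide="ignore"):
            lj = np.log(joint)
        lj[counts == 0] = 0.0
        val = float((counts * lj).sum())
        return -val if np.isfinite(val) else 1e12

    x0 = np.log([0.3, 2.0, 0.3])
    bounds = [
        (np.log(1e-6), np.log(_T_MAX)),
        (np.log(1e-2), np.log(1e2)),
        (np.log(1e-4), np.log(99.0)),
    ]
    res = minimize(neg_ll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200, "ftol": 1e-12})
    t, kappa, omega = np.exp(res.x)
    model = CodonModel(kappa=kappa, omega=omega, pi=pi)
    rho_s, f_s = model.synonymous_fractions()
    dS = t * rho_s / (3.0 * f_s)
    dN = t * (1.0 - rho_s) / (3.0 * (1.0 - f_s))
    return PairwiseDnds(
        t=float(t), kappa=float(kappa), omega=float(omega),
        dN=float(dN), dS=float(dS), saturated=bool(t > 0.98 * _T_MAX),
    )


def lineage_rates(
    gene_id: str,
    alignment: CodonAlignment,
    gene_tree: GeneTree,
    outgroups: tuple[str, ...] = OUTGROUPS,
) -> pd.DataFrame:
    """Per-species rate rows for one gene: GTR cophenetic distance to the
    outgroup(s) (from the gene tree) plus pairwise dN and dS to each outgroup
    present, averaged over outgroups.

    Codon frequencies for all pairwise fits are the gene alignment's F3x4.
    Returns one row per non-outgroup species present in the gene tree.
    """
    taxa = gene_tree.taxa
    present_outgroups = [og for og in outgroups if og in taxa]
    if not present_outgroups:
        raise ValueError("no outgroup present")
    pi = f3x4(alignment)
    rows = []
    for sp in alignment.taxa:
        if sp in outgroups or sp not in taxa:
            continue
        fits = [
            estimate_pairwise_dnds(alignment.row(sp), alignment.row(og), pi)
            for og in present_outgroups
        ]
        rows.append({
            "gene_id": gene_id,
            "species": sp,
            "gtr_distance": outgroup_distance(gene_tree, sp, outgroups),
            "dS": float(np.mean([f.dS for f in fits])),
            "dN": float(np.mean([f.dN for f in fits])),
            "omega": float(np.mean([f.omega for f in fits])),
            "saturated": any(f.saturated for f in fits),
        })
    return pd.DataFrame(
        rows, columns=["gene_id", "species", "gtr_distance", "dS", "dN",
                       "omega", "saturated"],
    )
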