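"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own likelihood machinery:
transition probabilities come from ``scipy.linalg.expm``, rate matrices are
rebuilt from first principles with Biopython's translation table, and tree
likelihoods are brute-force sums over all internal-node state assignments.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.linalg import expm

from frostsel import SimulationConfig, SpeciesTopology, simulate_gene


@pytest.fixture(scope="session")
def topology() -> SpeciesTopology:
    return SpeciesTopology()


@pytest.fixture(scope="session")
def small_lti_alignment(topology):
    """One LTI gene (strong planted selection) at 200 codons."""
    cfg = SimulationConfig(n_codons=200, seed=42)
    return simulate_gene(topology, cfg, "lti", 42)


@pytest.fixture(scope="session")
def small_background_alignment(topology):
    cfg = SimulationConfig(n_codons=200, seed=43)
    return simulate_gene(topology, cfg, "background", 43)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

NUC = "ACGT"


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             rooting="force-rooted")


def enum_nuc_loglik(taxa, matrix, tree, model) -> float:
    """Brute-force GTR(+gamma) log-likelihood: explicit sum over all
    internal-node state assignments, P(t) by scipy expm."""
    Q = model.rate_matrix()
    cats = model.category_rates()
    pi = model.freqs
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    leaves = {n.taxon.label: n for n in nodes if n.is_leaf()}
    row = {t: i for i, t in enumerate(taxa)}

    total = 0.0
    n_sites = matrix.shape[1]
    for site in range(n_sites):
        site_like = 0.0
        for r in cats:
            P = {
                id(n): expm(Q * (n.edge.length or 0.0) * r)
                for n in nodes if n.parent_node is not None
            }
            cat_like = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                states = {id(n): s for n, s in zip(internals, assign)}
                for lab, leaf in leaves.items():
                    obs = matrix[row[lab], site]
                    states[id(leaf)] = obs
                prob = pi[states[id(tree.seed_node)]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    a = states[id(n.parent_node)]
                    b = states[id(n)]
                    if b == -1:  # missing: sum over states = 1
                        continue
                    prob *= P[id(n)][a, b]
                cat_like += prob
            site_like += cat_like / len(cats)
        total += np.log(site_like)
    return float(total)


def oracle_codon_tables():
    """(sense codons, syn matrix, transition matrix, single-step matrix)
    rebuilt from scratch with Biopython."""
    codons = [
        "".join(c) for c in itertools.product(NUC, repeat=3)
        if str(Seq("".join(c)).translate()) != "*"
    ]
    n = len(codons)
    aa = [str(Seq(c).translate()) for c in codons]
    ti_pairs = {frozenset("AG"), frozenset("CT")}
    single = np.zeros((n, n), bool)
    syn = np.zeros((n, n), bool)
    ti = np.zeros((n, n), bool)
    for i, a in enumerate(codons):
        for j, b in enumerate(codons):
            diffs = [p for p in range(3) if a[p] != b[p]]
            if len(diffs) == 1:
                single[i, j] = True
                syn[i, j] = aa[i] == aa[j]
                ti[i, j] = frozenset(a[diffs[0]] + b[diffs[0]]) in ti_pairs
    return codons, syn, ti, single


def oracle_codon_Q(kappa, omega, pi, syn, ti, single) -> np.ndarray:
    Q = np.zeros_like(syn, dtype=float)
    n = len(pi)
    for i in range(n):
        for j in range(n):
            if not single[i, j]:
                continue
            rate = pi[j]
            if ti[i, j]:
                rate *= kappa
            if not syn[i, j]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def enum_codon_mixture_loglik(
    taxa, codon_matrix, tree, params, foreground_edge_clade=None
) -> float:
    """Brute-force branch-site mixture likelihood on a small tree: explicit
    sum over site classes and internal-node codon states, with the oracle's
    own rate matrices (scipy expm) and the shared background-mixture scale."""
    codons, syn, ti, single = oracle_codon_tables()
    pi = np.maximum(np.asarray(params.pi, float), 1e-12)
    pi = pi / pi.sum()
    weights = params.class_proportions()
    om_bg, om_fg = params.class_omegas()
    # shared scale: background-mixture expected flux
    scale = 0.0
    for w, om in zip(weights, om_bg):
        Q = oracle_codon_Q(params.kappa, om, pi, syn, ti, single)
        scale += w * -np.sum(pi * np.diag(Q))
    Qs = {
        om: oracle_codon_Q(params.kappa, om, pi, syn, ti, single) / scale
        for om in set(np.concatenate([om_bg, om_fg]))
    }
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    leaves = {n.taxon.label: n for n in nodes if n.is_leaf()}
    row = {t: i for i, t in enumerate(taxa)}
    present = set(leaves)

    def is_foreground(node) -> bool:
        if foreground_edge_clade is None:
            return False
        sub = {l.taxon.label for l in node.leaf_iter()}
        target = set(foreground_edge_clade) & present
        return sub == target or sub == present - target

    total = 0.0
    n_states = len(codons)
    for site in range(codon_matrix.shape[1]):
        site_like = 0.0
        for k, w in enumerate(weights):
            if w <= 0:
                continue
            P = {}
            for n in nodes:
                if n.parent_node is None:
                    continue
                om = om_fg[k] if is_foreground(n) else om_bg[k]
                P[id(n)] = expm(Qs[om] * (n.edge.length or 0.0))
            class_like = 0.0
            for assign in itertools.product(
                range(n_states), repeat=len(internals)
            ):
                states = {id(n): s for n, s in zip(internals, assign)}
                for lab, leaf in leaves.items():
                    states[id(leaf)] = codon_matrix[row[lab], site]
                prob = pi[states[id(tree.seed_node)]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    b = states[id(n)]
                    if b == -1:
                        continue
                    prob *= P[id(n)][states[id(n.parent_node)], b]
                class_like += prob
            site_like += w * class_like
        total += np.log(site_like)
    return float(total)
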