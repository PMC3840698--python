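"""Codon rate matrix, F3x4 frequencies and mixture likelihood."""

import numpy as np
import pytest
from conftest import enum_codon_mixture_loglik, tree_from_newick

from frostsel import (
    BranchSiteParams,
    CodonAlignment,
    CodonModel,
    CodonTreeLik,
    build_codon_Q,
    codon_loglik,
    f3x4,
)
from frostsel.genetic_code import (
    CODON_INDEX,
    N_CODONS,
    SENSE_CODONS,
    codons_to_indices,
)
from frostsel.markov import expected_rate


class TestCodonQ:
    def test_synonymous_transition_cell(self):
        """TTT->TTC is a synonymous transition: rate proportional to
        kappa * pi(TTC)."""
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(N_CODONS))
        kappa, omega = 3.0, 0.4
        Q = build_codon_Q(kappa, omega, pi, normalize=False)
        i, j = CODON_INDEX["TTT"], CODON_INDEX["TTC"]
        assert Q[i, j] == pytest.approx(kappa * pi[j], rel=1e-12)
        # TTT->TTA is a nonsynonymous transversion (Phe -> Leu)
        k = CODON_INDEX["TTA"]
        assert Q[i, k] == pytest.approx(omega * pi[k], rel=1e-12)
        # two-position changes are forbidden
        m = CODON_INDEX["TCC"]
        assert Q[i, m] == 0.0

    def test_rows_sum_to_zero_and_scaling(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            pi = rng.dirichlet(np.ones(N_CODONS))
            Q = build_codon_Q(rng.uniform(0.5, 5), rng.uniform(0.01, 3), pi)
            assert np.abs(Q.sum(axis=1)).max() < 1e-12
            assert expected_rate(Q, pi) == pytest.approx(1.0, abs=1e-12)
            # reversibility: pi_i q_ij == pi_j q_ji
            flux = pi[:, None] * Q
            assert np.abs(flux - flux.T).max() < 1e-12

    def test_uniform_neutral_symmetry(self):
        """kappa=1, omega=1, uniform pi: all permitted rates equal."""
        pi = np.full(N_CODONS, 1 / N_CODONS)
        Q = build_codon_Q(1.0, 1.0, pi, normalize=False)
        off = Q[~np.eye(N_CODONS, dtype=bool)]
        permitted = off[off > 0]
        assert np.allclose(permitted, permitted[0])

    def test_invalid_parameters_rejected(self):
        pi = np.full(N_CODONS, 1 / N_CODONS)
        with pytest.raises(ValueError):
            build_codon_Q(-1.0, 0.5, pi)
        with pytest.raises(ValueError):
            build_codon_Q(2.0, 0.5, np.ones(N_CODONS))  # doesn't sum to 1


class TestF3x4:
    def test_uniform_composition(self):
        """Uniform base usage at all positions forces pi_j = 1/61."""
        aln = CodonAlignment(
            ["x"], codons_to_indices("ACGTACGTACGT")[None, :]
        )
        pi = f3x4(aln)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(pi, 1 / 61)

    def test_hand_counted_products(self):
        """Two codons AAA and ACG: position freqs are (A)=1, (A/C)=.5 each,
        (A/G)=.5 each; pi is the product, renormalised over sense codons."""
        aln = CodonAlignment(["x"], codons_to_indices("AAAACG")[None, :])
        pi = f3x4(aln)
        raw = {}
        p1 = {"A": 1.0}
        p2 = {"A": 0.5, "C": 0.5}
        p3 = {"A": 0.5, "G": 0.5}
        for c in SENSE_CODONS:
            raw[c] = p1.get(c[0], 0) * p2.get(c[1], 0) * p3.get(c[2], 0)
        total = sum(raw.values())
        for c in ("AAA", "ACG", "AAG", "ACA"):
            assert pi[CODON_INDEX[c]] == pytest.approx(raw[c] / total,
                                                       abs=1e-12)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)


def _toy_params(pi, omega2=3.0, p0=0.6, p1=0.2):
    return BranchSiteParams(p0=p0, p1=p1, omega0=0.2, omega2=omega2,
                            kappa=2.0, pi=pi)


class TestMixtureLikelihood:
    def test_matches_enumeration_oracle_terminal_foreground(self):
        """3-taxon, 5-codon branch-site likelihood equals the brute-force
        sum over internal states and site classes within 1e-8."""
        rng = np.random.default_rng(7)
        newick = "(a:0.15,b:0.4,c:0.2);"  # trifurcating root: 1 internal node
        tree = tree_from_newick(newick)
        mat = rng.integers(0, N_CODONS, size=(3, 5))
        aln = CodonAlignment(["a", "b", "c"], mat)
        pi = rng.dirichlet(np.ones(N_CODONS))
        params = _toy_params(pi)
        fg = frozenset({"a"})
        got = codon_loglik(aln, tree, params, foreground_clade=fg)
        want = enum_codon_mixture_loglik(
            ["a", "b", "c"], mat, tree_from_newick(newick), params,
            foreground_edge_clade=fg,
        )
        assert got == pytest.approx(want, abs=1e-8)

    def test_matches_enumeration_oracle_internal_foreground(self):
        """4-taxon tree with an unambiguous internal foreground branch."""
        rng = np.random.default_rng(17)
        newick = "((a:0.15,b:0.4):0.12,c:0.2,d:0.3);"
        tree = tree_from_newick(newick)
        mat = rng.integers(0, N_CODONS, size=(4, 4))
        aln = CodonAlignment(["a", "b", "c", "d"], mat)
        pi = rng.dirichlet(np.ones(N_CODONS))
        params = _toy_params(pi, omega2=5.0)
        fg = frozenset({"a", "b"})
        got = codon_loglik(aln, tree, params, foreground_clade=fg)
        want = enum_codon_mixture_loglik(
            ["a", "b", "c", "d"], mat, tree_from_newick(newick), params,
            foreground_edge_clade=fg,
        )
        assert got == pytest.approx(want, abs=1e-8)

    def test_missing_data_matches_oracle(self):
        rng = np.random.default_rng(8)
        newick = "((a:0.1,b:0.3):0.2,c:0.25);"
        mat = rng.integers(0, N_CODONS, size=(3, 4))
        mat[1, 2] = -1  # gap treated as missing
        aln = CodonAlignment(["a", "b", "c"], mat)
        pi = rng.dirichlet(np.ones(N_CODONS))
        params = _toy_params(pi)
        got = codon_loglik(aln, tree_from_newick(newick), params)
        want = enum_codon_mixture_loglik(
            ["a", "b", "c"], mat, tree_from_newick(newick), params
        )
        assert got == pytest.approx(want, abs=1e-8)

    def test_degenerate_mixture_equals_single_omega(self):
        """All classes at omega=1 collapse to the single-omega model."""
        rng = np.random.default_rng(9)
        newick = "((a:0.1,b:0.3):0.2,c:0.25);"
        tree = tree_from_newick(newick)
        mat = rng.integers(0, N_CODONS, size=(3, 6))
        aln = CodonAlignment(["a", "b", "c"], mat)
        pi = rng.dirichlet(np.ones(N_CODONS))
        params = BranchSiteParams(p0=0.5, p1=0.3, omega0=1.0, omega2=1.0,
                                  kappa=2.0, pi=pi)
        single = CodonModel(kappa=2.0, omega=1.0, pi=pi)
        lik = CodonTreeLik(aln, tree)
        assert lik.loglik_mixture(params) == pytest.approx(
            lik.loglik_single(single), abs=1e-10
        )

    def test_foreground_designation_irrelevant_when_omega2_matches(self):
        """With omega2 = 1 and p0 = 0 (everything neutral), the likelihood
        cannot depend on which branch is called foreground."""
        rng = np.random.default_rng(10)
        newick = "((a:0.1,b:0.3):0.2,(c:0.25,d:0.15):0.1);"
        mat = rng.integers(0, N_CODONS, size=(4, 5))
        aln = CodonAlignment(["a", "b", "c", "d"], mat)
        pi = rng.dirichlet(np.ones(N_CODONS))
        params = BranchSiteParams(p0=1e-9, p1=0.5, omega0=1.0, omega2=1.0,
                                  kappa=2.0, pi=pi)
        l1 = codon_loglik(aln, tree_from_newick(newick), params,
                          foreground_clade=frozenset({"a", "b"}))
        l2 = codon_loglik(aln, tree_from_newick(newick), params,
                          foreground_clade=frozenset({"c", "d"}))
        assert l1 == pytest.approx(l2, abs=1e-9)

    def test_posteriors_sum_to_one(self, small_lti_alignment, topology):
        aln, _ = small_lti_alignment
        tree = topology.tree()
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = 0.1
        pi = f3x4(aln)
        lik = CodonTreeLik(aln, tree,
                           foreground_clade=topology.branch_clade(
                               "BP_ancestral"))
        post = lik.site_class_posteriors(_toy_params(pi))
        assert post.shape == (4, aln.n_codons)
        assert np.abs(post.sum(axis=0) - 1.0).max() < 1e-10
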