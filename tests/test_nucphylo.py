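"""GTR pruning likelihood, ML distances, gene trees and QC rules."""

import dendropy
import numpy as np
import pytest
from conftest import enum_nuc_loglik, tree_from_newick

from frostsel import (
    GtrModel,
    SimulationConfig,
    check_topology,
    fit_gene_tree,
    gtr_loglik,
    long_branch_qc,
    ml_pairwise_distance,
    outgroup_distance,
    simulate_gene,
)
from frostsel.gtr import discrete_gamma_rates, jukes_cantor_distance
from frostsel.nucphylo import QcResult, neighbor_joining_tree


def _random_model(rng, gamma=True):
    return GtrModel(
        rates=rng.uniform(0.5, 3.0, size=6),
        freqs=rng.dirichlet(np.ones(4) * 10),
        alpha=float(rng.uniform(0.3, 2.0)) if gamma else None,
    )


class TestPruningLikelihood:
    @pytest.mark.parametrize("gamma", [False, True])
    def test_matches_enumeration_oracle(self, gamma):
        """4-taxon, 10-site pruning equals brute-force enumeration over all
        internal-node assignments within 1e-8 log-units."""
        rng = np.random.default_rng(5)
        newick = "((a:0.1,b:0.35):0.15,(c:0.2,d:0.05):0.08);"
        taxa = ["a", "b", "c", "d"]
        mat = rng.integers(0, 4, size=(4, 10))
        mat[2, 7] = -1  # one missing site
        model = _random_model(rng, gamma=gamma)
        got = gtr_loglik((taxa, mat), tree_from_newick(newick), model)
        want = enum_nuc_loglik(taxa, mat, tree_from_newick(newick), model)
        assert got == pytest.approx(want, abs=1e-8)

    def test_collapsed_tree_single_site(self):
        """Single site, 2 identical tips, zero branch lengths: the
        likelihood collapses to the stationary frequency of the base."""
        model = GtrModel(freqs=np.array([0.1, 0.2, 0.3, 0.4]))
        tree = tree_from_newick("(a:0.0,b:0.0);")
        for base in range(4):
            mat = np.array([[base], [base]])
            ll = gtr_loglik((["a", "b"], mat), tree, model)
            assert ll == pytest.approx(np.log(model.freqs[base]), abs=1e-10)

    def test_rerooting_invariance(self):
        """Reversible model: the likelihood is identical for any rooting."""
        rng = np.random.default_rng(6)
        taxa = ["a", "b", "c", "d"]
        mat = rng.integers(0, 4, size=(4, 20))
        model = _random_model(rng)
        base = "((a:0.1,b:0.35):0.15,(c:0.2,d:0.05):0.08);"
        ll0 = gtr_loglik((taxa, mat), tree_from_newick(base), model)
        # reroot along each edge by writing equivalent newicks
        rerooted = [
            "(a:0.05,(b:0.35,((c:0.2,d:0.05):0.08):0.15):0.05);",
            "((a:0.1,b:0.35):0.23,c:0.2,d:0.05);",
            "(((a:0.1,b:0.35):0.15,(c:0.2,d:0.05):0.08):0.0);",
        ]
        for nwk in rerooted:
            tree = dendropy.Tree.get(data=nwk, schema="newick")
            ll = gtr_loglik((taxa, mat), tree, model)
            assert ll == pytest.approx(ll0, abs=1e-8)

    def test_empty_alignment_rejected(self):
        model = GtrModel()
        tree = tree_from_newick("(a:0.1,b:0.1);")
        with pytest.raises(ValueError):
            gtr_loglik((["a", "c"], np.zeros((2, 3), dtype=int)), tree, model)


class TestGammaRates:
    def test_mean_one_and_monotone(self):
        for alpha in (0.2, 1.0, 7.5):
            r = discrete_gamma_rates(alpha, 4)
            assert r.mean() == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(r) > 0)
        # large alpha: rates collapse toward 1 (rate homogeneity)
        assert np.allclose(discrete_gamma_rates(500.0, 4), 1.0, atol=0.1)


class TestPairwiseDistance:
    def test_jukes_cantor_closed_form(self):
        """Under equal rates and frequencies the ML distance equals the
        JC69 closed form within 1e-4."""
        rng = np.random.default_rng(11)
        model = GtrModel(rates=np.ones(6), freqs=np.full(4, 0.25))
        n = 50_000
        for t_true in (0.05, 0.3, 0.8):
            a = rng.integers(0, 4, size=n)
            # JC transition: stay with prob 1/4 + 3/4 e^{-4t/3}
            p_same = 0.25 + 0.75 * np.exp(-4.0 * t_true / 3.0)
            change = rng.random(n) > p_same
            b = a.copy()
            b[change] = (a[change] + rng.integers(1, 4, size=change.sum())) % 4
            p_mm = float(np.mean(a != b))
            want = jukes_cantor_distance(p_mm)
            got = ml_pairwise_distance(a, b, model)
            assert got == pytest.approx(want, abs=1e-4)

    def test_identical_sequences(self):
        model = GtrModel()
        a = np.tile(np.arange(4), 50)
        assert ml_pairwise_distance(a, a.copy(), model) < 1e-6


class TestFitGeneTree:
    def test_recovers_species_topology(self, topology):
        """Data simulated on the species tree at ample length recovers a
        congruent topology in nearly all replicates."""
        cfg = SimulationConfig(n_codons=400, seed=100)
        ok = 0
        n_rep = 12
        for i in range(n_rep):
            aln, _ = simulate_gene(topology, cfg, "background", 1000 + i)
            gt = fit_gene_tree(aln)
            ok += check_topology(gt, topology)
        assert ok >= n_rep - 1

    def test_identical_sequences_zero_branch(self):
        rng = np.random.default_rng(13)
        mat = rng.integers(0, 4, size=(3, 900))
        mat = np.vstack([mat, mat[2]])  # taxon d identical to c
        gt = fit_gene_tree((["a", "b", "c", "d"], mat))
        pdm = gt.tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in gt.tree.taxon_namespace}
        assert pdm.patristic_distance(tax["c"], tax["d"]) < 1e-6

    def test_loglik_improves_over_nj_start(self):
        rng = np.random.default_rng(14)
        cfg = SimulationConfig(n_codons=150, seed=101)
        from frostsel import SpeciesTopology

        aln, _ = simulate_gene(SpeciesTopology(), cfg, "background", 2000)
        gt = fit_gene_tree(aln)
        assert np.isfinite(gt.log_likelihood)
        # fitted likelihood at least matches a crude equal-rates model
        crude = gtr_loglik(aln, gt.tree, GtrModel(freqs=gt.model.freqs))
        assert gt.log_likelihood >= crude - 1e-6


class TestTopologyCheck:
    def test_pruned_reference_passes(self, topology):
        gene = topology.pruned_tree(
            {"rice", "brachypodium", "barley", "lolium", "maize"})
        assert check_topology(gene, topology)

    def test_swapped_positions_fail(self, topology):
        wrong = dendropy.Tree.get(
            data="((sorghum,maize),(brachypodium,(rice,((wheat,barley),"
                 "(lolium,festuca)))));",
            schema="newick",
        )
        assert not check_topology(wrong, topology)

    def test_five_taxon_set_decidable(self, topology):
        """One species per required clade: the pruned reference has a unique
        unrooted shape, so congruence is decidable and a correct tree
        passes while a scrambled one fails."""
        taxa = {"maize", "rice", "brachypodium", "wheat", "festuca"}
        good = topology.pruned_tree(taxa)
        assert check_topology(good, topology)
        bad = dendropy.Tree.get(
            data="((maize,brachypodium),(rice,(wheat,festuca)));",
            schema="newick",
        )
        assert not check_topology(bad, topology)


class TestLongBranchQc:
    def _tree(self, lengths: dict[str, float]) -> dendropy.Tree:
        nwk = ("((a:{a},b:{b}):{ab},c:{c},d:{d});").format(**lengths)
        return dendropy.Tree.get(data=nwk, schema="newick")

    def test_all_equal_kept(self):
        t = self._tree(dict(a=0.1, b=0.1, ab=0.1, c=0.1, d=0.1))
        assert long_branch_qc(t) == QcResult("keep", None, 1.0)

    def test_external_branch_above_factor_dropped(self):
        t = self._tree(dict(a=0.31, b=0.1, ab=0.05, c=0.1, d=0.08))
        res = long_branch_qc(t)
        assert res.action == "drop_taxon" and res.taxon == "a"
        assert res.ratio == pytest.approx(3.1, rel=1e-9)

    def test_exactly_three_fold_kept(self):
        """The rule is strict: exactly 3.0x the second longest is kept."""
        t = self._tree(dict(a=0.30, b=0.1, ab=0.05, c=0.1, d=0.08))
        assert long_branch_qc(t).action == "keep"

    def test_internal_long_branch_discards(self):
        t = self._tree(dict(a=0.1, b=0.1, ab=0.4, c=0.1, d=0.08))
        assert long_branch_qc(t).action == "discard_tree"

    def test_idempotent_on_kept_tree(self):
        t = self._tree(dict(a=0.2, b=0.1, ab=0.15, c=0.1, d=0.08))
        first = long_branch_qc(t)
        assert first.action == "keep"
        assert long_branch_qc(t) == first

    def test_root_bifurcation_counts_as_one_branch(self):
        """Two root-adjacent edges represent a single unrooted branch and
        must be summed before applying the rule."""
        nwk = "((a:0.1,b:0.1):0.16,(c:0.1,d:0.1):0.16);"
        t = dendropy.Tree.get(data=nwk, schema="newick",
                              rooting="force-rooted")
        res = long_branch_qc(t)
        assert res.action == "discard_tree"  # merged 0.32 > 3 * 0.1


class TestOutgroupDistance:
    def test_hand_worked_toy(self, topology):
        tree = topology.tree()
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = 0.1
        # rice -> sorghum: rice + bep + pacmad-stem... every edge is 0.1;
        # the path rice->sorghum crosses 4 edges, rice->maize also 4
        d = outgroup_distance(tree, "rice")
        assert d == pytest.approx(0.4, abs=1e-12)
        # wheat crosses 7 edges to either outgroup
        assert outgroup_distance(tree, "wheat") == pytest.approx(0.7,
                                                                 abs=1e-12)

    def test_mean_when_both_outgroups_present(self):
        nwk = "((sorghum:0.3,maize:0.5):0.1,rice:0.2);"
        t = dendropy.Tree.get(data=nwk, schema="newick")
        # rice->sorghum = 0.6, rice->maize = 0.8
        assert outgroup_distance(t, "rice") == pytest.approx(0.7, abs=1e-12)

    def test_single_outgroup_and_missing(self):
        nwk = "((sorghum:0.3,rice:0.2):0.1,barley:0.4);"
        t = dendropy.Tree.get(data=nwk, schema="newick")
        assert outgroup_distance(t, "barley") == pytest.approx(0.8, abs=1e-12)
        with pytest.raises(ValueError):
            outgroup_distance(t, "wheat")


def test_neighbor_joining_recovers_additive_tree():
    """NJ on exactly additive distances returns the generating topology."""
    nwk = "((a:0.1,b:0.2):0.05,(c:0.15,d:0.1):0.07);"
    ref = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = ref.phylogenetic_distance_matrix()
    taxa = sorted(t.label for t in ref.taxon_namespace)
    tax = {t.label: t for t in ref.taxon_namespace}
    D = np.array([
        [0.0 if x == y else pdm.patristic_distance(tax[x], tax[y])
         for y in taxa] for x in taxa
    ])
    nj_tree = neighbor_joining_tree(taxa, D)
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nj_tree.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns,
                           rooting="force-unrooted")
    t2 = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns,
                           rooting="force-unrooted")
    from dendropy.calculate import treecompare

    assert treecompare.symmetric_difference(t1, t2) == 0
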