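"""Branch-site test for positive selection on the ancestral Pooideae branch.

Simulates one LTI gene with omega2 = 8 planted on 15% of sites on the
BP_ancestral branch, then runs the branch-site likelihood-ratio test there
and on the unselected core-Pooideae stem for contrast.
"""

from frostsel import (
    SimulationConfig,
    SpeciesTopology,
    fit_branch_site,
    fit_gene_tree,
    simulate_gene,
)

topology = SpeciesTopology()
cfg = SimulationConfig(n_codons=300, seed=11)
aln, truth = simulate_gene(topology, cfg, "lti", 11)
gt = fit_gene_tree(aln)

for branch in ("BP_ancestral", "CP_stem"):
    res = fit_branch_site(aln, gt.tree, branch, gene_id="demo")
    print(f"{branch}: lnL0={res.lnl_null:.2f} lnL1={res.lnl_alt:.2f} "
          f"LR={res.lr:.2f} P={res.p_value:.2e} omega2={res.omega2:.2f}")
    if res.neb_sites:
        print(f"  NEB sites (posterior >= 0.9): "
              f"{', '.join(map(str, res.neb_sites[:12]))}"
          + (" ..." if len(res.neb_sites) > 12 else ""))

planted = truth["selected_sites"].split(";")
print(f"\n{len(planted)} sites were simulated under positive selection on"
      "\nBP_ancestral; a large LR with omega2 >> 1 on that branch and a"
      "\nnear-zero LR on CP_stem is the expected signature.")
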