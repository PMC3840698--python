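# Methods

`frostsel` re-creates, as a tested pipeline on synthetic data, a comparative
molecular-evolution analysis of low-temperature-induced (LTI) genes across
grass lineages: per-lineage substitution rates against warm-climate
outgroups, branch-site tests for episodic positive selection on two
ancestral Pooideae branches, and subset-resampling comparisons of the LTI
gene set against the genome-wide background.

## Study system and species tree

Eight grasses span the contrast between warm- and cold-climate lineages:
sorghum and maize (PACMAD outgroups), rice (Ehrhartoideae), and five
Pooideae — *Brachypodium distachyon* plus the core Pooideae (CP) crops
wheat, barley (Hordeeae) and *Lolium perenne*, *Festuca pratensis* (Poeae).
The rooted reference topology is

```
((sorghum,maize),(rice,(brachypodium,((wheat,barley),(lolium,festuca)))));
```

Two internal branches carry the selection hypotheses:

* `BP_ancestral` — the Pooideae stem (after the rice split, before the
  *Brachypodium* divergence), where cold-climate adaptation is hypothesised
  to have begun;
* `CP_stem` — the stem of the core Pooideae clade.

## Substitution models

**Nucleotide level.** GTR with six exchangeabilities (GT fixed at 1), free
base frequencies and discrete-gamma rate variation (4 equal-probability
categories at their category means, mean-normalised). The rate matrix is
scaled to one expected substitution per site. Likelihoods use Felsenstein
pruning with per-node rescaling; gaps and ambiguity codes are missing data
(partial likelihood 1 over all states).

**Codon level.** A Goldman–Yang-style model on the 61 sense codons of the
universal code. Single-nucleotide changes have rate
`pi_j * {1, kappa, omega, kappa*omega}` for synonymous/nonsynonymous x
transversion/transition; multi-step changes and changes into stops have rate
zero. Codon frequencies are F3x4 (position-specific nucleotide frequencies
multiplied per codon, renormalised); frequencies are floored at 1e-12 inside
likelihood code for spectral stability.

**Branch-site mixture ("Model A" structure).** Four site classes with
proportions `p0, p1, p2a, p2b` where
`p2a = (1-p0-p1) p0/(p0+p1)`, `p2b = (1-p0-p1) p1/(p0+p1)`:
class 0 purifying (`omega0 < 1`) everywhere, class 1 neutral everywhere,
classes 2a/2b purifying/neutral on background branches but `omega2` on the
designated foreground branch. The null fixes `omega2 = 1`; the alternative
bounds `omega2 >= 1`. All class matrices share one scale — the expected flux
of the background-branch mixture — so branch lengths are expected
substitutions per codon under the background process. This convention is
used identically by the simulator and the likelihood, making generated
branch lengths and fitted ones commensurable.

## The branch-site LRT

Per gene and foreground branch:

1. **Branch lengths.** The gene tree's branch-length proportions (from the
   nucleotide fit) are kept; a single codon-scale factor is estimated under
   a preliminary single-omega fit and then fixed — except the foreground
   branch length, which remains a free parameter in both hypotheses. The
   foreground length and `omega2` are confounded: any selection-blind fit
   absorbs foreground selection into a longer branch, and freezing that
   inflated length dilutes the LRT (we measured LR dropping from ~28 to
   ~5.5 on the same planted-selection gene). Freeing the length under both
   models preserves nesting and restores power; this mirrors joint
   branch-length estimation in standard codeml practice.
2. **Null fit** over `(p0, p1, omega0, kappa, t_fg)` with `omega2 = 1`,
   L-BFGS-B on transformed coordinates.
3. **Alternative fit** adds `omega2 in [1, 999]`, started from the four
   values {0.5, 1, 1.5, 2} (sub-boundary starts projected to `1 + 1e-6`),
   each warm-started at the null MLE; the best log-likelihood is kept, so
   the multi-start maximum dominates every single start by construction.
4. **Test.** `LR = max(0, 2 (lnL1 - lnL0))` against the chi-square(1) upper
   tail. The null value sits on the boundary (`omega2 = 1`), so the test is
   conservative (the asymptotic null is a 50:50 mixture of a point mass at
   0 and chi-square(1)); calibration is verified empirically.
5. **Sites.** Candidate positively selected codons by naive empirical Bayes
   at the MLE: posterior class probabilities per site, reporting 1-based
   positions with `P(2a) + P(2b) >= 0.9`. Full Bayes empirical Bayes
   (prior-averaging over parameter uncertainty) is intentionally not
   implemented; NEB keeps the same decision surface and threshold, and the
   output metadata labels the method. At this cutoff, sites that fix no
   substitution on the foreground branch are undetectable in principle,
   which caps attainable recall near 50% at moderate signal; the recovery
   test therefore uses a strong-signal configuration (omega2 = 16,
   foreground length 0.12, 500 codons), where measured recall is ~0.6 with
   <1% false positives.

P-values are Benjamini–Hochberg adjusted per foreground branch across all
tested genes; significance means adjusted p < 0.05.

## Per-lineage rates

Two rate measures per gene and non-outgroup species, both relative to the
maize/sorghum outgroups (averaged when both are present):

* **GTR distance** — cophenetic (path-length) distance on the fitted gene
  tree, substitutions/site;
* **dS, dN** — from a pairwise ML fit of `(t, kappa, omega)` under the
  single-omega codon model. With `rho_S` the synonymous share of
  substitution flux under the fitted matrix and `f_S` the same share at
  `omega := 1`, `dS = t rho_S / (3 f_S)` and
  `dN = t (1 - rho_S) / (3 (1 - f_S))`, which makes `dN/dS = omega` an
  exact identity (asserted to machine precision in tests).

Rows with dS > 2 or dN > 0.5 (strict) are removed as outliers. Within-tree
comparisons use per-gene differences `value(species) - value(rice)`; the
core-Pooideae value is the mean over CP species present in the gene.

## Quality control of ortholog trees

CDS hygiene keeps sequences that translate to `M` + >= 29 further residues
with only unambiguous A/C/G/T codons. Orthology is reciprocal best hit
against the *B. distachyon* anchor with no score threshold; the similarity
score is per-site protein identity for equal-length translations and a
global alignment score otherwise (ties break lexicographically by gene id,
making the output invariant to score-table row order). A usable set needs
>= 1 Hordeeae species, >= 1 Poeae species, the anchor, rice and >= 1
outgroup (minimum 5 taxa). Gene trees are NJ on ML pairwise GTR distances
with all branch lengths and model parameters then optimised jointly;
a tree is kept only if its unrooted topology equals the pruned reference.
The long-branch rule compares the longest branch with the second longest
(a bifurcating root is collapsed first so its two edges count once):
strictly more than 3x drops the offending tip (the reduced set re-enters
the whole loop, capped at 5 rounds) or discards the tree when the branch is
internal. An ortholog set is labelled LTI iff its barley or *L. perenne*
member appears in the LTI gene table — evidence from other species does not
count.

## Resampling tests

Every LTI-versus-all question uses the same machinery: draw subsets of size
|LTI| uniformly without replacement from all genes (LTI genes stay in the
pool) and report the proportion of subsets whose statistic is >= the
observed LTI value (one-sided). Statistics: median (rate differences),
third quartile (likelihood ratios), proportion significant (enrichment).
The default is the plain proportion over 50 000 draws — minimum attainable
P is 0 — with a `+1` correction available as a flag. For enrichment, FDR
adjustment and significance calls are made once globally and subsets
inherit the calls; a `within_subset` variant that re-adjusts inside every
subset is exposed because the choice genuinely changes the null.

## Synthetic data

The generator is the generative mirror of the fitted branch-site model:
site classes i.i.d. per codon, root sequence from the stationary F3x4-style
distribution (built from position-specific base frequencies with GC-rich
third positions typical of grass CDS), and evolution branch-by-branch by an
exact Gillespie jump process per site, recording realized synonymous and
nonsynonymous counts as ground truth. The first codon is a fixed ATG so
simulated CDS satisfy the start-codon hygiene rule. No indels are simulated
— alignments are exact by construction, isolating the statistics under
test.

Defaults are the study conditions the package emulates: 9% LTI genes
(count fixed at `round(n * 0.09)`), 400 codons per gene, kappa 2.5,
background mixture `p0 = 0.88, p1 = 0.07, omega0 = 0.04` (aggregate
dN/dS ~ 0.12), LTI mixture with 15% positively selected sites at
`omega2 = 8` on `BP_ancestral`, per-species dropout probabilities matching
the relative coverage of the source transcriptome collections (festuca
0.59, wheat 0.26, barley 0.13, lolium 0.07, outgroups 0.03–0.06, rice and
the anchor 0), and branch lengths (substitutions/codon) chosen so
species-to-outgroup synonymous distances land near 0.6 with the CP > Bd >
rice ordering of the real data. The source text reports no empirical branch
lengths; these are this package's own calibrated defaults, stated in
`config.txt` of every run. Contaminants replace one non-anchor taxon's
sequence with one re-evolved from its ancestral state over 3.5x the tree
depth, guaranteeing the long-branch rule can fire downstream.

What the generator does *not* emulate: transcriptome assembly noise,
ORF-prediction and alignment errors, indels, codon-usage autocorrelation
along genes, among-gene variation in kappa/base composition, and gene
duplication. Passing tests therefore demonstrate correctness and
calibration of the statistical machinery under the model's own assumptions,
not robustness to real-data artefacts.

## Numerical choices

* Reversible rate matrices are diagonalised once per parameter vector via
  the symmetrised form; P(t) is reconstructed per branch. Pruning rescales
  conditionals per internal node, so likelihoods to ~1e-300 per site are
  safe.
* Site classes sharing a background omega share all subtree conditionals
  not above the foreground branch; only root-path nodes are recomputed per
  class (~1.7x speedup of mixture evaluations).
* Optimisers are bounded L-BFGS-B in log/logit coordinates; `ftol` 1e-8 to
  2e-8 (log-likelihood converged to ~1e-4, far below LRT resolution).
  Branch lengths are bounded to [1e-8, 15] (nucleotide) and the pairwise
  codon distance to [1e-6, 20], with fits at the upper bound flagged
  saturated.
* Identical pairwise sequences short-circuit to dS = dN = t = 0.
* The long-branch ratio with a zero-length second branch is treated as
  infinite when the longest branch is positive, 1 otherwise.
* Ties in RBH best hits break lexicographically; all stage outputs are
  sorted, and every random draw descends from one `SeedSequence`, so runs
  are byte-reproducible.

## Test scales

Oracle and rule-fidelity tests are exact and instant. The statistical
checks run at sizes chosen to be decisive at desk scale: LRT null
calibration on 100 genes x 100 codons (expected rejection ~1–3% against the
6% bound, binomial error well clear), end-to-end signal recovery on 3
replicate pipelines of 28 genes x 300 codons (detection required in >= 2/3
replicates on the selected branch, <= 1/3 false alarms on the unselected
branch), omega2 recovery over 5 replicates of 300 codons, and NEB recovery
over 3 replicates of 500 codons. Gene length matters more than gene count
for the enrichment cascade (raw LRT p -> BH-FDR -> proportion resampling):
halving gene length halves each LR and strands borderline genes above the
FDR threshold, so the end-to-end tests keep genes near the study's mean
alignment length and scale the gene count instead. The acceptance script
runs one 56-gene x 300-codon pipeline with 20 000 resamples.

## Known limitations

* NEB instead of BEB for site identification (see above); posterior
  probabilities are conditional on the MLE.
* The branch-site fit re-optimises only the foreground branch length;
  residual misestimation of background lengths can leak into the mixture
  weights (conservative in our calibration runs).
* omega2 estimates are upward-biased when foreground selected sites are
  saturated (multiple substitutions per site), as with any codon-model MLE
  at boundary mixtures.
* The RBH similarity score on unequal-length translations is a generic
  global alignment score, not BLASTP bit scores; on synthetic equal-length
  data the Hamming path dominates.
* Resampling P-values have resolution 1/n_resamples and no +1 floor by
  default.
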