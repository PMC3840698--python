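"""Branch-site likelihood-ratio test for episodic positive selection.

The alternative model is the branch-site site-class mixture of
:mod:`frostsel.codonmodel` with ``omega2 >= 1`` free on the designated
foreground branch; the null fixes ``omega2 = 1``.  Twice the log-likelihood
difference is compared with a chi-square distribution with one degree of
freedom (a conservative convention, since the null value lies on the
boundary of the parameter space).

Fitting protocol:

* branch lengths are fixed before the test: the input tree's branch-length
  proportions are kept and a single overall codon-scale factor is estimated
  under a preliminary single-omega fit.  The one exception is the foreground
  branch itself, whose length is confounded with omega2 (selection inflates
  the apparent length under any selection-blind fit); it is therefore
  re-optimised as a free parameter inside BOTH the null and the alternative
  fit, which preserves the nesting of the LRT;
* the alternative is started from four omega2 values {0.5, 1, 1.5, 2}
  (starts below the omega2 >= 1 bound are projected just above it), each
  warm-started at the null MLE for the remaining parameters, and the best
  log-likelihood is kept;
* candidate positively selected codons are reported by naive empirical
  Bayes at the MLE: 1-based positions whose posterior probability of the
  positively selected classes (2a + 2b) is at least 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import CodonAlignment
from .codonmodel import (
    BranchSiteParams,
    CodonModel,
    CodonTreeLik,
    ForegroundMissingError,
    f3x4,
)
from .topology import BRANCH_CLADES

__all__ = [
    "SelectionTestResult",
    "fit_branch_site",
    "fit_codon_scale",
    "lrt_pvalue",
    "neb_sites",
    "ForegroundMissingError",
]

OMEGA2_STARTS = (0.5, 1.0, 1.5, 2.0)
_OMEGA2_EPS = 1e-6


def lrt_pvalue(lnl_null: float, lnl_alt: float) -> float:
    """Upper chi-square(1) tail at LR = max(0, 2*(lnl_alt - lnl_null))."""
    lr = max(0.0, 2.0 * (lnl_alt - lnl_null))
    return float(chi2.sf(lr, df=1))


@dataclass
class SelectionTestResult:
    gene_id: str
    foreground: str
    lnl_null: float
    lnl_alt: float
    omega2: float
    neb_sites: tuple[int, ...] = ()
    p_fdr: float = float("nan")
    params_alt: BranchSiteParams | None = field(default=None, repr=False)
    params_null: BranchSiteParams | None = field(default=None, repr=False)

    @property
    def lr(self) -> float:
        return max(0.0, 2.0 * (self.lnl_alt - self.lnl_null))

    @property
    def p_value(self) -> float:
        return lrt_pvalue(self.lnl_null, self.lnl_alt)


def _resolve_clade(foreground) -> tuple[str, frozenset[str]]:
    if isinstance(foreground, str):
        return foreground, BRANCH_CLADES[foreground]
    return "custom", frozenset(foreground)


def _mixture_neg_ll(lik, pi, fg_eid, omega2_fixed):
    """Objective over x = (q, r, omega0, log kappa[, log omega2], log t_fg);
    the foreground branch length t_fg is the last element."""

    def neg_ll(x):
        q, r, omega0 = x[0], x[1], x[2]
        kappa = float(np.exp(x[3]))
        omega2 = float(np.exp(x[4])) if omega2_fixed is None else omega2_fixed
        lik.edge_lengths[fg_eid] = float(np.exp(x[-1]))
        try:
            params = BranchSiteParams(
                p0=q * r, p1=q * (1 - r), omega0=omega0,
                omega2=max(omega2, 1.0), kappa=kappa, pi=pi,
            )
        except ValueError:
            return 1e12
        val = lik.loglik_mixture(params)
        return -val if np.isfinite(val) else 1e12

    return neg_ll


def _x_to_params(x, pi, omega2_fixed) -> BranchSiteParams:
    omega2 = float(np.exp(x[4])) if omega2_fixed is None else omega2_fixed
    return BranchSiteParams(
        p0=float(x[0] * x[1]), p1=float(x[0] * (1 - x[1])),
        omega0=float(x[2]), omega2=max(omega2, 1.0),
        kappa=float(np.exp(x[3])), pi=pi,
    )


_BOUNDS_COMMON = [
    (1e-3, 1.0),            # q = p0 + p1
    (1e-6, 1.0 - 1e-6),     # r = p0 / (p0 + p1)
    (1e-4, 1.0),            # omega0
    (np.log(0.05), np.log(50.0)),  # log kappa
]
_BOUNDS_TFG = (np.log(1e-6), np.log(5.0))  # log foreground branch length


def fit_codon_scale(
    alignment: CodonAlignment,
    tree: dendropy.Tree,
    pi: np.ndarray | None = None,
    maxiter: int = 60,
) -> tuple[float, float, float]:
    """Preliminary single-omega fit of the overall codon branch-length
    scale: returns ``(scale, kappa_hat, omega_hat)`` where multiplying the
    tree's branch lengths by ``scale`` puts them in expected substitutions
    per codon.  Foreground-independent, so one fit per gene serves every
    foreground branch."""
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if set(alignment.taxa) != tips:
        alignment = alignment.subset([t for t in alignment.taxa if t in tips])
    if pi is None:
        pi = f3x4(alignment)
    lik = CodonTreeLik(alignment, tree)
    base = lik.edge_lengths.copy()
    if base.sum() <= 0:
        raise ValueError("gene tree has no positive branch lengths")

    def neg_ll(x):
        s, kappa, omega = np.exp(x)
        lik.edge_lengths = base * s
        val = lik.loglik_single(CodonModel(kappa=kappa, omega=omega, pi=pi))
        return -val if np.isfinite(val) else 1e12

    res = minimize(
        neg_ll, np.log([3.0, 2.0, 0.2]), method="L-BFGS-B",
        bounds=[(np.log(1e-3), np.log(1e3)), (np.log(0.05), np.log(50.0)),
                (np.log(1e-4), np.log(20.0))],
        options={"maxiter": maxiter, "ftol": 1e-8},
    )
    s_hat, kappa_hat, omega_hat = np.exp(res.x)
    return float(s_hat), float(kappa_hat), float(omega_hat)


def fit_branch_site(
    alignment: CodonAlignment,
    tree: dendropy.Tree,
    foreground,
    gene_id: str = "",
    omega2_starts: tuple[float, ...] = OMEGA2_STARTS,
    maxiter: int = 60,
    prelim: tuple[float, float, float] | None = None,
    posterior_cutoff: float = 0.9,
) -> SelectionTestResult:
    """Null and alternative branch-site fits on one gene.

    ``foreground`` is a named branch (``"BP_ancestral"`` / ``"CP_stem"``) or
    a clade leaf set; the branch must exist in the gene tree (its clade must
    survive taxon dropout), otherwise :class:`ForegroundMissingError` is
    raised and the caller should skip the gene for this branch.

    Branch lengths on ``tree`` are used as relative proportions only; their
    absolute codon-model scale is re-estimated (see module docs).  A
    precomputed :func:`fit_codon_scale` result may be passed as ``prelim``
    to share the preliminary fit across foreground branches.
    """
    name, clade = _resolve_clade(foreground)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if set(alignment.taxa) != tips:
        alignment = alignment.subset([t for t in alignment.taxa if t in tips])
    pi = f3x4(alignment)
    lik = CodonTreeLik(alignment, tree, foreground_clade=clade)
    base = lik.edge_lengths.copy()
    if base.sum() <= 0:
        raise ValueError("gene tree has no positive branch lengths")

    if prelim is None:
        prelim = fit_codon_scale(alignment, tree, pi=pi, maxiter=maxiter)
    s_hat, kappa_hat, omega_hat = prelim
    lik.edge_lengths = base * s_hat
    fg_eid = int(np.nonzero(lik.edge_foreground)[0][0])
    t_fg0 = max(float(lik.edge_lengths[fg_eid]), 1e-6)

    # null: omega2 fixed at 1; foreground branch length free
    x0_null = np.array([0.9, 0.85, min(float(omega_hat), 0.9),
                        np.log(kappa_hat), np.log(t_fg0)])
    null_obj = _mixture_neg_ll(lik, pi, fg_eid, omega2_fixed=1.0)
    nres = minimize(null_obj, x0_null, method="L-BFGS-B",
                    bounds=_BOUNDS_COMMON + [_BOUNDS_TFG],
                    options={"maxiter": maxiter, "ftol": 2e-8})
    lnl_null = -float(nres.fun)
    params_null = _x_to_params(nres.x, pi, omega2_fixed=1.0)

    # alternative: omega2 >= 1 free, multi-start warm-started at null MLE
    alt_obj = _mixture_neg_ll(lik, pi, fg_eid, omega2_fixed=None)
    bounds_alt = _BOUNDS_COMMON + [(np.log(1.0), np.log(999.0)), _BOUNDS_TFG]
    best = None
    for start in omega2_starts:
        w2 = start if start >= 1.0 else 1.0 + _OMEGA2_EPS
        x0 = np.concatenate([nres.x[:4], [np.log(w2), nres.x[4]]])
        ares = minimize(alt_obj, x0, method="L-BFGS-B", bounds=bounds_alt,
                        options={"maxiter": maxiter, "ftol": 2e-8})
        if best is None or ares.fun < best.fun:
            best = ares
    lnl_alt = -float(best.fun)
    params_alt = _x_to_params(best.x, pi, omega2_fixed=None)
    lik.edge_lengths[fg_eid] = float(np.exp(best.x[-1]))

    sites = neb_sites(lik, params_alt, cutoff=posterior_cutoff)
    return SelectionTestResult(
        gene_id=gene_id, foreground=name, lnl_null=lnl_null, lnl_alt=lnl_alt,
        omega2=params_alt.omega2, neb_sites=sites,
        params_alt=params_alt, params_null=params_null,
    )


def neb_sites(
    lik: CodonTreeLik, params: BranchSiteParams, cutoff: float = 0.9
) -> tuple[int, ...]:
    """1-based codon positions whose naive-empirical-Bayes posterior of the
    positively selected classes (2a + 2b) is >= ``cutoff``."""
    post = lik.site_class_posteriors(params)
    selected = post[2] + post[3]
    return tuple(int(i) + 1 for i in np.nonzero(selected >= cutoff)[0])
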