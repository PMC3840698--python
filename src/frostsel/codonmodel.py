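"""Codon substitution models and likelihood machinery.

The substitution process is the Goldman–Yang-style codon model: only
single-nucleotide codon changes have nonzero rate, with rate
``pi_j * {1, kappa, omega, kappa*omega}`` for {synonymous transversion,
synonymous transition, nonsynonymous transversion, nonsynonymous transition}.
Codon frequencies default to F3x4 (position-specific nucleotide frequencies
multiplied per codon, renormalised over the 61 sense codons).

The branch-site mixture (the "Model A" structure) has four site classes:

=====  ==============  ===================  ===================
class  proportion      background branches  foreground branches
=====  ==============  ===================  ===================
0      p0              omega0 (< 1)         omega0
1      p1              1                    1
2a     p2a             omega0               omega2
2b     p2b             1                    omega2
=====  ==============  ===================  ===================

with ``p2a = (1-p0-p1) p0/(p0+p1)`` and ``p2b = (1-p0-p1) p1/(p0+p1)``.
The null model fixes ``omega2 = 1``; the alternative bounds ``omega2 >= 1``.

All rate matrices used within one mixture share a single scale factor — the
expected substitution flux of the background-branch mixture — so branch
lengths are expected substitutions per codon under the background process.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .alignment import CodonAlignment
from .genetic_code import (
    CODON_NUC,
    IS_SYNONYMOUS,
    IS_TRANSITION,
    N_CODONS,
    SINGLE_STEP,
)
from .markov import SpectralQ, expected_rate
from .topology import edge_for_clade

_PI_FLOOR = 1e-12


def gy94_raw_Q(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unnormalised codon rate matrix; rows sum to zero.

    q_ij = pi_j, pi_j*kappa, pi_j*omega or pi_j*kappa*omega for single-step
    changes (transversion/transition x synonymous/nonsynonymous); zero for
    multi-step changes and changes into stop codons (stops are outside the
    state space entirely).
    """
    factor = np.where(IS_TRANSITION, kappa, 1.0) * np.where(
        IS_SYNONYMOUS, 1.0, omega
    )
    Q = np.where(SINGLE_STEP, factor * pi[None, :], 0.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_codon_Q(
    kappa: float, omega: float, pi: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """Codon rate matrix, scaled (by default) to one expected substitution
    per codon per unit branch length at stationarity."""
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("pi must be 61 frequencies summing to 1")
    Q = gy94_raw_Q(kappa, omega, pi)
    if normalize:
        Q = Q / expected_rate(Q, pi)
    return Q


def f3x4(alignment: CodonAlignment) -> np.ndarray:
    """F3x4 codon frequencies from an in-frame alignment.

    Position-specific nucleotide frequencies are multiplied per codon, stop
    codons are implicitly zeroed (they are outside the 61-state space), and
    the result is renormalised.  Missing codons are ignored in the counts.
    """
    codons = alignment.codons[alignment.codons >= 0]
    if codons.size == 0:
        raise ValueError("alignment has no ungapped codons")
    pos_freqs = np.empty((3, 4))
    for p in range(3):
        counts = np.bincount(CODON_NUC[codons, p], minlength=4).astype(float)
        pos_freqs[p] = counts / counts.sum()
    pi = (
        pos_freqs[0, CODON_NUC[:, 0]]
        * pos_freqs[1, CODON_NUC[:, 1]]
        * pos_freqs[2, CODON_NUC[:, 2]]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate base composition")
    return pi / total


def _floored(pi: np.ndarray) -> np.ndarray:
    """Numerically safe frequencies for spectral decompositions."""
    pi = np.maximum(np.asarray(pi, dtype=float), _PI_FLOOR)
    return pi / pi.sum()


@dataclass
class CodonModel:
    """Single-omega codon model (used for pairwise dN/dS and as the
    preliminary branch-length model)."""

    kappa: float
    omega: float
    pi: np.ndarray

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.omega < 0:
            raise ValueError("kappa must be > 0 and omega >= 0")
        self.pi = _floored(self.pi)

    def rate_matrix(self, normalize: bool = True) -> np.ndarray:
        return build_codon_Q(self.kappa, self.omega, self.pi, normalize)

    def synonymous_fractions(self) -> tuple[float, float]:
        """(flux fraction rho_S, site fraction f_S).

        rho_S is the synonymous share of total substitution flux under the
        fitted matrix; f_S is the same share under the matrix with omega := 1
        (the "synonymous site" fraction of this mutation process).
        """
        Q = gy94_raw_Q(self.kappa, self.omega, self.pi)
        syn_flux = float(np.sum(self.pi[:, None] * np.where(IS_SYNONYMOUS, Q, 0.0)))
        tot_flux = expected_rate(Q, self.pi)
        rho_s = syn_flux / tot_flux
        Q1 = gy94_raw_Q(self.kappa, 1.0, self.pi)
        syn1 = float(np.sum(self.pi[:, None] * np.where(IS_SYNONYMOUS, Q1, 0.0)))
        f_s = syn1 / expected_rate(Q1, self.pi)
        return rho_s, f_s


@dataclass
class BranchSiteParams:
    """Parameters of the branch-site site-class mixture (see module docs)."""

    p0: float
    p1: float
    omega0: float
    omega2: float
    kappa: float
    pi: np.ndarray

    def __post_init__(self) -> None:
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1 + 1e-9:
            raise ValueError("need p0, p1 >= 0 with p0 + p1 <= 1")
        if self.p0 + self.p1 <= 0:
            raise ValueError("p0 + p1 must be positive")
        if not 0 < self.omega0 <= 1:
            raise ValueError("omega0 must lie in (0, 1]")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        self.pi = _floored(self.pi)

    @property
    def p2a(self) -> float:
        p2 = max(0.0, 1.0 - self.p0 - self.p1)
        return p2 * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        p2 = max(0.0, 1.0 - self.p0 - self.p1)
        return p2 * self.p1 / (self.p0 + self.p1)

    def class_proportions(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2a, self.p2b])

    def class_omegas(self) -> tuple[np.ndarray, np.ndarray]:
        """(background, foreground) omega per site class."""
        background = np.array([self.omega0, 1.0, self.omega0, 1.0])
        foreground = np.array([self.omega0, 1.0, self.omega2, self.omega2])
        return background, foreground

    def normalizer(self) -> float:
        """Shared rate-matrix scale: expected flux of the background-branch
        mixture, so branch lengths are substitutions/codon under the
        background process."""
        weights = self.class_proportions()
        background, _ = self.class_omegas()
        total = 0.0
        for w, om in zip(weights, background):
            if w > 0:
                total += w * expected_rate(gy94_raw_Q(self.kappa, om, self.pi),
                                           self.pi)
        return total


class CodonTreeLik:
    """Pruning likelihood of a codon alignment on a fixed tree under a
    site-class mixture, with one designated foreground branch set.

    The tree structure and site patterns are precompiled once; repeated
    evaluations (during optimisation) only rebuild the per-omega transition
    matrices.  Branch lengths are read from ``edge_lengths`` (expected
    substitutions/codon) and may be rescaled between evaluations.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: dendropy.Tree,
        foreground_clade: frozenset[str] | None = None,
    ):
        taxa = alignment.taxa
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        if tips != set(taxa):
            raise ValueError("alignment taxa do not match tree tips")
        patterns, inverse, counts = np.unique(
            alignment.codons, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns
        self.pattern_counts = counts
        self.site_to_pattern = inverse.ravel()
        self.n_sites = alignment.n_codons

        fg_edge = None
        if foreground_clade is not None:
            fg_edge = edge_for_clade(tree, foreground_clade)
            if fg_edge is None:
                raise ForegroundMissingError(
                    f"no branch subtends {sorted(foreground_clade & tips)}"
                )
        # compile postorder: for each internal node, its children with edge ids
        nodes = list(tree.postorder_node_iter())
        node_id = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root_id = node_id[id(tree.seed_node)]
        self.is_leaf = np.array([n.is_leaf() for n in nodes])
        self.leaf_states: dict[int, np.ndarray] = {}
        self.children: list[list[tuple[int, int]]] = [[] for _ in nodes]
        self.edge_lengths: list[float] = []
        self.edge_foreground: list[bool] = []
        row = {t: i for i, t in enumerate(taxa)}
        for n in nodes:
            i = node_id[id(n)]
            if n.is_leaf():
                self.leaf_states[i] = patterns[row[n.taxon.label]]
            for child in n.child_nodes():
                eid = len(self.edge_lengths)
                self.edge_lengths.append(float(child.edge.length or 0.0))
                self.edge_foreground.append(child.edge is fg_edge)
                self.children[i].append((node_id[id(child)], eid))
        self.edge_lengths = np.array(self.edge_lengths)
        self.edge_foreground = np.array(self.edge_foreground)
        if foreground_clade is not None and not self.edge_foreground.any():
            raise ForegroundMissingError("foreground branch lost in traversal")
        # internal nodes strictly above the foreground edge ("path" nodes)
        # must be recomputed per site class; everything below and beside the
        # foreground branch depends only on the class's background omega and
        # can be shared between classes
        path: set[int] = set()
        if self.edge_foreground.any():
            fg_head = None
            for i in range(self.n_nodes):
                for child_id, eid in self.children[i]:
                    if self.edge_foreground[eid]:
                        fg_head = i
            node = fg_head
            # walk up: parents are the internal nodes listing node as child
            parent_of = {}
            for i in range(self.n_nodes):
                for child_id, _ in self.children[i]:
                    parent_of[child_id] = i
            while node is not None:
                path.add(node)
                node = parent_of.get(node)
        self._path_nodes = [
            i for i in range(self.n_nodes) if not self.is_leaf[i] and i in path
        ]
        self._off_path_nodes = [
            i for i in range(self.n_nodes)
            if not self.is_leaf[i] and i not in path
        ]

    # -- likelihood ----------------------------------------------------

    def _class_site_logliks(
        self,
        weights: np.ndarray,
        omegas_bg: np.ndarray,
        omegas_fg: np.ndarray,
        kappa: float,
        pi: np.ndarray,
        scale: float,
    ) -> np.ndarray:
        """(n_classes, n_patterns) per-class log-likelihoods.

        Site classes sharing a background omega also share every subtree
        conditional not above the foreground branch; those are computed once
        per distinct background omega and only the nodes on the path from
        the foreground branch to the root are recomputed per class.
        """
        pi = _floored(pi)
        distinct: dict[float, SpectralQ] = {}
        for om in np.concatenate([omegas_bg, omegas_fg]):
            key = round(float(om), 12)
            if key not in distinct:
                distinct[key] = SpectralQ(
                    gy94_raw_Q(kappa, float(om), pi) / scale, pi
                )
        npat = self.patterns.shape[1]
        out = np.empty((len(weights), npat))
        prob_cache: dict[tuple[float, int], np.ndarray] = {}

        def P_for(om: float, eid: int) -> np.ndarray:
            key = (round(float(om), 12), eid)
            P = prob_cache.get(key)
            if P is None:
                P = distinct[key[0]].probs(self.edge_lengths[eid])
                prob_cache[key] = P
            return P

        def compute_node(i, om_bg, om_fg, part, cum, shared_part, shared_cum):
            L = np.ones((N_CODONS, npat))
            sc = np.zeros(npat)
            for child_id, eid in self.children[i]:
                om = om_fg if self.edge_foreground[eid] else om_bg
                P = P_for(om, eid)
                if self.is_leaf[child_id]:
                    states = self.leaf_states[child_id]
                    contrib = np.ones((N_CODONS, npat))
                    present = states >= 0
                    contrib[:, present] = P[:, states[present]]
                    L *= contrib
                else:
                    child_L = part.get(child_id)
                    if child_L is None:
                        child_L = shared_part[child_id]
                        sc += shared_cum[child_id]
                    else:
                        sc += cum[child_id]
                    L *= P @ child_L
            m = L.max(axis=0)
            if not np.all(m > 0):
                return False
            L /= m
            part[i] = L
            cum[i] = sc + np.log(m)
            return True

        groups: dict[float, list[int]] = {}
        for k in range(len(weights)):
            groups.setdefault(round(float(omegas_bg[k]), 12), []).append(k)

        for bg_key, class_ids in groups.items():
            shared_part: dict[int, np.ndarray] = {}
            shared_cum: dict[int, np.ndarray] = {}
            ok = True
            for i in self._off_path_nodes:
                if not compute_node(i, bg_key, bg_key, shared_part,
                                    shared_cum, shared_part, shared_cum):
                    ok = False
                    break
            if not ok:
                out[class_ids] = -np.inf
                continue
            if not self._path_nodes:
                root_like = pi @ shared_part[self.root_id]
                with np.errstate(divide="ignore"):
                    ll = np.log(root_like) + shared_cum[self.root_id]
                out[class_ids] = ll
                continue
            for k in class_ids:
                part: dict[int, np.ndarray] = {}
                cum: dict[int, np.ndarray] = {}
                ok = True
                for i in self._path_nodes:
                    if not compute_node(i, bg_key, float(omegas_fg[k]),
                                        part, cum, shared_part, shared_cum):
                        ok = False
                        break
                if not ok:
                    out[k] = -np.inf
                    continue
                root_like = pi @ part[self.root_id]
                with np.errstate(divide="ignore"):
                    out[k] = np.log(root_like) + cum[self.root_id]
        return out

    def loglik_mixture(self, params: BranchSiteParams) -> float:
        weights = params.class_proportions()
        bg, fg = params.class_omegas()
        per_class = self._class_site_logliks(
            weights, bg, fg, params.kappa, params.pi, params.normalizer()
        )
        site_ll = _weighted_logsumexp(per_class, weights)
        return float(site_ll @ self.pattern_counts)

    def loglik_single(self, model: CodonModel, scale: float | None = None) -> float:
        """Single-omega likelihood; ``scale`` defaults to the model's own
        normalising flux (branch lengths = substitutions/codon)."""
        if scale is None:
            scale = expected_rate(
                gy94_raw_Q(model.kappa, model.omega, model.pi), model.pi
            )
        per_class = self._class_site_logliks(
            np.ones(1), np.array([model.omega]), np.array([model.omega]),
            model.kappa, model.pi, scale,
        )
        return float(per_class[0] @ self.pattern_counts)

    def site_class_posteriors(self, params: BranchSiteParams) -> np.ndarray:
        """(4, n_sites) posterior class probabilities at the given parameter
        values (naive empirical Bayes when evaluated at the MLE)."""
        weights = params.class_proportions()
        bg, fg = params.class_omegas()
        per_class = self._class_site_logliks(
            weights, bg, fg, params.kappa, params.pi, params.normalizer()
        )
        with np.errstate(divide="ignore"):
            logw = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)),
                            -np.inf)
        joint = logw[:, None] + per_class
        joint -= joint.max(axis=0, keepdims=True)
        post = np.exp(joint)
        post /= post.sum(axis=0, keepdims=True)
        return post[:, self.site_to_pattern]


class ForegroundMissingError(ValueError):
    """The requested foreground branch does not exist in this gene tree."""


def _weighted_logsumexp(per_class: np.ndarray, weights: np.ndarray) -> np.ndarray:
    active = weights > 0
    logw = np.log(weights[active])[:, None]
    vals = per_class[active] + logw
    mx = vals.max(axis=0)
    safe = np.isfinite(mx)
    out = np.full(per_class.shape[1], -np.inf)
    out[safe] = mx[safe] + np.log(
        np.exp(vals[:, safe] - mx[safe]).sum(axis=0)
    )
    return out


def codon_loglik(
    alignment: CodonAlignment,
    tree: dendropy.Tree,
    params: BranchSiteParams | CodonModel,
    foreground_clade: frozenset[str] | None = None,
) -> float:
    """One-shot mixture (or single-omega) codon log-likelihood.

    Branch lengths on ``tree`` are expected substitutions per codon under
    the background process.  For repeated evaluation build a
    :class:`CodonTreeLik` once instead.
    """
    lik = CodonTreeLik(alignment, tree, foreground_clade)
    if isinstance(params, CodonModel):
        return lik.loglik_single(params)
    return lik.loglik_mixture(params)
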