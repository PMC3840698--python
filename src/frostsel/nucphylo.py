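"""Nucleotide-level phylogenetics for ortholog gene trees.

Implements the tree stage of the pipeline: GTR(+gamma) likelihood by
Felsenstein pruning, ML pairwise distances, neighbour-joining topology with
joint branch-length/model optimisation, congruence checking against the
reference species topology, the long-branch quality-control rule, and
cophenetic distances to the PACMAD outgroups.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
from dendropy.calculate import treecompare
from scipy.optimize import minimize, minimize_scalar
from skbio import DistanceMatrix
from skbio.tree import nj

from .alignment import CodonAlignment
from .gtr import GtrModel
from .topology import OUTGROUPS, SpeciesTopology

_MIN_BL = 1e-8
_MAX_BL = 15.0


def _nuc_matrix(alignment) -> tuple[list[str], np.ndarray]:
    if isinstance(alignment, CodonAlignment):
        return alignment.taxa, alignment.nucleotides()
    taxa, mat = alignment
    return list(taxa), np.asarray(mat, dtype=np.int64)


def _compress(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns (n_taxa, n_patterns) and their counts."""
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts


def _pruning_loglik(
    taxa: list[str],
    patterns: np.ndarray,
    counts: np.ndarray,
    tree: dendropy.Tree,
    model: GtrModel,
) -> float:
    """Pruning log-likelihood over compressed site patterns, averaged over
    equal-weight discrete-gamma categories.  Gaps (-1) are missing data."""
    n_states = 4
    npat = patterns.shape[1]
    row = {t: i for i, t in enumerate(taxa)}
    pi = model.freqs
    spectral = model.spectral()
    cat_rates = model.category_rates()

    # leaf partials shared across categories
    leaf_partial: dict[str, np.ndarray] = {}
    for t in taxa:
        states = patterns[row[t]]
        L = np.zeros((n_states, npat))
        present = states >= 0
        L[:, ~present] = 1.0
        L[states[present], np.nonzero(present)[0]] = 1.0
        leaf_partial[t] = L

    per_cat = np.empty((len(cat_rates), npat))
    for c, r in enumerate(cat_rates):
        log_scale = np.zeros(npat)
        partial: dict[int, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                partial[id(node)] = leaf_partial[node.taxon.label]
                continue
            L = np.ones((n_states, npat))
            for child in node.child_nodes():
                t_len = (child.edge.length or 0.0) * r
                P = spectral.probs(t_len)
                L *= P @ partial.pop(id(child))
            m = L.max(axis=0)
            bad = m <= 0
            if np.any(bad):
                return -np.inf
            L /= m
            log_scale += np.log(m)
            partial[id(node)] = L
        root_L = pi @ partial[id(tree.seed_node)]
        if np.any(root_L <= 0):
            return -np.inf
        per_cat[c] = np.log(root_L) + log_scale
    # equal-weight mixture over categories, combined in log space
    mx = per_cat.max(axis=0)
    site_ll = mx + np.log(np.exp(per_cat - mx).mean(axis=0))
    return float(site_ll @ counts)


def gtr_loglik(alignment, tree: dendropy.Tree, model: GtrModel) -> float:
    """GTR(+gamma) log-likelihood of a nucleotide alignment on a tree.

    ``alignment`` may be a :class:`CodonAlignment` (flattened to nucleotides)
    or a ``(taxa, matrix)`` pair of nucleotide indices (-1 = missing).
    """
    taxa, mat = _nuc_matrix(alignment)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tips != set(taxa):
        raise ValueError("alignment taxa do not match tree tips")
    patterns, counts = _compress(mat)
    return _pruning_loglik(taxa, patterns, counts, tree, model)


def ml_pairwise_distance(
    seq_a: np.ndarray, seq_b: np.ndarray, model: GtrModel
) -> float:
    """ML distance between two nucleotide index sequences under ``model``.

    Sites where either sequence is missing are excluded (pairwise deletion).
    """
    ok = (seq_a >= 0) & (seq_b >= 0)
    a, b = seq_a[ok], seq_b[ok]
    if a.size == 0:
        raise ValueError("no shared sites between sequences")
    counts = np.bincount(4 * a + b, minlength=16).reshape(4, 4)
    pi = model.freqs
    spectral = model.spectral()
    cat_rates = model.category_rates()

    def neg_ll(t: float) -> float:
        joint = np.zeros((4, 4))
        for r in cat_rates:
            joint += pi[:, None] * spectral.probs(t * r)
        joint /= len(cat_rates)
        with np.errstate(divide="ignore"):
            lj = np.log(joint)
        lj[counts == 0] = 0.0
        val = float((counts * lj).sum())
        return -val if np.isfinite(val) else np.inf

    res = minimize_scalar(neg_ll, bounds=(_MIN_BL, _MAX_BL), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def pairwise_distance_matrix(alignment, model: GtrModel) -> np.ndarray:
    taxa, mat = _nuc_matrix(alignment)
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ml_pairwise_distance(mat[i], mat[j], model)
    return D


@dataclass
class GeneTree:
    """Estimated gene tree: topology with ML branch lengths (expected
    nucleotide substitutions/site) and the fitted GTR model."""

    tree: dendropy.Tree
    model: GtrModel
    log_likelihood: float
    converged: bool = True

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def taxa(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}


def neighbor_joining_tree(taxa: list[str], D: np.ndarray) -> dendropy.Tree:
    """NJ topology from a distance matrix (negative NJ branch lengths are
    clipped to ~0), returned as an unrooted dendropy tree."""
    dm = DistanceMatrix(D, ids=list(taxa))
    sk_tree = nj(dm)
    buf = io.StringIO()
    sk_tree.write(buf, format="newick")
    tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick",
                             rooting="force-unrooted")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = max(float(edge.length), _MIN_BL)
    return tree


def fit_gene_tree(
    alignment,
    model: GtrModel | None = None,
    optimize_model: bool = True,
    maxiter: int = 60,
) -> GeneTree:
    """ML gene tree: NJ on ML pairwise GTR distances, then joint bounded
    optimisation of all branch lengths and model parameters.

    The default model is GTR+gamma (4 categories) with empirical base
    frequencies; exchangeabilities and the gamma shape are optimised when
    ``optimize_model`` is true.
    """
    taxa, mat = _nuc_matrix(alignment)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa for a gene tree")
    if model is None:
        counts = np.bincount(mat[mat >= 0].ravel(), minlength=4) + 1.0
        freqs = counts / counts.sum()
        model = GtrModel(freqs=freqs, alpha=1.0)
    # distances for NJ under the single-rate version of the model
    dist_model = GtrModel(rates=model.rates.copy(), freqs=model.freqs.copy())
    D = pairwise_distance_matrix((taxa, mat), dist_model)
    tree = neighbor_joining_tree(taxa, D)
    patterns, counts_ = _compress(mat)

    edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
    use_gamma = model.alpha is not None

    def unpack(x: np.ndarray) -> GtrModel:
        k = len(edges)
        for e, v in zip(edges, x[:k]):
            e.length = float(np.exp(v))
        if not optimize_model:
            return model
        rates = np.append(np.exp(x[k : k + 5]), 1.0)
        alpha = float(np.exp(x[k + 5])) if use_gamma else None
        return GtrModel(rates=rates, freqs=model.freqs.copy(), alpha=alpha,
                        n_categories=model.n_categories)

    def neg_ll(x: np.ndarray) -> float:
        m = unpack(x)
        ll = _pruning_loglik(taxa, patterns, counts_, tree, m)
        return -ll if np.isfinite(ll) else 1e12

    x0 = [np.log(max(e.length or _MIN_BL, _MIN_BL)) for e in edges]
    bounds = [(np.log(_MIN_BL), np.log(_MAX_BL))] * len(edges)
    if optimize_model:
        x0 += list(np.log(model.rates[:5]))
        bounds += [(np.log(1e-4), np.log(1e3))] * 5
        if use_gamma:
            x0.append(np.log(model.alpha))
            bounds.append((np.log(0.02), np.log(50.0)))
    res = minimize(neg_ll, np.array(x0), method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "ftol": 1e-9})
    fitted = unpack(res.x)
    ll = _pruning_loglik(taxa, patterns, counts_, tree, fitted)
    return GeneTree(tree=tree, model=fitted, log_likelihood=ll,
                    converged=bool(res.success))


def check_topology(gene_tree, species_topology: SpeciesTopology) -> bool:
    """True iff the unrooted gene-tree topology equals the species topology
    pruned to the taxa present in the gene tree."""
    tree = gene_tree.tree if isinstance(gene_tree, GeneTree) else gene_tree
    taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    ref = species_topology.pruned_tree(taxa)
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=tree.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns,
                           rooting="force-unrooted")
    t2 = dendropy.Tree.get(data=ref.as_string(schema="newick"),
                           schema="newick", taxon_namespace=tns,
                           rooting="force-unrooted")
    return treecompare.symmetric_difference(t1, t2) == 0


@dataclass(frozen=True)
class QcResult:
    action: str  # keep | drop_taxon | discard_tree
    taxon: str | None
    ratio: float


def long_branch_qc(gene_tree, factor: float = 3.0) -> QcResult:
    """Long-branch rule: if the longest branch is strictly more than
    ``factor`` times the second longest, drop the offending tip (external
    branch) or discard the tree (internal branch); otherwise keep.

    A bifurcating root is collapsed first so the two root-adjacent edges
    count as the single unrooted branch they represent.
    """
    tree = gene_tree.tree if isinstance(gene_tree, GeneTree) else gene_tree
    work = tree.clone(depth=1)
    root_children = work.seed_node.child_nodes()
    if len(root_children) == 2:
        work.collapse_basal_bifurcation()
    branches = []
    for edge in work.preorder_edge_iter():
        if edge.head_node.parent_node is None:
            continue
        head = edge.head_node
        label = head.taxon.label if head.is_leaf() else None
        branches.append((float(edge.length or 0.0), label))
    if len(branches) < 4:
        raise ValueError("long-branch QC needs at least 4 branches")
    branches.sort(key=lambda b: -b[0])
    longest, second = branches[0][0], branches[1][0]
    if second > 0:
        ratio = longest / second
    else:
        ratio = np.inf if longest > 0 else 1.0
    if ratio <= factor:
        return QcResult("keep", None, ratio)
    tip = branches[0][1]
    if tip is not None:
        return QcResult("drop_taxon", tip, ratio)
    return QcResult("discard_tree", None, ratio)


def outgroup_distance(
    gene_tree, species: str, outgroups: tuple[str, ...] = OUTGROUPS
) -> float:
    """Cophenetic (path-length) distance from ``species`` to the outgroup
    tips present in the tree; the mean when both outgroups are present."""
    tree = gene_tree.tree if isinstance(gene_tree, GeneTree) else gene_tree
    labels = {leaf.taxon.label: leaf.taxon for leaf in tree.leaf_node_iter()}
    if species not in labels:
        raise ValueError(f"{species} absent from tree")
    present = [og for og in outgroups if og in labels]
    if not present:
        raise ValueError("no outgroup present in tree")
    pdm = tree.phylogenetic_distance_matrix()
    dists = [
        0.0 if og == species
        else float(pdm.patristic_distance(labels[species], labels[og]))
        for og in present
    ]
    return float(np.mean(dists))
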