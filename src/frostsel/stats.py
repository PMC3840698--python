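"""Rate summaries, subset resampling tests and multiple-testing control.

The comparative questions all have the same shape: is some statistic of the
LTI (low-temperature-induced) gene subset extreme relative to random subsets
of the same size drawn from all genes?  P-values are the proportion of
resampled subsets whose statistic is equal to or more extreme than the
observed one (one-sided, "greater" by default; the LTI subset itself is part
of the sampling pool).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .topology import CORE_POOIDEAE, RICE

DS_OUTLIER = 2.0
DN_OUTLIER = 0.5


def filter_outliers(
    rates: pd.DataFrame, ds_max: float = DS_OUTLIER, dn_max: float = DN_OUTLIER
) -> pd.DataFrame:
    """Drop rate rows with dS > ds_max or dN > dn_max (strict inequalities:
    a row at exactly the bound is kept).  Idempotent."""
    if rates.empty:
        return rates
    keep = ~((rates["dS"] > ds_max) | (rates["dN"] > dn_max))
    return rates[keep].reset_index(drop=True)


def rate_difference(
    rates: pd.DataFrame,
    species_or_group: str,
    metric: str,
    reference: str = RICE,
) -> pd.Series:
    """Per-gene within-tree rate difference: value(species) - value(rice).

    For the group ``"core_pooideae"`` the species value is the mean over the
    core Pooideae species present in that gene.  Genes lacking the species
    (or the reference) are skipped.  Returns a Series indexed by gene_id.
    """
    if metric not in ("gtr_distance", "dS", "dN"):
        raise ValueError(f"unknown metric {metric!r}")
    ref = (
        rates[rates["species"] == reference]
        .set_index("gene_id")[metric]
    )
    if species_or_group == "core_pooideae":
        sub = rates[rates["species"].isin(CORE_POOIDEAE)]
        val = sub.groupby("gene_id")[metric].mean()
    else:
        val = (
            rates[rates["species"] == species_or_group]
            .set_index("gene_id")[metric]
        )
    diff = (val - ref).dropna()
    diff.name = f"{metric}_diff_{species_or_group}_vs_{reference}"
    return diff


_STATISTICS: dict[str, Callable[[np.ndarray], float]] = {
    "median": lambda x: float(np.median(x)),
    "third_quartile": lambda x: float(np.percentile(x, 75)),
    "proportion_true": lambda x: float(np.mean(x)),
}


@dataclass
class ResamplingResult:
    statistic: str
    observed: float
    n_resamples: int
    pvalue: float
    null_mean: float
    null_draws: np.ndarray | None = None

    def __repr__(self) -> str:  # keep the draws out of reprs
        return (
            f"ResamplingResult(statistic={self.statistic!r}, "
            f"observed={self.observed:.6g}, P={self.pvalue:.4g}, "
            f"n_resamples={self.n_resamples})"
        )


def resample_pvalue(
    all_gene_values: pd.Series,
    lti_gene_ids: Iterable[str],
    statistic: str = "median",
    n_resamples: int = 50_000,
    tail: str = "greater",
    seed: int | np.random.Generator = 0,
    include_observed: bool = False,
    keep_draws: bool = True,
) -> ResamplingResult:
    """One-sided subset resampling test.

    Draws ``n_resamples`` subsets of size |LTI| uniformly without replacement
    from all genes (the LTI genes stay in the pool) and computes the
    proportion of subsets whose statistic is >= (tail "greater") or <=
    (tail "less") the observed LTI statistic.  ``include_observed`` adds the
    observed subset as one extra pseudo-draw (the "+1" small-sample
    correction); the default matches the plain proportion definition, whose
    minimum attainable P is 0.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    stat = _STATISTICS[statistic]
    values = np.asarray(all_gene_values.values, dtype=float)
    index = pd.Index(all_gene_values.index)
    lti_ids = [g for g in lti_gene_ids if g in index]
    m = len(lti_ids)
    if m == 0:
        raise ValueError("LTI subset is empty (no overlap with values)")
    if m > len(values):
        raise ValueError("subset larger than population")
    observed = stat(values[index.get_indexer(lti_ids)])

    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = len(values)
    draws = np.empty(n_resamples)
    if n * n_resamples <= 5e7:
        keys = rng.random((n_resamples, n))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        subsets = values[idx]
        if statistic == "median":
            draws = np.median(subsets, axis=1)
        elif statistic == "third_quartile":
            draws = np.percentile(subsets, 75, axis=1)
        else:
            draws = subsets.mean(axis=1)
    else:
        for i in range(n_resamples):
            draws[i] = stat(values[rng.choice(n, size=m, replace=False)])

    if tail == "greater":
        hits = int(np.sum(draws >= observed))
    else:
        hits = int(np.sum(draws <= observed))
    if include_observed:
        p = (hits + 1) / (n_resamples + 1)
    else:
        p = hits / n_resamples
    return ResamplingResult(
        statistic=statistic,
        observed=float(observed),
        n_resamples=n_resamples,
        pvalue=float(p),
        null_mean=float(draws.mean()),
        null_draws=draws if keep_draws else None,
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving,
    monotone, bounded by 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    foreground: str
    n_total: int
    n_lti: int
    n_significant_total: int
    n_significant_lti: int
    proportion_all: float
    proportion_lti: float
    alpha: float
    fdr_scope: str
    resampling: ResamplingResult
    calls: pd.Series  # gene_id -> significant after FDR (global scope)


def selection_enrichment(
    pvalues: pd.Series,
    lti_gene_ids: Iterable[str],
    foreground: str = "",
    alpha: float = 0.05,
    n_resamples: int = 50_000,
    seed: int | np.random.Generator = 0,
    fdr_scope: str = "global",
) -> EnrichmentResult:
    """Is the proportion of genes with a significant selection test higher
    in the LTI subset than expected for a random subset of the same size?

    ``pvalues`` are raw LRT p-values indexed by gene_id.  With the default
    ``fdr_scope="global"`` the FDR adjustment and the significance calls are
    made once over all genes and resampled subsets inherit those calls; with
    ``"within_subset"`` the adjustment is recomputed inside every subset
    (including the observed LTI subset), making the null depend on
    subset-specific rank structure.
    """
    pvalues = pvalues.dropna()
    lti_ids = [g for g in lti_gene_ids if g in pvalues.index]
    q_global = pd.Series(fdr_adjust(pvalues.values), index=pvalues.index)
    calls = q_global < alpha

    if fdr_scope == "global":
        res = resample_pvalue(
            calls.astype(float), lti_ids, statistic="proportion_true",
            n_resamples=n_resamples, seed=seed,
        )
    elif fdr_scope == "within_subset":
        rng = (
            seed if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        p_arr = pvalues.values
        m = len(lti_ids)
        observed = float(
            np.mean(fdr_adjust(pvalues.loc[lti_ids].values) < alpha)
        )
        draws = np.array([
            np.mean(
                fdr_adjust(p_arr[rng.choice(p_arr.size, m, replace=False)])
                < alpha
            )
            for _ in range(n_resamples)
        ])
        res = ResamplingResult(
            statistic="proportion_true", observed=observed,
            n_resamples=n_resamples,
            pvalue=float(np.mean(draws >= observed)),
            null_mean=float(draws.mean()), null_draws=draws,
        )
    else:
        raise ValueError("fdr_scope must be 'global' or 'within_subset'")

    n_sig_lti = int(calls.loc[lti_ids].sum())
    return EnrichmentResult(
        foreground=foreground,
        n_total=len(pvalues),
        n_lti=len(lti_ids),
        n_significant_total=int(calls.sum()),
        n_significant_lti=n_sig_lti,
        proportion_all=float(calls.mean()),
        proportion_lti=n_sig_lti / max(len(lti_ids), 1),
        alpha=alpha,
        fdr_scope=fdr_scope,
        resampling=res,
        calls=calls,
    )
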