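"""General time-reversible (GTR) nucleotide model with discrete-gamma rates.

Parameterisation follows the field convention: six symmetric exchangeability
parameters (order AC, AG, AT, CG, CT, GT; GT fixed to 1 for identifiability),
four base frequencies, and an optional gamma shape ``alpha`` discretised into
equal-probability categories whose rates are the category means
(mean-normalised so the expected rate is 1).  The rate matrix is scaled to
one expected substitution per site per unit branch length at stationarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .markov import SpectralQ, expected_rate

#: index pairs (ACGT order) for the six exchangeabilities AC AG AT CG CT GT
RATE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
TRANSITION_RATE_INDICES = (1, 4)  # AG and CT


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability slices of a
    Gamma(alpha, 1/alpha) distribution (mean 1)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_categories
    bounds = gamma_dist.ppf(np.arange(k + 1) / k, alpha, scale=1.0 / alpha)
    # E[X; X in slice] = F_{alpha+1}(b) difference when scale = 1/alpha
    upper = gamma_dist.cdf(bounds, alpha + 1.0, scale=1.0 / alpha)
    rates = k * np.diff(upper)
    return rates / rates.mean()


@dataclass
class GtrModel:
    rates: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 2.0, 1.0, 1.0, 2.0, 1.0])
    )
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float | None = None
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rates.shape != (6,) or np.any(self.rates <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise ValueError("need 4 positive base frequencies")
        if abs(self.freqs.sum() - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape must be positive")

    def rate_matrix(self) -> np.ndarray:
        """Q scaled to 1 expected substitution/site at stationarity."""
        Q = np.zeros((4, 4))
        for s, (i, j) in zip(self.rates, RATE_PAIRS):
            Q[i, j] = s * self.freqs[j]
            Q[j, i] = s * self.freqs[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q / expected_rate(Q, self.freqs)

    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.n_categories)

    def spectral(self) -> SpectralQ:
        return SpectralQ(self.rate_matrix(), self.freqs)


def jukes_cantor_distance(p_mismatch: float) -> float:
    """Closed-form JC69 distance for an observed mismatch proportion."""
    arg = 1.0 - 4.0 * p_mismatch / 3.0
    if arg <= 0:
        return float("inf")
    return -0.75 * np.log(arg)
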