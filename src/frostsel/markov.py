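"""Spectral machinery for time-reversible continuous-time Markov chains.

Every substitution model in this package (nucleotide GTR and the codon
models) is reversible, so its rate matrix can be symmetrised by the square
root of the stationary distribution and diagonalised once; transition
probability matrices for any branch length are then a cheap reconstruction.
"""

from __future__ import annotations

import numpy as np


class SpectralQ:
    """Eigendecomposition of a reversible rate matrix Q with stationary
    distribution pi, giving P(t) = exp(Qt) for arbitrary t."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        rpi = np.sqrt(pi)
        sym = Q * (rpi[:, None] / rpi[None, :])
        sym = 0.5 * (sym + sym.T)  # enforce symmetry against round-off
        w, U = np.linalg.eigh(sym)
        self.eigenvalues = w
        self._A = U / rpi[:, None]          # diag(1/rpi) @ U
        self._B = (U * rpi[:, None]).T      # U.T @ diag(rpi)
        self.pi = pi

    def probs(self, t: float) -> np.ndarray:
        """Transition probability matrix P(t); rows sum to 1."""
        P = (self._A * np.exp(self.eigenvalues * t)) @ self._B
        np.clip(P, 0.0, None, out=P)
        return P


def expected_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    """Total substitution flux -sum_i pi_i q_ii at stationarity."""
    return float(-np.sum(pi * np.diag(Q)))
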