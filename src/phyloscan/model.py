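"""Continuous-time Markov substitution model and discrete-gamma rate machinery.

A single reversible amino-acid model serves both the sequence simulator and the
site-likelihood engine.  The default is the "equal exchangeability" model: all
exchangeabilities identical, configurable stationary frequencies (with equal
frequencies this is the 20-state Poisson/Felsenstein-81 model).  Rate matrices
are normalized to one expected substitution per unit branch length.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from scipy.stats import gamma as _gamma_dist

#: Canonical amino-acid alphabet (alphabetical one-letter codes).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
N_STATES = len(AMINO_ACIDS)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def aa_index(residue: str) -> int:
    """Return the state index of a residue; raises KeyError for unknowns."""
    return _AA_INDEX[residue]


class SubstitutionModel:
    """Reversible CTMC over the 20 amino acids.

    Parameters
    ----------
    exchangeabilities:
        Symmetric (20, 20) matrix of relative rates; the diagonal is ignored.
    freqs:
        Stationary frequencies, length 20, summing to 1.  Defaults to uniform.
    """

    def __init__(self, exchangeabilities: np.ndarray | None = None,
                 freqs: np.ndarray | None = None):
        if freqs is None:
            freqs = np.full(N_STATES, 1.0 / N_STATES)
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (N_STATES,) or not np.isclose(freqs.sum(), 1.0):
            raise ValueError("freqs must be 20 probabilities summing to 1")
        if np.any(freqs <= 0):
            raise ValueError("freqs must be strictly positive")
        if exchangeabilities is None:
            exchangeabilities = np.ones((N_STATES, N_STATES))
        S = np.asarray(exchangeabilities, dtype=float)
        if S.shape != (N_STATES, N_STATES) or not np.allclose(S, S.T):
            raise ValueError("exchangeabilities must be symmetric (20, 20)")

        Q = S * freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # scale to 1 expected substitution / unit time at stationarity
        mu = -(freqs * np.diag(Q)).sum()
        Q = Q / mu

        self.freqs = freqs
        self.rate_matrix = Q
        # symmetrized eigendecomposition for stable, fast exponentials
        sqrt_pi = np.sqrt(freqs)
        B = (Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        B = 0.5 * (B + B.T)
        evals, evecs = linalg.eigh(B)
        self._evals = evals
        self._left = evecs / sqrt_pi[:, None]     # rows scaled by 1/sqrt(pi)
        self._right = (evecs * sqrt_pi[:, None]).T

    @classmethod
    def equal_exchange(cls, freqs: np.ndarray | None = None) -> "SubstitutionModel":
        """Equal-exchangeability model with the given stationary frequencies."""
        return cls(None, freqs)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows are parent states, columns child states."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self._left * np.exp(self._evals * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Equal-probability discrete-gamma category rates (ascending, mean 1).

    Each of the ``n_categories`` equal-probability bins of a Gamma(shape, 1/shape)
    distribution is represented by its median; medians are then rescaled to
    average exactly 1 so that branch lengths keep their interpretation.
    Category 1 (index 0) is the slowest.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if n_categories < 1:
        raise ValueError("need at least one category")
    if n_categories == 1:
        return np.ones(1)
    probs = (np.arange(n_categories) + 0.5) / n_categories
    rates = _gamma_dist.ppf(probs, a=shape, scale=1.0 / shape)
    return rates / rates.mean()
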