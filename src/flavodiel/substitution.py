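"""Amino-acid substitution model with discrete-gamma rate heterogeneity.

Implements a general time-reversible amino-acid model parameterised by a
symmetric exchangeability matrix and equilibrium frequencies, with the WAG
matrix as the default, plus the standard discrete-gamma approximation to
among-site rate variation (equal-probability categories, category rate =
conditional mean, overall mean rate normalised to 1).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from ._wag_data import WAG_ALPHABET, WAG_EXCHANGEABILITIES, WAG_FREQUENCIES

AMINO_ACIDS = WAG_ALPHABET
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_STATES = 20
GAP_CHARS = set("-.Xx*")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an amino-acid string as integer codes; gaps/unknowns become -1."""
    return np.array([AA_INDEX.get(c.upper(), -1) for c in seq], dtype=np.int64)


def decode_sequence(codes: np.ndarray) -> str:
    return "".join("-" if c < 0 else AMINO_ACIDS[c] for c in codes)


def wag_exchangeabilities() -> np.ndarray:
    """Symmetric 20x20 WAG exchangeability matrix (zero diagonal)."""
    s = np.zeros((N_STATES, N_STATES))
    it = iter(WAG_EXCHANGEABILITIES)
    for i in range(N_STATES):
        for j in range(i + 1, N_STATES):
            v = next(it)
            s[i, j] = s[j, i] = v
    return s


def wag_frequencies() -> np.ndarray:
    return np.asarray(WAG_FREQUENCIES, dtype=float)


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Equal-probability discrete-gamma category rates with mean exactly 1.

    Category boundaries are quantiles of Gamma(alpha, mean 1); the rate of
    each category is its conditional mean, computed from the regularised
    incomplete gamma function.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    k = int(n_categories)
    if k == 1:
        return np.ones(1)
    edges = _gamma_dist.ppf(np.arange(k + 1) / k, alpha, scale=1.0 / alpha)
    edges[0], edges[-1] = 0.0, np.inf
    upper = np.where(np.isinf(edges[1:]), 1.0, gammainc(alpha + 1.0, alpha * edges[1:]))
    lower = gammainc(alpha + 1.0, alpha * edges[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


class SubstitutionModel:
    """Reversible amino-acid rate matrix Q with gamma rate categories.

    Parameters
    ----------
    exchangeabilities:
        Symmetric 20x20 matrix of relative rates (diagonal ignored).
        Defaults to WAG.
    frequencies:
        Equilibrium frequencies pi (length 20, sums to 1). Defaults to the
        WAG empirical frequencies.
    alpha:
        Shape of the gamma distribution of among-site rates.
    n_categories:
        Number of discrete gamma categories.
    """

    def __init__(
        self,
        exchangeabilities: np.ndarray | None = None,
        frequencies: np.ndarray | None = None,
        alpha: float = 1.0,
        n_categories: int = 4,
    ) -> None:
        s = wag_exchangeabilities() if exchangeabilities is None else np.asarray(exchangeabilities, float)
        pi = wag_frequencies() if frequencies is None else np.asarray(frequencies, float)
        if s.shape != (N_STATES, N_STATES) or not np.allclose(s, s.T):
            raise ValueError("exchangeability matrix must be symmetric 20x20")
        if pi.shape != (N_STATES,) or abs(pi.sum() - 1.0) > 1e-9 or (pi <= 0).any():
            raise ValueError("frequencies must be positive and sum to 1")
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise to one expected substitution per unit branch length
        mean_rate = -(pi * np.diag(q)).sum()
        q /= mean_rate
        self.frequencies = pi
        self.rate_matrix = q
        self.alpha = float(alpha)
        self.n_categories = int(n_categories)
        self.category_rates = discrete_gamma_rates(self.alpha, self.n_categories)
        self.category_weights = np.full(self.n_categories, 1.0 / self.n_categories)
        # symmetrised eigendecomposition for fast P(t) = exp(Qt)
        half = np.sqrt(pi)
        b = half[:, None] * q / half[None, :]
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec.T * half[None, :]
        self._right = eigvec / half[:, None]

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * t * rate); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        p = (self._right * np.exp(self._eigval * (t * rate))[None, :]) @ self._left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of per-category transition matrices, shape (K, 20, 20)."""
        return np.stack([self.transition_matrix(t, r) for r in self.category_rates])
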