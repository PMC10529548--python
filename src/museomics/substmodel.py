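"""General time-reversible substitution model with discrete-gamma rate
variation and a proportion of invariant sites (GTR+Γ+I).

The rate matrix is normalised to one expected substitution per unit branch
length at stationarity (before the invariant-site mixture), the convention
under which Jukes-Cantor distances obey p = 3/4 (1 - exp(-4t/3)). Gamma rate
categories are the means of four (by default) equal-probability slices of a
Gamma(shape, 1/shape) distribution, themselves normalised to mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma_dist

STATES = "ACGT"

#: Exchangeability order: AC, AG, AT, CG, CT, GT
EXCHANGE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass
class SubstitutionModelParams:
    """GTR+Γ(+I) parameters.

    exchangeabilities: 6 positive rates in order AC, AG, AT, CG, CT, GT
    base_freqs: stationary frequencies (sum to 1)
    gamma_shape: shape of the gamma rate-variation law; None disables Γ
    n_gamma_categories: number of discrete categories
    p_inv: proportion of invariant (zero-rate) sites
    """

    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    n_gamma_categories: int = 4
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6 or any(x <= 0 for x in self.exchangeabilities):
            raise ValueError("need 6 positive exchangeabilities")
        if len(self.base_freqs) != 4 or abs(sum(self.base_freqs) - 1.0) > 1e-12:
            raise ValueError("base_freqs must be 4 values summing to 1")
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must be in [0, 1)")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")


JC = SubstitutionModelParams()


def rate_matrix(params: SubstitutionModelParams) -> np.ndarray:
    """Normalised GTR rate matrix Q (expected rate 1 at stationarity)."""
    pi = np.asarray(params.base_freqs, dtype=float)
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(params.exchangeabilities, EXCHANGE_PAIRS):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def category_rates(params: SubstitutionModelParams) -> tuple[np.ndarray, np.ndarray]:
    """(rates, weights) of the among-site rate mixture, invariant class first
    when p_inv > 0. Rates have weighted mean (1 - p_inv)·1 + p_inv·0 scaled so
    variable-class mean is 1."""
    if params.gamma_shape is None:
        rates = np.array([1.0])
        weights = np.array([1.0])
    else:
        a = params.gamma_shape
        n = params.n_gamma_categories
        # mean of each equal-probability slice, via the standard identity
        # E[X | slice] = n * (F_{a+1}(q_hi) - F_{a+1}(q_lo)) for Gamma(a, 1/a)
        edges = _gamma_dist.ppf(np.linspace(0, 1, n + 1), a, scale=1.0 / a)
        cdf_ap1 = _gamma_dist.cdf(edges * a, a + 1, scale=1.0)  # Gamma(a+1,1) at a*x
        rates = n * np.diff(cdf_ap1)
        rates = rates / rates.mean()
        weights = np.full(n, 1.0 / n)
    if params.p_inv > 0:
        rates = np.concatenate(([0.0], rates))
        weights = np.concatenate(([params.p_inv], weights * (1 - params.p_inv)))
    return rates, weights


class GtrModel:
    """Eigendecomposed GTR model for fast transition-probability evaluation.

    Reversibility makes diag(sqrt(pi)) Q diag(1/sqrt(pi)) symmetric, so the
    decomposition is numerically exact and P(t) = U exp(L t) U^{-1} is cheap
    per branch.
    """

    def __init__(self, params: SubstitutionModelParams):
        self.params = params
        self.pi = np.asarray(params.base_freqs, dtype=float)
        self.Q = rate_matrix(params)
        sq = np.sqrt(self.pi)
        B = (self.Q * sq[:, None]) / sq[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
        self.eigval = eigval
        self.U = eigvec / sq[:, None]
        self.Uinv = eigvec.T * sq[None, :]
        self.rates, self.weights = category_rates(params)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) for a single rate-1 branch of length t (expected subs/site)."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        P = (self.U * np.exp(self.eigval * t)) @ self.Uinv
        return np.clip(P, 0.0, None)

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(t·r_c) stacked over rate categories, shape (ncat, 4, 4)."""
        expo = np.exp(self.rates[:, None] * (self.eigval * t))  # (ncat, 4)
        P = (self.U[None, :, :] * expo[:, None, :]) @ self.Uinv
        return np.maximum(P, 0.0)

    def transition_matrices_batch(self, ts: np.ndarray) -> np.ndarray:
        """P for a vector of branch lengths, shape (len(ts), ncat, 4, 4)."""
        expo = np.exp(
            np.asarray(ts)[:, None, None] * self.rates[None, :, None] * self.eigval
        )  # (n, ncat, 4)
        P = (self.U[None, None, :, :] * expo[:, :, None, :]) @ self.Uinv
        return np.maximum(P, 0.0)
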