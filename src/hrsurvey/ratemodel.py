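"""Amino-acid substitution model: LG exchangeabilities with discrete-gamma
rate heterogeneity.

The generator matrix is Q_ij = s_ij * pi_j (i != j), scaled so the expected
substitution rate at equilibrium is one substitution per site per unit
branch length.  Transition matrices P(t) = exp(Qt) are computed through the
symmetric eigendecomposition of D^{1/2} Q D^{-1/2} (D = diag(pi)), which is
exact and stable for reversible models.  Gamma rate categories have equal
weights; each category rate is the mean of its quantile slice, so the mean
rate is exactly 1.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .scoring import AMINO_ACIDS

N_AA = 20


def discretize_gamma(alpha: float, n_categories: int) -> tuple:
    """Equal-weight discretisation of a mean-1 gamma distribution.

    Returns ``(rates, weights)``; ``rates[k]`` is the conditional mean of
    the k-th quantile slice, so ``sum(rates * weights) == 1`` exactly.
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    n = n_categories
    if n == 1:
        return np.array([1.0]), np.array([1.0])
    # X ~ Gamma(alpha, scale=1/alpha); E[X | slice] via the shape alpha+1 CDF
    bounds = gamma_dist.ppf(np.arange(1, n) / n, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1.0, bounds * alpha), [1.0]])
    lower = np.concatenate([[0.0], upper[:-1]])
    rates = n * (upper - lower)
    rates = rates / (rates.mean())  # exact mean 1 against round-off
    weights = np.full(n, 1.0 / n)
    return rates, weights


def _read_lg_asset():
    text = (importlib.resources.files("hrsurvey") / "data" / "lg.txt").read_text()
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    S = np.zeros((N_AA, N_AA))
    for i, ln in enumerate(rows[:N_AA - 1], start=1):
        vals = [float(x) for x in ln.split()]
        S[i, :i] = vals
        S[:i, i] = vals
    freqs = np.array([float(x) for x in rows[N_AA - 1].split()])
    return S, freqs / freqs.sum()


@dataclass
class RateModel:
    """A reversible amino-acid CTMC with discrete-gamma site rates."""

    name: str = "LG"
    exchangeabilities: np.ndarray = None
    frequencies: np.ndarray = None
    gamma_shape: float = 1.0
    n_categories: int = 6
    rates: np.ndarray = field(default=None, repr=False)
    weights: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.exchangeabilities is None or self.frequencies is None:
            S, pi = _read_lg_asset()
            if self.exchangeabilities is None:
                self.exchangeabilities = S
            if self.frequencies is None:
                self.frequencies = pi
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.frequencies = self.frequencies / self.frequencies.sum()
        self.rates, self.weights = discretize_gamma(self.gamma_shape,
                                                    self.n_categories)
        pi = self.frequencies
        Q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -float(pi @ np.diag(Q))
        self.Q = Q / scale
        # symmetric form for the eigendecomposition
        sqp = np.sqrt(pi)
        A = (self.Q * sqp[:, None]) / sqp[None, :]
        A = 0.5 * (A + A.T)  # exact symmetry against round-off
        self._eigval, U = np.linalg.eigh(A)
        self._left = U / sqp[:, None] * 1.0
        self._right = (U * sqp[:, None]).T

    def with_shape(self, alpha: float) -> "RateModel":
        return RateModel(self.name, self.exchangeabilities, self.frequencies,
                         alpha, self.n_categories)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(rate * t) = exp(Q * rate * t); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._eigval * rate * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def category_matrices(self, t: float) -> np.ndarray:
        """One transition matrix per gamma category, shape (ncat, 20, 20)."""
        return np.stack([self.transition_matrix(t, r) for r in self.rates])

    def sample_equilibrium(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(N_AA, size=n, p=self.frequencies)


def lg_model(alpha: float = 1.0, n_categories: int = 6) -> RateModel:
    """The LG model with the published frequencies (the survey's tree model)."""
    return RateModel(gamma_shape=alpha, n_categories=n_categories)


AA_ORDER = AMINO_ACIDS
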