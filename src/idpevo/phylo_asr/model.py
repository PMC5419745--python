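"""GTR-form amino-acid substitution models with discrete-gamma rates.

A model is specified by a symmetric exchangeability matrix ``S``,
equilibrium frequencies ``pi``, a gamma shape ``alpha`` with ``k``
discrete categories, and an invariant-sites fraction ``p_inv``.  The
derived rate matrix is normalised to one expected substitution per
site per unit branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._jtt import AMINO_ACIDS, JTT_EXCHANGEABILITIES, JTT_FREQUENCIES

N_STATES = 20


@dataclass
class SubstitutionModel:
    """Reversible amino-acid substitution model (GTR form).

    Attributes
    ----------
    exchangeabilities
        Symmetric nonnegative 20x20 matrix ``S`` (diagonal ignored).
    frequencies
        Equilibrium frequencies ``pi`` (sum to 1).
    alpha
        Gamma shape for among-site rate variation (> 0).
    k
        Number of discrete gamma categories (>= 1; ``k=1`` means no
        rate variation).
    p_inv
        Proportion of invariant sites in ``[0, 1)``.
    """

    exchangeabilities: np.ndarray = field(
        default_factory=lambda: JTT_EXCHANGEABILITIES.copy()
    )
    frequencies: np.ndarray = field(default_factory=lambda: JTT_FREQUENCIES.copy())
    alpha: float = 1.0
    k: int = 4
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        S, pi = self.exchangeabilities, self.frequencies
        if S.shape != (N_STATES, N_STATES):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(S < 0):
            raise ValueError("exchangeabilities must be nonnegative")
        if pi.shape != (N_STATES,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("frequencies must be a length-20 probability vector")
        if self.alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")
        if self.k < 1:
            raise ValueError("need at least one rate category")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must lie in [0, 1)")

    @classmethod
    def jtt(cls, alpha: float = 1.0, k: int = 4, p_inv: float = 0.0) -> "SubstitutionModel":
        """The packaged JTT model with the given rate-variation settings."""
        return cls(alpha=alpha, k=k, p_inv=p_inv)

    @classmethod
    def poisson(cls, alpha: float = 1.0, k: int = 1, p_inv: float = 0.0) -> "SubstitutionModel":
        """Equal-rates model: uniform exchangeabilities and frequencies."""
        S = np.ones((N_STATES, N_STATES))
        np.fill_diagonal(S, 0.0)
        return cls(S, np.full(N_STATES, 1.0 / N_STATES), alpha, k, p_inv)

    def with_alpha(self, alpha: float, p_inv: float | None = None) -> "SubstitutionModel":
        return replace(
            self, alpha=alpha, p_inv=self.p_inv if p_inv is None else p_inv
        )

    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """Site-rate categories ``(rates, probabilities)`` including the
        invariant class.

        Gamma categories are equal-probability with category-mean rates.
        With ``p_inv > 0`` the variable-site rates are rescaled by
        ``1/(1 - p_inv)`` so the overall expected rate remains 1.
        """
        rates = discrete_gamma_rates(self.alpha, self.k)
        probs = np.full(self.k, 1.0 / self.k)
        if self.p_inv > 0:
            rates = np.concatenate([[0.0], rates / (1.0 - self.p_inv)])
            probs = np.concatenate([[self.p_inv], probs * (1.0 - self.p_inv)])
        return rates, probs


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability discrete gamma categories.

    The underlying density is Gamma(shape=alpha, rate=alpha), i.e. mean 1;
    the returned category rates have probability-weighted mean exactly 1.
    """
    if k == 1:
        return np.ones(1)
    # category boundaries via quantiles of Gamma(alpha, rate=alpha)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # E[r | b_i < r < b_{i+1}] * k via the incomplete-gamma identity
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean() * 1.0  # exact renormalisation of fp error


def build_rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Build the normalised instantaneous rate matrix ``Q``.

    ``Q_ij = S_ij * pi_j`` for ``i != j``, the diagonal makes row sums
    zero, and the matrix is scaled so ``-sum_i pi_i Q_ii = 1``.
    """
    S, pi = model.exchangeabilities, model.frequencies
    Q = S * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.dot(pi, np.diag(Q))
    if rate <= 0:
        raise ValueError("degenerate model: zero expected substitution rate")
    return Q / rate


class TransitionKernel:
    """Eigendecomposition-backed transition probabilities ``P(t)``.

    Exploits reversibility: ``diag(sqrt(pi)) Q diag(1/sqrt(pi))`` is
    symmetric, so ``P(t)`` is computed from a single symmetric
    eigendecomposition for any number of branch length / rate products.
    """

    def __init__(self, model: SubstitutionModel):
        self.model = model
        self.Q = build_rate_matrix(model)
        pi = model.frequencies
        sqrt_pi = np.sqrt(pi)
        sym = (self.Q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((sym + sym.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec / sqrt_pi[:, None]       # diag(1/sqrt(pi)) U
        self._right = (eigvec * sqrt_pi[:, None]).T  # U^T diag(sqrt(pi))

    def probability_matrix(self, t: float) -> np.ndarray:
        """``P(t) = exp(Q t)``; ``t`` is branch length times site rate."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        P = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(P, 0.0, 1.0, out=P)
        return P
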