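"""Among-site rate-heterogeneity distributions.

All distributions are discrete with mean-one normalization
(sum of weight*rate = 1), so branch lengths stay in expected
substitutions per site regardless of the heterogeneity model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = ["RateDistribution", "single_rate", "discrete_gamma_rates",
           "make_free_rates", "add_invariant"]


@dataclass(frozen=True)
class RateDistribution:
    rates: np.ndarray
    weights: np.ndarray
    kind: str = "single"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "rates", np.asarray(self.rates, float))
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        if self.rates.shape != self.weights.shape:
            raise ValueError("rates and weights must have equal length")
        if np.any(self.rates < 0) or np.any(self.weights < 0):
            raise ValueError("rates and weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
        if abs(float(self.weights @ self.rates) - 1.0) > 1e-8:
            raise ValueError("mean rate must be 1")

    @property
    def n_categories(self) -> int:
        return self.rates.shape[0]


def single_rate() -> RateDistribution:
    return RateDistribution(np.array([1.0]), np.array([1.0]), "single")


def discrete_gamma_rates(alpha: float, m: int) -> RateDistribution:
    """Discrete-gamma: m equal-weight categories, each rate the mean of
    one equal-probability slice of Gamma(shape=alpha, rate=alpha)."""
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    m = int(m)
    if m < 1:
        raise ValueError("need at least one category")
    if m == 1:
        return RateDistribution(np.array([1.0]), np.array([1.0]), "gamma",
                                {"alpha": alpha, "m": 1})
    # category boundaries are quantiles; slice means via the regularized
    # lower incomplete gamma with shape alpha+1 (standard mean-rate scheme)
    bounds = gamma_dist.ppf(np.arange(m + 1) / m, alpha, scale=1.0 / alpha)
    cdf1 = gammainc(alpha + 1.0, alpha * bounds)
    rates = m * np.diff(cdf1)
    rates = rates / (rates.mean())  # exact mean-one despite tail round-off
    weights = np.full(m, 1.0 / m)
    return RateDistribution(rates, weights, "gamma", {"alpha": alpha, "m": m})


def make_free_rates(raw_rates, raw_weights) -> RateDistribution:
    """Free-rates distribution from raw positive rates/weights: weights are
    renormalized to the simplex, rates rescaled to mean one."""
    r = np.asarray(raw_rates, float)
    w = np.asarray(raw_weights, float)
    if np.any(r <= 0) or np.any(w <= 0):
        raise ValueError("free-rate inputs must be strictly positive")
    w = w / w.sum()
    r = r / float(w @ r)
    return RateDistribution(r, w, "freerate", {"m": r.shape[0]})


def add_invariant(p_inv: float, base: RateDistribution) -> RateDistribution:
    """Prepend a rate-zero (invariant-sites) category with weight p_inv;
    remaining rates rescaled so the mean rate stays one."""
    if not (0.0 <= p_inv < 1.0):
        raise ValueError("invariant proportion must be in [0, 1)")
    rates = np.concatenate([[0.0], base.rates / (1.0 - p_inv)])
    weights = np.concatenate([[p_inv], base.weights * (1.0 - p_inv)])
    return RateDistribution(rates, weights, f"invariant+{base.kind}",
                            {**base.params, "p_inv": p_inv})
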