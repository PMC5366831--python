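"""Gaussian mixture primitives for online phonetic category learning.

Each perceptual dimension (an acoustic or visual cue, or the integrated
audiovisual dimension) is represented as a mixture of ``K`` Gaussians.  A
component is parameterized by a location ``mu`` (cue units), a spread
``sigma`` (same units, strictly positive) and a frequency-of-occurrence
weight ``phi`` in [0, 1]; the ``phi`` vector of a mixture sums to 1.  The
mixture is trained by stochastic gradient ascent on the log-likelihood of
one token at a time, with winner-take-all competition on the ``phi``
updates: only the component with the largest ``phi`` gradient has its
``phi`` changed, after which the vector is renormalized.  Components that
are not needed to describe the input distribution are thereby driven to
near-zero ``phi`` ("pruned") rather than removed.

The category-structured reliability metric :func:`cue_weight` measures how
well a dimension separates categories: pairs of components whose means are
far apart relative to their spreads (and which both occur often) raise the
weight.  This is the opposite behaviour of the classic 1/sigma^2 rule,
which is appropriate for unimodal estimation noise but penalizes exactly
the between-category spread that makes a phonetic cue informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PHI_FLOOR",
    "SIGMA_FLOOR",
    "LearningRates",
    "Mixture",
    "component_likelihood",
    "mixture_likelihood",
    "component_posterior",
    "central_tendency",
    "variability",
    "cue_weight",
    "gradient_deltas",
    "apply_winner_take_all",
]

#: Default floors preventing division blow-ups in the 1/phi and sigma^-3
#: gradient terms.  Units: phi is dimensionless; sigma's floor is in the
#: mixture's own cue units.
PHI_FLOOR = 1e-6
SIGMA_FLOOR = 1e-3

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class LearningRates:
    """Per-parameter step sizes (cue units per unit gradient)."""

    eta_mu: float
    eta_sigma: float
    eta_phi: float

    def __post_init__(self) -> None:
        if not (self.eta_mu > 0 and self.eta_sigma > 0 and self.eta_phi > 0):
            raise ValueError("learning rates must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.eta_mu, self.eta_sigma, self.eta_phi])


@dataclass
class Mixture:
    """A ``K``-component Gaussian mixture over one perceptual dimension.

    Parameters are stored as flat float64 arrays of equal length.  ``label``
    identifies the dimension (``"MH"``, ``"MW"``, ``"F2"``, ``"F3"`` or
    ``"integrated"``).  The component count is fixed for the life of the
    mixture; pruning only drives ``phi`` toward the floor.
    """

    mu: np.ndarray
    sigma: np.ndarray
    phi: np.ndarray
    label: str = ""
    phi_floor: float = PHI_FLOOR
    sigma_floor: float = SIGMA_FLOOR

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).copy()
        self.sigma = np.asarray(self.sigma, dtype=float).copy()
        self.phi = np.asarray(self.phi, dtype=float).copy()
        if not (self.mu.shape == self.sigma.shape == self.phi.shape):
            raise ValueError("mu, sigma, phi must have identical shapes")
        if self.mu.ndim != 1 or self.mu.size == 0:
            raise ValueError("mixture parameters must be non-empty 1-d arrays")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if np.any(self.phi < 0) or np.any(self.phi > 1):
            raise ValueError("phi must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.mu.size

    def copy(self) -> "Mixture":
        return Mixture(self.mu, self.sigma, self.phi, self.label,
                       self.phi_floor, self.sigma_floor)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "K": self.K,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "phi": self.phi.tolist(),
            "phi_floor": self.phi_floor,
            "sigma_floor": self.sigma_floor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Mixture":
        m = cls(np.asarray(d["mu"]), np.asarray(d["sigma"]), np.asarray(d["phi"]),
                d.get("label", ""), d.get("phi_floor", PHI_FLOOR),
                d.get("sigma_floor", SIGMA_FLOOR))
        if m.K != d.get("K", m.K):
            raise ValueError("inconsistent component count in serialized mixture")
        return m


def _check_finite(x: float) -> float:
    x = float(x)
    if not np.isfinite(x):
        raise ValueError(f"cue value must be finite, got {x!r}")
    return x


def component_likelihood(x: float, mu: float, sigma: float, phi: float) -> float:
    """phi-weighted Gaussian density of one component at ``x``.

    Returns ``phi * N(x; mu, sigma)``; exactly 0 when ``phi`` is 0.
    """
    x = _check_finite(x)
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    if phi == 0.0:
        return 0.0
    z = (x - mu) / sigma
    return phi * np.exp(-0.5 * z * z) / (_SQRT2PI * sigma)


def _component_densities(x: float, m: Mixture) -> np.ndarray:
    """Vector of phi-weighted component densities G_j(x)."""
    x = _check_finite(x)
    z = (x - m.mu) / m.sigma
    return m.phi * np.exp(-0.5 * z * z) / (_SQRT2PI * m.sigma)


def mixture_likelihood(x: float, m: Mixture) -> float:
    """Total mixture density M(x) = sum_j G_j(x)."""
    return float(_component_densities(x, m).sum())


def component_posterior(x: float, m: Mixture, j: int | None = None):
    """Responsibility G_j(x) / M(x) of component(s) for token ``x``.

    When every component's density underflows to zero (all ``phi`` at the
    floor, or ``x`` astronomically far from every component) the posterior
    falls back to uniform over components with ``phi`` above the floor.
    """
    g = _component_densities(x, m)
    total = g.sum()
    if total > 0.0:
        post = g / total
    else:
        active = m.phi > m.phi_floor
        if not active.any():
            active = np.ones_like(m.phi, dtype=bool)
        post = active / active.sum()
    if j is None:
        return post
    return float(post[j])


def central_tendency(m: Mixture) -> float:
    """phi-weighted mean of component locations: c = sum(mu*phi)/sum(phi)."""
    tot = m.phi.sum()
    if tot <= 0:
        raise ValueError("central tendency undefined: all phi are zero")
    return float(np.dot(m.mu, m.phi) / tot)


def variability(m: Mixture, c: float | None = None) -> float:
    """Mixture variance about the central tendency (squared cue units).

    v = sum_j phi_j * ((mu_j - c)^2 + sigma_j^2) / sum_j phi_j — the law of
    total variance for the mixture, combining between-component spread of
    the means with within-component variance.
    """
    tot = m.phi.sum()
    if tot <= 0:
        raise ValueError("variability undefined: all phi are zero")
    if c is None:
        c = central_tendency(m)
    return float(np.dot(m.phi, (m.mu - c) ** 2 + m.sigma ** 2) / tot)


def cue_weight(m: Mixture) -> float:
    """Category-structured reliability of the dimension.

    w = (1/2) * sum_{m,n} phi_m phi_n (mu_m - mu_n)^2 / (sigma_m sigma_n).

    For exactly two non-zero components this reduces to the two-category
    form phi_1 phi_2 (mu_1 - mu_2)^2 / (sigma_1 sigma_2).  Computed in
    O(K) via the expansion (mu_m - mu_n)^2 = mu_m^2 + mu_n^2 - 2 mu_m mu_n:
    with a = phi/sigma, b = a*mu, d = a*mu^2 the double sum halved equals
    sum(a)*sum(d) - sum(b)^2.
    """
    a = m.phi / m.sigma
    b = a * m.mu
    d = b * m.mu
    w = a.sum() * d.sum() - b.sum() ** 2
    # guard tiny negative round-off when all means coincide
    return float(max(w, 0.0))


def cue_weight_pairwise(m: Mixture) -> float:
    """O(K^2) literal pairwise evaluation of :func:`cue_weight` (reference)."""
    diff = m.mu[:, None] - m.mu[None, :]
    num = np.outer(m.phi, m.phi) * diff ** 2
    den = np.outer(m.sigma, m.sigma)
    return float((num / den).sum() / 2.0)


def gradient_deltas(x: float, m: Mixture, rates: LearningRates) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-component parameter steps (dphi, dmu, dsigma) for one token.

    These are the learning-rate-scaled partial derivatives of log M(x):

      dphi_j   = eta_phi   * (G_j/M) / phi_j
      dmu_j    = eta_mu    * (G_j/M) * (x - mu_j) / sigma_j^2
      dsigma_j = eta_sigma * (G_j/M) * (sigma_j^-3 (x - mu_j)^2 - sigma_j^-1)

    ``1/phi_j`` uses the floored phi so pruned components still yield finite
    (large) phi gradients and can be revived by outlying tokens.
    """
    x = _check_finite(x)
    resp = component_posterior(x, m)
    diff = x - m.mu
    dphi = rates.eta_phi * resp / np.maximum(m.phi, m.phi_floor)
    dmu = rates.eta_mu * resp * diff / m.sigma ** 2
    dsigma = rates.eta_sigma * resp * (diff ** 2 / m.sigma ** 3 - 1.0 / m.sigma)
    return dphi, dmu, dsigma


def apply_winner_take_all(m: Mixture, deltas: tuple[np.ndarray, np.ndarray, np.ndarray],
                          rule: str = "posterior") -> Mixture:
    """Apply one trial's updates in place and return the mixture.

    Every component receives its mu and sigma step; only one winning
    component (ties broken toward the lowest index) receives its phi step,
    after which phi is floored and renormalized to sum to 1 and sigma is
    floored, so the mixture invariants hold after every trial.

    ``rule`` selects the winner:

    * ``"posterior"`` (default): the component with the highest posterior
      G_j(x)/M(x) for the token.  Because the posterior carries phi, this
      is a rich-get-richer competition — frequently winning components
      starve their neighbours, pruning unneeded components toward the phi
      floor, which is the behaviour that lets the model discover how many
      categories a dimension has.
    * ``"dphi"``: the component with the largest phi gradient.  Since
      dphi_j is proportional to N_j(x)/M(x), phi cancels and the winner
      is simply the best-fitting component shape regardless of how often
      it has won before; no component is ever starved, so mixtures keep
      many active components.  Kept for sensitivity analysis.
    """
    dphi, dmu, dsigma = deltas
    if rule == "posterior":
        # resp_j = dphi_j * max(phi_j, floor) / eta_phi; eta is a common
        # positive factor, so the argmax is unchanged by omitting it
        winner = int(np.argmax(dphi * np.maximum(m.phi, m.phi_floor)))
    elif rule == "dphi":
        winner = int(np.argmax(dphi))  # np.argmax returns the first maximal index
    else:
        raise ValueError(f"unknown winner rule {rule!r}")
    m.mu += dmu
    m.sigma = np.maximum(m.sigma + dsigma, m.sigma_floor)
    m.phi[winner] += dphi[winner]
    np.maximum(m.phi, m.phi_floor, out=m.phi)
    m.phi /= m.phi.sum()
    return m
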