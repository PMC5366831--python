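"""Cue normalization, orientation standardization, and reliability weighting.

Raw cue values live in incommensurable units (Hz for formant onsets,
mm for mouth geometry).  Before reaching the integrated audiovisual
mixture each value is (1) centered and scaled by the cue mixture's own
current central tendency and variability into a z-score-like quantity,
(2) sign-standardized so that lower values always point toward /b/, and
(3) passed through a compressive transform ``sign(z) |z|^t / s`` that
tames extreme tokens (defaults t=0.9, s=2.5).  The four normalized values
are then combined as a weighted sum, the weights being the normalized
category-structured reliabilities of the four cue mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import warnings

import numpy as np

from .mixture import Mixture, central_tendency, variability, cue_weight

__all__ = [
    "DEFAULT_T",
    "DEFAULT_S",
    "NormalizationState",
    "CueWeights",
    "orientation_sign",
    "signed_power_transform",
    "normalize_and_scale",
    "combine_cues",
    "compute_weights",
]

log = logging.getLogger(__name__)

DEFAULT_T = 0.9
DEFAULT_S = 2.5


def signed_power_transform(z, t: float = DEFAULT_T, s: float = DEFAULT_S):
    """Odd, monotone compressive map: sign(z) |z|^t / s."""
    z = np.asarray(z, dtype=float)
    out = np.sign(z) * np.abs(z) ** t / s
    return float(out) if out.ndim == 0 else out


@dataclass
class NormalizationState:
    """Current normalization of one cue dimension.

    c: central tendency (cue units); v: variability (squared cue units);
    sign: orientation multiplier in {-1, +1}; t, s: scaling parameters.
    The transform ``signed_power_transform`` is pluggable so alternative
    readings of the scaling step can be swapped in for sensitivity runs.
    """

    c: float
    v: float
    sign: int = 1
    t: float = DEFAULT_T
    s: float = DEFAULT_S
    transform: object = field(default=signed_power_transform, repr=False)

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError("variability v must be strictly positive")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")
        if not (0 < self.t <= 1):
            raise ValueError("t must lie in (0, 1]")
        if not self.s > 0:
            raise ValueError("s must be strictly positive")

    @classmethod
    def from_mixture(cls, m: Mixture, sign: int = 1,
                     t: float = DEFAULT_T, s: float = DEFAULT_S) -> "NormalizationState":
        c = central_tendency(m)
        return cls(c=c, v=variability(m, c), sign=sign, t=t, s=s)


@dataclass(frozen=True)
class CueWeights:
    """Raw and sum-to-one normalized per-cue reliability weights."""

    raw: np.ndarray
    normalized: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))
        object.__setattr__(self, "normalized", np.asarray(self.normalized, dtype=float))
        if np.any(self.raw < 0) or np.any(self.normalized < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.normalized.sum() - 1.0) > 1e-9:
            raise ValueError("normalized weights must sum to 1")


def orientation_sign(mean_b, mean_other=None, cue: str | None = None) -> int:
    """+1 when the /b/ category mean is the lower one on this cue, else -1.

    Applied to the z-scored value this puts /b/ below the contrasting
    category on every normalized dimension, giving the integrated mixture
    a common reference frame.  Equal means are degenerate; +1 is returned
    with a warning.

    Accepts either the two category means directly, or a contrast spec
    plus a cue label: ``orientation_sign(contrast, cue="MH")``.
    """
    if cue is not None or hasattr(mean_b, "category_a"):
        contrast = mean_b
        if cue is None:
            raise TypeError("cue label required when passing a contrast spec")
        mean_b = contrast.category_a.means[cue]
        mean_other = contrast.category_b.means[cue]
    if mean_b < mean_other:
        return 1
    if mean_b > mean_other:
        return -1
    warnings.warn("degenerate cue: category means are equal; using sign +1")
    return 1


def normalize_and_scale(x: float, state: NormalizationState) -> float:
    """Map a raw cue value to its dimensionless scaled input.

    z = sign * (x - c) / sqrt(v), then the compressive transform.  Strictly
    monotone in x (for sign=+1) and odd-symmetric about c.
    """
    x = float(x)
    if not np.isfinite(x):
        raise ValueError(f"cue value must be finite, got {x!r}")
    z = state.sign * (x - state.c) / np.sqrt(state.v)
    return float(state.transform(z, state.t, state.s))


def combine_cues(values, weights: CueWeights) -> float:
    """Weighted sum of normalized cue inputs (the integrated-mixture input)."""
    values = np.asarray(values, dtype=float)
    w = weights.normalized
    if values.shape != w.shape:
        raise ValueError(
            f"got {values.size} cue values for {w.size} weights")
    return float(np.dot(values, w))


def compute_weights(cue_mixtures) -> CueWeights:
    """Reliability weights of the cue mixtures, normalized to sum to 1.

    If every raw weight is zero (all mixtures collapsed onto a single
    location) the weights fall back to uniform, with a warning.
    """
    raw = np.array([cue_weight(m) for m in cue_mixtures], dtype=float)
    total = raw.sum()
    if total > 0:
        normalized = raw / total
    else:
        log.warning("all raw cue weights are zero; falling back to uniform")
        normalized = np.full(raw.size, 1.0 / raw.size)
    return CueWeights(raw=raw, normalized=normalized)
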