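"""Synthetic training tokens and audiovisual test continua.

The learner is never shown real recordings: training tokens are sampled
from per-category Gaussians over the four cues, parameterized by published
summary statistics (means and SDs per cue per phoneme) measured from the
AVOZES Australian English audiovisual corpus.  Cues are drawn
independently within a token (the four cues were chosen to be maximally
uncorrelated) and the two categories are sampled equiprobably by default.
Sampled values are not truncated: physically implausible tails are exactly
what the compressive input scaling exists to tame, though a truncation
bound can be supplied for sensitivity runs.

Test stimuli form a 9 x 9 grid: nine auditory steps (moving F2 and F3
jointly) crossed with nine visual steps (moving mouth height and width
jointly).  Per cue, step 3 sits at the /b/ prototype mean and step 7 at
the contrasting prototype mean, with equal spacing of a quarter of the
prototype difference per step, so steps 1 and 9 extrapolate half a
prototype range beyond each category.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CUES",
    "VISUAL_CUES",
    "AUDITORY_CUES",
    "CategoryCueStats",
    "ContrastSpec",
    "TestGrid",
    "TokenStream",
    "avozes_defaults",
    "sample_token",
    "sample_tokens",
    "build_test_grid",
    "contrast_from_config",
    "tokens_to_csv",
]

#: Canonical cue ordering used by every array-valued interface.
CUES = ("MH", "MW", "F2", "F3")
VISUAL_CUES = ("MH", "MW")
AUDITORY_CUES = ("F2", "F3")

#: Cue units, for documentation and CSV headers.
CUE_UNITS = {"MH": "mm", "MW": "mm", "F2": "Hz", "F3": "Hz"}

# Published AVOZES category statistics: mean (SD) per cue per phoneme.
# Mouth height/width are articulation ranges in mm; F2/F3 are onset minima
# in Hz.
_AVOZES = {
    "b": {"MW": (6.51, 6.39), "MH": (13.63, 5.30),
          "F2": (1026.0, 155.70), "F3": (2286.0, 360.16)},
    "d": {"MW": (3.89, 2.50), "MH": (6.09, 4.17),
          "F2": (1289.0, 232.80), "F3": (2404.0, 326.98)},
    "g": {"MW": (5.16, 4.40), "MH": (4.70, 3.69),
          "F2": (1311.0, 210.30), "F3": (2249.0, 290.26)},
}


@dataclass(frozen=True)
class CategoryCueStats:
    """Gaussian cue statistics of one phoneme category."""

    phoneme: str
    means: dict
    sds: dict

    def __post_init__(self) -> None:
        missing = [c for c in CUES if c not in self.means or c not in self.sds]
        if missing:
            raise ValueError(f"category {self.phoneme!r} missing cues: {missing}")
        if any(self.sds[c] <= 0 for c in CUES):
            raise ValueError("all cue SDs must be strictly positive")

    def mean_vector(self) -> np.ndarray:
        return np.array([self.means[c] for c in CUES], dtype=float)

    def sd_vector(self) -> np.ndarray:
        return np.array([self.sds[c] for c in CUES], dtype=float)


@dataclass(frozen=True)
class ContrastSpec:
    """A two-category phonetic contrast; category_a is always /b/."""

    category_a: CategoryCueStats
    category_b: CategoryCueStats
    p_a: float = 0.5
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.p_a < 1.0):
            raise ValueError("sampling probability p_a must lie in (0, 1)")

    @property
    def mean_matrix(self) -> np.ndarray:
        """(2, n_cues) category means, row 0 = /b/."""
        return np.stack([self.category_a.mean_vector(),
                         self.category_b.mean_vector()])

    @property
    def sd_matrix(self) -> np.ndarray:
        return np.stack([self.category_a.sd_vector(),
                         self.category_b.sd_vector()])


def avozes_defaults(contrast_name: str) -> ContrastSpec:
    """Built-in AVOZES contrast: ``"bd"`` (/b/-/d/) or ``"bg"`` (/b/-/g/)."""
    key = contrast_name.lower().replace("/", "").replace("-", "")
    if key not in ("bd", "bg"):
        raise ValueError(
            f"unknown contrast {contrast_name!r}; valid contrasts: 'bd', 'bg'")
    other = key[1]
    mk = lambda ph: CategoryCueStats(
        ph, {c: _AVOZES[ph][c][0] for c in CUES}, {c: _AVOZES[ph][c][1] for c in CUES})
    return ContrastSpec(mk("b"), mk(other), name=key)


# ---------------------------------------------------------------------------
# Token sampling

#: Tokens are drawn from per-rep RNG streams in fixed-size blocks so that a
#: rep's stream is identical whether it is trained alone, in a vectorized
#: batch, or across checkpoint placements.  Part of the determinism contract.
TOKEN_CHUNK = 4096


def sample_tokens(contrast: ContrastSpec, n: int, rng: np.random.Generator,
                  truncate_at: float | None = None):
    """Draw ``n`` training tokens.

    Returns ``(values, categories)``: an (n, 4) float array in ``CUES``
    order and an (n,) int array (0 = /b/, 1 = the contrasting category).
    One uniform draw selects each token's category, then one standard
    normal draw per cue is scaled by that category's statistics; this
    draw order is fixed and shared by all training backends.
    """
    cats = (rng.random(n) >= contrast.p_a).astype(np.int64)
    z = rng.standard_normal((n, len(CUES)))
    if truncate_at is not None:
        np.clip(z, -truncate_at, truncate_at, out=z)
    means = contrast.mean_matrix[cats]
    sds = contrast.sd_matrix[cats]
    return means + sds * z, cats


def sample_token(contrast: ContrastSpec, rng: np.random.Generator):
    """Draw a single token; returns (values (4,), category)."""
    values, cats = sample_tokens(contrast, 1, rng)
    return values[0], int(cats[0])


class TokenStream:
    """Chunked deterministic token stream for one replication.

    Draws ``TOKEN_CHUNK`` tokens at a time from ``rng``; ``take(n)`` returns
    the next ``n`` tokens, and ``skip(n)`` discards them while consuming the
    identical random draws (used for bit-exact checkpoint resume).
    """

    def __init__(self, contrast: ContrastSpec, rng: np.random.Generator,
                 truncate_at: float | None = None, chunk: int = TOKEN_CHUNK):
        self.contrast = contrast
        self.rng = rng
        self.truncate_at = truncate_at
        self.chunk = int(chunk)
        self._buf = np.empty((0, len(CUES)))
        self._cats = np.empty(0, dtype=np.int64)
        self._pos = 0

    def _refill(self) -> None:
        self._buf, self._cats = sample_tokens(
            self.contrast, self.chunk, self.rng, self.truncate_at)
        self._pos = 0

    def take(self, n: int):
        """Next ``n`` tokens as ((n, 4) values, (n,) categories)."""
        out_v, out_c, got = [], [], 0
        while got < n:
            if self._pos >= len(self._buf):
                self._refill()
            m = min(n - got, len(self._buf) - self._pos)
            out_v.append(self._buf[self._pos:self._pos + m])
            out_c.append(self._cats[self._pos:self._pos + m])
            self._pos += m
            got += m
        return np.concatenate(out_v), np.concatenate(out_c)

    def skip(self, n: int) -> None:
        self.take(n)


# ---------------------------------------------------------------------------
# Test continua


@dataclass(frozen=True)
class TestGrid:
    """81 audiovisual test stimuli on a 9 x 9 step grid.

    ``stimuli[a, v]`` is the 4-cue vector (``CUES`` order) at auditory step
    ``a+1`` and visual step ``v+1``; steps are 1-based in all interfaces.
    """

    contrast: ContrastSpec
    step_values: np.ndarray  # (4 cues, 9 steps) raw cue values

    N_STEPS = 9
    B_STEP = 3      # /b/ prototype anchor
    OTHER_STEP = 7  # contrasting-prototype anchor

    @property
    def stimuli(self) -> np.ndarray:
        out = np.empty((self.N_STEPS, self.N_STEPS, len(CUES)))
        for i, cue in enumerate(CUES):
            steps = self.step_values[i]
            axis = 1 if cue in VISUAL_CUES else 0  # visual cues follow the visual axis
            if axis == 0:
                out[:, :, i] = steps[:, None]
            else:
                out[:, :, i] = steps[None, :]
        return out

    def stimulus(self, aud_step: int, vis_step: int) -> np.ndarray:
        """Cue vector at 1-based (auditory, visual) steps."""
        return self.stimuli[aud_step - 1, vis_step - 1]


def build_test_grid(contrast: ContrastSpec) -> TestGrid:
    """Anchor step 3 at the /b/ prototype and step 7 at the other prototype.

    Per cue, step i = mu_b + (i - 3) * (mu_other - mu_b) / 4 for i = 1..9;
    auditory steps move F2 and F3 jointly and visual steps move MH and MW
    jointly.
    """
    mu_b = contrast.category_a.mean_vector()
    mu_o = contrast.category_b.mean_vector()
    i = np.arange(1, TestGrid.N_STEPS + 1)
    step_values = mu_b[:, None] + (i - TestGrid.B_STEP)[None, :] * \
        ((mu_o - mu_b) / (TestGrid.OTHER_STEP - TestGrid.B_STEP))[:, None]
    return TestGrid(contrast=contrast, step_values=step_values)


# ---------------------------------------------------------------------------
# Plain-text interfaces


def contrast_from_config(cfg: dict) -> ContrastSpec:
    """Build a ContrastSpec from a plain config mapping.

    Expected keys::

        category_a: {phoneme: b, MH: [13.63, 5.30], MW: [...], F2: [...], F3: [...]}
        category_b: {phoneme: d, ...}
        p_a: 0.5            # optional
        name: custom-bd     # optional

    Each cue maps to a ``[mean, sd]`` pair.
    """
    def parse(cat: dict) -> CategoryCueStats:
        means = {c: float(cat[c][0]) for c in CUES}
        sds = {c: float(cat[c][1]) for c in CUES}
        return CategoryCueStats(str(cat.get("phoneme", "?")), means, sds)

    return ContrastSpec(parse(cfg["category_a"]), parse(cfg["category_b"]),
                        p_a=float(cfg.get("p_a", 0.5)),
                        name=str(cfg.get("name", "custom")))


def tokens_to_csv(values: np.ndarray, categories: np.ndarray, path) -> None:
    """Export a sampled token stream for audit."""
    df = pd.DataFrame(values, columns=list(CUES))
    df.insert(0, "category", categories)
    df.insert(0, "trial", np.arange(1, len(df) + 1))
    df.to_csv(path, index=False)
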