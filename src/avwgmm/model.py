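"""The five-mixture audiovisual model and its online training loop.

An :class:`AVModel` holds one Gaussian mixture per cue (mouth height,
mouth width, F2 onset, F3 onset) plus an integrated mixture trained on
the reliability-weighted sum of the normalized cue inputs.  On every
training trial:

1. each cue mixture takes a gradient step (with winner-take-all phi
   competition) on its raw cue value;
2. the per-cue normalization (central tendency and variability) is
   refreshed from the just-updated cue mixtures;
3. cue reliabilities are recomputed and normalized into weights;
4. the token's cue values are normalized, sign-standardized, compressed,
   and combined into a single dimensionless integrated input;
5. the integrated mixture takes the same kind of gradient step on that
   input.

This module provides the per-trial reference implementation and the
checkpointing/serialization layer; :mod:`avwgmm.batch` runs the same
procedure vectorized across replications for full-scale simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .data import (AUDITORY_CUES, CUES, ContrastSpec, TokenStream,
                   avozes_defaults)
from .mixture import (PHI_FLOOR, SIGMA_FLOOR, LearningRates, Mixture,
                      apply_winner_take_all, gradient_deltas)
from .weighting import (DEFAULT_S, DEFAULT_T, CueWeights, NormalizationState,
                        combine_cues, compute_weights, normalize_and_scale,
                        orientation_sign)

__all__ = [
    "TABLE_RATES",
    "DEFAULT_INIT_MU_SPREAD",
    "TrainingConfig",
    "AVModel",
    "Checkpoint",
    "rep_rng",
    "initialize_model",
    "train_trial",
    "train",
]

#: Published learning rates per mixture (eta_mu, eta_sigma, eta_phi).  The
#: phi rate of the visual cues is deliberately 10x slower than the
#: auditory/integrated rate; the asymmetry is part of the model.
TABLE_RATES = {
    "MW": LearningRates(0.009, 0.008, 0.00005),
    "MH": LearningRates(0.009, 0.008, 0.00005),
    "F2": LearningRates(40.0, 20.0, 0.0005),
    "F3": LearningRates(80.0, 40.0, 0.0005),
    "integrated": LearningRates(0.00001, 0.00001, 0.0005),
}

#: SD of the random initial component locations, per cue (cue units).
DEFAULT_INIT_MU_SPREAD = {"MH": 3.0, "MW": 3.0, "F2": 250.0, "F3": 350.0}

DEFAULT_CHECKPOINTS = (100, 1_000, 10_000, 100_000, 150_000)


@dataclass(frozen=True)
class TrainingConfig:
    """Everything that, together with a contrast and a seed, fixes a run.

    ``checkpoint_mode`` selects whether the developmental test times are
    snapshots of one continuous run per replication (default) or
    independently seeded runs per test time.
    """

    K: int = 50
    n_trials: int = 150_000
    checkpoints: tuple = DEFAULT_CHECKPOINTS
    n_reps: int = 500
    base_seed: int = 0
    init_mu_spread: dict = field(default_factory=lambda: dict(DEFAULT_INIT_MU_SPREAD))
    integrated_init_mu_loc: float = 0.0
    integrated_init_mu_spread: float = 0.75
    integrated_init_sigma: float = 0.14
    t: float = DEFAULT_T
    s: float = DEFAULT_S
    rates: dict = field(default_factory=lambda: dict(TABLE_RATES))
    phi_floor: float = PHI_FLOOR
    sigma_floor: float = SIGMA_FLOOR
    truncate_at: float | None = None
    checkpoint_mode: str = "continuous"
    winner_rule: str = "posterior"

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        ck = tuple(sorted(int(c) for c in self.checkpoints))
        if ck != tuple(self.checkpoints):
            object.__setattr__(self, "checkpoints", ck)
        if not ck or ck[0] < 1 or ck[-1] > self.n_trials:
            raise ValueError("checkpoints must lie within [1, n_trials]")
        if self.checkpoint_mode not in ("continuous", "independent"):
            raise ValueError("checkpoint_mode must be 'continuous' or 'independent'")
        if self.winner_rule not in ("posterior", "dphi"):
            raise ValueError("winner_rule must be 'posterior' or 'dphi'")
        missing = [c for c in (*CUES, "integrated") if c not in self.rates]
        if missing:
            raise ValueError(f"missing learning rates for: {missing}")

    def with_updates(self, **kw) -> "TrainingConfig":
        return replace(self, **kw)


def rep_rng(base_seed: int, rep_index: int, stream: int | None = None) -> np.random.Generator:
    """Independent, individually re-runnable RNG for one replication.

    Streams are split by ``SeedSequence(base_seed, spawn_key=(rep,))`` so a
    rep's draws do not depend on how many reps run, in what order, or on
    worker scheduling.  ``stream`` keys sub-streams (independent-runs
    checkpoint mode).
    """
    key = (rep_index,) if stream is None else (rep_index, stream)
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=key))


@dataclass
class AVModel:
    """Four cue mixtures + integrated mixture + normalization constants."""

    contrast: ContrastSpec
    cue_mixtures: dict
    integrated: Mixture
    signs: np.ndarray
    t: float = DEFAULT_T
    s: float = DEFAULT_S
    rates: dict = field(default_factory=lambda: dict(TABLE_RATES))
    trial_counter: int = 0
    winner_rule: str = "posterior"

    def norm_state(self, cue: str) -> NormalizationState:
        """Current normalization of one cue, from its mixture."""
        i = CUES.index(cue)
        return NormalizationState.from_mixture(
            self.cue_mixtures[cue], sign=int(self.signs[i]), t=self.t, s=self.s)

    def weights(self) -> CueWeights:
        return compute_weights([self.cue_mixtures[c] for c in CUES])

    def integrated_input(self, values, weights: CueWeights | None = None) -> float:
        """Normalized, weighted integrated input for a raw 4-cue vector."""
        if weights is None:
            weights = self.weights()
        normed = [normalize_and_scale(values[i], self.norm_state(c))
                  for i, c in enumerate(CUES)]
        return combine_cues(normed, weights)

    def copy(self) -> "AVModel":
        return AVModel(self.contrast,
                       {c: m.copy() for c, m in self.cue_mixtures.items()},
                       self.integrated.copy(), self.signs.copy(),
                       self.t, self.s, dict(self.rates), self.trial_counter,
                       self.winner_rule)


@dataclass
class Checkpoint:
    """Snapshot of one replication at one developmental test time."""

    rep: int
    trial: int
    model: AVModel
    weights: CueWeights

    # -- JSON schema -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": "avwgmm-checkpoint-v1",
            "rep": self.rep,
            "trial": self.trial,
            "contrast": self.model.contrast.name,
            "t": self.model.t,
            "s": self.model.s,
            "winner_rule": self.model.winner_rule,
            "signs": self.model.signs.tolist(),
            "mixtures": {c: self.model.cue_mixtures[c].to_dict() for c in CUES},
            "integrated": self.model.integrated.to_dict(),
            "weights": {"raw": self.weights.raw.tolist(),
                        "normalized": self.weights.normalized.tolist()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict, contrast: ContrastSpec | None = None,
                  rates: dict | None = None) -> "Checkpoint":
        if d.get("schema") != "avwgmm-checkpoint-v1":
            raise ValueError("unrecognized checkpoint schema")
        if contrast is None:
            contrast = avozes_defaults(d["contrast"])
        model = AVModel(
            contrast=contrast,
            cue_mixtures={c: Mixture.from_dict(d["mixtures"][c]) for c in CUES},
            integrated=Mixture.from_dict(d["integrated"]),
            signs=np.asarray(d["signs"], dtype=int),
            t=float(d["t"]), s=float(d["s"]),
            rates=rates or dict(TABLE_RATES),
            trial_counter=int(d["trial"]),
            winner_rule=d.get("winner_rule", "posterior"),
        )
        weights = CueWeights(np.asarray(d["weights"]["raw"]),
                             np.asarray(d["weights"]["normalized"]))
        return cls(rep=int(d["rep"]), trial=int(d["trial"]),
                   model=model, weights=weights)

    @classmethod
    def from_json(cls, path, **kw) -> "Checkpoint":
        with open(path) as fh:
            return cls.from_dict(json.load(fh), **kw)


def initialize_model(contrast: ContrastSpec, config: TrainingConfig,
                     rng: np.random.Generator) -> AVModel:
    """Random initial state for one replication.

    Per cue: component locations are drawn from a normal centered on the
    midpoint of the two prototype means with a cue-specific spread; every
    component's sigma starts at the mean of the two prototype SDs, and
    every phi at 1/K.  The integrated mixture starts in normalized-input
    space: locations ~ N(0, 1), sigma 0.5, phi 1/K.  Draw order (cues in
    canonical order, then integrated) is part of the determinism contract.
    """
    K = config.K
    mu_b = contrast.category_a.mean_vector()
    mu_o = contrast.category_b.mean_vector()
    sd_b = contrast.category_a.sd_vector()
    sd_o = contrast.category_b.sd_vector()

    cue_mixtures = {}
    for i, cue in enumerate(CUES):
        mid = 0.5 * (mu_b[i] + mu_o[i])
        mu = mid + config.init_mu_spread[cue] * rng.standard_normal(K)
        sigma = np.full(K, 0.5 * (sd_b[i] + sd_o[i]))
        phi = np.full(K, 1.0 / K)
        cue_mixtures[cue] = Mixture(mu, sigma, phi, label=cue,
                                    phi_floor=config.phi_floor,
                                    sigma_floor=config.sigma_floor)
    imu = (config.integrated_init_mu_loc
           + config.integrated_init_mu_spread * rng.standard_normal(K))
    integrated = Mixture(imu, np.full(K, config.integrated_init_sigma),
                         np.full(K, 1.0 / K), label="integrated",
                         phi_floor=config.phi_floor,
                         sigma_floor=config.sigma_floor)
    signs = np.array([orientation_sign(mu_b[i], mu_o[i]) for i in range(len(CUES))])
    return AVModel(contrast=contrast, cue_mixtures=cue_mixtures,
                   integrated=integrated, signs=signs,
                   t=config.t, s=config.s, rates=dict(config.rates),
                   winner_rule=config.winner_rule)


def train_trial(model: AVModel, values) -> tuple[AVModel, CueWeights]:
    """One online trial on a raw 4-cue token; returns (model, trial weights)."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite token at trial {model.trial_counter + 1}: {values}")
    # (1) cue-level updates on raw values
    for i, cue in enumerate(CUES):
        m = model.cue_mixtures[cue]
        deltas = gradient_deltas(values[i], m, model.rates[cue])
        apply_winner_take_all(m, deltas, model.winner_rule)
    # (2-3) refreshed normalization and weights from the updated mixtures
    states = [model.norm_state(c) for c in CUES]
    weights = model.weights()
    # (4) integrated input
    normed = [normalize_and_scale(values[i], st) for i, st in enumerate(states)]
    x_int = combine_cues(normed, weights)
    if not np.isfinite(x_int):
        raise ValueError(
            f"non-finite integrated input at trial {model.trial_counter + 1}")
    # (5) integrated update
    deltas = gradient_deltas(x_int, model.integrated, model.rates["integrated"])
    apply_winner_take_all(model.integrated, deltas, model.winner_rule)
    model.trial_counter += 1
    return model, weights


def train(contrast: ContrastSpec, config: TrainingConfig, rep_index: int,
          resume_from: Checkpoint | None = None) -> list[Checkpoint]:
    """Train one replication per trial, snapshotting at each checkpoint.

    This is the readable reference path; full-scale simulations use
    :func:`avwgmm.batch.train_replications`, which runs the identical
    procedure vectorized across replications.  ``resume_from`` continues a
    serialized checkpoint bit-exactly by replaying (and discarding) the
    RNG draws the original run had already consumed.
    """
    rng = rep_rng(config.base_seed, rep_index)
    stream = TokenStream(contrast, rng, truncate_at=config.truncate_at)
    if resume_from is None:
        model = initialize_model(contrast, config, rng)
        start = 0
    else:
        initialize_model(contrast, config, rng)  # consume the init draws
        model = resume_from.model.copy()
        start = resume_from.trial
        stream.skip(start)

    checkpoints: list[Checkpoint] = []
    weights = model.weights()
    trial = start
    for ck in config.checkpoints:
        if ck <= start:
            continue
        values, _ = stream.take(ck - trial)
        for row in values:
            model, weights = train_trial(model, row)
        trial = ck
        checkpoints.append(Checkpoint(rep=rep_index, trial=trial,
                                      model=model.copy(), weights=weights))
    return checkpoints
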