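"""End-to-end experiment definitions, variants, and results bundles.

Two main simulations (the /b/-/d/ and /b/-/g/ contrasts, 500 replications
by default) plus three robustness variants of the /b/-/d/ simulation:

* ``no_scaling`` — the compressive input scaling disabled (t = 1, s = 1);
* ``equal_rates`` — the auditory phi learning rates slowed to the visual
  rate (0.00005 for all four cues), removing the auditory/visual rate
  asymmetry;
* ``matched_init`` — per-cue initial location spreads adjusted so all
  four cues start with the same expected reliability weight (within
  0.9%), removing the initial auditory weight advantage.

A results bundle is a directory of plain-text artifacts (manifest,
aggregate JSON, per-replication CSV tables, optional checkpoint JSONs)
fully determined by its manifest.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .batch import BatchResult, train_replications
from .data import CUES, ContrastSpec, avozes_defaults, contrast_from_config
from .evaluation import (convergence_table, evaluate_result, influence_table,
                         surface_table, weights_table)
from .mixture import LearningRates
from .model import TABLE_RATES, TrainingConfig

__all__ = [
    "EXPERIMENTS",
    "ExperimentManifest",
    "experiment_config",
    "variant_matched_init",
    "expected_initial_weights",
    "simulated_initial_weights",
    "run_experiment",
    "headline",
]

EXPERIMENTS = ("sim1", "sim2", "robustness:no_scaling",
               "robustness:equal_rates", "robustness:matched_init")

#: Robustness variants run 100 replications, like the original study.
_VARIANT_REPS = 100


def _canonical(experiment: str) -> str:
    e = experiment.lower()
    if e in ("no_scaling", "equal_rates", "matched_init"):
        e = "robustness:" + e
    if e not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {experiment!r}; valid: {', '.join(EXPERIMENTS)}")
    return e


# ---------------------------------------------------------------------------
# Initial-weight analysis (matched-init variant)


def expected_initial_weights(contrast: ContrastSpec,
                             config: TrainingConfig) -> np.ndarray:
    """Expected initial raw reliability weight per cue.

    Under the initialization (locations ~ N(mid, s0), common sigma
    sigma_bar, phi uniform) the raw weight equals the biased sample
    variance of the K location draws over sigma_bar^2, whose expectation
    is s0^2 (K - 1) / (K sigma_bar^2).
    """
    K = config.K
    sigma_bar = contrast.sd_matrix.mean(0)
    s0 = np.array([config.init_mu_spread[c] for c in CUES])
    return s0 ** 2 * (K - 1) / (K * sigma_bar ** 2)


def simulated_initial_weights(contrast: ContrastSpec, config: TrainingConfig,
                              n_reps: int = 2000, seed: int = 0) -> np.ndarray:
    """Mean normalized initial weights over freshly drawn initial states."""
    rng = np.random.default_rng(seed)
    K = config.K
    sigma_bar = contrast.sd_matrix.mean(0)
    s0 = np.array([config.init_mu_spread[c] for c in CUES])
    mid = contrast.mean_matrix.mean(0)
    mu = mid[None, :, None] + s0[None, :, None] * rng.standard_normal(
        (n_reps, len(CUES), K))
    raw = mu.var(axis=-1) / sigma_bar[None, :] ** 2  # phi uniform, sigma common
    return (raw / raw.sum(-1, keepdims=True)).mean(0)


def variant_matched_init(config: TrainingConfig,
                         contrast: ContrastSpec | None = None,
                         tol: float = 1e-10, max_iter: int = 200) -> TrainingConfig:
    """Equalize the four cues' expected initial weights.

    Deterministic bisection per cue on the analytic expected-weight curve
    (monotone in the spread), targeting the mean of the current expected
    raw weights; idempotent because matched spreads leave that target
    unchanged.  The result makes the expected initial normalized weights
    exactly equal; tests verify the simulated weights agree within 0.9%.
    """
    if contrast is None:
        contrast = avozes_defaults("bd")
    K = config.K
    sigma_bar = contrast.sd_matrix.mean(0)
    target = expected_initial_weights(contrast, config).mean()
    spreads = {}
    for i, cue in enumerate(CUES):
        lo, hi = 0.0, 10.0 * sigma_bar[i]

        def expected(s0: float) -> float:
            return s0 ** 2 * (K - 1) / (K * sigma_bar[i] ** 2)

        if expected(hi) < target:
            raise RuntimeError(
                f"matched-init search failed to bracket the target weight "
                f"for cue {cue} (target {target:.4g}, max {expected(hi):.4g})")
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            if expected(mid) < target:
                lo = mid
            else:
                hi = mid
            if hi - lo < tol * sigma_bar[i]:
                break
        spreads[cue] = 0.5 * (lo + hi)
    return config.with_updates(init_mu_spread=spreads)


# ---------------------------------------------------------------------------
# Experiment construction


def _equal_rate_table() -> dict:
    rates = dict(TABLE_RATES)
    for cue in ("F2", "F3"):
        r = rates[cue]
        rates[cue] = LearningRates(r.eta_mu, r.eta_sigma, 0.00005)
    return rates


def experiment_config(experiment: str, base: TrainingConfig | None = None
                      ) -> tuple[ContrastSpec, TrainingConfig]:
    """Contrast and training configuration for a named experiment."""
    experiment = _canonical(experiment)
    base = base or TrainingConfig()
    if experiment == "sim2":
        return avozes_defaults("bg"), base
    contrast = avozes_defaults("bd")
    if experiment == "sim1":
        return contrast, base
    base = base.with_updates(n_reps=min(base.n_reps, _VARIANT_REPS))
    if experiment == "robustness:no_scaling":
        return contrast, base.with_updates(t=1.0, s=1.0)
    if experiment == "robustness:equal_rates":
        return contrast, base.with_updates(rates=_equal_rate_table())
    return contrast, variant_matched_init(base, contrast)


@dataclass(frozen=True)
class ExperimentManifest:
    """Everything needed to reproduce a results bundle byte-for-byte."""

    experiment: str
    config: TrainingConfig
    contrast_name: str
    seed: int
    out_dir: str = "."
    version: str = __version__

    @property
    def config_hash(self) -> str:
        blob = json.dumps(_config_dict(self.config), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "contrast": self.contrast_name,
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "version": self.version,
            "config_hash": self.config_hash,
            "config": _config_dict(self.config),
            "python": platform.python_version(),
        }


def _config_dict(config: TrainingConfig) -> dict:
    d = asdict(config)
    d["rates"] = {k: [v.eta_mu, v.eta_sigma, v.eta_phi]
                  for k, v in config.rates.items()}
    d["checkpoints"] = list(config.checkpoints)
    return d


def make_manifest(experiment: str, seed: int, out_dir=".",
                  base: TrainingConfig | None = None,
                  **overrides) -> ExperimentManifest:
    experiment = _canonical(experiment)
    contrast, config = experiment_config(
        experiment, (base or TrainingConfig()).with_updates(base_seed=seed))
    if overrides:
        config = config.with_updates(**overrides)
    return ExperimentManifest(experiment=experiment, config=config,
                              contrast_name=contrast.name, seed=seed,
                              out_dir=str(out_dir))


# ---------------------------------------------------------------------------
# Execution and bundles


def headline(summaries: dict) -> dict:
    """Compact per-checkpoint summary mirroring the study's key numbers."""
    out = {}
    for trial in sorted(summaries):
        s = summaries[trial]
        out[str(trial)] = {
            "convergence_pct": round(s["convergence_pct"], 2),
            "mean_weights": {c: round(w, 4) for c, w in
                             zip(s["cues"], s["weights_all"]["mean"])},
            "A_influence": _r(s["A_influence_converged"]["mean"]),
            "V_influence": _r(s["V_influence_converged"]["mean"]),
            "congruent_accuracy_pct": _r(
                s["congruent_accuracy_pct_converged"]["mean"]),
        }
    return out


def _r(x, nd=4):
    return None if x is None else round(float(x), nd)


def run_experiment(manifest: ExperimentManifest, backend: str = "auto",
                   n_jobs: int = 1, save_checkpoints: str = "none",
                   save_surfaces: bool = True):
    """Run one experiment end to end and write its results bundle.

    Returns ``(result, reports, summaries)``.  ``save_checkpoints`` is
    ``"none"``, ``"final"`` or ``"all"``.  Bundle contents are independent
    of ``n_jobs`` and of the evaluation order.
    """
    if save_checkpoints not in ("none", "final", "all"):
        raise ValueError("save_checkpoints must be 'none', 'final' or 'all'")
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    probe.write_text("")  # fail fast on an unwritable output directory
    probe.unlink()

    contrast = (avozes_defaults(manifest.contrast_name)
                if manifest.contrast_name in ("bd", "bg") else None)
    if contrast is None:
        raise ValueError(f"manifest names unknown contrast {manifest.contrast_name!r}")
    result = train_replications(contrast, manifest.config, backend=backend,
                                n_jobs=n_jobs)
    reports, summaries = evaluate_result(result)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2)
    with open(out / "aggregate.json", "w") as fh:
        json.dump({"experiment": manifest.experiment,
                   "headline": headline(summaries),
                   "per_checkpoint": {str(t): summaries[t] for t in summaries}},
                  fh, indent=2)
    for name, table in (("convergence", convergence_table(reports)),
                        ("weights", weights_table(reports)),
                        ("influence", influence_table(reports)),
                        ("surfaces", surface_table(reports) if save_surfaces
                         else None)):
        if table is None:
            continue
        table.insert(0, "sim", manifest.experiment)
        table.to_csv(out / f"{name}.csv", index=False)
    if save_checkpoints != "none":
        ckdir = out / "checkpoints"
        ckdir.mkdir(exist_ok=True)
        trials = ([result.trials[-1]] if save_checkpoints == "final"
                  else result.trials)
        for trial in trials:
            for p in range(result.n_reps):
                ck = result.checkpoint(trial, p)
                ck.to_json(ckdir / f"rep{ck.rep:04d}_trial{trial:06d}.json")
    return result, reports, summaries
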