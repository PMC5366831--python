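"""Vectorized multi-replication trainer.

Full-scale simulations run hundreds of replications of 150,000 online
trials; the per-trial reference loop in :mod:`avwgmm.model` is far too
slow for that.  This module runs the *identical* procedure — same token
streams, same update order, same floors — over all replications at once,
either through a numba-compiled kernel (default when numba is available)
or a pure-numpy batch path.  Equivalence with the reference loop is
enforced by tests at 1e-10 relative tolerance; bit-exactness holds within
a backend (the two backends' libm calls can differ in the last ulps).

Replications are independent by construction (per-rep RNG streams), so
optional joblib parallelism across rep blocks cannot change results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import CUES, ContrastSpec, TokenStream
from .mixture import Mixture
from .model import (AVModel, Checkpoint, TrainingConfig, initialize_model,
                    rep_rng)
from .weighting import CueWeights

__all__ = ["Snapshot", "BatchResult", "train_replications", "batch_weights"]

log = logging.getLogger(__name__)

_SQRT2PI = np.sqrt(2.0 * np.pi)
_SEGMENT = 8192  # trials handed to the kernel per call (memory bound)

try:  # pragma: no cover - exercised implicitly by backend selection
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# Weight computation on parameter arrays


def batch_weights(cue_mu, cue_sigma, cue_phi):
    """Raw and normalized reliability weights from (R, C, K) arrays."""
    a = cue_phi / cue_sigma
    b = a * cue_mu
    d = b * cue_mu
    raw = a.sum(-1) * d.sum(-1) - b.sum(-1) ** 2
    np.maximum(raw, 0.0, out=raw)
    total = raw.sum(-1, keepdims=True)
    norm = np.where(total > 0, raw / np.where(total > 0, total, 1.0),
                    1.0 / raw.shape[-1])
    return raw, norm


# ---------------------------------------------------------------------------
# numba kernel

if _HAVE_NUMBA:

    @numba.njit(cache=False)
    def _nb_update(mu, sg, ph, x, emu, esg, eph, phf, sgf, post_rule):
        K = mu.size
        g = np.empty(K)
        M = 0.0
        for j in range(K):
            z = (x - mu[j]) / sg[j]
            gj = ph[j] * np.exp(-0.5 * z * z) / (_SQRT2PI * sg[j])
            g[j] = gj
            M += gj
        if M > 0.0:
            for j in range(K):
                g[j] /= M
        else:  # total underflow: uniform over components above the phi floor
            cnt = 0
            for j in range(K):
                if ph[j] > phf:
                    cnt += 1
            if cnt == 0:
                for j in range(K):
                    g[j] = 1.0 / K
            else:
                for j in range(K):
                    g[j] = (1.0 / cnt) if ph[j] > phf else 0.0
        best = 0
        bestval = -1.0
        win_dphi = 0.0
        for j in range(K):
            resp = g[j]
            pj = ph[j] if ph[j] > phf else phf
            dphi = eph * resp / pj
            crit = resp if post_rule else dphi
            if crit > bestval:
                bestval = crit
                best = j
                win_dphi = dphi
            diff = x - mu[j]
            s = sg[j]
            mu[j] += emu * resp * diff / (s * s)
            s2 = s + esg * resp * (diff * diff / (s * s * s) - 1.0 / s)
            sg[j] = s2 if s2 > sgf else sgf
        ph[best] += win_dphi
        S = 0.0
        for j in range(K):
            if ph[j] < phf:
                ph[j] = phf
            S += ph[j]
        for j in range(K):
            ph[j] /= S

    @numba.njit(cache=False)
    def _nb_trials(cmu, csg, cph, imu, isg, iph, tok, signs, crates, irates,
                   t_exp, s_div, phf, sgf, post_rule):
        R, C, K = cmu.shape
        T = tok.shape[1]
        wr = np.empty(C)
        xn = np.empty(C)
        for r in range(R):
            for n in range(T):
                for c in range(C):
                    _nb_update(cmu[r, c], csg[r, c], cph[r, c], tok[r, n, c],
                               crates[c, 0], crates[c, 1], crates[c, 2],
                               phf, sgf, post_rule)
                wsum = 0.0
                for c in range(C):
                    mu = cmu[r, c]
                    sg = csg[r, c]
                    ph = cph[r, c]
                    tot = 0.0
                    m1 = 0.0
                    for j in range(K):
                        tot += ph[j]
                        m1 += mu[j] * ph[j]
                    cc = m1 / tot
                    vv = 0.0
                    sa = 0.0
                    sb = 0.0
                    sd = 0.0
                    for j in range(K):
                        dj = mu[j] - cc
                        vv += ph[j] * (dj * dj + sg[j] * sg[j])
                        aj = ph[j] / sg[j]
                        sa += aj
                        sb += aj * mu[j]
                        sd += aj * mu[j] * mu[j]
                    vv /= tot
                    w = sa * sd - sb * sb
                    wr[c] = w if w > 0.0 else 0.0
                    wsum += wr[c]
                    z = signs[c] * (tok[r, n, c] - cc) / np.sqrt(vv)
                    az = -z if z < 0.0 else z
                    f = az ** t_exp / s_div
                    xn[c] = f if z >= 0.0 else -f
                xint = 0.0
                if wsum > 0.0:
                    for c in range(C):
                        xint += wr[c] / wsum * xn[c]
                else:
                    for c in range(C):
                        xint += xn[c] / C
                _nb_update(imu[r], isg[r], iph[r], xint,
                           irates[0], irates[1], irates[2], phf, sgf,
                           post_rule)


# ---------------------------------------------------------------------------
# numpy fallback


def _np_update(mu, sg, ph, x, emu, esg, eph, phf, sgf, post_rule):
    """One winner-take-all gradient step for (R, K) mixture arrays."""
    z = (x[:, None] - mu) / sg
    g = ph * np.exp(-0.5 * z * z) / (_SQRT2PI * sg)
    M = g.sum(1)
    ok = M > 0
    resp = np.empty_like(g)
    if ok.all():
        resp[:] = g / M[:, None]
    else:
        resp[ok] = g[ok] / M[ok, None]
        for r in np.flatnonzero(~ok):
            active = ph[r] > phf
            if not active.any():
                resp[r] = 1.0 / ph.shape[1]
            else:
                resp[r] = active / active.sum()
    dphi = eph * resp / np.maximum(ph, phf)
    winner = np.argmax(resp if post_rule else dphi, axis=1)
    diff = x[:, None] - mu
    mu += emu * resp * diff / sg ** 2
    np.maximum(sg + esg * resp * (diff ** 2 / sg ** 3 - 1.0 / sg), sgf, out=sg)
    rows = np.arange(ph.shape[0])
    ph[rows, winner] += dphi[rows, winner]
    np.maximum(ph, phf, out=ph)
    ph /= ph.sum(1, keepdims=True)


def _np_trials(cmu, csg, cph, imu, isg, iph, tok, signs, crates, irates,
               t_exp, s_div, phf, sgf, post_rule):
    R, C, K = cmu.shape
    for n in range(tok.shape[1]):
        x = tok[:, n, :]
        for c in range(C):
            _np_update(cmu[:, c], csg[:, c], cph[:, c], x[:, c],
                       crates[c, 0], crates[c, 1], crates[c, 2], phf, sgf,
                       post_rule)
        tot = cph.sum(-1)
        cc = (cmu * cph).sum(-1) / tot
        vv = (cph * ((cmu - cc[..., None]) ** 2 + csg ** 2)).sum(-1) / tot
        wraw, wnorm = batch_weights(cmu, csg, cph)
        z = signs[None, :] * (x - cc) / np.sqrt(vv)
        xn = np.sign(z) * np.abs(z) ** t_exp / s_div
        xint = (wnorm * xn).sum(-1)
        _np_update(imu, isg, iph, xint, irates[0], irates[1], irates[2],
                   phf, sgf, post_rule)


# ---------------------------------------------------------------------------
# Driver


@dataclass
class Snapshot:
    """All replications' parameters at one checkpoint trial."""

    trial: int
    cue_mu: np.ndarray      # (R, C, K)
    cue_sigma: np.ndarray
    cue_phi: np.ndarray
    int_mu: np.ndarray      # (R, K)
    int_sigma: np.ndarray
    int_phi: np.ndarray
    weights_raw: np.ndarray   # (R, C)
    weights_norm: np.ndarray


@dataclass
class BatchResult:
    """Checkpointed training result for a set of replications."""

    contrast: ContrastSpec
    config: TrainingConfig
    reps: np.ndarray                  # rep indices, (R,)
    snapshots: dict                   # trial -> Snapshot
    signs: np.ndarray

    @property
    def trials(self) -> list[int]:
        return sorted(self.snapshots)

    @property
    def n_reps(self) -> int:
        return self.reps.size

    def model(self, trial: int, rep_pos: int) -> AVModel:
        """Reconstruct one replication's AVModel at a checkpoint."""
        s = self.snapshots[trial]
        cfg = self.config
        cues = {c: Mixture(s.cue_mu[rep_pos, i], s.cue_sigma[rep_pos, i],
                           s.cue_phi[rep_pos, i], label=c,
                           phi_floor=cfg.phi_floor, sigma_floor=cfg.sigma_floor)
                for i, c in enumerate(CUES)}
        integrated = Mixture(s.int_mu[rep_pos], s.int_sigma[rep_pos],
                             s.int_phi[rep_pos], label="integrated",
                             phi_floor=cfg.phi_floor, sigma_floor=cfg.sigma_floor)
        return AVModel(contrast=self.contrast, cue_mixtures=cues,
                       integrated=integrated, signs=self.signs.copy(),
                       t=cfg.t, s=cfg.s, rates=dict(cfg.rates),
                       trial_counter=trial)

    def checkpoint(self, trial: int, rep_pos: int) -> Checkpoint:
        s = self.snapshots[trial]
        return Checkpoint(rep=int(self.reps[rep_pos]), trial=trial,
                          model=self.model(trial, rep_pos),
                          weights=CueWeights(s.weights_raw[rep_pos],
                                             s.weights_norm[rep_pos]))


def _select_backend(backend: str) -> str:
    if backend == "auto":
        return "numba" if _HAVE_NUMBA else "numpy"
    if backend == "numba" and not _HAVE_NUMBA:
        raise RuntimeError("numba backend requested but numba is not importable")
    if backend not in ("numba", "numpy"):
        raise ValueError(f"unknown backend {backend!r}")
    return backend


def _init_arrays(contrast, config, reps, stream_key):
    """Initial parameter arrays + token streams, consuming per-rep RNG draws."""
    R, K, C = len(reps), config.K, len(CUES)
    cmu = np.empty((R, C, K))
    csg = np.empty((R, C, K))
    cph = np.empty((R, C, K))
    imu = np.empty((R, K))
    isg = np.empty((R, K))
    iph = np.empty((R, K))
    streams = []
    signs = None
    for p, rep in enumerate(reps):
        rng = rep_rng(config.base_seed, int(rep), stream_key)
        model = initialize_model(contrast, config, rng)
        for i, c in enumerate(CUES):
            m = model.cue_mixtures[c]
            cmu[p, i], csg[p, i], cph[p, i] = m.mu, m.sigma, m.phi
        imu[p], isg[p], iph[p] = (model.integrated.mu, model.integrated.sigma,
                                  model.integrated.phi)
        signs = model.signs
        streams.append(TokenStream(contrast, rng, truncate_at=config.truncate_at))
    return cmu, csg, cph, imu, isg, iph, signs, streams


def _run_block(contrast, config, reps, checkpoints, backend, stream_key=None):
    cmu, csg, cph, imu, isg, iph, signs, streams = _init_arrays(
        contrast, config, reps, stream_key)
    signs_f = signs.astype(np.float64)
    crates = np.array([config.rates[c].as_array() for c in CUES])
    irates = config.rates["integrated"].as_array()
    step = _nb_trials if backend == "numba" else _np_trials

    snapshots = {}
    trial = 0
    for ck in checkpoints:
        while trial < ck:
            n = min(ck - trial, _SEGMENT)
            tok = np.stack([st.take(n)[0] for st in streams])
            step(cmu, csg, cph, imu, isg, iph, tok, signs_f, crates, irates,
                 config.t, config.s, config.phi_floor, config.sigma_floor,
                 config.winner_rule == "posterior")
            trial += n
        wraw, wnorm = batch_weights(cmu, csg, cph)
        snapshots[ck] = Snapshot(ck, cmu.copy(), csg.copy(), cph.copy(),
                                 imu.copy(), isg.copy(), iph.copy(),
                                 wraw, wnorm)
        log.info("checkpoint trial=%d reps=%d mean_weights=%s", ck, len(reps),
                 np.array2string(wnorm.mean(0), precision=3))
    return BatchResult(contrast, config, np.asarray(reps), snapshots, signs)


def _merge(results: list[BatchResult]) -> BatchResult:
    first = results[0]
    if len(results) == 1:
        return first
    snapshots = {}
    for trial in first.snapshots:
        parts = [r.snapshots[trial] for r in results]
        snapshots[trial] = Snapshot(
            trial,
            *[np.concatenate([getattr(s, f) for s in parts])
              for f in ("cue_mu", "cue_sigma", "cue_phi", "int_mu",
                        "int_sigma", "int_phi", "weights_raw", "weights_norm")])
    return BatchResult(first.contrast, first.config,
                       np.concatenate([r.reps for r in results]),
                       snapshots, first.signs)


def train_replications(contrast: ContrastSpec, config: TrainingConfig,
                       reps=None, backend: str = "auto",
                       n_jobs: int = 1) -> BatchResult:
    """Train a set of replications and return all checkpoint snapshots.

    ``reps`` is a sequence of replication indices (default
    ``range(config.n_reps)``); each index determines its own RNG stream,
    so any subset reproduces the corresponding slice of a larger run.  In
    ``independent`` checkpoint mode each test time is a separately seeded
    run of that duration rather than a snapshot of one continuous run.
    """
    backend = _select_backend(backend)
    if reps is None:
        reps = range(config.n_reps)
    reps = list(int(r) for r in reps)

    def run(checkpoints, stream_key=None):
        if n_jobs == 1 or len(reps) < 2 * n_jobs:
            return _run_block(contrast, config, reps, checkpoints, backend,
                              stream_key)
        from joblib import Parallel, delayed

        blocks = np.array_split(np.asarray(reps), n_jobs)
        parts = Parallel(n_jobs=n_jobs)(
            delayed(_run_block)(contrast, config, list(b), checkpoints,
                                backend, stream_key)
            for b in blocks if b.size)
        return _merge(parts)

    if config.checkpoint_mode == "continuous":
        return run(tuple(config.checkpoints))
    # independent mode: one fresh run (own sub-stream) per test duration
    merged_snaps = {}
    out = None
    for ci, ck in enumerate(config.checkpoints):
        out = run((ck,), stream_key=ci)
        merged_snaps[ck] = out.snapshots[ck]
    return BatchResult(contrast, config, out.reps, merged_snaps, out.signs)
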