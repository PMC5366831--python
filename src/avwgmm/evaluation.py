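"""Convergence assessment, identification surfaces, and congruency metrics.

A trained replication is scored by (1) whether its integrated mixture
maps the two category prototypes onto distinct components (at least a
two-category audiovisual solution — the convergence criterion; collapse
to one component is overgeneralization), (2) its 9 x 9 identification
surface, the Luce-choice probability of the non-/b/ response at every
audiovisual test stimulus, and (3) summary statistics of that surface:
auditory and visual influence computed from the four incongruent/
congruent corner cells, and accuracy on the two congruent corners.

Influence definitions (corner cells, steps 1 and 9 on each axis; ``A``
= auditory step, ``V`` = visual step, subscripts name the signalled
phoneme)::

    A_influence = ((AdVb - AbVb) + (AdVd - AbVd)) / 2
    V_influence = ((AbVd - AbVb) + (AdVd - AdVb)) / 2
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .batch import BatchResult
from .data import CUES, ContrastSpec, TestGrid, build_test_grid
from .mixture import Mixture, _component_densities
from .model import AVModel
from .weighting import CueWeights, normalize_and_scale

__all__ = [
    "ConvergenceReport",
    "IdentificationSurface",
    "InfluenceSummary",
    "RepReport",
    "map_prototypes",
    "luce_choice",
    "identification_surface",
    "influence",
    "congruent_accuracy",
    "evaluate_rep",
    "aggregate",
    "evaluate_result",
]


@dataclass(frozen=True)
class ConvergenceReport:
    """Category structure of one replication's solution at one test time."""

    rep: int
    trial: int
    proto_component_a: int
    proto_component_b: int
    converged: bool
    n_above_threshold: int
    one_category_cues: dict = field(default_factory=dict)


@dataclass(frozen=True)
class IdentificationSurface:
    """P(non-/b/ response) over the 9 x 9 audiovisual test grid.

    ``proportions[a, v]`` is the response proportion at auditory step
    ``a+1``, visual step ``v+1``.
    """

    proportions: np.ndarray
    rep: int = -1
    trial: int = -1

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (TestGrid.N_STEPS, TestGrid.N_STEPS):
            raise ValueError("surface must be 9 x 9")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("response proportions must lie in [0, 1]")
        object.__setattr__(self, "proportions", p)

    @property
    def corners(self) -> dict:
        p = self.proportions
        return {"AbVb": float(p[0, 0]), "AbVd": float(p[0, -1]),
                "AdVb": float(p[-1, 0]), "AdVd": float(p[-1, -1])}


@dataclass(frozen=True)
class InfluenceSummary:
    """Corner-cell congruency summary of one identification surface."""

    AbVb: float
    AbVd: float
    AdVb: float
    AdVd: float
    A_influence: float
    V_influence: float


@dataclass(frozen=True)
class RepReport:
    """Everything measured on one replication at one test time."""

    convergence: ConvergenceReport
    weights: CueWeights
    surface: IdentificationSurface
    influence: InfluenceSummary
    congruent_accuracy: float


def _integrated_inputs(model: AVModel, stimuli: np.ndarray) -> np.ndarray:
    """Integrated inputs for (..., 4) raw cue vectors, vectorized."""
    states = [model.norm_state(c) for c in CUES]
    weights = model.weights().normalized
    out = np.zeros(stimuli.shape[:-1])
    for i, st in enumerate(states):
        z = st.sign * (stimuli[..., i] - st.c) / np.sqrt(st.v)
        out += weights[i] * st.transform(z, st.t, st.s)
    return out


def map_prototypes(model: AVModel, contrast: ContrastSpec | None = None):
    """Integrated components with highest posterior at each prototype.

    The prototype stimuli are the two categories' mean vectors on all
    four cues.  Returns (index_a, index_b); ties break to the lowest
    index.  A degenerate integrated mixture simply yields equal indices
    (reported as non-converged downstream) rather than raising.
    """
    if contrast is None:
        contrast = model.contrast
    protos = contrast.mean_matrix  # (2, 4)
    u = _integrated_inputs(model, protos)
    idx = [int(np.argmax(_component_densities(ui, model.integrated)))
           for ui in u]
    return idx[0], idx[1]


def luce_choice(model: AVModel, stimulus, proto_indices) -> float:
    """P(non-/b/ response | stimulus) under the Luce choice rule.

    The strengths are the phi-weighted densities of the two prototype-
    mapped integrated components at the stimulus's integrated input:
    P = G_b(x) / (G_b(x) + G_b'(x)) with b' the contrasting category.
    """
    ia, ib = proto_indices
    u = _integrated_inputs(model, np.asarray(stimulus, dtype=float))
    g = _component_densities(float(u), model.integrated)
    denom = g[ia] + g[ib]
    if denom <= 0.0:
        warnings.warn("both prototype components have zero density; returning 0.5")
        return 0.5
    return float(g[ib] / denom)


def identification_surface(model: AVModel, grid: TestGrid | None = None,
                           proto_indices=None, rep: int = -1) -> IdentificationSurface:
    """Luce-choice response proportions at all 81 grid stimuli."""
    if grid is None:
        grid = build_test_grid(model.contrast)
    if proto_indices is None:
        proto_indices = map_prototypes(model)
    ia, ib = proto_indices
    u = _integrated_inputs(model, grid.stimuli)  # (9, 9)
    m = model.integrated
    z_a = (u - m.mu[ia]) / m.sigma[ia]
    z_b = (u - m.mu[ib]) / m.sigma[ib]
    ga = m.phi[ia] * np.exp(-0.5 * z_a ** 2) / (np.sqrt(2 * np.pi) * m.sigma[ia])
    gb = m.phi[ib] * np.exp(-0.5 * z_b ** 2) / (np.sqrt(2 * np.pi) * m.sigma[ib])
    denom = ga + gb
    with np.errstate(invalid="ignore"):
        p = np.where(denom > 0, gb / np.where(denom > 0, denom, 1.0), 0.5)
    return IdentificationSurface(p, rep=rep, trial=model.trial_counter)


def influence(surface: IdentificationSurface) -> InfluenceSummary:
    """Auditory and visual influence from the surface's corner cells."""
    c = surface.corners
    a_inf = ((c["AdVb"] - c["AbVb"]) + (c["AdVd"] - c["AbVd"])) / 2.0
    v_inf = ((c["AbVd"] - c["AbVb"]) + (c["AdVd"] - c["AdVb"])) / 2.0
    return InfluenceSummary(A_influence=a_inf, V_influence=v_inf, **c)


def congruent_accuracy(surface: IdentificationSurface) -> float:
    """Mean P(correct) over the two congruent corner stimuli.

    At (auditory 1, visual 1) the generating category is /b/, so the
    correct-response probability is 1 - P(non-/b/); at (9, 9) it is
    P(non-/b/).
    """
    p = surface.proportions
    return float(((1.0 - p[0, 0]) + p[-1, -1]) / 2.0)


def _cue_one_category_flags(model: AVModel) -> dict:
    """Per-cue flag: do both prototypes map to one cue-level component?"""
    protos = model.contrast.mean_matrix
    flags = {}
    for i, cue in enumerate(CUES):
        m = model.cue_mixtures[cue]
        ja = int(np.argmax(_component_densities(protos[0, i], m)))
        jb = int(np.argmax(_component_densities(protos[1, i], m)))
        flags[cue] = ja == jb
    return flags


def evaluate_rep(model: AVModel, grid: TestGrid | None = None,
                 rep: int = -1, weights: CueWeights | None = None) -> RepReport:
    """Full per-replication report at the model's current trial count."""
    if grid is None:
        grid = build_test_grid(model.contrast)
    ia, ib = map_prototypes(model)
    thresh = 1.0 / model.integrated.K
    conv = ConvergenceReport(
        rep=rep, trial=model.trial_counter,
        proto_component_a=ia, proto_component_b=ib,
        converged=ia != ib,
        n_above_threshold=int((model.integrated.phi > thresh).sum()),
        one_category_cues=_cue_one_category_flags(model))
    surf = identification_surface(model, grid, (ia, ib), rep=rep)
    if weights is None:
        weights = model.weights()
    return RepReport(convergence=conv, weights=weights, surface=surf,
                     influence=influence(surf),
                     congruent_accuracy=congruent_accuracy(surf))


# ---------------------------------------------------------------------------
# Aggregation across replications


def aggregate(reports: list[RepReport]) -> dict:
    """Summaries across replications at one test time.

    Identification, influence and accuracy aggregates are computed both
    over all replications and over converged ones only (the inclusion
    rule used for the headline congruency numbers); convergence counts
    always cover all replications.
    """
    if not reports:
        raise ValueError("aggregate requires at least one replication report")
    trial = reports[0].convergence.trial
    conv_mask = np.array([r.convergence.converged for r in reports])
    weights = np.stack([r.weights.normalized for r in reports])
    surfaces = np.stack([r.surface.proportions for r in reports])
    a_inf = np.array([r.influence.A_influence for r in reports])
    v_inf = np.array([r.influence.V_influence for r in reports])
    acc = np.array([r.congruent_accuracy for r in reports])

    def stats(arr, mask):
        sel = arr[mask] if mask is not None else arr
        if sel.size == 0:
            return {"mean": None, "sd": None}
        return {"mean": np.mean(sel, axis=0).tolist(),
                "sd": np.std(sel, axis=0, ddof=0).tolist()}

    out = {
        "trial": trial,
        "n_reps": len(reports),
        "n_converged": int(conv_mask.sum()),
        "convergence_pct": 100.0 * conv_mask.mean(),
        "cues": list(CUES),
        "weights_all": stats(weights, None),
        "weights_converged": stats(weights, conv_mask),
        "A_influence_all": stats(a_inf, None),
        "V_influence_all": stats(v_inf, None),
        "A_influence_converged": stats(a_inf, conv_mask),
        "V_influence_converged": stats(v_inf, conv_mask),
        "congruent_accuracy_pct_all": stats(100.0 * acc, None),
        "congruent_accuracy_pct_converged": stats(100.0 * acc, conv_mask),
        "mean_surface_all": surfaces.mean(0).tolist(),
        "mean_surface_converged": (surfaces[conv_mask].mean(0).tolist()
                                   if conv_mask.any() else None),
    }
    return out


def evaluate_result(result: BatchResult, grid: TestGrid | None = None):
    """Evaluate every replication at every checkpoint of a batch run.

    Returns ``(reports, summaries)``: ``reports[trial]`` is the list of
    per-rep :class:`RepReport` and ``summaries[trial]`` the aggregate
    dict.
    """
    if grid is None:
        grid = build_test_grid(result.contrast)
    reports = {}
    summaries = {}
    for trial in result.trials:
        s = result.snapshots[trial]
        per_rep = []
        for p in range(result.n_reps):
            model = result.model(trial, p)
            w = CueWeights(s.weights_raw[p], s.weights_norm[p])
            per_rep.append(evaluate_rep(model, grid, rep=int(result.reps[p]),
                                        weights=w))
        reports[trial] = per_rep
        summaries[trial] = aggregate(per_rep)
    return reports, summaries


# ---------------------------------------------------------------------------
# Tabular exports


def convergence_table(reports: dict) -> pd.DataFrame:
    rows = []
    for trial, reps in reports.items():
        for r in reps:
            c = r.convergence
            row = {"rep": c.rep, "trial": trial, "converged": c.converged,
                   "n_above_threshold": c.n_above_threshold,
                   "proto_component_a": c.proto_component_a,
                   "proto_component_b": c.proto_component_b}
            row.update({f"one_category_{cue}": v
                        for cue, v in c.one_category_cues.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def weights_table(reports: dict) -> pd.DataFrame:
    rows = []
    for trial, reps in reports.items():
        for r in reps:
            for i, cue in enumerate(CUES):
                rows.append({"rep": r.convergence.rep, "trial": trial,
                             "cue": cue, "raw_weight": r.weights.raw[i],
                             "normalized_weight": r.weights.normalized[i]})
    return pd.DataFrame(rows)


def influence_table(reports: dict) -> pd.DataFrame:
    rows = []
    for trial, reps in reports.items():
        for r in reps:
            inf = r.influence
            rows.append({"rep": r.convergence.rep, "trial": trial,
                         "AbVb": inf.AbVb, "AbVd": inf.AbVd,
                         "AdVb": inf.AdVb, "AdVd": inf.AdVd,
                         "A_influence": inf.A_influence,
                         "V_influence": inf.V_influence,
                         "congruent_accuracy": r.congruent_accuracy,
                         "converged": r.convergence.converged})
    return pd.DataFrame(rows)


def surface_table(reports: dict) -> pd.DataFrame:
    rows = []
    for trial, reps in reports.items():
        for r in reps:
            p = r.surface.proportions
            for a in range(p.shape[0]):
                for v in range(p.shape[1]):
                    rows.append({"rep": r.convergence.rep, "trial": trial,
                                 "auditory_step": a + 1, "visual_step": v + 1,
                                 "p_response_b_contrast": p[a, v]})
    return pd.DataFrame(rows)
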