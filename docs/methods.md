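# Methods

## The model

`avwgmm` implements an unsupervised, online model of audiovisual phonetic
category acquisition. A learner observes tokens of two stop-consonant
categories, each token a four-dimensional cue vector: F2 and F3 onset
(acoustic, Hz) and mouth height and mouth width (visual, mm, articulation
ranges). Each cue dimension is represented as a mixture of K = 50
Gaussians; a fifth, *integrated* mixture (also K = 50) represents the
abstract audiovisual category dimension. A mixture component j carries a
location μ_j, spread σ_j > 0 and frequency-of-occurrence weight
φ_j ∈ [0, 1], with Σ_j φ_j = 1 per mixture. K is deliberately far larger
than the true category count: the learner must discover how many
categories a dimension has by pruning, not be told.

On each trial, with token x:

1. **Cue-level learning.** Each cue mixture takes a stochastic gradient
   step on the token log-likelihood log M(x) = log Σ_j G_j(x), where
   G_j(x) = φ_j N(x; μ_j, σ_j). All components receive their μ and σ
   steps (scaled by per-mixture learning rates η_μ, η_σ); the φ step is
   winner-take-all: only one component adds its Δφ_j = η_φ (G_j/M)(1/φ_j),
   after which φ is renormalized to sum to one. The winner is the
   component with the highest posterior G_j(x)/M(x) (see "Winner
   selection" below).
2. **Normalization.** Each cue's central tendency c = Σ μ_j φ_j / Σ φ_j
   and variability v = Σ φ_j((μ_j − c)² + σ_j²)/Σ φ_j are recomputed from
   the just-updated mixture, and the token is mapped to a z-score-like
   value z = sign·(x − c)/√v. The orientation sign (fixed per cue from
   the generating prototypes) makes lower normalized values point toward
   /b/ on every dimension. A compressive transform
   x_norm = sign(z)·|z|^t / s (defaults t = 0.9, s = 2.5) then damps
   extreme tokens.
3. **Weighting by reliability.** Each cue's raw weight is the
   category-structured reliability
   w = ½ Σ_m Σ_n φ_m φ_n (μ_m − μ_n)²/(σ_m σ_n),
   which rewards dimensions whose components are far apart relative to
   their spreads — the opposite of the classic 1/σ² rule, which would
   penalize exactly the between-category spread that makes a phonetic cue
   informative. Raw weights are normalized to sum to one; the integrated
   input is the weighted sum of the four normalized cue values.
4. **Integrated learning.** The integrated mixture takes the same kind of
   gradient step on that scalar input.

### Evaluation

A replication has *converged* at a test time if the two all-cue category
prototypes map (by highest integrated-mixture posterior) onto distinct
components; mapping both onto one component is overgeneralization.
Identification responses use the Luce choice rule on the two
prototype-mapped components, P(/d/ | x) = G_d(x)/(G_b(x) + G_d(x)),
evaluated over a 9 × 9 grid of audiovisual stimuli (auditory steps move
F2/F3 jointly, visual steps move MH/MW jointly; per cue, step 3 is the
/b/ prototype mean, step 7 the contrasting mean, steps spaced by a
quarter of the prototype difference). Auditory and visual influence are
corner-cell contrasts of that surface,

    A = ((AdVb − AbVb) + (AdVd − AbVd)) / 2
    V = ((AbVd − AbVb) + (AdVd − AdVb)) / 2,

and congruent accuracy is the mean probability assigned to the generating
category at the two congruent corners. Influence and accuracy aggregates
are reported over converged replications (overgeneralized runs have no
two-category response to measure); convergence percentages always cover
all replications. Unfiltered aggregates are emitted alongside.

## Parameters

| Parameter | Default | Units | Notes |
|---|---|---|---|
| K | 50 | — | components per mixture, all five mixtures |
| η_μ, η_σ, η_φ (MW, MH) | 0.009, 0.008, 0.00005 | mm-scaled | visual φ rate is 10× slower than auditory — part of the model |
| η_μ, η_σ, η_φ (F2) | 40, 20, 0.0005 | Hz-scaled | |
| η_μ, η_σ, η_φ (F3) | 80, 40, 0.0005 | Hz-scaled | |
| η_μ, η_σ, η_φ (integrated) | 1e-5, 1e-5, 0.0005 | normalized units | |
| t, s | 0.9, 2.5 | — | compressive scaling; t = s = 1 disables it |
| cue init μ spread | 3 (visual), 250 (F2), 350 (F3) | cue units | locations ~ N(prototype midpoint, spread) |
| cue init σ | mean of the two prototype SDs | cue units | |
| init φ | 1/K | — | |
| integrated init | μ ~ N(0, 0.75), σ = 0.14, φ = 1/K | normalized units | see below |
| φ floor, σ floor | 1e-6, 1e-3 | —, cue units | numerical guards (below) |
| n_trials, test times | 150,000; {100, 1k, 10k, 100k, 150k} | trials | |
| replications | 500 (main), 100 (variants) | — | |

Category statistics (means and SDs of the four cues for /b/, /d/, /ɡ/,
measured from the AVOZES Australian English corpus) ship as built-in
constants and parameterize both the token sampler and the test grid.

## Design choices on genuinely open points

**Winner selection.** The φ gradient of the mixture log-likelihood is
Δφ_j ∝ (G_j/M)(1/φ_j) = N_j/M, in which φ cancels: selecting the winner
by "largest Δφ" literally means the best-fitting component *shape* wins
regardless of how often it has won before. Under that rule no component
is ever starved, mixtures retain many active components indefinitely, and
the model loses its defining behaviour — discovering the category count
by pruning. We therefore select the winner by highest posterior
G_j(x)/M(x), the rule used by this model family's predecessors for
competitive category learning: because the posterior carries φ, winning
raises a component's future chance of winning, and unneeded components
are driven to the φ floor. Both rules are implemented
(`TrainingConfig.winner_rule`); a unit test demonstrates that only the
posterior rule prunes a K = 20 mixture trained on a two-Gaussian source
down to two survivors. Note the *update applied* to the winner is the
unchanged Δφ_j above in both cases.

**Integrated-mixture initialization.** The normalized-input space has no
published starting state. We initialize locations ~ N(0, 0.75) and
σ = 0.14: the spread covers the range the compressive transform can
produce, and σ is of the order of the within-category spread of the
integrated input, so that the prototype-posterior mapping is
density-driven rather than φ-driven from the start. These two constants
are the one place where the model was calibrated against the study-level
outcomes the package is meant to reproduce (early congruent accuracy and
the child-stage influence values); they are configurable, and the
reproduction harness documents their effect. A structural tension is
worth recording: with a single integrated σ scale, near-ceiling congruent
accuracy and strongly graded incongruent responses at the *same* early
test time constrain σ from opposite sides (the congruent and incongruent
integrated inputs differ only by a fixed geometric factor of ≈ 2.5), so
the defaults are a compromise between the two.

**Equation renderings.** The variability expression is implemented as the
mixture variance Σ φ_j((μ_j − c)² + σ_j²)/Σ φ_j (law of total variance);
the source rendering drops an operator, and the alternative reading
(μ_j·c²) is dimensionally incoherent. Its square root is the z divisor,
making the normalized value "z-score-like". The scaling expression is
implemented as sign(z)|z|^t/s — the operator placement is ambiguous in
the source, and this form is the sign-preserving compressive map the
text describes; it is exposed as a pluggable transform
(`NormalizationState.transform`) for sensitivity analysis.

**Update order.** Cue-level updates → normalization refresh → weight
recomputation → integrated update, every trial. The alternative
(weighting with pre-update cue mixtures) differs by one trial's drift and
was not observed to matter at the scales tested.

**Checkpointing.** The five test times are snapshots of one continuous
run per replication (the developmental-trajectory reading, where a
replication is an individual). `checkpoint_mode="independent"` instead
re-seeds a fresh run per duration.

## Numerical choices

- **Floors.** φ ≥ 1e-6 and σ ≥ 1e-3 (cue units) prevent blow-ups in the
  1/φ and σ⁻³ gradient terms. Floors are applied before φ
  renormalization, so a φ exactly at the floor may end negligibly below
  it after division; tests allow 1% slack at the floor.
- **Ties and underflow.** Winner ties break to the lowest component
  index. If every component density underflows to zero (possible only
  for astronomically outlying inputs), responsibilities fall back to
  uniform over above-floor components.
- **Reliability metric in O(K).** The pairwise double sum is evaluated
  through its moment expansion (Σa·Σd − (Σb)² with a = φ/σ, b = aμ,
  d = aμ²), clipped at zero against cancellation round-off; an O(K²)
  reference implementation backs the property tests.
- **Backends.** Full-scale runs execute a numba-compiled kernel looping
  replications × trials; a pure-numpy batch path and a per-trial
  reference implementation compute the same procedure. All backends
  consume identical token streams (chunked draws of 4096 tokens from a
  per-replication PCG64 stream keyed by `(base_seed, rep)`), so a
  replication is bit-reproducible within a backend and agrees across
  backends to ~1e-9 relative (libm differences accumulate over 10⁵
  trials). Checkpoint resume replays and discards the consumed draws,
  which is exact and avoids serializing RNG state.
- **Matched-initial-weights search.** Under the initialization above, a
  cue's expected initial raw weight is s₀²(K−1)/(K σ̄²) (s₀ the location
  spread, σ̄ the starting σ). The variant bisects each cue's s₀ on this
  monotone curve to a common target (the mean of the default expected
  weights); the equal-start criterion is verified on simulated trial-0
  weights, whose means agree within 0.9 percentage points.

## The synthetic-data generator

Training tokens are drawn category-first (equiprobable by default), then
each cue independently from that category's Normal. This emulates the
statistical structure the model is about — category-conditional cue
distributions with realistic overlap — and deliberately omits much that
real speech has: cue correlations within a token, talker and prosodic
variability, temporal structure, and missing modalities (every token is
fully audiovisual). Sampled values are not truncated, so physically
impossible tails (negative mm) occur at realistic rates; the compressive
transform exists to damp exactly such values, and an optional truncation
bound is available. Passing tests therefore show that the *learning
mechanism* behaves as described on distributionally faithful input — not
that it would survive the additional structure of natural speech.

## Problem sizes

Unit and property tests run at reduced scale (K ≤ 20, ≤ 10⁵ updates).
The study-level checks and the reproduction script run 100 replications
per experiment at the full 150,000 trials — a scale at which the
percentages of interest have Monte-Carlo standard errors of ~1-2 points
(the original used 500 replications for the two main simulations and 100
for the robustness variants).

## Known limitations

- **Mouth width on /b/–/d/.** The MW dimension (similar category means,
  strongly unequal SDs) is reported in the source study to usually
  collapse to one category, ending with a near-zero weight. Our learner
  instead settles reliably on a three-component solution — the narrow /d/
  spike plus the wide /b/ distribution split into two flanking
  components — which is a higher-likelihood description of that mixture
  but inflates MW's pairwise reliability weight (and thereby depresses
  the other cues' normalized weights at the end of training). Winner-only
  (hard) μ/σ updates were tried and rejected: they distort recovered
  means outward on every cue. Which solution family an online learner
  reaches here depends on implementation details below the level the
  source describes.
- **Overgeneralization under perturbation.** The source reports that
  equalizing the φ rates or matching initial weights increases
  end-of-training overgeneralization (93%/89% convergence vs 97.8%).
  Across every initialization we examined, our implementation's
  integrated mixture essentially never overgeneralizes at the end of
  training, so these reductions are not reproduced; the robustness
  variants remain at ceiling. The propensity to collapse late in training
  evidently hinges on the unpublished integrated-mixture starting state.
- The orientation signs are fixed from the generating prototypes, not
  learned; three-way category training is out of scope (the cue set does
  not support a /d/–/ɡ/ distinction); no fitting to individual human
  subjects is attempted.
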