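# Example configuration for `avwgmm run --config`.
# Every key is optional and overrides the corresponding TrainingConfig
# default; omit a key to keep the published value.

# Components per mixture (all five mixtures). The learner must discover
# how many of these it actually needs.
K: 50

# Online training length and the developmental test times (trials at
# which the model is snapshotted and evaluated).
n_trials: 150000
checkpoints: [100, 1000, 10000, 100000, 150000]

# Replications (independent simulated learners) and the master seed.
# Each replication draws its own RNG stream from (base_seed, rep).
n_reps: 100
base_seed: 1

# Spread (SD, in cue units) of the random initial component locations,
# centered on the midpoint of the two prototype means.
init_mu_spread:
  MH: 3.0     # mm
  MW: 3.0     # mm
  F2: 250.0   # Hz
  F3: 350.0   # Hz

# Integrated-mixture starting state, in normalized-input units.
integrated_init_mu_spread: 0.75
integrated_init_sigma: 0.14

# Compressive input scaling: x_norm = sign(z) |z|^t / s.
# Set both to 1 to disable (the "no scaling" robustness variant).
t: 0.9
s: 2.5

# Numerical guards: components are never removed, only driven toward the
# phi floor; sigma is floored in each mixture's own cue units.
phi_floor: 1.0e-6
sigma_floor: 1.0e-3

# Winner-take-all competition rule for the phi update: "posterior"
# (rich-get-richer; prunes unneeded components) or "dphi" (largest phi
# gradient; kept for sensitivity analysis — does not prune).
winner_rule: posterior

# "continuous": the test times are snapshots of one continuous run per
# replication. "independent": a separately seeded run per test time.
checkpoint_mode: continuous

# Optional: clip sampled tokens at +/- this many SDs (unset = no
# truncation; extreme draws are damped by the t/s scaling instead).
# truncate_at: 3.0
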