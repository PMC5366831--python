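"""The three robustness variants of the /b/-/d/ simulation.

Compares final-checkpoint convergence (fraction of learners keeping
distinct integrated categories for the two prototypes) between the
default configuration and the three perturbations: no input scaling
(t = s = 1), equal phi learning rates for all cues, and initial location
spreads matched so all cues start with equal expected weights.
"""

from avwgmm import TrainingConfig
from avwgmm.batch import train_replications
from avwgmm.data import avozes_defaults
from avwgmm.evaluation import evaluate_result
from avwgmm.experiments import experiment_config, simulated_initial_weights

N_REPS = 20  # increase toward 100+ for stable percentages

for name in ("sim1", "no_scaling", "equal_rates", "matched_init"):
    contrast, config = experiment_config(
        name, TrainingConfig(n_reps=N_REPS, base_seed=42))
    result = train_replications(contrast, config)
    _, summaries = evaluate_result(result)
    final = max(result.trials)
    print(f"{name:>13}: convergence at trial {final} = "
          f"{summaries[final]['convergence_pct']:.0f}%")

matched = experiment_config("matched_init")[1]
w = simulated_initial_weights(avozes_defaults("bd"), matched)
print("\nmatched-init simulated starting weights:",
      ", ".join(f"{x:.3f}" for x in w))
print("(all four cues now start within a percentage point of each other,")
print("removing the default configuration's initial auditory advantage)")
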