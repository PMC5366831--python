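"""Identification responses over the 9 x 9 audiovisual test grid.

Trains one learner, builds the 81-stimulus continuum (auditory steps move
F2/F3 jointly, visual steps move mouth height/width jointly; steps 3 and
7 sit at the /b/ and /d/ prototypes), and prints the Luce-choice
probability of a /d/ response at each grid cell.
"""

import numpy as np

from avwgmm import (TrainingConfig, avozes_defaults, build_test_grid,
                    identification_surface, train_replications)

contrast = avozes_defaults("bd")
config = TrainingConfig(n_trials=50_000, checkpoints=(50_000,), n_reps=1,
                        base_seed=11)
model = train_replications(contrast, config).model(50_000, 0)

surface = identification_surface(model, build_test_grid(contrast))
print("P(/d/ response); rows = auditory step 1..9, cols = visual step 1..9")
for a in range(9):
    row = " ".join(f"{p:5.2f}" for p in surface.proportions[a])
    print(f"  aud {a + 1}: {row}")
print("\nThe lower-left corner (both cues /b/-like) should be near 0 and the")
print("upper-right corner near 1; how steeply the surface turns along each")
print("axis shows how much that modality drives this learner's decisions.")
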