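"""Simulate the ENN and benchmark it against lesioned controls.

Builds the full empirically-estimated network on a 24-subject synthetic
cohort, simulates 960 counterbalanced pseudo-trials per subject into
predicted motor prototypes, and decodes them against held-out subjects'
actual motor patterns - for the intact model and for the context-lesioned
control whose context-to-hidden connections are zeroed.
"""

import numpy as np

from ennflow import enn, evaluation, synth

brain = synth.build_ground_truth(seed=0)
cohort = synth.generate_cohort(24, brain, seed=1)
actual = np.stack([s.actual_motor_betas for s in cohort.subjects])

base = enn.build_enn(cohort)
for variant in ("full", "context_lesion"):
    model = enn.build_enn_variant(variant, cohort, base=base)
    predicted = evaluation.cohort_prototypes(model, cohort, seed=2)
    for hand in ("left", "right"):
        accs = evaluation.cross_subject_decode(
            predicted, actual, model.layers, hand=hand, n_reps=100, seed=3
        )
        print(f"{variant:<16} {hand:<6} hand: mean accuracy "
              f"{100 * accs.mean():.2f}%")

print("\nThe intact model transforms rule + stimulus activations into the"
      "\ncorrect response patterns.  Zeroing the context connections makes the"
      "\nsame-hand prototypes identical (inputs are counterbalanced), so the"
      "\ntie-breaking decoder scores exactly 50.00% - structural chance.")
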