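"""The C-PRO task paradigm: contexts, solver, counterbalanced pseudo-trials.

Enumerates the 64 task contexts and 256 stimulus sets, solves a few trials,
and draws the standard 960-pseudo-trial counterbalanced sample.
"""

from collections import Counter

from ennflow import task

contexts = task.enumerate_contexts()
stimuli = task.enumerate_stimulus_sets()
print(f"{len(contexts)} task contexts x {len(stimuli)} stimulus sets "
      f"= {len(contexts) * len(stimuli)} unique trial types")

ctx = contexts[0]
print(f"\nExample context: logic={ctx.logic_rule.name}, "
      f"sensory={ctx.sensory_rule.name}, motor={ctx.motor_rule.name}")
for si in (0, 64):
    stim = stimuli[si]
    outcome = task.evaluate_statement(ctx, stim)
    resp = task.solve_trial(ctx, stim)
    print(f"  color pair {stim.pair_labels('color')} -> statement "
          f"{'TRUE' if outcome else 'FALSE'} -> press {resp.value}")

trials = task.sample_counterbalanced_pseudo_trials(n_per_context=15, seed=0)
counts = Counter(t.correct_response.value for t in trials)
print(f"\n{len(trials)} counterbalanced pseudo-trials; per response: "
      f"{dict(sorted(counts.items()))}")
print("Each response is correct exactly 240 times, and every response sees the"
      "\nsame multiset of stimulus conditions - any decodable difference between"
      "\npredicted response patterns must come from the model, not the inputs.")
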