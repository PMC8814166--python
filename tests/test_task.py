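"""The task paradigm: enumeration, solver, encoding, counterbalanced sampling."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ennflow import task

CONTEXTS = task.enumerate_contexts()
STIMULI = task.enumerate_stimulus_sets()


class TestEnumeration:
    def test_cardinalities(self):
        assert len(CONTEXTS) == 64
        assert len(STIMULI) == 256
        assert len(CONTEXTS) * len(STIMULI) == 16384

    def test_contexts_distinct_and_canonical(self):
        assert len(set(CONTEXTS)) == 64
        first = CONTEXTS[0]
        assert (
            first.logic_rule.name,
            first.sensory_rule.name,
            first.motor_rule.name,
        ) == ("both", "red", "left_middle")
        assert [c.context_id for c in CONTEXTS] == list(range(64))

    def test_stimulus_sets_distinct(self):
        assert len(set(STIMULI)) == 256

    def test_each_response_correct_in_quarter_of_trial_types(self):
        table = task.response_table()
        assert np.bincount(table.ravel()).tolist() == [4096] * 4


class TestSolver:
    @pytest.mark.parametrize(
        "logic, pair, expected",
        [
            ("both", (0, 0), True),
            ("both", (0, 1), False),
            ("not_both", (0, 0), False),
            ("not_both", (1, 1), True),
            ("either", (0, 1), True),
            ("either", (1, 1), False),
            ("neither", (1, 1), True),
            ("neither", (0, 1), False),
        ],
    )
    def test_statement_truth_table(self, logic, pair, expected):
        ctx = task.TaskContext(
            next(r for r in task.LOGIC_RULES if r.name == logic),
            task.SENSORY_RULES[0],  # "red" -> color dimension
            task.MOTOR_RULES[0],
        )
        pair_idx = task.PAIR_CONDITIONS.index(pair)
        stim = task.StimulusSet((pair_idx, 0, 0, 0))
        assert task.evaluate_statement(ctx, stim) is expected

    def test_both_red_true_for_quarter_of_stimuli(self):
        ctx = CONTEXTS[0]  # (both, red, left_middle)
        n_true = sum(task.evaluate_statement(ctx, s) for s in STIMULI)
        assert n_true == 64

    def test_false_case_maps_to_sibling_finger(self):
        ctx = CONTEXTS[0]
        true_stim = task.StimulusSet((0, 0, 0, 0))  # red-red
        false_stim = task.StimulusSet((1, 0, 0, 0))  # red-blue
        assert task.solve_trial(ctx, true_stim) is task.MotorResponse.LEFT_MIDDLE
        assert task.solve_trial(ctx, false_stim) is task.MotorResponse.LEFT_INDEX

    def test_solver_symmetry_under_sibling_motor_rule(self):
        """Swapping the motor rule for its same-hand sibling swaps the response."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            ctx = CONTEXTS[rng.integers(64)]
            stim = STIMULI[rng.integers(256)]
            sibling = next(
                r
                for r in task.MOTOR_RULES
                if r.name == task.MotorResponse(ctx.motor_rule.name).sibling.value
            )
            swapped = task.TaskContext(ctx.logic_rule, ctx.sensory_rule, sibling)
            assert (
                task.solve_trial(swapped, stim)
                is task.solve_trial(ctx, stim).sibling
            )


class TestEncoding:
    def test_full_trial_has_seven_active_units(self):
        vec = task.encode_trial(CONTEXTS[17], STIMULI[133])
        assert vec.shape == (28,)
        assert set(np.unique(vec)) <= {0.0, 1.0}
        assert vec.sum() == 7

    def test_context_only_has_three_active_units(self):
        assert task.encode_trial(CONTEXTS[5]).sum() == 3

    def test_encoding_injective_over_all_trial_types(self):
        seen = {
            task.encode_trial(c, s).tobytes() for c in CONTEXTS for s in STIMULI
        }
        assert len(seen) == 16384

    @given(ci=st.integers(0, 63), si=st.integers(0, 255))
    @settings(max_examples=50, deadline=None)
    def test_encoding_marks_exactly_the_trial_units(self, ci, si):
        ctx, stim = CONTEXTS[ci], STIMULI[si]
        vec = task.encode_trial(ctx, stim)
        expected = {r.unit_index for r in ctx.rules} | set(stim.unit_indices)
        assert set(np.flatnonzero(vec)) == expected


class TestCounterbalancedSampler:
    def test_default_sampling_counts(self):
        trials = task.sample_counterbalanced_pseudo_trials(15, seed=42)
        assert len(trials) == 960
        per_resp = Counter(t.correct_response for t in trials)
        assert set(per_resp.values()) == {240}
        per_ctx = Counter(t.context.context_id for t in trials)
        assert set(per_ctx.values()) == {15}

    def test_stimulus_multisets_identical_across_responses(self):
        trials = task.sample_counterbalanced_pseudo_trials(15, seed=7)
        ms = {r: Counter() for r in task.MotorResponse}
        for t in trials:
            ms[t.correct_response][t.stimulus.pair_indices] += 1
        ref = ms[task.MotorResponse.LEFT_MIDDLE]
        assert all(m == ref for m in ms.values())

    def test_correct_response_matches_solver(self):
        trials = task.sample_counterbalanced_pseudo_trials(3, seed=3)
        for t in trials[::17]:
            assert t.correct_response is task.solve_trial(t.context, t.stimulus)

    def test_deterministic_given_seed(self):
        a = task.sample_counterbalanced_pseudo_trials(15, seed=5)
        b = task.sample_counterbalanced_pseudo_trials(15, seed=5)
        assert a == b
        c = task.sample_counterbalanced_pseudo_trials(15, seed=6)
        assert a != c

    def test_strict_mode_equalizes_truth_counts(self):
        trials = task.sample_counterbalanced_pseudo_trials(4, seed=1, mode="strict")
        assert len(trials) == 256
        truths = Counter(
            (t.context.logic_rule.name, task.evaluate_statement(t.context, t.stimulus))
            for t in trials
        )
        for logic in task.LOGIC_RULE_NAMES:
            # per logic rule: 4 sensory x 4 motor cells x 4 trials, half TRUE
            assert truths[(logic, True)] == truths[(logic, False)] == 32

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            task.sample_counterbalanced_pseudo_trials(0, seed=0)
        with pytest.raises(ValueError):
            task.sample_counterbalanced_pseudo_trials(15, seed=0, mode="strict")
        with pytest.raises(ValueError):
            task.sample_counterbalanced_pseudo_trials(15, seed=0, mode="nope")

    def test_tsv_frame_columns(self):
        trials = task.sample_counterbalanced_pseudo_trials(1, seed=0)
        df = task.pseudo_trials_to_frame(trials)
        assert list(df.columns) == [
            "context_id", "logic", "sensory", "motor",
            "color", "orientation", "pitch", "continuity", "correct_response",
        ]
        assert len(df) == 64
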