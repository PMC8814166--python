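"""ENN composition, forward propagation, prototypes, and lesion variants."""

import numpy as np
import pytest

from ennflow import enn, task
from ennflow.connectivity import VertexWeightMap
from ennflow.synth import LayerAssignment


def toy_model(nonlinearity="relu", variant="full"):
    """2-vertex layers with hand-set weights for manual arithmetic."""
    layers = LayerAssignment(
        context=np.array([0, 1]),
        stimulus=np.array([2, 3]),
        hidden=np.array([4, 5]),
        motor_left=np.array([6]),
        motor_right=np.array([7]),
    )
    w_c2h = VertexWeightMap(W=np.array([[1.0, 0.0], [0.0, -1.0]]))
    w_s2h = VertexWeightMap(W=np.array([[0.5, 0.5], [-0.5, 0.5]]))
    w_h2m = VertexWeightMap(W=np.array([[1.0, 2.0], [3.0, -1.0]]))
    return enn.EnnModel(
        layers=layers, w_c2h=w_c2h, w_s2h=w_s2h, w_h2m=w_h2m,
        nonlinearity=nonlinearity, variant=variant,
    )


@pytest.fixture(scope="module")
def full_model(cohort24):
    return enn.build_enn(cohort24)


class TestCompose:
    def test_identical_rule_patterns_average_to_themselves(self):
        betas = np.tile([1.0, 2.0, 3.0], (12, 1))
        ctx = task.enumerate_contexts()[10]
        assert np.allclose(enn.compose_context_pattern(betas, ctx), [1, 2, 3])

    def test_context_mean_is_order_invariant_and_manual(self):
        betas = np.zeros((12, 3))
        ctx = task.enumerate_contexts()[0]  # rules at units 0, 4, 8
        betas[0] = [3.0, 0.0, 0.0]
        betas[4] = [0.0, 6.0, 0.0]
        betas[8] = [0.0, 0.0, 9.0]
        assert np.allclose(enn.compose_context_pattern(betas, ctx), [1, 2, 3])

    def test_stimulus_pattern_selects_relevant_dimension_row(self):
        betas = np.arange(16 * 4, dtype=float).reshape(16, 4)
        ctx = task.enumerate_contexts()[0]  # sensory "red" -> color, dim 0
        stim = task.StimulusSet((2, 3, 1, 0))
        got = enn.compose_stimulus_pattern(betas, ctx, stim)
        assert np.array_equal(got, betas[2])  # color pair index 2

    def test_same_sensory_rule_same_stimulus_same_pattern(self):
        rng = np.random.default_rng(0)
        betas = rng.normal(size=(16, 6))
        contexts = task.enumerate_contexts()
        a = next(c for c in contexts if c.sensory_rule.name == "high_pitch")
        b = next(
            c for c in contexts
            if c.sensory_rule.name == "high_pitch" and c is not a
        )
        stim = task.enumerate_stimulus_sets()[77]
        assert np.array_equal(
            enn.compose_stimulus_pattern(betas, a, stim),
            enn.compose_stimulus_pattern(betas, b, stim),
        )

    def test_wrong_row_counts_raise(self):
        ctx = task.enumerate_contexts()[0]
        with pytest.raises(ValueError):
            enn.compose_context_pattern(np.zeros((11, 3)), ctx)
        with pytest.raises(ValueError):
            enn.compose_stimulus_pattern(
                np.zeros((15, 3)), ctx, task.enumerate_stimulus_sets()[0]
            )


class TestForward:
    def test_zero_inputs_zero_output(self):
        m = toy_model()
        assert np.allclose(enn.enn_forward(m, np.zeros(2), np.zeros(2)), 0.0)

    def test_all_negative_preactivations_give_zero_under_relu(self):
        m = toy_model()
        # ctx (0,1): pre = (0*1+1*0, 0*0+1*-1) = (0,-1); stim (0,1): (-0.5, 0.5)
        # combined (-0.5, -0.5) -> relu -> 0
        out = enn.enn_forward(m, np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert np.allclose(out, 0.0)

    def test_manual_arithmetic_with_and_without_relu(self):
        x_c, x_s = np.array([1.0, 1.0]), np.array([1.0, 0.0])
        # pre = (1, -1) + (0.5, 0.5) = (1.5, -0.5)
        m = toy_model("relu")
        # relu -> (1.5, 0); out = (1.5*1, 1.5*2) = (1.5, 3.0)
        assert np.allclose(enn.enn_forward(m, x_c, x_s), [1.5, 3.0])
        m2 = toy_model("none", variant="no_relu")
        # linear -> (1.5, -0.5); out = (1.5-1.5, 3+0.5) = (0.0, 3.5)
        assert np.allclose(enn.enn_forward(m2, x_c, x_s), [0.0, 3.5])

    def test_linear_variant_is_additive(self):
        m = toy_model("none", variant="no_relu")
        rng = np.random.default_rng(1)
        a_c, a_s = rng.normal(size=2), rng.normal(size=2)
        b_c, b_s = rng.normal(size=2), rng.normal(size=2)
        lhs = enn.enn_forward(m, a_c + b_c, a_s + b_s)
        rhs = enn.enn_forward(m, a_c, a_s) + enn.enn_forward(m, b_c, b_s)
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_relu_breaks_additivity(self):
        m = toy_model("relu")
        a_c, a_s = np.array([1.0, 1.0]), np.array([1.0, 0.0])
        b_c, b_s = np.array([0.0, 1.0]), np.array([0.0, 1.0])
        lhs = enn.enn_forward(m, a_c + b_c, a_s + b_s)
        rhs = enn.enn_forward(m, a_c, a_s) + enn.enn_forward(m, b_c, b_s)
        assert not np.allclose(lhs, rhs)


class TestPrototypes:
    def test_prototypes_average_240_trials_each(self, cohort24, full_model):
        trials = task.sample_counterbalanced_pseudo_trials(15, seed=1)
        p = enn.simulate_predicted_prototypes(
            full_model, cohort24.subjects[0], trials
        )
        assert p.patterns.shape == (4, len(full_model.layers.motor))
        assert p.n_trials_per_response == 240

    def test_context_lesion_same_hand_prototypes_identical(self, cohort24, full_model):
        les = enn.build_enn_variant("context_lesion", cohort24, base=full_model)
        trials = task.sample_counterbalanced_pseudo_trials(15, seed=2)
        p = enn.simulate_predicted_prototypes(les, cohort24.subjects[1], trials)
        assert np.array_equal(p.patterns[0], p.patterns[1])
        assert np.array_equal(p.patterns[2], p.patterns[3])

    def test_ground_truth_maps_recover_correct_prototypes(self, brain):
        """Noise-free subject + true weights: each prototype is nearest its own
        actual response template."""
        from ennflow import synth as synth_mod
        from ennflow.connectivity import VertexWeightMap as VWM

        cfg = synth_mod.GroundTruthConfig(subject_beta_sd=0.0, observation_sd=0.0,
                                          rest_T=5)
        b = synth_mod.build_ground_truth(cfg, seed=51)
        subj = synth_mod.simulate_subject_data(b, 52)
        model = enn.EnnModel(
            layers=b.layer_assignment(),
            w_c2h=VWM(W=b.G_c2h), w_s2h=VWM(W=b.G_s2h), w_h2m=VWM(W=b.G_h2m),
        )
        trials = task.sample_counterbalanced_pseudo_trials(15, seed=53)
        p = enn.simulate_predicted_prototypes(model, subj, trials)
        for k in range(4):
            rs = [np.corrcoef(p.patterns[k], b.actual_motor_group[j])[0, 1]
                  for j in range(4)]
            assert int(np.argmax(rs)) == k

    def test_uncounterbalanced_trials_rejected(self, cohort24, full_model):
        trials = task.sample_counterbalanced_pseudo_trials(2, seed=0)[:100]
        with pytest.raises(ValueError):
            enn.simulate_predicted_prototypes(
                full_model, cohort24.subjects[0], trials
            )


class TestVariants:
    def test_context_lesion_equals_zero_context_forward(self, cohort24, full_model):
        les = enn.build_enn_variant("context_lesion", cohort24, base=full_model)
        rng = np.random.default_rng(0)
        x_c = rng.normal(size=len(full_model.layers.context))
        x_s = rng.normal(size=len(full_model.layers.stimulus))
        lhs = enn.enn_forward(les, x_c, x_s)
        rhs = enn.enn_forward(full_model, np.zeros_like(x_c), x_s)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_no_hidden_variant_is_structurally_direct(self, cohort24):
        m = enn.build_enn_variant("no_hidden", cohort24, n_components=100)
        assert m.w_direct is not None and m.w_c2h is None
        n_in = len(m.layers.context) + len(m.layers.stimulus)
        assert m.w_direct.W.shape == (n_in, len(m.layers.motor))

    def test_shuffled_fc_identity_permutation_equals_full(self, cohort24, full_model):
        ident = (
            np.arange(full_model.w_c2h.W.shape[0]),
            np.arange(full_model.w_s2h.W.shape[0]),
        )
        m = enn.build_enn_variant(
            "shuffled_fc", cohort24, base=full_model, permutations=ident
        )
        assert np.array_equal(m.w_c2h.W, full_model.w_c2h.W)
        assert np.array_equal(m.w_s2h.W, full_model.w_s2h.W)

    def test_shuffled_fc_preserves_weight_multiset(self, cohort24, full_model):
        m = enn.build_enn_variant("shuffled_fc", cohort24, base=full_model, seed=3)
        assert not np.array_equal(m.w_c2h.W, full_model.w_c2h.W)
        assert np.allclose(
            np.sort(m.w_c2h.W, axis=0), np.sort(full_model.w_c2h.W, axis=0)
        )

    def test_random_hidden_size_within_ten_percent(self, cohort24, full_model):
        m = enn.build_enn_variant(
            "random_hidden", cohort24, base=full_model, n_components=100, seed=4
        )
        target = len(full_model.layers.hidden)
        assert 0.9 * target <= len(m.layers.hidden) <= 1.1 * target
        assert m.w_c2h.W.shape[1] == len(m.layers.hidden)

    def test_top_k_variant_uses_given_hidden_vertices(self, cohort24):
        table = cohort24.brain.parcel_table
        hidden = np.concatenate([table[0]["vertices"], table[2]["vertices"]])
        m = enn.build_enn_variant(
            "top_k", cohort24, hidden_vertices=hidden, n_components=100
        )
        assert np.array_equal(m.layers.hidden, hidden)
        assert m.w_c2h.W.shape == (len(m.layers.context), len(hidden))
        # the context parcel overlaps the new hidden layer -> excluded rows
        overlap_rows = np.where(np.isin(m.layers.context, hidden))[0]
        assert np.all(m.w_c2h.W[overlap_rows] == 0)

    def test_unknown_variant_rejected(self, cohort24):
        with pytest.raises(ValueError):
            enn.build_enn_variant("banana", cohort24)
        with pytest.raises(ValueError):
            enn.build_enn_variant("top_k", cohort24)  # needs hidden_vertices
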