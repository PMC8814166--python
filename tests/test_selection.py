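"""Layer identification: decoding maps, motor contrasts, RSMs, hub ranking."""

import numpy as np
import pytest

from ennflow import ann, selection, synth


@pytest.fixture(scope="module")
def betas8(cohort8):
    return np.stack([s.condition_betas for s in cohort8.subjects])


@pytest.fixture(scope="module")
def actual8(cohort8):
    return np.stack([s.actual_motor_betas for s in cohort8.subjects])


class TestSubjectFolds:
    def test_folds_partition_subjects(self):
        rng = np.random.default_rng(0)
        folds = selection.subject_folds(26, 12, rng)
        allv = np.concatenate(folds)
        assert np.array_equal(np.sort(allv), np.arange(26))
        sizes = sorted(len(f) for f in folds)
        assert sizes == [2] * 10 + [3] * 2

    def test_fewer_subjects_than_folds_raises(self):
        with pytest.raises(ValueError):
            selection.subject_folds(3, 4, np.random.default_rng(0))


class TestParcelwiseDecoding:
    def test_color_decoding_flags_true_stimulus_parcel_only(self, cohort8, betas8):
        table = cohort8.brain.parcel_table
        df = selection.parcelwise_decoding(
            betas8[:, 12:16], np.arange(4), table, n_folds=8, seed=0
        )
        by_kind = df.set_index("parcel_id")
        color_parcel = next(
            pid for pid, info in table.items()
            if info["kind"] == "stimulus" and info["name"] == "stimulus_0"
        )
        assert bool(by_kind.loc[color_parcel, "fdr_significant"])
        distractors = [pid for pid, info in table.items()
                       if info["kind"] == "distractor"]
        assert not by_kind.loc[distractors, "fdr_significant"].any()

    def test_rule_decoding_flags_context_parcels(self, cohort8, betas8):
        table = cohort8.brain.parcel_table
        df = selection.parcelwise_decoding(
            betas8[:, :12], np.arange(12), table, n_folds=8, seed=0
        )
        ctx = [pid for pid, info in table.items() if info["kind"] == "context"]
        assert df.set_index("parcel_id").loc[ctx, "fdr_significant"].all()
        assert df.attrs["chance"] == pytest.approx(1 / 12)

    def test_permuted_labels_near_chance(self, cohort8, betas8):
        """Chance calibration: permuted 4-way ~ 25%, permuted 12-way ~ 8.33%."""
        table = {0: cohort8.brain.parcel_table[0]}
        acc4 = [
            selection.parcelwise_decoding(
                betas8[:, 12:16], np.arange(4), table, n_folds=8,
                seed=s, permute_labels=True,
            )["accuracy"].iloc[0]
            for s in range(30)
        ]
        se4 = np.std(acc4, ddof=1) / np.sqrt(len(acc4))
        assert abs(np.mean(acc4) - 0.25) < 3 * max(se4, 1e-3)


class TestMotorContrast:
    def test_zero_noise_contrast_recovers_finger_preference(self):
        """Within the hand's candidate block (the analysis is restricted per
        hand), the signed masks follow the template difference exactly."""
        cfg = synth.GroundTruthConfig(subject_beta_sd=0.0, rest_T=5)
        b = synth.build_ground_truth(cfg, seed=31)
        half = b.config.v_motor // 2
        # paired t on identical rows is undefined; add microscopic jitter
        rng = np.random.default_rng(0)
        actual = np.stack([
            b.actual_motor_group + 1e-9 * rng.normal(size=b.actual_motor_group.shape)
            for _ in range(8)
        ])
        for hand, sl, (mid, idx) in (
            ("left", slice(0, half), (0, 1)),
            ("right", slice(half, None), (2, 3)),
        ):
            idx_mask, mid_mask = selection.motor_univariate_contrast(
                actual[:, :, sl], hand
            )
            diff = b.actual_motor_group[idx, sl] - b.actual_motor_group[mid, sl]
            assert np.array_equal(idx_mask, diff > 0)
            assert np.array_equal(mid_mask, diff < 0)

    def test_swapping_conditions_swaps_masks(self, actual8):
        idx_m, mid_m = selection.motor_univariate_contrast(actual8, "left")
        swapped = actual8[:, [1, 0, 2, 3], :]
        idx_s, mid_s = selection.motor_univariate_contrast(swapped, "left")
        assert np.array_equal(idx_m, mid_s) and np.array_equal(mid_m, idx_s)

    def test_pure_noise_yields_no_stable_detections(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(size=(10, 4, 60))
        idx_m, mid_m = selection.motor_univariate_contrast(noise, "right")
        assert (idx_m.sum() + mid_m.sum()) <= 3  # FDR keeps false positives rare

    def test_unknown_hand_rejected(self, actual8):
        with pytest.raises(ValueError):
            selection.motor_univariate_contrast(actual8, "middle")


class TestBaselineMotorDecoding:
    def test_clean_cohort_decodes_near_perfectly(self, actual8):
        res = selection.baseline_motor_decoding(
            actual8, "left", n_reps=20, n_perm=20, seed=0
        )
        assert res["mean_accuracy"] > 0.9
        assert res["p_value"] < 0.2  # small n_perm bounds p from below

    def test_permuted_null_near_two_way_chance(self, actual8):
        res = selection.baseline_motor_decoding(
            actual8, "right", n_reps=10, n_perm=60, seed=1
        )
        null = res["null"].null_samples
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean() - 0.5) < 4 * se + 0.02

    def test_feature_selection_inside_fold_differs_from_leaky_selection(self):
        """Selecting features on the full data (leak) changes results on noisy
        cohorts - guarding the no-leakage code path."""
        rng = np.random.default_rng(3)
        signal = np.zeros((12, 4, 80))
        signal[:, 1, :3] += 0.8  # weak index-finger signal on 3 vertices
        noisy = signal + rng.normal(size=signal.shape)
        fair = selection.baseline_motor_decoding(
            noisy, "left", n_reps=15, n_perm=5, seed=7, select_within_fold=True
        )
        leaky = selection.baseline_motor_decoding(
            noisy, "left", n_reps=15, n_perm=5, seed=7, select_within_fold=False
        )
        assert not np.allclose(fair["accuracies"], leaky["accuracies"])

    def test_too_few_subjects_raise(self, actual8):
        with pytest.raises(ValueError):
            selection.baseline_motor_decoding(actual8[:5], "left")


class TestParcelRsm:
    def test_identical_condition_patterns_give_unit_rsm(self):
        betas = np.tile(np.linspace(0, 1, 9), (28, 1))
        rsm = selection.parcel_rsm(betas, np.arange(9))
        assert np.allclose(rsm, 1.0)

    def test_orthogonal_patterns_give_near_zero_offdiagonals(self):
        rng = np.random.default_rng(0)
        betas = rng.normal(size=(28, 4000))
        rsm = selection.parcel_rsm(betas, np.arange(4000))
        off = rsm[np.triu_indices(28, 1)]
        assert np.abs(off).max() < 0.1

    def test_tiny_parcel_rejected(self):
        with pytest.raises(ValueError):
            selection.parcel_rsm(np.zeros((28, 5)), np.arange(1))


class TestHubSelection:
    def test_identical_rsm_scores_spearman_one_and_rank_one(self, cohort8):
        rng = np.random.default_rng(4)
        ref = np.corrcoef(rng.normal(size=(28, 40)))
        rsms = {0: ref.copy(), 1: np.corrcoef(rng.normal(size=(28, 40)))}
        table = {0: {"name": "a", "vertices": np.arange(5)},
                 1: {"name": "b", "vertices": np.arange(5, 10)}}
        ranking, hub = selection.select_conjunction_hubs(rsms, ref, table, k=1)
        assert ranking.iloc[0]["parcel_id"] == 0
        assert ranking.iloc[0]["spearman_rho"] == pytest.approx(1.0)
        assert np.array_equal(hub, np.arange(5))

    def test_true_hidden_parcel_ranks_first(self, cohort8, trained_rsm):
        brain = cohort8.brain
        rsms = selection.cohort_parcel_rsms(cohort8)
        ranking, hub = selection.select_conjunction_hubs(
            rsms, trained_rsm, brain.parcel_table, k=1
        )
        assert ranking.iloc[0]["name"] == "hidden_0"
        assert np.array_equal(hub, brain.layer_assignment().hidden)

    def test_shuffled_parameter_null_scores_below_trained(
        self, cohort8, trained_ann, trained_rsm
    ):
        """The weight-shuffle control RSM resembles the conjunction parcel less
        than the trained RSM does."""
        params, _ = trained_ann
        null_rsm = ann.shuffled_parameter_null_rsm(params, n_perm=50, seed=0)
        brain = cohort8.brain
        rsms = selection.cohort_parcel_rsms(cohort8)
        hidden_pid = next(pid for pid, info in brain.parcel_table.items()
                          if info["kind"] == "hidden")
        table = brain.parcel_table
        rank_t, _ = selection.select_conjunction_hubs(
            {hidden_pid: rsms[hidden_pid]}, trained_rsm, table, k=1
        )
        rank_n, _ = selection.select_conjunction_hubs(
            {hidden_pid: rsms[hidden_pid]}, null_rsm, table, k=1
        )
        assert rank_t.iloc[0]["spearman_rho"] > rank_n.iloc[0]["spearman_rho"]

    def test_hub_recovery_degrades_with_beta_noise(self, trained_rsm):
        """Rank of the true hidden parcel worsens (monotonically in rho) as
        subject beta noise grows."""
        rhos = []
        for sd in (0.2, 1.0, 4.0):
            cfg = synth.GroundTruthConfig(subject_beta_sd=sd, rest_T=5)
            b = synth.build_ground_truth(cfg, seed=41)
            cohort = synth.generate_cohort(6, b, seed=42)
            rsms = selection.cohort_parcel_rsms(cohort)
            ranking, _ = selection.select_conjunction_hubs(
                rsms, trained_rsm, b.parcel_table, k=1
            )
            row = ranking[ranking["name"] == "hidden_0"].iloc[0]
            rhos.append(row["spearman_rho"])
        assert rhos[0] > rhos[1] > rhos[2]
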