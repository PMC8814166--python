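"""Layer identification from cohort activation patterns.

Finds where each ENN layer lives: parcels with decodable stimulus or rule
activations (cross-validated MVPA with binomial tests and BH-FDR across
parcels), motor-output vertices from a paired index-vs-middle univariate
contrast per hand, a bootstrap baseline of motor decodability with
within-fold feature selection, and conjunction hubs ranked by the Spearman
similarity between each parcel's 28-condition RSM and the reference
network's hidden-layer RSM (Fisher-z transformed upper triangles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import (
    PermutationNull,
    binomial_pvalue,
    fdr_bh,
    min_distance_classify,
    paired_ttest_contrast,
    permutation_pvalue,
)
from .synth import SyntheticCohort

__all__ = [
    "subject_folds",
    "parcelwise_decoding",
    "motor_univariate_contrast",
    "baseline_motor_decoding",
    "parcel_rsm",
    "cohort_parcel_rsms",
    "select_conjunction_hubs",
]


def subject_folds(
    n_subjects: int, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Partition subjects into n_folds groups: seeded shuffle, then contiguous
    blocks with remainders spread across the first folds."""
    if n_subjects < n_folds:
        raise ValueError("fewer subjects than folds")
    order = rng.permutation(n_subjects)
    sizes = np.full(n_folds, n_subjects // n_folds)
    sizes[: n_subjects % n_folds] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [order[bounds[i] : bounds[i + 1]] for i in range(n_folds)]


def parcelwise_decoding(
    betas: np.ndarray,
    labels: np.ndarray,
    parcels: dict,
    n_folds: int = 12,
    classifier: str = "min_distance",
    alpha: float = 0.05,
    seed: int = 0,
    permute_labels: bool = False,
) -> pd.DataFrame:
    """Group-level cross-validated decoding per parcel.

    ``betas`` is (n_subjects, n_conditions, V_total); ``labels`` gives the class
    of each condition; ``parcels`` maps parcel id -> {"name", "vertices", ...}.
    Folds partition subjects; centroids are trained on training subjects'
    condition patterns and tested on held-out subjects' patterns, accuracies
    pooled over folds.  One-sided binomial p against chance = 1/n_classes,
    BH-FDR across parcels.  ``permute_labels`` shuffles the training labels
    within each fold while leaving test labels intact (chance calibration; a
    joint train+test permutation would merely rename the classes).
    """
    betas = np.asarray(betas)
    labels = np.asarray(labels)
    n_subj, n_cond, _ = betas.shape
    rng = np.random.default_rng(seed)
    n_classes = len(np.unique(labels))
    folds = subject_folds(n_subj, n_folds, rng)
    perm_rng = np.random.default_rng(seed + 10_000_019)

    rows = []
    for pid, info in parcels.items():
        verts = info["vertices"]
        sub = betas[:, :, verts]
        correct = total = 0
        for f in range(n_folds):
            test_subj = folds[f]
            train_subj = np.concatenate([folds[g] for g in range(n_folds) if g != f])
            train_x = sub[train_subj].reshape(-1, len(verts))
            train_y = np.tile(labels, len(train_subj))
            if permute_labels:
                train_y = train_y[perm_rng.permutation(len(train_y))]
            test_x = sub[test_subj].reshape(-1, len(verts))
            test_y = np.tile(labels, len(test_subj))
            pred = min_distance_classify(train_x, train_y, test_x, method=classifier)
            correct += int(np.sum(pred == test_y))
            total += len(test_y)
        acc = correct / total
        rows.append(
            {
                "parcel_id": pid,
                "name": info.get("name", str(pid)),
                "accuracy": acc,
                "p_value": binomial_pvalue(correct, total, 1.0 / n_classes),
                "n_test": total,
            }
        )
    df = pd.DataFrame(rows)
    df["fdr_significant"], df["p_adjusted"] = fdr_bh(df["p_value"].values, alpha)
    df.attrs["chance"] = 1.0 / n_classes
    df.attrs["n_classes"] = n_classes
    return df


def motor_univariate_contrast(
    actual_motor_betas: np.ndarray,
    hand: str,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Index- and middle-preferring vertex masks from a two-sided paired t
    contrast (index - middle) across subjects, BH-FDR over candidate vertices.

    ``actual_motor_betas`` is (n_subjects, 4, V) in canonical response order
    (left_middle, left_index, right_middle, right_index); ``hand`` selects
    which response pair is contrasted.  Returns (index_mask, middle_mask).
    """
    if hand not in ("left", "right"):
        raise ValueError("hand must be 'left' or 'right'")
    mid, idx = (0, 1) if hand == "left" else (2, 3)
    t, p = paired_ttest_contrast(
        actual_motor_betas[:, idx, :], actual_motor_betas[:, mid, :]
    )
    sig, _ = fdr_bh(p, alpha)
    return sig & (t > 0), sig & (t < 0)


def baseline_motor_decoding(
    actual_motor_betas: np.ndarray,
    hand: str,
    n_folds: int = 4,
    n_reps: int = 1000,
    n_perm: int = 1000,
    feature_alpha: float = 0.05,
    seed: int = 0,
    select_within_fold: bool = True,
) -> dict:
    """Bootstrap noise-ceiling of 2-way finger decoding on one hand.

    Four-fold subject cross-validation; within each training fold, feature
    selection keeps vertices whose paired index-vs-middle t-test reaches
    p < ``feature_alpha`` (selection on the full data would leak test
    information; ``select_within_fold=False`` exists only to demonstrate the
    leak).  Training subjects are bootstrap-resampled each repetition.
    Returns accuracies (n_reps), the permutation null, and the averaged p.
    """
    if actual_motor_betas.shape[0] < 2 * n_folds:
        raise ValueError("need at least 2 subjects per fold")
    mid, idx = (0, 1) if hand == "left" else (2, 3)
    pair = actual_motor_betas[:, [mid, idx], :]  # n_subj x 2 x V
    n_subj = pair.shape[0]
    rng = np.random.default_rng(seed)

    def run_cv(flip: np.ndarray | None) -> float:
        folds = subject_folds(n_subj, n_folds, rng)
        correct = total = 0
        for f in range(n_folds):
            test_subj = folds[f]
            train_subj = np.concatenate([folds[g] for g in range(n_folds) if g != f])
            sel_subj = train_subj if select_within_fold else np.arange(n_subj)
            _, p = paired_ttest_contrast(
                pair[sel_subj, 1, :], pair[sel_subj, 0, :]
            )
            feat = np.where(p < feature_alpha)[0]
            if feat.size == 0:
                feat = np.arange(pair.shape[2])
            boot = rng.choice(train_subj, size=len(train_subj), replace=True)
            train_x = pair[boot][:, :, feat].reshape(-1, feat.size)
            train_y = np.tile([0, 1], len(boot))
            if flip is not None:
                fl = flip[boot]
                train_y = np.where(np.repeat(fl, 2), 1 - train_y, train_y)
            test_x = pair[test_subj][:, :, feat].reshape(-1, feat.size)
            test_y = np.tile([0, 1], len(test_subj))
            pred = min_distance_classify(train_x, train_y, test_x)
            correct += int(np.sum(pred == test_y))
            total += len(test_y)
        return correct / total

    accuracies = np.array([run_cv(None) for _ in range(n_reps)])
    null = np.array(
        [run_cv(rng.integers(0, 2, size=n_subj).astype(bool)) for _ in range(n_perm)]
    )
    pnull = PermutationNull(null, n_perm, seed)
    p_values = [permutation_pvalue(a, pnull) for a in accuracies]
    return {
        "accuracies": accuracies,
        "mean_accuracy": float(accuracies.mean()),
        "null": pnull,
        "p_value": float(np.mean(p_values)),
    }


def parcel_rsm(condition_betas: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """28x28 Pearson RSM of condition patterns restricted to a parcel."""
    if len(vertices) < 2:
        raise ValueError("parcel needs at least 2 vertices")
    return np.corrcoef(np.asarray(condition_betas)[:, vertices])


def cohort_parcel_rsms(cohort: SyntheticCohort) -> dict[int, np.ndarray]:
    """Group-mean parcel RSMs: per-subject RSMs averaged across subjects."""
    out: dict[int, np.ndarray] = {}
    for pid, info in cohort.brain.parcel_table.items():
        rsms = [
            parcel_rsm(s.condition_betas, info["vertices"]) for s in cohort.subjects
        ]
        out[pid] = np.mean(rsms, axis=0)
    return out


def _fisher_upper(rsm: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(rsm.shape[0], k=1)
    r = np.clip(rsm[iu], -1 + 1e-7, 1 - 1e-7)
    return np.arctanh(r)


def select_conjunction_hubs(
    parcel_rsms: dict[int, np.ndarray],
    ann_rsm: np.ndarray,
    parcel_table: dict,
    k: int = 10,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Rank parcels by Spearman correlation between Fisher-z upper triangles of
    each parcel's RSM and the reference hidden-layer RSM; the conjunction
    hidden layer is the vertex union of the top-k parcels."""
    ref = _fisher_upper(ann_rsm)
    rows = []
    for pid, rsm in parcel_rsms.items():
        rho, _ = sps.spearmanr(_fisher_upper(rsm), ref)
        rows.append(
            {
                "parcel_id": pid,
                "name": parcel_table[pid].get("name", str(pid)),
                "spearman_rho": float(rho),
            }
        )
    ranking = (
        pd.DataFrame(rows)
        .sort_values("spearman_rho", ascending=False)
        .reset_index(drop=True)
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    top = ranking.head(k)["parcel_id"].tolist()
    hidden = np.concatenate([parcel_table[pid]["vertices"] for pid in top])
    return ranking, np.sort(hidden)
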