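"""Cross-subject decoding of predicted motor prototypes against actual patterns.

The decisive test of an ENN: train a minimum-distance classifier on the
model's predicted motor-response prototypes of the training subjects and
decode the actual (GLM-style) motor-response patterns of held-out subjects,
in a subject-level k-fold scheme (3:1 train:test).  Training subjects are
bootstrap-resampled with replacement each repetition, each drawn subject
contributing one prototype per class; this keeps per-class centroids exactly
identical whenever a lesion makes a subject's class prototypes identical,
so structurally chance-level variants score exactly 50% per hand under the
deterministic tie-break.  Per-hand 2-way decoding restricts to that hand's
two responses and its output vertices; 4-way uses everything.  Significance
comes from label-permutation nulls with +1-corrected p values averaged
across repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import task
from .enn import EnnModel, build_enn, build_enn_variant, simulate_predicted_prototypes
from .stats import PermutationNull, min_distance_classify, permutation_pvalue
from .synth import SyntheticCohort

__all__ = [
    "DecodeOutcome",
    "EvaluationReport",
    "cohort_prototypes",
    "cross_subject_decode",
    "permutation_null_decode",
    "evaluate_model",
    "evaluate_variant_suite",
]

_HAND_CLASSES = {"left": (0, 1), "right": (2, 3)}


@dataclass
class DecodeOutcome:
    hand: str  # "left" | "right" | "all"
    accuracies: np.ndarray  # n_reps
    null: PermutationNull
    p_value: float  # mean over repetitions

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())


@dataclass
class EvaluationReport:
    outcomes: dict  # (variant, hand) -> DecodeOutcome
    family_accuracies: dict = field(default_factory=dict)  # (variant, hand) -> array
    family_percentile: dict = field(default_factory=dict)  # (variant, hand) -> float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (variant, hand), out in self.outcomes.items():
            rows.append(
                {
                    "variant": variant,
                    "hand": hand,
                    "mean_accuracy": out.mean_accuracy,
                    "p_value": out.p_value,
                    "null_mean": float(out.null.null_samples.mean()),
                    "n_reps": len(out.accuracies),
                }
            )
        for (variant, hand), pct in self.family_percentile.items():
            rows.append(
                {
                    "variant": variant,
                    "hand": hand,
                    "mean_accuracy": float(
                        np.mean(self.family_accuracies[(variant, hand)])
                    ),
                    "p_value": np.nan,
                    "null_mean": np.nan,
                    "n_reps": len(self.family_accuracies[(variant, hand)]),
                    "full_model_percentile": pct,
                }
            )
        return pd.DataFrame(rows)


def cohort_prototypes(
    model: EnnModel, cohort: SyntheticCohort, n_per_context: int = 15, seed: int = 0
) -> np.ndarray:
    """Predicted prototypes for every subject (n_subj x 4 x V_motor); each
    subject gets an independently sampled counterbalanced pseudo-trial set."""
    rng = np.random.default_rng(seed)
    protos = []
    for subj in cohort.subjects:
        trials = task.sample_counterbalanced_pseudo_trials(
            n_per_context, seed=int(rng.integers(2**31 - 1))
        )
        protos.append(simulate_predicted_prototypes(model, subj, trials).patterns)
    return np.stack(protos)


def _restrict(patterns: np.ndarray, layers, hand: str) -> tuple[np.ndarray, np.ndarray]:
    """Select the class rows and motor-vertex columns for a hand ('all' keeps both)."""
    motor = layers.motor
    if hand == "all":
        classes = np.arange(4)
        cols = np.arange(len(motor))
    else:
        classes = np.array(_HAND_CLASSES[hand])
        block = layers.motor_left if hand == "left" else layers.motor_right
        cols = np.where(np.isin(motor, block))[0]
    return patterns[:, classes][:, :, cols], classes


def _decode_once(
    pred: np.ndarray,
    actual: np.ndarray,
    folds: list[np.ndarray],
    rng: np.random.Generator,
    permute_labels: bool = False,
) -> float:
    """One k-fold pass: bootstrap training subjects, train on predicted
    prototypes, test on actual patterns.

    ``permute_labels`` shuffles the pooled training-label vector (preserving
    class counts) — the label-permutation null."""
    n_classes = pred.shape[1]
    n_folds = len(folds)
    correct = total = 0
    for f in range(n_folds):
        test_subj = folds[f]
        train_subj = np.concatenate([folds[g] for g in range(n_folds) if g != f])
        boot = rng.choice(train_subj, size=len(train_subj), replace=True)
        train_x = pred[boot].reshape(-1, pred.shape[2])
        train_y = np.tile(np.arange(n_classes), len(boot))
        if permute_labels:
            train_y = train_y[rng.permutation(len(train_y))]
        test_x = actual[test_subj].reshape(-1, actual.shape[2])
        test_y = np.tile(np.arange(n_classes), len(test_subj))
        pred_y = min_distance_classify(train_x, train_y, test_x)
        correct += int(np.sum(pred_y == test_y))
        total += len(test_y)
    return correct / total


def cross_subject_decode(
    predicted: np.ndarray,
    actual: np.ndarray,
    layers,
    hand: str = "left",
    n_folds: int = 4,
    n_reps: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Accuracy distribution (n_reps) of k-fold cross-subject decoding.

    ``predicted`` and ``actual`` are (n_subj, 4, V_motor) in canonical response
    order.  Fold assignment is reshuffled and training subjects are
    bootstrap-resampled every repetition.
    """
    n_subj = predicted.shape[0]
    if n_subj < n_folds:
        raise ValueError("need at least n_folds subjects")
    rng = np.random.default_rng(seed)
    pred_r, _ = _restrict(predicted, layers, hand)
    act_r, _ = _restrict(actual, layers, hand)
    from .selection import subject_folds

    accs = np.empty(n_reps)
    for i in range(n_reps):
        folds = subject_folds(n_subj, n_folds, rng)
        accs[i] = _decode_once(pred_r, act_r, folds, rng)
    return accs


def permutation_null_decode(
    predicted: np.ndarray,
    actual: np.ndarray,
    layers,
    hand: str = "left",
    n_folds: int = 4,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationNull:
    """Null accuracy distribution with training labels permuted per subject."""
    n_subj = predicted.shape[0]
    rng = np.random.default_rng(seed)
    pred_r, _ = _restrict(predicted, layers, hand)
    act_r, _ = _restrict(actual, layers, hand)
    from .selection import subject_folds

    null = np.empty(n_perm)
    for i in range(n_perm):
        folds = subject_folds(n_subj, n_folds, rng)
        null[i] = _decode_once(pred_r, act_r, folds, rng, permute_labels=True)
    return PermutationNull(null, n_perm, seed)


def evaluate_model(
    predicted: np.ndarray,
    actual: np.ndarray,
    layers,
    hands: tuple[str, ...] = ("left", "right", "all"),
    n_folds: int = 4,
    n_reps: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, DecodeOutcome]:
    """Decode + permutation null + averaged p for each hand (and 4-way)."""
    out = {}
    for hi, hand in enumerate(hands):
        accs = cross_subject_decode(
            predicted, actual, layers, hand, n_folds, n_reps, seed=seed + 1000 * hi
        )
        null = permutation_null_decode(
            predicted, actual, layers, hand, n_folds, n_perm, seed=seed + 1000 * hi + 500
        )
        p = float(np.mean([permutation_pvalue(a, null) for a in accs]))
        out[hand] = DecodeOutcome(hand=hand, accuracies=accs, null=null, p_value=p)
    return out


def evaluate_variant_suite(
    cohort: SyntheticCohort,
    layers=None,
    variants: tuple[str, ...] = (
        "full",
        "no_hidden",
        "random_hidden",
        "no_relu",
        "context_lesion",
        "shuffled_fc",
    ),
    hands: tuple[str, ...] = ("left", "right"),
    n_components: int = 500,
    n_per_context: int = 15,
    n_folds: int = 4,
    n_reps: int = 1000,
    n_perm: int = 1000,
    n_family: int = 1000,
    family_reps: int = 20,
    seed: int = 0,
    top_k_hidden: dict | None = None,
) -> EvaluationReport:
    """Run the full decode + null for each variant.

    ``random_hidden`` and ``shuffled_fc`` are 1000-member families by default
    (``n_family``): each member is evaluated with a lighter repetition count
    (``family_reps``) and the report records where the full model's mean
    accuracy falls within the family (percentile).  ``top_k_hidden`` maps a
    variant name like ``"top_10"`` to a hidden-vertex array.  ``layers``
    defaults to the generator's ground-truth assignment; a selected assignment
    may restrict the motor layer to a subset of the true motor vertices.
    """
    gt_motor = cohort.brain.layer_assignment().motor
    if layers is None:
        layers = cohort.brain.layer_assignment()
    if not np.all(np.isin(layers.motor, gt_motor)):
        raise ValueError("selected motor vertices must lie in the motor layer")
    # actual_motor_betas columns follow the ground-truth motor axis
    pos = np.searchsorted(gt_motor, layers.motor)
    actual = np.stack([s.actual_motor_betas for s in cohort.subjects])[:, :, pos]
    base = build_enn(cohort, layers, n_components)
    proto_seed = seed + 7
    full_pred = cohort_prototypes(base, cohort, n_per_context, seed=proto_seed)

    report = EvaluationReport(outcomes={})
    full_means: dict[str, float] = {}
    # families need the full model's mean accuracy; evaluate it first
    ordered = sorted(variants, key=lambda v: v != "full")
    for variant in ordered:
        if variant in ("random_hidden", "shuffled_fc"):
            if not full_means:
                raise ValueError("family variants require 'full' in variants")
            for hand in hands:
                fam = np.empty(n_family)
                for j in range(n_family):
                    member = build_enn_variant(
                        variant, cohort, base=base, layers=layers,
                        n_components=n_components, seed=seed + 31 * j + 1,
                    )
                    mp = cohort_prototypes(
                        member, cohort, n_per_context, seed=proto_seed
                    )
                    fam[j] = cross_subject_decode(
                        mp, actual, member.layers, hand, n_folds,
                        family_reps, seed=seed + j,
                    ).mean()
                report.family_accuracies[(variant, hand)] = fam
                report.family_percentile[(variant, hand)] = float(
                    np.mean(full_means[hand] > fam) * 100.0
                )
            continue
        if variant.startswith("top_"):
            model = build_enn_variant(
                "top_k", cohort, base=base, layers=layers,
                n_components=n_components,
                hidden_vertices=(top_k_hidden or {})[variant],
            )
        else:
            model = build_enn_variant(
                variant, cohort, base=base, layers=layers,
                n_components=n_components, seed=seed,
            )
        pred = (
            full_pred
            if variant == "full"
            else cohort_prototypes(model, cohort, n_per_context, seed=proto_seed)
        )
        outcomes = evaluate_model(
            pred, actual, model.layers, hands, n_folds, n_reps, n_perm, seed=seed
        )
        for hand, out in outcomes.items():
            report.outcomes[(variant, hand)] = out
            if variant == "full":
                full_means[hand] = out.mean_accuracy
    return report
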