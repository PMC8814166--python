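"""The C-PRO (Concrete Permuted Rule Operations) cognitive paradigm.

C-PRO crosses 4 logic rules x 4 sensory rules x 4 motor rules into 64 task
contexts.  A trial presents two consecutive audiovisual stimuli; the logic
rule is applied to the presence of the sensory rule's target feature in the
two stimuli, and the outcome selects a finger press: TRUE presses the motor
rule's finger, FALSE presses the other finger of the same hand.

This module provides the combinatorics (contexts, stimulus sets, the 28-unit
binary trial encoding), an exact ground-truth solver, and a counterbalanced
pseudo-trial sampler whose per-response stimulus multisets are identical
across the four responses by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Domain",
    "Rule",
    "TaskContext",
    "StimulusSet",
    "MotorResponse",
    "PseudoTrialSpec",
    "RULES",
    "LOGIC_RULES",
    "SENSORY_RULES",
    "MOTOR_RULES",
    "N_RULE_UNITS",
    "N_STIMULUS_UNITS",
    "N_INPUT_UNITS",
    "enumerate_contexts",
    "enumerate_stimulus_sets",
    "evaluate_statement",
    "solve_trial",
    "encode_trial",
    "sample_counterbalanced_pseudo_trials",
    "pseudo_trials_to_frame",
]


class Domain(str, Enum):
    LOGIC = "logic"
    SENSORY = "sensory"
    MOTOR = "motor"


@dataclass(frozen=True)
class Rule:
    """One of the 12 task rules; ``unit_index`` is its input-unit position (0-11)."""

    domain: Domain
    name: str
    unit_index: int


LOGIC_RULE_NAMES = ("both", "not_both", "either", "neither")
SENSORY_RULE_NAMES = ("red", "vertical", "high_pitch", "constant")
MOTOR_RULE_NAMES = ("left_middle", "left_index", "right_middle", "right_index")

LOGIC_RULES = tuple(
    Rule(Domain.LOGIC, name, i) for i, name in enumerate(LOGIC_RULE_NAMES)
)
SENSORY_RULES = tuple(
    Rule(Domain.SENSORY, name, 4 + i) for i, name in enumerate(SENSORY_RULE_NAMES)
)
MOTOR_RULES = tuple(
    Rule(Domain.MOTOR, name, 8 + i) for i, name in enumerate(MOTOR_RULE_NAMES)
)
RULES = LOGIC_RULES + SENSORY_RULES + MOTOR_RULES

N_RULE_UNITS = 12
N_STIMULUS_UNITS = 16
N_INPUT_UNITS = N_RULE_UNITS + N_STIMULUS_UNITS

# Stimulus dimensions in canonical order, each with (target feature, other feature).
# The sensory rule named by a context points at exactly one dimension; its target
# feature is what the logic rule tests for.
DIMENSIONS = ("color", "orientation", "pitch", "continuity")
DIMENSION_FEATURES = {
    "color": ("red", "blue"),
    "orientation": ("vertical", "horizontal"),
    "pitch": ("high", "low"),
    "continuity": ("constant", "beeping"),
}
SENSORY_RULE_DIMENSION = {
    "red": "color",
    "vertical": "orientation",
    "high_pitch": "pitch",
    "constant": "continuity",
}

#: The four ordered pair conditions of a dimension, as (first, second) indices into
#: DIMENSION_FEATURES[dim]; 0 is the target feature.  Pair condition p of dimension d
#: occupies input unit 12 + 4*d + p.
PAIR_CONDITIONS = ((0, 0), (0, 1), (1, 0), (1, 1))


class MotorResponse(str, Enum):
    LEFT_MIDDLE = "left_middle"
    LEFT_INDEX = "left_index"
    RIGHT_MIDDLE = "right_middle"
    RIGHT_INDEX = "right_index"

    @property
    def hand(self) -> str:
        return "left" if self.value.startswith("left") else "right"

    @property
    def finger(self) -> str:
        return self.value.split("_")[1]

    @property
    def sibling(self) -> "MotorResponse":
        """The other finger on the same hand."""
        other = "index" if self.finger == "middle" else "middle"
        return MotorResponse(f"{self.hand}_{other}")

    @property
    def index(self) -> int:
        return MOTOR_RULE_NAMES.index(self.value)


@dataclass(frozen=True)
class TaskContext:
    logic_rule: Rule
    sensory_rule: Rule
    motor_rule: Rule

    def __post_init__(self) -> None:
        if (
            self.logic_rule.domain is not Domain.LOGIC
            or self.sensory_rule.domain is not Domain.SENSORY
            or self.motor_rule.domain is not Domain.MOTOR
        ):
            raise ValueError("TaskContext needs one rule per domain")

    @property
    def rules(self) -> tuple[Rule, Rule, Rule]:
        return (self.logic_rule, self.sensory_rule, self.motor_rule)

    @property
    def relevant_dimension(self) -> str:
        return SENSORY_RULE_DIMENSION[self.sensory_rule.name]

    @property
    def context_id(self) -> int:
        """Canonical index 0-63 (logic-major, then sensory, then motor)."""
        li = self.logic_rule.unit_index
        si = self.sensory_rule.unit_index - 4
        mi = self.motor_rule.unit_index - 8
        return li * 16 + si * 4 + mi


@dataclass(frozen=True)
class StimulusSet:
    """One ordered stimulus pair per dimension, as pair-condition indices 0-3."""

    pair_indices: tuple[int, int, int, int]  # (color, orientation, pitch, continuity)

    def __post_init__(self) -> None:
        if len(self.pair_indices) != 4 or any(
            not 0 <= p <= 3 for p in self.pair_indices
        ):
            raise ValueError("pair_indices must be 4 integers in 0-3")

    def pair_condition(self, dimension: str) -> tuple[int, int]:
        return PAIR_CONDITIONS[self.pair_indices[DIMENSIONS.index(dimension)]]

    def pair_labels(self, dimension: str) -> tuple[str, str]:
        feats = DIMENSION_FEATURES[dimension]
        a, b = self.pair_condition(dimension)
        return feats[a], feats[b]

    @property
    def unit_indices(self) -> tuple[int, int, int, int]:
        """The four active stimulus-pair input units (12-27)."""
        return tuple(
            N_RULE_UNITS + 4 * d + p for d, p in enumerate(self.pair_indices)
        )


@dataclass(frozen=True)
class PseudoTrialSpec:
    context: TaskContext
    stimulus: StimulusSet
    correct_response: MotorResponse


def enumerate_contexts() -> list[TaskContext]:
    """All 64 task contexts in canonical (logic-major) order."""
    return [
        TaskContext(lr, sr, mr)
        for lr, sr, mr in itertools.product(LOGIC_RULES, SENSORY_RULES, MOTOR_RULES)
    ]


def enumerate_stimulus_sets() -> list[StimulusSet]:
    """All 256 stimulus sets (4 pair conditions per dimension) in canonical order."""
    return [
        StimulusSet(pairs) for pairs in itertools.product(range(4), repeat=4)
    ]


def evaluate_statement(context: TaskContext, stimulus: StimulusSet) -> bool:
    """Apply the context's logic rule to target-feature presence in the two stimuli."""
    f1, f2 = (p == 0 for p in stimulus.pair_condition(context.relevant_dimension))
    logic = context.logic_rule.name
    if logic == "both":
        return f1 and f2
    if logic == "not_both":
        return not (f1 and f2)
    if logic == "either":  # inclusive or
        return f1 or f2
    if logic == "neither":
        return not f1 and not f2
    raise ValueError(f"unknown logic rule {logic!r}")


def solve_trial(context: TaskContext, stimulus: StimulusSet) -> MotorResponse:
    """Ground-truth correct response: TRUE presses the motor rule's finger, FALSE
    the other finger on the same hand."""
    response = MotorResponse(context.motor_rule.name)
    return response if evaluate_statement(context, stimulus) else response.sibling


def encode_trial(
    context: TaskContext, stimulus: StimulusSet | None = None
) -> np.ndarray:
    """Binary 28-unit input vector: 3 rule units plus, if a stimulus is given, its
    4 stimulus-pair units (7 active units for a full trial)."""
    vec = np.zeros(N_INPUT_UNITS, dtype=np.float64)
    for rule in context.rules:
        vec[rule.unit_index] = 1.0
    if stimulus is not None:
        for u in stimulus.unit_indices:
            vec[u] = 1.0
    return vec


def response_table() -> np.ndarray:
    """64 x 256 table of correct response indices over all trial types."""
    contexts = enumerate_contexts()
    stimuli = enumerate_stimulus_sets()
    table = np.empty((len(contexts), len(stimuli)), dtype=np.int64)
    for ci, ctx in enumerate(contexts):
        for si, stim in enumerate(stimuli):
            table[ci, si] = solve_trial(ctx, stim).index
    return table


# Pair conditions of the relevant dimension for which each logic rule is TRUE.
_TRUE_PAIRS = {
    "both": (0,),
    "not_both": (1, 2, 3),
    "either": (0, 1, 2),
    "neither": (3,),
}


def _truth_quota(logic: str, n: int, mode: str) -> int:
    if mode == "strict":
        if n % 2:
            raise ValueError("strict mode requires an even n_per_context")
        return n // 2
    rate = len(_TRUE_PAIRS[logic]) / 4.0
    return int(np.floor(n * rate + 0.5))


def sample_counterbalanced_pseudo_trials(
    n_per_context: int = 15,
    seed: int = 0,
    mode: str = "quota",
) -> list[PseudoTrialSpec]:
    """Sample ``64 * n_per_context`` pseudo-trials with exact response counterbalancing.

    For each (logic, sensory) cell a truth-count quota fixes how many of the
    ``n_per_context`` sampled stimulus sets make the rule statement TRUE (for
    n=15: both/neither 4, not_both/either 11 — matching the rules' 1/4 vs 3/4
    truth rates).  The same per-cell stimulus multiset is reused for all four
    motor rules, so each response is correct for exactly one quarter of the
    trials and the stimulus multisets assigned to the four responses are
    identical.  ``mode="strict"`` instead forces a truth count of n/2 in every
    cell (n even), which additionally equalizes the per-response context
    mixtures.

    Deterministic given ``seed``.
    """
    if n_per_context < 1:
        raise ValueError("n_per_context must be >= 1")
    if mode not in ("quota", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    stimuli = enumerate_stimulus_sets()

    trials: list[PseudoTrialSpec] = []
    contexts = enumerate_contexts()
    # One stimulus multiset per (logic, sensory) cell, shared by the 4 motor rules.
    for logic_rule in LOGIC_RULES:
        for sensory_rule in SENSORY_RULES:
            dim_idx = DIMENSIONS.index(SENSORY_RULE_DIMENSION[sensory_rule.name])
            q = _truth_quota(logic_rule.name, n_per_context, mode)
            true_pairs = _TRUE_PAIRS[logic_rule.name]
            false_pairs = tuple(p for p in range(4) if p not in true_pairs)
            if (q > 0 and not true_pairs) or (q < n_per_context and not false_pairs):
                raise ValueError(
                    "counterbalancing quota unsatisfiable for "
                    f"{logic_rule.name} with n_per_context={n_per_context}"
                )
            cell_stimuli: list[StimulusSet] = []
            for k in range(n_per_context):
                relevant = rng.choice(true_pairs if k < q else false_pairs)
                pairs = list(rng.integers(0, 4, size=4))
                pairs[dim_idx] = int(relevant)
                cell_stimuli.append(StimulusSet(tuple(pairs)))
            for motor_rule in MOTOR_RULES:
                ctx = TaskContext(logic_rule, sensory_rule, motor_rule)
                for stim in cell_stimuli:
                    trials.append(
                        PseudoTrialSpec(ctx, stim, solve_trial(ctx, stim))
                    )
    assert len(trials) == len(contexts) * n_per_context
    return trials


def pseudo_trials_to_frame(trials: Sequence[PseudoTrialSpec]) -> pd.DataFrame:
    """Serialize pseudo-trials to a table (TSV-friendly)."""
    rows = []
    for t in trials:
        row = {
            "context_id": t.context.context_id,
            "logic": t.context.logic_rule.name,
            "sensory": t.context.sensory_rule.name,
            "motor": t.context.motor_rule.name,
        }
        for dim in DIMENSIONS:
            row[dim] = "-".join(t.stimulus.pair_labels(dim))
        row["correct_response"] = t.correct_response.value
        rows.append(row)
    return pd.DataFrame(rows)
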