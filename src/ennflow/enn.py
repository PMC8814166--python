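"""The empirically-estimated neural network (ENN) and its lesioned variants.

An ENN is a layered network whose units are data vertices and whose
inter-layer weights are resting-state FC estimates rather than trained
parameters.  A pseudo-trial's inputs are composed from condition-wise
activation estimates:

    X_context  = (R_logic + R_sensory + R_motor) / 3      (additive compositionality)
    X_stimulus = the activation pattern of the stimulus-pair condition in the
                 dimension named by the context's sensory rule (other
                 dimensions contribute nothing)

and propagated through the conjunction hubs with a ReLU at baseline:

    X_hidden = relu(X_context W_context2hidden + X_stimulus W_stimulus2hidden)
    X_output = X_hidden W_hidden2output

Averaging the outputs of counterbalanced pseudo-trials by their
solver-correct response gives four predicted motor prototypes per subject.
Control variants remove the hidden layer (direct input->output FC), replace
it with random parcels, drop the ReLU, zero the context connections, or
shuffle the input weight maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import task
from .connectivity import (
    VertexWeightMap,
    apply_fc,
    compose_vertex_weights,
    estimate_pcr_fc,
    group_average_fc,
)
from .synth import LayerAssignment, SyntheticCohort, SyntheticSubject

__all__ = [
    "EnnModel",
    "PredictedPrototypes",
    "VARIANTS",
    "estimate_layer_fc",
    "build_enn",
    "build_enn_variant",
    "compose_context_pattern",
    "compose_stimulus_pattern",
    "enn_forward",
    "simulate_predicted_prototypes",
]

VARIANTS = (
    "full",
    "no_hidden",
    "random_hidden",
    "no_relu",
    "context_lesion",
    "shuffled_fc",
    "top_k",
)


@dataclass
class EnnModel:
    layers: LayerAssignment
    w_c2h: VertexWeightMap | None
    w_s2h: VertexWeightMap | None
    w_h2m: VertexWeightMap | None
    w_direct: VertexWeightMap | None = None  # no_hidden variant only
    nonlinearity: str = "relu"  # "relu" | "none"
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.nonlinearity not in ("relu", "none"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.variant == "no_hidden":
            if self.w_direct is None:
                raise ValueError("no_hidden variant needs w_direct")
        elif self.w_c2h is None or self.w_s2h is None or self.w_h2m is None:
            raise ValueError("hidden-layer variants need all three maps")


@dataclass
class PredictedPrototypes:
    """Per-subject predicted motor-output patterns, one per response (4 x V_motor)."""

    patterns: np.ndarray
    n_trials_per_response: int


def estimate_layer_fc(
    cohort: SyntheticCohort,
    layers: LayerAssignment,
    n_components: int = 500,
) -> tuple[VertexWeightMap, VertexWeightMap, VertexWeightMap]:
    """Group-averaged composed FC maps for context->hidden, stimulus->hidden,
    hidden->motor.

    FC is estimated per subject from rest and averaged in composed vertex space
    (subject-specific component loadings are not alignable across subjects).
    Source vertices overlapping the target layer are excluded from predictors.
    """
    specs = [
        ("context", layers.context, layers.hidden, "hidden"),
        ("stimulus", layers.stimulus, layers.hidden, "hidden"),
        ("hidden", layers.hidden, layers.motor, "motor"),
    ]
    out = []
    for name, src, tgt, tgt_name in specs:
        overlap = np.where(np.isin(src, tgt))[0]
        maps = []
        for subj in cohort.subjects:
            fc = estimate_pcr_fc(
                subj.rest[:, src],
                subj.rest[:, tgt],
                n_components=n_components,
                excluded=overlap,
                source=name,
                target=tgt_name,
            )
            maps.append(compose_vertex_weights(fc))
        out.append(group_average_fc(maps))
    return tuple(out)


def build_enn(
    cohort: SyntheticCohort,
    layers: LayerAssignment | None = None,
    n_components: int = 500,
) -> EnnModel:
    """The full ENN: group FC maps over the given (or ground-truth) layers."""
    layers = layers or cohort.brain.layer_assignment()
    w_c2h, w_s2h, w_h2m = estimate_layer_fc(cohort, layers, n_components)
    return EnnModel(layers=layers, w_c2h=w_c2h, w_s2h=w_s2h, w_h2m=w_h2m)


def compose_context_pattern(
    rule_betas: np.ndarray, context: task.TaskContext
) -> np.ndarray:
    """(R_logic + R_sensory + R_motor) / 3 over the rows of ``rule_betas``."""
    if rule_betas.shape[0] != 12:
        raise ValueError("rule_betas must have 12 rows")
    idx = [r.unit_index for r in context.rules]
    return rule_betas[idx].mean(axis=0)


def compose_stimulus_pattern(
    stimulus_betas: np.ndarray,
    context: task.TaskContext,
    stimulus: task.StimulusSet,
) -> np.ndarray:
    """The activation pattern of the relevant dimension's pair condition.

    The context's sensory rule names the relevant dimension; only that
    dimension's pair-condition pattern enters (all other stimulus activations
    are set to 0, i.e., contribute nothing)."""
    if stimulus_betas.shape[0] != 16:
        raise ValueError("stimulus_betas must have 16 rows")
    dim = task.DIMENSIONS.index(context.relevant_dimension)
    unit = 4 * dim + stimulus.pair_indices[dim]
    return stimulus_betas[unit]


def enn_forward(
    model: EnnModel, x_context: np.ndarray, x_stimulus: np.ndarray
) -> np.ndarray:
    """One activity-flow pass; patterns may be batched (leading axis)."""
    if model.variant == "no_hidden":
        x = np.concatenate(
            [np.atleast_2d(x_context), np.atleast_2d(x_stimulus)], axis=-1
        )
        out = apply_fc(model.w_direct, x)
        return out[0] if np.ndim(x_context) == 1 else out
    pre = apply_fc(model.w_c2h, x_context) + apply_fc(model.w_s2h, x_stimulus)
    hidden = np.maximum(pre, 0.0) if model.nonlinearity == "relu" else pre
    return apply_fc(model.w_h2m, hidden)


def simulate_predicted_prototypes(
    model: EnnModel,
    subject: SyntheticSubject,
    pseudo_trials: Sequence[task.PseudoTrialSpec],
) -> PredictedPrototypes:
    """Forward every pseudo-trial and average outputs by solver-correct response."""
    layers = model.layers
    rule_b = subject.rule_betas[:, layers.context]
    stim_b = subject.stimulus_betas[:, layers.stimulus]
    # A trial's inputs are fully determined by (context_id, active stimulus
    # unit), so forward each unique combo once and gather.  Combined with the
    # canonical (sorted) summation below, this makes prototypes of responses
    # with identical input multisets bitwise identical — the property that
    # yields exactly-50% decoding for structurally chance-level lesions.
    n = len(pseudo_trials)
    combo_key = np.empty(n, dtype=np.int64)
    resp = np.empty(n, dtype=np.int64)
    combos: dict[tuple[int, int], int] = {}
    combo_trials: list[task.PseudoTrialSpec] = []
    for i, t in enumerate(pseudo_trials):
        dim = task.DIMENSIONS.index(t.context.relevant_dimension)
        unit = 4 * dim + t.stimulus.pair_indices[dim]
        key = (t.context.context_id, unit)
        if key not in combos:
            combos[key] = len(combo_trials)
            combo_trials.append(t)
        combo_key[i] = combos[key]
        resp[i] = t.correct_response.index
    x_ctx = np.stack([compose_context_pattern(rule_b, t.context) for t in combo_trials])
    x_stim = np.stack(
        [compose_stimulus_pattern(stim_b, t.context, t.stimulus) for t in combo_trials]
    )
    combo_out = enn_forward(model, x_ctx, x_stim)
    outputs = combo_out[combo_key]
    counts = np.bincount(resp, minlength=4)
    if len(set(counts)) != 1:
        raise ValueError("pseudo-trials are not counterbalanced across responses")
    protos = np.empty((4, outputs.shape[1]))
    for k in range(4):
        rows = outputs[resp == k]
        rows = rows[np.lexsort(rows.T)]  # canonical order: equal multisets sum equally
        protos[k] = rows.mean(axis=0)
    return PredictedPrototypes(patterns=protos, n_trials_per_response=int(counts[0]))


def _random_parcel_hidden(
    cohort: SyntheticCohort, size_target: int, rng: np.random.Generator
) -> np.ndarray:
    """Union of whole parcels matching the hidden vertex count within +/-10%."""
    table = cohort.brain.parcel_table
    pids = list(table)
    lo, hi = 0.9 * size_target, 1.1 * size_target
    for _ in range(1000):
        order = rng.permutation(pids)
        chosen: list[int] = []
        total = 0
        for pid in order:
            sz = len(table[pid]["vertices"])
            if total + sz <= hi:
                chosen.append(pid)
                total += sz
            if total >= lo:
                break
        if lo <= total <= hi:
            return np.concatenate([table[pid]["vertices"] for pid in sorted(chosen)])
    raise RuntimeError("could not assemble a size-matched random hidden layer")


def build_enn_variant(
    variant: str,
    cohort: SyntheticCohort,
    base: EnnModel | None = None,
    layers: LayerAssignment | None = None,
    n_components: int = 500,
    seed: int = 0,
    hidden_vertices: np.ndarray | None = None,
    permutations: tuple[np.ndarray, np.ndarray] | None = None,
) -> EnnModel:
    """Build a lesioned / control variant.

    full            the base model (estimated if not supplied)
    no_hidden       FC re-estimated directly from [context, stimulus] to motor
    random_hidden   hidden layer replaced by a size-matched random parcel union,
                    all three FC maps re-estimated (one sample; call repeatedly)
    no_relu         nonlinearity removed
    context_lesion  W_context2hidden set to 0
    shuffled_fc     rows (source-vertex assignment) of both input weight maps
                    independently permuted (one sample; call repeatedly)
    top_k           hidden layer replaced by ``hidden_vertices`` (e.g., the
                    union of top-k ranked parcels), FC re-estimated
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    layers = layers or (base.layers if base is not None else cohort.brain.layer_assignment())

    if variant in ("full", "no_relu", "context_lesion", "shuffled_fc") and base is None:
        base = build_enn(cohort, layers, n_components)

    if variant == "full":
        return base
    if variant == "no_relu":
        return replace(base, nonlinearity="none", variant="no_relu")
    if variant == "context_lesion":
        zeroed = VertexWeightMap(
            W=np.zeros_like(base.w_c2h.W),
            source=base.w_c2h.source,
            target=base.w_c2h.target,
            provenance=base.w_c2h.provenance + "+context_lesion",
        )
        return replace(base, w_c2h=zeroed, variant="context_lesion")
    if variant == "shuffled_fc":
        rng = np.random.default_rng(seed)
        shuf = []
        for i, m in enumerate((base.w_c2h, base.w_s2h)):
            perm = (
                permutations[i]
                if permutations is not None
                else rng.permutation(m.W.shape[0])
            )
            shuf.append(
                VertexWeightMap(
                    W=m.W[perm],
                    source=m.source,
                    target=m.target,
                    provenance=m.provenance + "+row_shuffle",
                )
            )
        return replace(base, w_c2h=shuf[0], w_s2h=shuf[1], variant="shuffled_fc")
    if variant == "no_hidden":
        src = np.concatenate([layers.context, layers.stimulus])
        overlap = np.where(np.isin(src, layers.motor))[0]
        maps = [
            compose_vertex_weights(
                estimate_pcr_fc(
                    s.rest[:, src],
                    s.rest[:, layers.motor],
                    n_components=n_components,
                    excluded=overlap,
                    source="context+stimulus",
                    target="motor",
                )
            )
            for s in cohort.subjects
        ]
        return EnnModel(
            layers=layers,
            w_c2h=None,
            w_s2h=None,
            w_h2m=None,
            w_direct=group_average_fc(maps),
            variant="no_hidden",
        )
    if variant == "random_hidden":
        rng = np.random.default_rng(seed)
        hidden = _random_parcel_hidden(cohort, len(layers.hidden), rng)
        new_layers = replace(layers, hidden=hidden)
        w_c2h, w_s2h, w_h2m = estimate_layer_fc(cohort, new_layers, n_components)
        return EnnModel(
            layers=new_layers, w_c2h=w_c2h, w_s2h=w_s2h, w_h2m=w_h2m,
            variant="random_hidden",
        )
    # top_k
    if hidden_vertices is None:
        raise ValueError("top_k variant needs hidden_vertices")
    new_layers = replace(layers, hidden=np.asarray(hidden_vertices))
    w_c2h, w_s2h, w_h2m = estimate_layer_fc(cohort, new_layers, n_components)
    return EnnModel(
        layers=new_layers, w_c2h=w_c2h, w_s2h=w_s2h, w_h2m=w_h2m, variant="top_k"
    )
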