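"""Synthetic cohort generator with known ground-truth connectivity.

Emulates, at desk scale, the empirical structures the pipeline consumes:
per-subject resting-state time series over vertices whose cross-layer
statistical dependencies follow known linear weights, condition-wise
activation patterns (12 task rules, 16 stimulus-pair conditions, 4 motor
responses) with compositional rule structure, and a parcel partition with
true conjunction parcels plus distractor parcels.

The ground-truth inter-layer weights are constructed by training a compact
bias-free "teacher" network on the C-PRO analog and embedding its layers
into vertex space:

* rule and stimulus-pair conditions get mutually orthogonal spatial patterns
  over the context / stimulus input layers (random orthogonal embeddings);
* each teacher hidden unit owns a disjoint set of hidden-layer vertices with
  positive embedding weights, so the vertex-space ReLU commutes exactly with
  the teacher's ReLU;
* the four response templates occupy disjoint left- and right-hand blocks of
  the motor layer.

By construction, zero-noise activity-flow propagation
``relu(X_ctx G_c2h + X_stim G_s2h) G_h2m`` produces the solver-correct motor
template for every one of the 16384 trial types, which makes downstream
parameter-recovery claims testable.  Resting-state dynamics are linear
(white-noise innovations at the input layers propagated through the same
weights, plus observation noise) so that the linear FC estimator is
well-specified; the ReLU belongs to the task-evoked pathway only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import task

__all__ = [
    "GroundTruthConfig",
    "GroundTruthBrain",
    "SyntheticSubject",
    "SyntheticCohort",
    "LayerAssignment",
    "build_ground_truth",
    "simulate_subject_data",
    "generate_cohort",
]


@dataclass(frozen=True)
class LayerAssignment:
    """Vertex index sets for the ENN layers (indices into the whole-brain axis)."""

    context: np.ndarray
    stimulus: np.ndarray
    hidden: np.ndarray
    motor_left: np.ndarray
    motor_right: np.ndarray

    @property
    def motor(self) -> np.ndarray:
        return np.concatenate([self.motor_left, self.motor_right])


@dataclass
class GroundTruthConfig:
    v_context: int = 200
    v_stimulus: int = 200
    v_hidden: int = 150
    v_motor: int = 40
    n_distractor_parcels: int = 10
    distractor_size: int = 50
    n_context_parcels: int = 2
    n_stimulus_parcels: int = 4  # one per stimulus dimension (blocked embedding)
    teacher_hidden: int = 64
    rest_T: int = 1065
    innovation_sd: float = 1.0
    hidden_local_sd: float = 0.7
    observation_sd: float = 0.2
    subject_beta_sd: float = 0.5
    distractor_ar: float = 0.8
    n_per_context_actual: int = 15


def _orthogonal_rows(n_rows: int, n_cols: int, rng: np.random.Generator) -> np.ndarray:
    """n_rows orthonormal rows in R^n_cols, scaled so per-vertex RMS is ~1."""
    if n_rows > n_cols:
        raise ValueError("need n_rows <= n_cols")
    g = rng.standard_normal((n_cols, n_rows))
    q, _ = np.linalg.qr(g)
    return q.T * np.sqrt(n_cols)


def _teacher_training_set() -> tuple[np.ndarray, np.ndarray]:
    """All 256 distinct composed inputs (64 contexts x 4 relevant pair
    conditions) and their solver targets.

    Input features: the 12-dim context vector (three 1/3 entries) concatenated
    with the 16-dim one-hot of the context-relevant stimulus-pair unit —
    the feature-space analog of the ENN's composed input patterns."""
    contexts = task.enumerate_contexts()
    stimuli = task.enumerate_stimulus_sets()
    X = np.zeros((64 * 4, 28))
    y = np.zeros(64 * 4, dtype=np.int64)
    for ci, ctx in enumerate(contexts):
        dim = task.DIMENSIONS.index(ctx.relevant_dimension)
        for p in range(4):
            row = ci * 4 + p
            for r in ctx.rules:
                X[row, r.unit_index] = 1.0 / 3.0
            X[row, 12 + 4 * dim + p] = 1.0
            # any stimulus set with this relevant pair gives the same response
            stim = next(s for s in stimuli if s.pair_indices[dim] == p)
            y[row] = task.solve_trial(ctx, stim).index
    return X, y


def _train_teacher(
    n_hidden: int, rng: np.random.Generator, lr: float = 1e-3, max_steps: int = 8000
):
    """28 -> n_hidden -> 4 ReLU/sigmoid teacher trained on the composed-input
    task, from the same model family as the reference network (uniform fan-out
    init, MSE loss, Adam), so its hidden-layer representational geometry
    resembles a task-trained network's.

    The hidden bias is folded into the input weights afterwards (half into the
    context rows, half into the stimulus rows), which is exact because the
    context features always sum to 1 and exactly one stimulus unit is active;
    this keeps the embedded connectivity purely linear, as activity-flow
    propagation requires.  The output layer is bias-free and linear pre-sigmoid
    (the nearest-template readout is monotone-invariant).
    """
    X, y = _teacher_training_set()
    T = np.eye(4)[y]

    hw1, hw2 = np.sqrt(1.0 / n_hidden), np.sqrt(1.0 / 4)
    A = rng.uniform(-hw1, hw1, (28, n_hidden))
    b = rng.uniform(-hw1, hw1, n_hidden)
    C = rng.uniform(-hw2, hw2, (n_hidden, 4))
    params = [A, b, C]
    ms = [np.zeros_like(p) for p in params]
    vs = [np.zeros_like(p) for p in params]
    b1m, b2m, eps = 0.9, 0.999, 1e-8
    for t in range(1, max_steps + 1):
        Z = X @ A + b
        H = np.maximum(Z, 0.0)
        Y = 1.0 / (1.0 + np.exp(-(H @ C)))
        diff = Y - T
        dZ2 = (2.0 / diff.size) * diff * Y * (1.0 - Y)
        gC = H.T @ dZ2
        dH = dZ2 @ C.T
        dZ = dH * (Z > 0)
        gA = X.T @ dZ
        gb = dZ.sum(axis=0)
        for p, g, m, v in zip(params, [gA, gb, gC], ms, vs):
            m *= b1m; m += (1 - b1m) * g
            v *= b2m; v += (1 - b2m) * g * g
            p -= lr * (m / (1 - b1m**t)) / (np.sqrt(v / (1 - b2m**t)) + eps)
        if t % 500 == 0 and t >= 3000:
            acc = np.mean(np.argmax(Y, axis=1) == y)
            off = Y.copy()
            off[np.arange(len(y)), y] = -np.inf
            margin = np.min(Y[np.arange(len(y)), y] - np.max(off, axis=1))
            if acc == 1.0 and margin > 0.1:
                break
    # fold the hidden bias into the input weights (see docstring)
    A_abs = A.copy()
    A_abs[:12] += b / 2.0
    A_abs[12:] += b / 2.0
    Z = X @ A_abs
    acc = np.mean(np.argmax(np.maximum(Z, 0.0) @ C, axis=1) == y)
    return A_abs, C, float(acc)


@dataclass
class GroundTruthBrain:
    config: GroundTruthConfig
    seed: int
    # ground-truth inter-layer weights, vertex space
    G_c2h: np.ndarray  # v_context x v_hidden
    G_s2h: np.ndarray  # v_stimulus x v_hidden
    G_h2m: np.ndarray  # v_hidden x v_motor
    # group-level source patterns
    rule_patterns: np.ndarray  # 12 x v_context
    stimulus_patterns: np.ndarray  # 16 x v_stimulus
    motor_templates: np.ndarray  # 4 x v_motor (disjoint hand blocks)
    parcel_labels: np.ndarray  # v_total ints
    parcel_table: dict  # id -> {name, kind, vertices}
    actual_motor_group: np.ndarray | None = None  # 4 x v_motor

    @property
    def v_total(self) -> int:
        return len(self.parcel_labels)

    def layer_assignment(self) -> LayerAssignment:
        c = self.config
        off_s = c.v_context
        off_h = off_s + c.v_stimulus
        off_m = off_h + c.v_hidden
        half = c.v_motor // 2
        return LayerAssignment(
            context=np.arange(0, c.v_context),
            stimulus=np.arange(off_s, off_s + c.v_stimulus),
            hidden=np.arange(off_h, off_h + c.v_hidden),
            motor_left=np.arange(off_m, off_m + half),
            motor_right=np.arange(off_m + half, off_m + c.v_motor),
        )

    # ---- zero-noise task-evoked propagation -------------------------------
    def context_pattern(self, ctx: task.TaskContext) -> np.ndarray:
        idx = [r.unit_index for r in ctx.rules]
        return self.rule_patterns[idx].mean(axis=0)

    def stimulus_pattern(
        self, ctx: task.TaskContext, stim: task.StimulusSet
    ) -> np.ndarray:
        dim = task.DIMENSIONS.index(ctx.relevant_dimension)
        unit = 4 * dim + stim.pair_indices[dim]
        return self.stimulus_patterns[unit]

    def propagate(self, ctx: task.TaskContext, stim: task.StimulusSet) -> np.ndarray:
        """relu(X_ctx G_c2h + X_stim G_s2h) G_h2m -> motor pattern."""
        h = np.maximum(
            self.context_pattern(ctx) @ self.G_c2h
            + self.stimulus_pattern(ctx, stim) @ self.G_s2h,
            0.0,
        )
        return h @ self.G_h2m

    def nearest_template(self, motor_pattern: np.ndarray) -> int:
        """Cosine template matching (no re-centering): with equal-norm
        orthogonal templates this ranks responses exactly like the teacher's
        output units, at any motor-layer size."""
        t = self.motor_templates
        r = t @ motor_pattern / (np.linalg.norm(t, axis=1) + 1e-30)
        return int(np.argmax(r))

    def exhaustive_task_accuracy(self) -> float:
        """Nearest-template accuracy of zero-noise propagation over all 16384
        trial types.

        The 64 irrelevant-dimension combinations per (context, relevant pair)
        leave the propagation unchanged, so the sweep collapses to 256 cases."""
        contexts = task.enumerate_contexts()
        stimuli = task.enumerate_stimulus_sets()
        correct = 0
        for ctx in contexts:
            dim = task.DIMENSIONS.index(ctx.relevant_dimension)
            for p in range(4):
                stim = next(s for s in stimuli if s.pair_indices[dim] == p)
                pred = self.nearest_template(self.propagate(ctx, stim))
                correct += int(pred == task.solve_trial(ctx, stim).index)
        return correct / (64 * 4)


def _split_sizes(total: int, parts: int) -> list[int]:
    base = total // parts
    sizes = [base] * parts
    for i in range(total - base * parts):
        sizes[i] += 1
    return sizes


def build_ground_truth(
    config: GroundTruthConfig | None = None, seed: int = 0
) -> GroundTruthBrain:
    """Construct a ground-truth brain that provably performs the task.

    Raises if the embedded teacher fails the >= 99% exhaustive-sweep criterion.
    """
    cfg = config or GroundTruthConfig()
    rng = np.random.default_rng(seed)
    if cfg.v_motor % 2:
        raise ValueError("v_motor must be even (two hand blocks)")
    if cfg.teacher_hidden > cfg.v_hidden:
        raise ValueError("teacher_hidden must be <= v_hidden")

    A, C, teacher_acc = _train_teacher(cfg.teacher_hidden, rng)
    if teacher_acc < 0.99:
        raise RuntimeError(f"teacher failed task criterion: accuracy {teacher_acc:.3f}")

    # input embeddings: orthogonal condition patterns, per-vertex RMS ~ 1.
    # Stimulus patterns are dimension-blocked (each dimension's four pair
    # conditions live in their own vertex block, like segregated sensory
    # cortices), so a composed stimulus input occupies exactly one block.
    E_c = _orthogonal_rows(12, cfg.v_context, rng)
    E_s = np.zeros((16, cfg.v_stimulus))
    s_pos = 0
    for d, sz in enumerate(_split_sizes(cfg.v_stimulus, 4)):
        E_s[4 * d : 4 * (d + 1), s_pos : s_pos + sz] = _orthogonal_rows(4, sz, rng)
        s_pos += sz

    # hidden embedding: each teacher unit owns a disjoint vertex set, positive weights
    owner = np.arange(cfg.v_hidden) % cfg.teacher_hidden
    p_w = rng.uniform(0.5, 1.5, size=cfg.v_hidden)
    Pmat = np.zeros((cfg.teacher_hidden, cfg.v_hidden))
    Pmat[owner, np.arange(cfg.v_hidden)] = p_w
    unit_norm = np.array(
        [np.sum(p_w[owner == j] ** 2) for j in range(cfg.teacher_hidden)]
    )

    # motor embedding: 2 orthonormal rows per hand block
    half = cfg.v_motor // 2
    M = np.zeros((4, cfg.v_motor))
    M[:2, :half] = _orthogonal_rows(2, half, rng)
    M[2:, half:] = _orthogonal_rows(2, half, rng)

    # E E^T is diagonal (orthogonal rows), so E^T / row-norm^2 inverts the
    # embeddings: pattern @ (E^T / ||E_i||^2) recovers the condition features
    G_c2h = (E_c.T / np.sum(E_c**2, axis=1)) @ A[:12] @ Pmat
    G_s2h = (E_s.T / np.sum(E_s**2, axis=1)) @ A[12:] @ Pmat
    G_h2m = (Pmat / unit_norm[:, None]).T @ (C @ M)

    # Rescale so linear rest propagation has O(1) per-vertex std at each layer.
    # Uniform positive scalings commute with the ReLU, so task behavior and the
    # nearest-template readout are unchanged.
    hvar = cfg.innovation_sd**2 * (np.sum(G_c2h**2, axis=0) + np.sum(G_s2h**2, axis=0))
    s_h = 1.0 / np.sqrt(hvar.mean())
    G_c2h *= s_h
    G_s2h *= s_h
    # hidden rest variance = propagated input activity + local innovations
    Sigma_h = cfg.innovation_sd**2 * (
        G_c2h.T @ G_c2h + G_s2h.T @ G_s2h
    ) + cfg.hidden_local_sd**2 * np.eye(cfg.v_hidden)
    mvar = np.einsum("ij,ij->j", G_h2m, Sigma_h @ G_h2m)
    G_h2m *= 1.0 / np.sqrt(mvar.mean())

    # parcel partition
    labels = np.empty(
        cfg.v_context
        + cfg.v_stimulus
        + cfg.v_hidden
        + cfg.v_motor
        + cfg.n_distractor_parcels * cfg.distractor_size,
        dtype=np.int64,
    )
    table: dict[int, dict] = {}
    pid = 0
    pos = 0

    def add_parcel(name: str, kind: str, size: int) -> None:
        nonlocal pid, pos
        labels[pos : pos + size] = pid
        table[pid] = {"name": name, "kind": kind, "vertices": np.arange(pos, pos + size)}
        pid += 1
        pos += size

    for i, sz in enumerate(_split_sizes(cfg.v_context, cfg.n_context_parcels)):
        add_parcel(f"context_{i}", "context", sz)
    for i, sz in enumerate(_split_sizes(cfg.v_stimulus, cfg.n_stimulus_parcels)):
        add_parcel(f"stimulus_{i}", "stimulus", sz)
    add_parcel("hidden_0", "hidden", cfg.v_hidden)
    add_parcel("motor_left", "motor_left", half)
    add_parcel("motor_right", "motor_right", half)
    for i in range(cfg.n_distractor_parcels):
        add_parcel(f"distractor_{i}", "distractor", cfg.distractor_size)

    brain = GroundTruthBrain(
        config=cfg,
        seed=seed,
        G_c2h=G_c2h,
        G_s2h=G_s2h,
        G_h2m=G_h2m,
        rule_patterns=E_c,
        stimulus_patterns=E_s,
        motor_templates=M,
        parcel_labels=labels,
        parcel_table=table,
    )
    acc = brain.exhaustive_task_accuracy()
    if acc < 0.99:
        raise RuntimeError(f"embedded brain failed task criterion: accuracy {acc:.3f}")

    # group-level "actual" motor prototypes: per-response average of zero-noise
    # propagation over a counterbalanced pseudo-trial set
    trials = task.sample_counterbalanced_pseudo_trials(
        cfg.n_per_context_actual, seed=seed
    )
    proto = np.zeros((4, cfg.v_motor))
    counts = np.zeros(4)
    for t in trials:
        k = t.correct_response.index
        proto[k] += brain.propagate(t.context, t.stimulus)
        counts[k] += 1
    brain.actual_motor_group = proto / counts[:, None]
    return brain


@dataclass
class SyntheticSubject:
    rest: np.ndarray  # T x v_total
    rule_betas: np.ndarray  # 12 x v_total
    stimulus_betas: np.ndarray  # 16 x v_total
    actual_motor_betas: np.ndarray  # 4 x v_motor
    seed: int

    @property
    def condition_betas(self) -> np.ndarray:
        """The 28-condition stack (12 rules then 16 stimulus pairs)."""
        return np.vstack([self.rule_betas, self.stimulus_betas])


@dataclass
class SyntheticCohort:
    brain: GroundTruthBrain
    subjects: list[SyntheticSubject]
    seed: int

    def __len__(self) -> int:
        return len(self.subjects)


def _group_condition_betas(brain: GroundTruthBrain) -> np.ndarray:
    """28 x v_total group activation patterns for single-condition probes.

    Input-layer vertices carry the condition's own spatial pattern; hidden
    (conjunction) vertices carry its zero-noise propagated ReLU response,
    mirroring the one-hot probe convention of the reference network.  Motor
    vertices stay at baseline: these are encoding-phase condition estimates,
    and a single presented condition is not a completed trial, so it evokes
    no response-locked motor activity (response patterns live in
    ``actual_motor_betas``)."""
    lay = brain.layer_assignment()
    out = np.zeros((28, brain.v_total))
    for r in range(12):
        out[r, lay.context] = brain.rule_patterns[r]
        out[r, lay.hidden] = np.maximum(brain.rule_patterns[r] @ brain.G_c2h, 0.0)
    for s in range(16):
        out[12 + s, lay.stimulus] = brain.stimulus_patterns[s]
        out[12 + s, lay.hidden] = np.maximum(
            brain.stimulus_patterns[s] @ brain.G_s2h, 0.0
        )
    return out


def simulate_subject_data(brain: GroundTruthBrain, subject_seed: int) -> SyntheticSubject:
    """One subject: linear rest propagation plus observation noise; betas are the
    group patterns plus subject-level Gaussian perturbation."""
    cfg = brain.config
    rng = np.random.default_rng(subject_seed)
    lay = brain.layer_assignment()
    T = cfg.rest_T

    rest = np.zeros((T, brain.v_total))
    ctx_innov = rng.normal(0.0, cfg.innovation_sd, size=(T, cfg.v_context))
    stim_innov = rng.normal(0.0, cfg.innovation_sd, size=(T, cfg.v_stimulus))
    # conjunction hubs have local spontaneous activity of their own, which
    # propagates to motor; without it the hidden->motor weights would be
    # unidentifiable from rest (input-driven hidden activity is low-rank)
    hidden = ctx_innov @ brain.G_c2h + stim_innov @ brain.G_s2h
    if cfg.hidden_local_sd > 0:
        hidden = hidden + rng.normal(
            0.0, cfg.hidden_local_sd, size=(T, cfg.v_hidden)
        )
    rest[:, lay.context] = ctx_innov
    rest[:, lay.stimulus] = stim_innov
    rest[:, lay.hidden] = hidden
    rest[:, lay.motor] = hidden @ brain.G_h2m
    # distractor parcels: AR(1) noise, uncorrelated with the layers
    d_start = lay.motor[-1] + 1
    n_d = brain.v_total - d_start
    if n_d > 0:
        phi = cfg.distractor_ar
        innov = rng.normal(0.0, np.sqrt(1 - phi**2), size=(T, n_d))
        d = np.empty((T, n_d))
        d[0] = rng.normal(0.0, 1.0, size=n_d)
        for t in range(1, T):
            d[t] = phi * d[t - 1] + innov[t]
        rest[:, d_start:] = d
    if cfg.observation_sd > 0:
        rest += rng.normal(0.0, cfg.observation_sd, size=rest.shape)

    group = _group_condition_betas(brain)
    cond = group + (
        rng.normal(0.0, cfg.subject_beta_sd, size=group.shape)
        if cfg.subject_beta_sd > 0
        else 0.0
    )
    actual = brain.actual_motor_group + (
        rng.normal(0.0, cfg.subject_beta_sd, size=(4, cfg.v_motor))
        if cfg.subject_beta_sd > 0
        else 0.0
    )
    return SyntheticSubject(
        rest=rest.astype(np.float32),
        rule_betas=cond[:12],
        stimulus_betas=cond[12:],
        actual_motor_betas=actual,
        seed=subject_seed,
    )


def generate_cohort(
    n_subjects: int, brain: GroundTruthBrain, seed: int = 0
) -> SyntheticCohort:
    """Independent subjects with seeds derived from the master seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    subjects = [simulate_subject_data(brain, int(s)) for s in subject_seeds]
    return SyntheticCohort(brain=brain, subjects=subjects, seed=seed)
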