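"""Reference feedforward ANN trained on the C-PRO analog.

The network maps the 28-unit binary trial encoding through two 1280-unit
ReLU hidden layers (Gaussian noise injected before the second) to a 4-unit
sigmoid output, one unit per finger press:

    X_h1 = relu(X W_in + b1)
    X_h2 = relu((X_h1 + I) W_h + b2),   I ~ N(0, 1/n_hidden)
    Y    = sigmoid(X_h2 W_out + b3)

It is trained with Adam on the mean squared error against one-hot targets
from the exact task solver, in mini-batches of 192 trials (each of the 64
contexts three times with random stimuli), and stops once the trailing
1000-batch mean accuracy exceeds 99.5%.  Its only downstream role is
representational: probing each input unit in isolation yields a 28x28
hidden-layer representational similarity matrix (RSM) used to locate
conjunction hubs in data.  A within-layer parameter-shuffle null RSM
controls for structure implied by the weight distributions alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import task

__all__ = [
    "AnnConfig",
    "AnnParameters",
    "TrainingTrace",
    "TrainingError",
    "init_parameters",
    "forward_ann",
    "train_ann",
    "exhaustive_accuracy",
    "probe_hidden_rsm",
    "shuffled_parameter_null_rsm",
]


class TrainingError(RuntimeError):
    """Raised when the stop rule is not met within max_batches."""


@dataclass
class AnnConfig:
    n_input: int = task.N_INPUT_UNITS
    n_hidden: int = 1280
    n_output: int = 4
    learning_rate: float = 1e-4
    batch_size: int = 192  # 64 contexts x 3
    noise_variance: float | None = None  # defaults to 1 / n_hidden
    stop_window: int = 1000
    stop_accuracy: float = 0.995
    max_batches: int = 30000
    shuffle_labels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size % 64:
            raise ValueError("batch_size must cover the 64 contexts equally")
        if self.noise_variance is None:
            self.noise_variance = 1.0 / self.n_hidden


@dataclass
class AnnParameters:
    W_in: np.ndarray
    b1: np.ndarray
    W_h: np.ndarray
    b2: np.ndarray
    W_out: np.ndarray
    b3: np.ndarray

    @property
    def n_hidden(self) -> int:
        return self.W_h.shape[0]

    def as_list(self) -> list[np.ndarray]:
        return [self.W_in, self.b1, self.W_h, self.b2, self.W_out, self.b3]


@dataclass
class TrainingTrace:
    loss: np.ndarray
    accuracy: np.ndarray
    stop_batch: int

    @property
    def trailing_accuracy(self) -> float:
        """Mean accuracy over the final stop-window batches."""
        return float(self.accuracy[-1000:].mean()) if len(self.accuracy) else 0.0


def init_parameters(config: AnnConfig, rng: np.random.Generator) -> AnnParameters:
    """Uniform U(-sqrt(k), sqrt(k)) init with k = 1/(units in the next layer);
    biases use the half-width of the weights they accompany."""

    def unif(shape, fan_out):
        hw = np.sqrt(1.0 / fan_out)
        return rng.uniform(-hw, hw, size=shape).astype(np.float32)

    h, o = config.n_hidden, config.n_output
    return AnnParameters(
        W_in=unif((config.n_input, h), h),
        b1=unif((h,), h),
        W_h=unif((h, h), h),
        b2=unif((h,), h),
        W_out=unif((h, o), o),
        b3=unif((o,), o),
    )


def forward_ann(
    params: AnnParameters,
    inputs: np.ndarray,
    noise_on: bool = False,
    noise_variance: float | None = None,
    rng: np.random.Generator | None = None,
):
    """Forward pass; returns (Y, H1, H2).

    With ``noise_on``, iid N(0, noise_variance) noise is added to the first
    hidden layer's activations before the second weight matrix (variance
    defaults to 1/n_hidden).
    """
    X = np.asarray(inputs, dtype=np.float32)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != params.W_in.shape[0]:
        raise ValueError(
            f"input width {X.shape[1]} != n_input {params.W_in.shape[0]}"
        )
    H1 = np.maximum(X @ params.W_in + params.b1, 0.0)
    if noise_on:
        if rng is None:
            rng = np.random.default_rng()
        var = 1.0 / params.n_hidden if noise_variance is None else noise_variance
        H1in = H1 + rng.normal(0.0, np.sqrt(var), size=H1.shape).astype(np.float32)
    else:
        H1in = H1
    H2 = np.maximum(H1in @ params.W_h + params.b2, 0.0)
    Z3 = H2 @ params.W_out + params.b3
    Y = 1.0 / (1.0 + np.exp(-Z3))
    return Y, H1, H2


def _build_trial_bank():
    """Input encodings and solver targets for all 64 x 256 trial types."""
    contexts = task.enumerate_contexts()
    stimuli = task.enumerate_stimulus_sets()
    ctx_enc = np.stack([task.encode_trial(c) for c in contexts]).astype(np.float32)
    stim_units = np.zeros((len(stimuli), task.N_INPUT_UNITS), dtype=np.float32)
    for si, s in enumerate(stimuli):
        stim_units[si, list(s.unit_indices)] = 1.0
    targets = task.response_table()
    return ctx_enc, stim_units, targets


def train_ann(config: AnnConfig) -> tuple[AnnParameters, TrainingTrace]:
    """Train with Adam (beta1=0.9, beta2=0.999, eps=1e-8) on MSE loss.

    Each mini-batch contains every context three times (for batch 192) with
    independently sampled stimuli.  Accuracy is argmax over the four sigmoid
    outputs (ties to the lowest index).  Raises :class:`TrainingError` if the
    trailing-window stop rule is unmet at ``max_batches``.  With
    ``shuffle_labels`` the 16384-entry trial->response table is permuted once
    before training (the memorization control), and the stop rule is not
    expected to be reached.
    """
    rng = np.random.default_rng(config.seed)
    params = init_parameters(config, rng)
    ctx_enc, stim_units, targets = _build_trial_bank()
    if config.shuffle_labels:
        flat = targets.ravel().copy()
        rng.shuffle(flat)
        targets = flat.reshape(targets.shape)
    eye4 = np.eye(config.n_output, dtype=np.float32)

    reps = config.batch_size // 64
    ctx_idx = np.repeat(np.arange(64), reps)
    Xctx = ctx_enc[ctx_idx]

    lr, b1m, b2m, eps = config.learning_rate, 0.9, 0.999, 1e-8
    plist = params.as_list()
    m = [np.zeros_like(p) for p in plist]
    v = [np.zeros_like(p) for p in plist]
    noise_sd = np.float32(np.sqrt(config.noise_variance))

    losses = np.empty(config.max_batches, dtype=np.float64)
    accs = np.empty(config.max_batches, dtype=np.float64)
    B = config.batch_size
    t = 0
    for batch in range(config.max_batches):
        stim_idx = rng.integers(0, 256, size=B)
        X = Xctx + stim_units[stim_idx]
        tgt_idx = targets[ctx_idx, stim_idx]
        T = eye4[tgt_idx]

        H1 = np.maximum(X @ params.W_in + params.b1, 0.0)
        I = rng.normal(0.0, noise_sd, size=H1.shape).astype(np.float32)
        H1in = H1 + I
        Z2 = H1in @ params.W_h + params.b2
        H2 = np.maximum(Z2, 0.0)
        Z3 = H2 @ params.W_out + params.b3
        Y = 1.0 / (1.0 + np.exp(-Z3))

        diff = Y - T
        losses[batch] = float(np.mean(diff**2))
        accs[batch] = float(np.mean(np.argmax(Y, axis=1) == tgt_idx))

        dZ3 = (2.0 / diff.size) * diff * Y * (1.0 - Y)
        gW_out = H2.T @ dZ3
        gb3 = dZ3.sum(axis=0)
        dH2 = dZ3 @ params.W_out.T
        dZ2 = dH2 * (Z2 > 0)
        gW_h = H1in.T @ dZ2
        gb2 = dZ2.sum(axis=0)
        dH1 = dZ2 @ params.W_h.T
        dZ1 = dH1 * (H1 > 0)
        gW_in = X.T @ dZ1
        gb1 = dZ1.sum(axis=0)

        t += 1
        bc1 = 1.0 - b1m**t
        bc2 = 1.0 - b2m**t
        for p, g, mi, vi in zip(plist, [gW_in, gb1, gW_h, gb2, gW_out, gb3], m, v):
            mi *= b1m
            mi += (1 - b1m) * g
            vi *= b2m
            vi += (1 - b2m) * g * g
            p -= lr * (mi / bc1) / (np.sqrt(vi / bc2) + eps)

        if (
            batch + 1 >= config.stop_window
            and accs[batch + 1 - config.stop_window : batch + 1].mean()
            > config.stop_accuracy
        ):
            stop = batch + 1
            return params, TrainingTrace(losses[:stop], accs[:stop], stop)

    err = TrainingError(
        f"stop rule (trailing {config.stop_window}-batch accuracy > "
        f"{config.stop_accuracy:.3f}) unmet after {config.max_batches} batches; "
        f"final trailing accuracy = {accs[-config.stop_window:].mean():.4f}"
    )
    err.trace = TrainingTrace(losses, accs, config.max_batches)
    err.params = params
    raise err


def exhaustive_accuracy(params: AnnParameters) -> float:
    """Argmax accuracy over all 16384 trial types, noise off."""
    ctx_enc, stim_units, targets = _build_trial_bank()
    correct = 0
    for ci in range(64):
        X = ctx_enc[ci][None, :] + stim_units
        Y, _, _ = forward_ann(params, X, noise_on=False)
        correct += int(np.sum(np.argmax(Y, axis=1) == targets[ci]))
    return correct / targets.size


def probe_hidden_rsm(params: AnnParameters) -> np.ndarray:
    """28x28 Pearson RSM of second-hidden-layer responses to one-hot input probes
    (12 rules then 16 stimulus-pair conditions; noise off)."""
    probes = np.eye(task.N_INPUT_UNITS, dtype=np.float32)
    _, _, H2 = forward_ann(params, probes, noise_on=False)
    return np.corrcoef(H2.astype(np.float64))


def shuffled_parameter_null_rsm(
    params: AnnParameters, n_perm: int = 10000, seed: int = 0
) -> np.ndarray:
    """Mean probe RSM over permutations that shuffle every weight matrix and bias
    vector within itself (preserving each layer's parameter distribution)."""
    rng = np.random.default_rng(seed)
    acc = np.zeros((task.N_INPUT_UNITS, task.N_INPUT_UNITS), dtype=np.float64)
    shuffled = AnnParameters(*[p.copy() for p in params.as_list()])
    for _ in range(n_perm):
        for src, dst in zip(params.as_list(), shuffled.as_list()):
            flat = src.ravel()[rng.permutation(src.size)]
            dst[...] = flat.reshape(src.shape)
        acc += probe_hidden_rsm(shuffled)
    return acc / n_perm
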