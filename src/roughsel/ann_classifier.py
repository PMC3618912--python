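"""One-hidden-layer sigmoid MLP trained by per-pattern backprop with momentum.

The network evaluates candidate reducts: the table is min-max normalized
column-wise to [0, 1] (decision column included, giving the regression
target), restricted to the reduct's columns, and fit by stochastic
gradient descent on the squared error with a momentum term.  A single
sigmoid output neuron carries the normalized class code; prediction maps
the output back to the nearest normalized class target.

Update rule for every weight w (and bias), with learning rate λ and
momentum μ::

    Δw(t) = λ · δ · input + μ · Δw(t−1),   w(t) = w(t−1) + Δw(t)

where δ_out = C(1−C)(target − C) at the output and the hidden deltas
back-propagate through the output weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MLPConfig",
    "MLPModel",
    "BackpropState",
    "NormalizationParams",
    "normalize",
    "init_model",
    "forward",
    "backprop_step",
    "train",
    "predict",
    "save_weights",
    "load_weights",
]


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class MLPConfig:
    n_inputs: int
    n_hidden: int = 4
    learning_rate: float = 0.5
    momentum: float = 0.8
    max_epochs: int = 1000
    target_mse: float = 0.0
    weight_init_range: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.n_hidden < 1 or self.n_inputs < 1:
            raise ValueError("need at least one input and one hidden neuron")


@dataclass
class MLPModel:
    """Weights, biases, and momentum buffers of a 1-hidden-layer network."""

    w_in: np.ndarray  # (n_inputs, n_hidden)
    w_out: np.ndarray  # (n_hidden,)
    b_hidden: np.ndarray  # (n_hidden,)
    b_out: float
    prev_dw_in: np.ndarray = field(default=None)  # type: ignore[assignment]
    prev_dw_out: np.ndarray = field(default=None)  # type: ignore[assignment]
    prev_db_hidden: np.ndarray = field(default=None)  # type: ignore[assignment]
    prev_db_out: float = 0.0

    def __post_init__(self) -> None:
        if self.prev_dw_in is None:
            self.prev_dw_in = np.zeros_like(self.w_in)
        if self.prev_dw_out is None:
            self.prev_dw_out = np.zeros_like(self.w_out)
        if self.prev_db_hidden is None:
            self.prev_db_hidden = np.zeros_like(self.b_hidden)

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_in.shape[1]

    def copy(self) -> "MLPModel":
        return MLPModel(
            self.w_in.copy(), self.w_out.copy(), self.b_hidden.copy(), self.b_out,
            self.prev_dw_in.copy(), self.prev_dw_out.copy(),
            self.prev_db_hidden.copy(), self.prev_db_out,
        )


@dataclass(frozen=True)
class BackpropState:
    net_hidden: np.ndarray
    out_hidden: np.ndarray
    out_value: float


@dataclass(frozen=True)
class NormalizationParams:
    a_min: np.ndarray
    a_max: np.ndarray


def normalize(
    matrix: np.ndarray, params: NormalizationParams | None = None
) -> tuple[np.ndarray, NormalizationParams]:
    """Column-wise min-max scaling to [0, 1].

    With ``params`` given, the stored minima/maxima are applied (values
    outside the fitted range scale past [0, 1] accordingly); otherwise
    they are fitted from ``matrix``.  A constant column maps to all zeros.
    """
    m = np.asarray(matrix, dtype=float)
    if params is None:
        params = NormalizationParams(m.min(axis=0), m.max(axis=0))
    span = params.a_max - params.a_min
    out = np.zeros_like(m)
    nonconst = span != 0
    out[:, nonconst] = (m[:, nonconst] - params.a_min[nonconst]) / span[nonconst]
    return out, params


def init_model(config: MLPConfig) -> MLPModel:
    rng = np.random.default_rng(config.seed)
    r = config.weight_init_range
    return MLPModel(
        w_in=rng.uniform(-r, r, size=(config.n_inputs, config.n_hidden)),
        w_out=rng.uniform(-r, r, size=config.n_hidden),
        b_hidden=rng.uniform(-r, r, size=config.n_hidden),
        b_out=float(rng.uniform(-r, r)),
    )


def forward(model: MLPModel, x: Sequence[float]) -> BackpropState:
    """Forward pass: NET_j = Σ x_i W_ij, C_j = σ(NET_j + β_j), same at the output."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_inputs,):
        raise ValueError(f"expected input of length {model.n_inputs}, got {x.shape}")
    net_hidden = x @ model.w_in
    out_hidden = _sigmoid(net_hidden + model.b_hidden)
    out_value = float(_sigmoid(out_hidden @ model.w_out + model.b_out))
    return BackpropState(net_hidden, out_hidden, out_value)


def backprop_step(model: MLPModel, x: Sequence[float], target: float, config: MLPConfig) -> float:
    """One per-pattern update, in place; returns the squared error before it.

    δ_out = C(1−C)(target−C); δ_hidden_j = C_j(1−C_j)·δ_out·A_j.  Each
    weight change adds μ times its previous change (momentum), and the
    buffers are refreshed with the applied changes.
    """
    x = np.asarray(x, dtype=float)
    state = forward(model, x)
    lam, mu = config.learning_rate, config.momentum
    err = target - state.out_value
    delta_out = state.out_value * (1.0 - state.out_value) * err
    delta_hidden = state.out_hidden * (1.0 - state.out_hidden) * (delta_out * model.w_out)

    dw_out = lam * delta_out * state.out_hidden + mu * model.prev_dw_out
    db_out = lam * delta_out + mu * model.prev_db_out
    dw_in = lam * np.outer(x, delta_hidden) + mu * model.prev_dw_in
    db_hidden = lam * delta_hidden + mu * model.prev_db_hidden

    model.w_out += dw_out
    model.b_out += db_out
    model.w_in += dw_in
    model.b_hidden += db_hidden
    model.prev_dw_out, model.prev_db_out = dw_out, db_out
    model.prev_dw_in, model.prev_db_hidden = dw_in, db_hidden
    return err * err


def train(
    model: MLPModel,
    inputs: np.ndarray,
    targets: Sequence[float],
    config: MLPConfig,
) -> list[float]:
    """Epoch loop over seeded-shuffled patterns; returns the per-epoch MSE log.

    Stops at ``max_epochs`` or once the epoch MSE drops to ``target_mse``.
    """
    inputs = np.asarray(inputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if inputs.shape[0] != targets.shape[0]:
        raise ValueError("inputs and targets disagree on the number of patterns")
    if inputs.shape[0] == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    log: list[float] = []
    for _ in range(config.max_epochs):
        order = rng.permutation(inputs.shape[0])
        sse = 0.0
        for idx in order:
            sse += backprop_step(model, inputs[idx], float(targets[idx]), config)
        mse = sse / inputs.shape[0]
        log.append(mse)
        if mse <= config.target_mse:
            break
    return log


def predict(model: MLPModel, x: Sequence[float], class_targets: dict[int, float]) -> int:
    """Class whose normalized target is nearest the output (ties → lower code)."""
    out = forward(model, x).out_value
    return min(sorted(class_targets), key=lambda c: (abs(class_targets[c] - out), c))


def save_weights(model: MLPModel, path) -> None:
    """Plain-text dump: header `n_inputs n_hidden n_outputs`, then matrices."""
    with open(path, "w") as fh:
        fh.write(f"{model.n_inputs} {model.n_hidden} 1\n")
        for row in model.w_in:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
        fh.write(" ".join(repr(float(v)) for v in model.w_out) + "\n")
        fh.write(" ".join(repr(float(v)) for v in model.b_hidden) + "\n")
        fh.write(repr(float(model.b_out)) + "\n")


def load_weights(path) -> MLPModel:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    try:
        n_in, n_hid, n_out = (int(v) for v in lines[0].split())
        if n_out != 1:
            raise ValueError("only single-output networks are supported")
        expected = 1 + n_in + 3
        if len(lines) != expected:
            raise ValueError(f"expected {expected} lines, found {len(lines)}")
        w_in = np.array([[float(v) for v in lines[1 + i].split()] for i in range(n_in)])
        if w_in.shape != (n_in, n_hid):
            raise ValueError("input weight matrix shape disagrees with header")
        w_out = np.array([float(v) for v in lines[1 + n_in].split()])
        b_hidden = np.array([float(v) for v in lines[2 + n_in].split()])
        if w_out.shape != (n_hid,) or b_hidden.shape != (n_hid,):
            raise ValueError("hidden-layer vector length disagrees with header")
        b_out = float(lines[3 + n_in])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed weight file {path}: {exc}") from exc
    return MLPModel(w_in, w_out, b_hidden, b_out)
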