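"""Parsimonious two-layer ReLU network for the XOR mixture task.

The architecture is deliberately minimal: K hidden ReLU units (K = 4 by
default, the smallest width that can represent the XOR solution), a linear
readout, and no bias terms in either layer.  The output is a single logit
f(x) = sum_k w2_k * relu(W1_k . x), trained online with binary
cross-entropy and plain SGD, one stimulus per step.

Because there are no biases, a stimulus that closes every ReLU gate yields
a logit of exactly zero.  That outcome is treated as a third response —
abstention — and counts as an error, so a "dead" network scores below the
usual 50% chance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import LabeledBatch, TaskDistribution

__all__ = [
    "NetworkParams",
    "PredictionOutcome",
    "init_network",
    "forward",
    "batch_logits",
    "sgd_step",
    "accuracy",
    "bce_loss",
    "xor_network",
]

DEFAULT_K = 4
DEFAULT_INIT_STD = 0.05


@dataclass(frozen=True)
class NetworkParams:
    """Weights of the two-layer network: W1 is (K, d), w2 is (K,). No biases."""

    W1: np.ndarray
    w2: np.ndarray

    def __post_init__(self) -> None:
        W1 = np.asarray(self.W1, dtype=float)
        w2 = np.asarray(self.w2, dtype=float)
        if W1.ndim != 2 or w2.ndim != 1 or W1.shape[0] != w2.shape[0]:
            raise ValueError("W1 must be (K, d) and w2 length K")
        if not (np.all(np.isfinite(W1)) and np.all(np.isfinite(w2))):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "W1", W1)
        object.__setattr__(self, "w2", w2)

    @property
    def K(self) -> int:
        return self.w2.shape[0]

    @property
    def d(self) -> int:
        return self.W1.shape[1]

    def to_flat_dict(self) -> dict[str, float]:
        out = {f"W1_{k}_{j}": float(self.W1[k, j]) for k in range(self.K) for j in range(self.d)}
        out.update({f"w2_{k}": float(self.w2[k]) for k in range(self.K)})
        return out

    @classmethod
    def from_flat_dict(cls, flat: dict[str, float]) -> "NetworkParams":
        K = 1 + max(int(key.split("_")[1]) for key in flat if key.startswith("w2_"))
        d = 1 + max(int(key.rsplit("_", 1)[1]) for key in flat if key.startswith("W1_"))
        W1 = np.array([[flat[f"W1_{k}_{j}"] for j in range(d)] for k in range(K)])
        w2 = np.array([flat[f"w2_{k}"] for k in range(K)])
        return cls(W1=W1, w2=w2)


@dataclass(frozen=True)
class PredictionOutcome:
    """A single prediction: the raw logit and the three-way decision.

    decision is "label1" for a positive logit, "label0" for a negative one
    and "abstain" when the logit is exactly zero (all gates closed).
    """

    logit: float
    decision: str


def init_network(
    K: int = DEFAULT_K,
    d: int = 100,
    init_std: float = DEFAULT_INIT_STD,
    seed: int | np.random.Generator | None = None,
) -> NetworkParams:
    """Gaussian(0, init_std^2) initialization of both layers, seeded."""
    if K < 1:
        raise ValueError("K must be positive")
    if d < 2:
        raise ValueError("d must be >= 2")
    if init_std <= 0:
        raise ValueError(f"init_std must be positive, got {init_std}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    W1 = rng.normal(0.0, init_std, size=(K, d))
    w2 = rng.normal(0.0, init_std, size=K)
    return NetworkParams(W1=W1, w2=w2)


def _decide(logit: float) -> str:
    if logit > 0:
        return "label1"
    if logit < 0:
        return "label0"
    return "abstain"


def forward(params: NetworkParams, x: np.ndarray) -> PredictionOutcome:
    """Logit and three-way decision for a single stimulus."""
    x = np.asarray(x, dtype=float)
    if x.shape != (params.d,):
        raise ValueError(f"x must have shape ({params.d},), got {x.shape}")
    h = np.maximum(params.W1 @ x, 0.0)
    logit = float(params.w2 @ h)
    return PredictionOutcome(logit=logit, decision=_decide(logit))


def batch_logits(params: NetworkParams, inputs: np.ndarray) -> np.ndarray:
    """Logits for an (n, d) stimulus matrix."""
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if inputs.shape[1] != params.d:
        raise ValueError(f"inputs must have {params.d} columns")
    h = np.maximum(inputs @ params.W1.T, 0.0)
    return h @ params.w2


def bce_loss(params: NetworkParams, x: np.ndarray, y: int) -> float:
    """Binary cross-entropy of sigmoid(f(x)) against label y."""
    logit = forward(params, x).logit
    # log(1 + exp(-|z|)) form for numerical stability
    return float(np.logaddexp(0.0, -logit) + (1 - y) * logit)


def sgd_step(
    params: NetworkParams, x: np.ndarray, y: int, eta_step: float
) -> NetworkParams:
    """One online SGD update on the BCE loss; both layers train.

    With p = sigmoid(f(x)) and delta = p - y:
      w2   <- w2   - eta_step * delta * h
      W1_k <- W1_k - eta_step * delta * w2_k * [W1_k . x > 0] * x
    using the pre-update w2 in the first-layer gradient.
    """
    if eta_step <= 0:
        raise ValueError(f"eta_step must be positive, got {eta_step}")
    if y not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {y!r}")
    x = np.asarray(x, dtype=float)
    if x.shape != (params.d,):
        raise ValueError(f"x must have shape ({params.d},), got {x.shape}")
    pre = params.W1 @ x
    h = np.maximum(pre, 0.0)
    logit = params.w2 @ h
    p = 1.0 / (1.0 + np.exp(-logit))
    delta = p - y
    w2_new = params.w2 - eta_step * delta * h
    gate = (pre > 0).astype(float)
    W1_new = params.W1 - eta_step * delta * (params.w2 * gate)[:, None] * x[None, :]
    return NetworkParams(W1=W1_new, w2=w2_new)


def accuracy(params: NetworkParams, batch: LabeledBatch) -> float:
    """Fraction of trials decided correctly; abstentions count as errors."""
    if len(batch) < 1:
        raise ValueError("batch must be non-empty")
    logits = batch_logits(params, batch.inputs)
    correct = ((logits > 0) & (batch.labels == 1)) | ((logits < 0) & (batch.labels == 0))
    return float(np.mean(correct))


def xor_network(task: TaskDistribution, scale: float = 1.0) -> NetworkParams:
    """The hand-constructed parsimonious XOR solution for a task geometry.

    Four units aligned with ±mu0 and ±mu1; the readout adds the mu1 pair
    and subtracts the mu0 pair, so the logit is |x.mu1| - |x.mu0| — the
    Bayes-optimal decision rule for the XOR mixture.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    W1 = np.stack([task.mu1, -task.mu1, task.mu0, -task.mu0]) * scale
    w2 = np.array([1.0, 1.0, -1.0, -1.0]) * scale
    return NetworkParams(W1=W1, w2=w2)
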