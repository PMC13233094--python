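"""XOR Gaussian-mixture discrimination task.

Stimuli live in R^d and are drawn from four isotropic Gaussian clusters
centered at +mu0, -mu0, +mu1 and -mu1, where mu0 and mu1 are orthonormal.
The two clusters on the mu_y axis share label y, so the label structure is
an XOR over the two feature axes: diagonally opposite clusters share a
label and the problem is not linearly separable.  The cluster standard
deviation sigma is the single difficulty knob — larger sigma means more
overlap between the mixtures and a harder discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TaskDistribution",
    "LabeledBatch",
    "make_task",
    "sample_batch",
    "bayes_decision",
    "bayes_accuracy",
]

_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class TaskDistribution:
    """Geometry of the XOR mixture: dimension and the two orthonormal class axes.

    Label 0 stimuli are centred on ±mu0, label 1 stimuli on ±mu1.
    """

    d: int
    mu0: np.ndarray
    mu1: np.ndarray

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError(f"d must be >= 2, got {self.d}")
        mu0 = np.asarray(self.mu0, dtype=float)
        mu1 = np.asarray(self.mu1, dtype=float)
        if mu0.shape != (self.d,) or mu1.shape != (self.d,):
            raise ValueError("mu0 and mu1 must be vectors of length d")
        if abs(np.linalg.norm(mu0) - 1.0) > _ORTHO_TOL:
            raise ValueError("mu0 must be a unit vector")
        if abs(np.linalg.norm(mu1) - 1.0) > _ORTHO_TOL:
            raise ValueError("mu1 must be a unit vector")
        if abs(float(mu0 @ mu1)) > _ORTHO_TOL:
            raise ValueError("mu0 and mu1 must be orthogonal")
        object.__setattr__(self, "mu0", mu0)
        object.__setattr__(self, "mu1", mu1)

    @property
    def centers(self) -> np.ndarray:
        """(2, d) array with row y holding mu_y."""
        return np.stack([self.mu0, self.mu1])


@dataclass(frozen=True)
class LabeledBatch:
    """A batch of labelled stimuli.

    ``center_signs`` records which mixture component (+mu_y or -mu_y)
    generated each stimulus; ``sigmas`` the per-trial noise level.
    """

    inputs: np.ndarray
    labels: np.ndarray
    center_signs: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self) -> None:
        inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        labels = np.asarray(self.labels, dtype=int)
        signs = np.asarray(self.center_signs, dtype=int)
        sigmas = np.asarray(self.sigmas, dtype=float)
        n = inputs.shape[0]
        if n < 1:
            raise ValueError("batch must contain at least one trial")
        if not (labels.shape == signs.shape == sigmas.shape == (n,)):
            raise ValueError("all per-trial fields must have equal length n")
        if not np.all(np.isfinite(inputs)):
            raise ValueError("inputs must be finite")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if not np.isin(signs, (-1, 1)).all():
            raise ValueError("center_signs must be +1 or -1")
        if (sigmas < 0).any():
            raise ValueError("sigmas must be non-negative")
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "center_signs", signs)
        object.__setattr__(self, "sigmas", sigmas)

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        d = self.inputs.shape[1]
        frame = pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "label": self.labels,
                "center_sign": self.center_signs,
                "sigma": self.sigmas,
            }
        )
        coords = pd.DataFrame(self.inputs, columns=[f"x_{j}" for j in range(d)])
        return pd.concat([frame, coords], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabeledBatch":
        frame = pd.read_csv(path)
        xcols = [c for c in frame.columns if c.startswith("x_")]
        return cls(
            inputs=frame[xcols].to_numpy(float),
            labels=frame["label"].to_numpy(int),
            center_signs=frame["center_sign"].to_numpy(int),
            sigmas=frame["sigma"].to_numpy(float),
        )


def make_task(d: int, seed: int | None = None, canonical: bool = False) -> TaskDistribution:
    """Build a task geometry: two orthonormal class axes in R^d.

    With ``canonical`` the axes are the first two standard basis vectors;
    otherwise a seeded random orthonormal pair (Gram-Schmidt on two
    Gaussian vectors).
    """
    if d < 2:
        raise ValueError(f"two orthogonal unit vectors require d >= 2, got d={d}")
    if canonical:
        mu0 = np.zeros(d)
        mu1 = np.zeros(d)
        mu0[0] = 1.0
        mu1[1] = 1.0
    else:
        rng = np.random.default_rng(seed)
        # Gram-Schmidt; retry the (measure-zero) degenerate draws.
        while True:
            a, b = rng.standard_normal((2, d))
            na = np.linalg.norm(a)
            if na < 1e-12:
                continue
            mu0 = a / na
            b = b - (b @ mu0) * mu0
            nb = np.linalg.norm(b)
            if nb < 1e-12:
                continue
            mu1 = b / nb
            break
    return TaskDistribution(d=d, mu0=mu0, mu1=mu1)


def sample_batch(
    task: TaskDistribution,
    sigma: float,
    n: int,
    subset: str = "both",
    seed: int | np.random.Generator | None = None,
) -> LabeledBatch:
    """Sample n labelled stimuli at difficulty sigma.

    For each trial: y ~ Bern(1/2); the component sign s is a fair coin
    (``subset="both"``), forced to +1 (``"plus"``) or -1 (``"minus"``);
    x = s * mu_y + sigma * g with g standard Gaussian in R^d.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    if subset not in ("both", "plus", "minus"):
        raise ValueError(f"subset must be 'both', 'plus' or 'minus', got {subset!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=n)
    if subset == "both":
        signs = rng.choice((-1, 1), size=n)
    else:
        signs = np.full(n, 1 if subset == "plus" else -1)
    noise = rng.standard_normal((n, task.d))
    inputs = signs[:, None] * task.centers[labels] + sigma * noise
    return LabeledBatch(
        inputs=inputs,
        labels=labels,
        center_signs=signs,
        sigmas=np.full(n, float(sigma)),
    )


def bayes_decision(task: TaskDistribution, inputs: np.ndarray) -> np.ndarray:
    """Bayes-optimal labels for stimuli under the XOR mixture.

    Both label-conditional densities share the isotropic covariance, so the
    likelihood ratio reduces to comparing cosh(x·mu_y / sigma^2) across the
    two labels, i.e. the decision is label 1 iff |x·mu1| > |x·mu0|.  The
    rule is sigma-free and invariant under x -> -x.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    a = np.abs(inputs @ task.mu0)
    b = np.abs(inputs @ task.mu1)
    return (b > a).astype(int)


def bayes_accuracy(
    task: TaskDistribution,
    sigma: float,
    n_mc: int = 100_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo accuracy of the Bayes-optimal classifier at difficulty sigma.

    This is an upper bound (up to MC error) on the accuracy of any learner
    evaluated at the same sigma.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if n_mc < 1:
        raise ValueError("n_mc must be positive")
    batch = sample_batch(task, sigma=sigma, n=n_mc, subset="both", seed=seed)
    predicted = bayes_decision(task, batch.inputs)
    return float(np.mean(predicted == batch.labels))
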