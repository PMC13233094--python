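"""Training curricula: per-step difficulty and feature-subset exposure.

Four named schedules over T online-SGD steps:

* ``ascending`` — sigma rises linearly from sigma_easy to sigma_hard.
* ``hard`` — sigma fixed at sigma_hard.
* ``random`` — the ascending difficulty multiset in a seeded random order.
* ``bad`` — random difficulty order, but early trials expose only one
  feature subset (one mixture component per class, e.g. {+mu0, +mu1}) and
  late trials only the other; the probability of the initial subset ramps
  linearly from 1 to 0 across training.

Every schedule carries ``sigma_t`` and ``p_plus_t``, the per-step
probability that the trial is drawn from the "+" subset.  For the three
unblocked curricula p_plus is identically 0.5 (fair coin over components).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CURRICULA",
    "CurriculumSchedule",
    "ascending_schedule",
    "hard_schedule",
    "random_schedule",
    "bad_schedule",
    "make_schedule",
]

CURRICULA = ("ascending", "hard", "random", "bad")

SIGMA_EASY = 0.1
SIGMA_HARD = 0.65


@dataclass(frozen=True)
class CurriculumSchedule:
    name: str
    sigma_t: np.ndarray
    p_plus_t: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in CURRICULA:
            raise ValueError(f"unknown curriculum {self.name!r}; expected one of {CURRICULA}")
        sigma_t = np.asarray(self.sigma_t, dtype=float)
        p_plus_t = np.asarray(self.p_plus_t, dtype=float)
        if sigma_t.ndim != 1 or sigma_t.shape != p_plus_t.shape:
            raise ValueError("sigma_t and p_plus_t must be 1-d arrays of equal length")
        if sigma_t.size < 1:
            raise ValueError("schedule must have at least one step")
        if (sigma_t < 0).any():
            raise ValueError("sigma_t must be non-negative")
        if ((p_plus_t < 0) | (p_plus_t > 1)).any():
            raise ValueError("p_plus_t must lie in [0, 1]")
        object.__setattr__(self, "sigma_t", sigma_t)
        object.__setattr__(self, "p_plus_t", p_plus_t)

    @property
    def T(self) -> int:
        return self.sigma_t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, self.T + 1),
                "sigma": self.sigma_t,
                "p_plus": self.p_plus_t,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _linear_ramp(T: int, start: float, stop: float) -> np.ndarray:
    # for T == 1 the schedule sits at its endpoint
    if T == 1:
        return np.array([stop], dtype=float)
    return np.linspace(start, stop, T)


def _check_range(T: int, sigma_easy: float, sigma_hard: float) -> None:
    if T < 1:
        raise ValueError(f"T must be positive, got {T}")
    if sigma_easy < 0:
        raise ValueError("sigma_easy must be non-negative")
    if sigma_easy > sigma_hard:
        raise ValueError(
            f"sigma_easy ({sigma_easy}) must not exceed sigma_hard ({sigma_hard})"
        )


def ascending_schedule(
    T: int, sigma_easy: float = SIGMA_EASY, sigma_hard: float = SIGMA_HARD
) -> CurriculumSchedule:
    """Difficulty rises linearly from sigma_easy to sigma_hard."""
    _check_range(T, sigma_easy, sigma_hard)
    return CurriculumSchedule(
        name="ascending",
        sigma_t=_linear_ramp(T, sigma_easy, sigma_hard),
        p_plus_t=np.full(T, 0.5),
    )


def hard_schedule(T: int, sigma_hard: float = SIGMA_HARD) -> CurriculumSchedule:
    """Difficulty pinned at sigma_hard throughout."""
    if T < 1:
        raise ValueError(f"T must be positive, got {T}")
    return CurriculumSchedule(
        name="hard",
        sigma_t=np.full(T, float(sigma_hard)),
        p_plus_t=np.full(T, 0.5),
    )


def random_schedule(
    T: int,
    sigma_easy: float = SIGMA_EASY,
    sigma_hard: float = SIGMA_HARD,
    seed: int | np.random.Generator | None = None,
) -> CurriculumSchedule:
    """The ascending difficulty multiset, presented in seeded random order."""
    _check_range(T, sigma_easy, sigma_hard)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma_t = rng.permutation(_linear_ramp(T, sigma_easy, sigma_hard))
    return CurriculumSchedule(name="random", sigma_t=sigma_t, p_plus_t=np.full(T, 0.5))


def bad_schedule(
    T: int,
    sigma_easy: float = SIGMA_EASY,
    sigma_hard: float = SIGMA_HARD,
    seed: int | np.random.Generator | None = None,
    crossfade: str = "stochastic",
) -> CurriculumSchedule:
    """Random difficulty order with blocked feature-subset exposure.

    The "+" subset {+mu0, +mu1} dominates early trials and the "-" subset
    {-mu0, -mu1} late trials.  With ``crossfade="stochastic"`` (default)
    p_plus ramps linearly from 1 at step 1 to 0 at step T and the subset is
    realised per step by a Bernoulli draw; ``crossfade="blocked"`` instead
    uses a deterministic half split (p_plus exactly 1 then 0).
    """
    _check_range(T, sigma_easy, sigma_hard)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma_t = rng.permutation(_linear_ramp(T, sigma_easy, sigma_hard))
    if crossfade == "stochastic":
        # T == 1 degenerates to pure initial-subset exposure
        p_plus_t = np.linspace(1.0, 0.0, T) if T > 1 else np.array([1.0])
    elif crossfade == "blocked":
        p_plus_t = (np.arange(T) < (T + 1) // 2).astype(float)
    else:
        raise ValueError(f"crossfade must be 'stochastic' or 'blocked', got {crossfade!r}")
    return CurriculumSchedule(name="bad", sigma_t=sigma_t, p_plus_t=p_plus_t)


def make_schedule(
    name: str,
    T: int,
    sigma_easy: float = SIGMA_EASY,
    sigma_hard: float = SIGMA_HARD,
    seed: int | np.random.Generator | None = None,
) -> CurriculumSchedule:
    """Dispatch on the curriculum name."""
    if name == "ascending":
        return ascending_schedule(T, sigma_easy, sigma_hard)
    if name == "hard":
        return hard_schedule(T, sigma_hard)
    if name == "random":
        return random_schedule(T, sigma_easy, sigma_hard, seed=seed)
    if name == "bad":
        return bad_schedule(T, sigma_easy, sigma_hard, seed=seed)
    raise ValueError(f"unknown curriculum {name!r}; expected one of {CURRICULA}")
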