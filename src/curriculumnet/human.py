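"""Synthetic random-dot-kinematogram (RDK) study generator.

The behavioral arm of the study shows participants clouds of 600 moving,
colored dots and asks for one of two key presses ('F'/'J').  The correct
key depends on the *conjunction* of majority motion direction (up/down)
and majority color (blue/yellow) under an XOR rule: e.g. yellow-up and
blue-down share a key, yellow-down and blue-up share the other.  Motion
coherence (fraction of coherently moving dots, 40-100%) is the difficulty
knob manipulated by the curricula; color coherence (66-100%) is
counterbalanced but not curriculum-structured.

This module generates counterbalanced trial tables for the four curricula
(100 training + 16 hard test trials per participant) and simulates
synthetic participants responding to them, so the human-side analysis
pipeline runs end-to-end without any data download.  The synthetic
responder is the same parsimonious network that models the simulated
populations, operating on a 2-d percept (signed motion and color
coherence) corrupted by Gaussian perceptual noise, with a lapse rate and a
forced guess whenever the network abstains (humans must answer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import network as net
from .curricula import CURRICULA
from .stats import achiever_split, bin_trajectory, pairwise_logistic_contrasts

__all__ = [
    "RDKTrial",
    "HumanDesign",
    "HumanDataset",
    "ResponderParams",
    "design_experiment",
    "xor_responder_params",
    "simulate_participant",
    "generate_study",
    "analyze_study",
    "read_participant_csv",
]

N_TRAIN = 100
N_TEST = 16
MOTION_COHERENCE_RANGE = (0.40, 1.00)
COLOR_COHERENCE_RANGE = (0.66, 1.00)
N_DOTS = 600
DOT_RADIUS_PX = 2
SPEED_PX_PER_FRAME = 1
TRAIN_BIN_SIZE = 20

# the four "one feature dimension held constant" subsets a bad-curriculum
# block can be built from: (feature, fixed sign)
_BAD_SUBSETS = (("color", -1), ("color", 1), ("motion", 1), ("motion", -1))

_COLOR_NAME = {1: "blue", -1: "yellow"}
_MOTION_NAME = {1: "up", -1: "down"}


@dataclass(frozen=True)
class RDKTrial:
    """One random-dot-kinematogram trial."""

    phase: str  # "train" or "test"
    index: int  # 1-based within phase
    motion_coherence: float
    motion_sign: int  # +1 up, -1 down
    color_coherence: float
    color_sign: int  # +1 blue, -1 yellow
    correct_response: str  # "F" or "J"
    n_dots: int = N_DOTS
    dot_radius_px: int = DOT_RADIUS_PX
    speed_px_per_frame: int = SPEED_PX_PER_FRAME

    def __post_init__(self) -> None:
        lo, hi = MOTION_COHERENCE_RANGE
        if not lo - 1e-9 <= self.motion_coherence <= hi + 1e-9:
            raise ValueError(f"motion coherence {self.motion_coherence} outside [{lo}, {hi}]")
        lo, hi = COLOR_COHERENCE_RANGE
        if not lo - 1e-9 <= self.color_coherence <= hi + 1e-9:
            raise ValueError(f"color coherence {self.color_coherence} outside [{lo}, {hi}]")
        if self.motion_sign not in (-1, 1) or self.color_sign not in (-1, 1):
            raise ValueError("signs must be +1 or -1")
        if self.correct_response not in ("F", "J"):
            raise ValueError("correct_response must be 'F' or 'J'")

    @property
    def pairing(self) -> str:
        return f"{_COLOR_NAME[self.color_sign]}-{_MOTION_NAME[self.motion_sign]}"

    @property
    def xor_sign(self) -> int:
        return self.motion_sign * self.color_sign


@dataclass(frozen=True)
class HumanDesign:
    """A single participant's counterbalanced trial sequence."""

    curriculum_name: str
    participant_id: int
    seed: int
    response_mapping: int  # +1: xor_sign +1 -> 'J'; -1: xor_sign +1 -> 'F'
    trials: tuple[RDKTrial, ...]
    subset_order: tuple | None = None  # ((feature, sign) first, (feature, sign) second)

    def __post_init__(self) -> None:
        n_train = sum(t.phase == "train" for t in self.trials)
        n_test = sum(t.phase == "test" for t in self.trials)
        if n_train != N_TRAIN or n_test != N_TEST:
            raise ValueError(f"expected {N_TRAIN} train + {N_TEST} test trials")
        for t in self.trials:
            expected = "J" if t.xor_sign * self.response_mapping > 0 else "F"
            if t.correct_response != expected:
                raise ValueError("trial violates the XOR response rule")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participant_id,
                "curriculum": self.curriculum_name,
                "phase": [t.phase for t in self.trials],
                "trial": [t.index for t in self.trials],
                "motion_coherence": [t.motion_coherence for t in self.trials],
                "motion_sign": [t.motion_sign for t in self.trials],
                "color_coherence": [t.color_coherence for t in self.trials],
                "color_sign": [t.color_sign for t in self.trials],
                "pairing": [t.pairing for t in self.trials],
                "correct_response": [t.correct_response for t in self.trials],
            }
        )


@dataclass(frozen=True)
class ResponderParams:
    """Synthetic participant: a d=2 parsimonious network plus human-like noise.

    nu is the Gaussian perceptual-noise SD applied to the 2-d percept,
    lapse the probability that the intended response is inverted, eta the
    per-trial learning rate of the online BCE/SGD update.
    """

    nu: float = 0.1
    lapse: float = 0.02
    eta: float = 1.0
    init_std: float = 0.05
    K: int = 4

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ValueError("nu must be non-negative")
        if not 0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.init_std <= 0 or self.K < 1:
            raise ValueError("init_std must be positive and K >= 1")


def _motion_sequence(curriculum_name: str, rng: np.random.Generator) -> np.ndarray:
    lo, hi = MOTION_COHERENCE_RANGE
    ramp = np.linspace(hi, lo, N_TRAIN)  # 1.00 down to 0.40
    if curriculum_name == "ascending":
        return ramp
    if curriculum_name == "hard":
        return np.full(N_TRAIN, lo)
    if curriculum_name in ("random", "bad"):
        return rng.permutation(ramp)
    raise ValueError(f"unknown curriculum {curriculum_name!r}; expected one of {CURRICULA}")


def _color_levels(n_levels: int) -> np.ndarray:
    lo, hi = COLOR_COHERENCE_RANGE
    return np.linspace(lo, hi, n_levels)


def _counterbalanced(values: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    reps = int(np.ceil(n / values.size))
    return rng.permutation(np.tile(values, reps)[:n])


def design_experiment(
    curriculum_name: str,
    participant_id: int,
    seed: int = 0,
    n_color_levels: int = 4,
) -> HumanDesign:
    """Build one participant's counterbalanced RDK trial sequence.

    Training motion coherence follows the curriculum (ascending: linear
    1.00 -> 0.40; hard: 0.40 throughout; random/bad: seeded permutation of
    the ascending levels).  Feature-sign pairings are counterbalanced
    across training trials, except under ``bad`` where the pairing comes
    from the participant's first subset with probability ramping linearly
    from 1 to 0.  Test trials are all at motion coherence 0.40 with each
    of the four pairings crossed with the color-coherence levels.
    Response mapping and (for bad) subset identity are counterbalanced
    across participants by their id.
    """
    rng = np.random.default_rng([seed, participant_id])
    response_mapping = 1 if participant_id % 2 == 0 else -1
    motion_coh = _motion_sequence(curriculum_name, rng)
    color_coh = _counterbalanced(_color_levels(n_color_levels), N_TRAIN, rng)

    subset_order: tuple | None = None
    if curriculum_name == "bad":
        first = _BAD_SUBSETS[(participant_id // 2) % len(_BAD_SUBSETS)]
        second = (first[0], -first[1])
        subset_order = (first, second)
        p_first = np.linspace(1.0, 0.0, N_TRAIN)
        motion_signs = np.empty(N_TRAIN, dtype=int)
        color_signs = np.empty(N_TRAIN, dtype=int)
        for t in range(N_TRAIN):
            feature, fixed = subset_order[0] if rng.random() < p_first[t] else subset_order[1]
            free = 1 if rng.random() < 0.5 else -1
            if feature == "color":
                color_signs[t], motion_signs[t] = fixed, free
            else:
                motion_signs[t], color_signs[t] = fixed, free
    else:
        pairings = np.array([(1, 1), (1, -1), (-1, 1), (-1, -1)])
        idx = _counterbalanced(np.arange(4), N_TRAIN, rng)
        motion_signs = pairings[idx, 0]
        color_signs = pairings[idx, 1]

    def response(m_sign: int, c_sign: int) -> str:
        return "J" if m_sign * c_sign * response_mapping > 0 else "F"

    trials = [
        RDKTrial(
            phase="train",
            index=t + 1,
            motion_coherence=float(motion_coh[t]),
            motion_sign=int(motion_signs[t]),
            color_coherence=float(color_coh[t]),
            color_sign=int(color_signs[t]),
            correct_response=response(int(motion_signs[t]), int(color_signs[t])),
        )
        for t in range(N_TRAIN)
    ]

    # test: every pairing x every color level, all at the hard motion coherence
    levels = _color_levels(n_color_levels)
    combos = [
        (m, c, lev)
        for m in (1, -1)
        for c in (1, -1)
        for lev in np.tile(levels, int(np.ceil(N_TEST / (4 * levels.size))))[
            : N_TEST // 4
        ]
    ]
    order = rng.permutation(len(combos))
    for j, idx_test in enumerate(order):
        m, c, lev = combos[idx_test]
        trials.append(
            RDKTrial(
                phase="test",
                index=j + 1,
                motion_coherence=MOTION_COHERENCE_RANGE[0],
                motion_sign=int(m),
                color_coherence=float(lev),
                color_sign=int(c),
                correct_response=response(int(m), int(c)),
            )
        )
    return HumanDesign(
        curriculum_name=curriculum_name,
        participant_id=participant_id,
        seed=seed,
        response_mapping=response_mapping,
        trials=tuple(trials),
        subset_order=subset_order,
    )


def xor_responder_params(response_mapping: int, scale: float = 5.0) -> net.NetworkParams:
    """A hand-built responder network that implements the XOR rule exactly.

    The logit is proportional to |z1 + z2| - |z1 - z2|, positive iff the two
    percept components share a sign; the readout sign follows the design's
    response mapping.  Useful as a noiseless oracle participant.
    """
    if response_mapping not in (-1, 1):
        raise ValueError("response_mapping must be +1 or -1")
    W1 = np.array([[1.0, 1.0], [-1.0, -1.0], [1.0, -1.0], [-1.0, 1.0]]) * scale
    w2 = np.array([1.0, 1.0, -1.0, -1.0]) * response_mapping * scale
    return net.NetworkParams(W1=W1, w2=w2)


def simulate_participant(
    design: HumanDesign,
    learner: ResponderParams = ResponderParams(),
    seed: int | np.random.Generator | None = None,
    initial_params: net.NetworkParams | None = None,
) -> np.ndarray:
    """Simulate one participant; returns per-trial correctness (0/1).

    Each trial's percept is (motion_sign * motion_coherence,
    color_sign * color_coherence) plus N(0, nu^2) noise.  The responder is
    a K-unit, d=2 parsimonious network updated online on every training
    trial (label 1 <=> key 'J'); it never updates during the test phase.
    An exactly-zero logit produces a fair guess (humans must answer); with
    probability ``lapse`` the response is inverted, so lapse = 0.5 makes
    every trial a coin flip.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if initial_params is None:
        params = net.init_network(K=learner.K, d=2, init_std=learner.init_std, seed=rng)
    else:
        params = initial_params
    # hot loop: operate on raw weight arrays (same arithmetic as
    # network.forward / network.sgd_step, inlined for speed)
    W1 = params.W1.copy()
    w2 = params.w2.copy()
    eta = learner.eta
    correct = np.empty(len(design.trials), dtype=int)
    for i, trial in enumerate(design.trials):
        percept = np.array(
            [
                trial.motion_sign * trial.motion_coherence,
                trial.color_sign * trial.color_coherence,
            ]
        ) + learner.nu * rng.standard_normal(2)
        y = 1 if trial.correct_response == "J" else 0
        pre = W1 @ percept
        h = np.maximum(pre, 0.0)
        logit = w2 @ h
        u_lapse = rng.random()
        guess = int(rng.integers(0, 2))
        response = guess if logit == 0.0 else int(logit > 0)
        if u_lapse < learner.lapse:
            # lapse = motor/attention error: the intended response is inverted,
            # so lapse = 0.5 yields exact chance regardless of the percept
            response = 1 - response
        correct[i] = int(response == y)
        if trial.phase == "train" and eta > 0:
            delta = 1.0 / (1.0 + np.exp(-logit)) - y
            gate_w2 = w2 * (pre > 0)  # pre-update readout, as in sgd_step
            w2 = w2 - eta * delta * h
            W1 = W1 - (eta * delta) * gate_w2[:, None] * percept[None, :]
    return correct


@dataclass(frozen=True)
class HumanDataset:
    """Trial-level synthetic study with its ground-truth generator settings."""

    frame: pd.DataFrame
    learner: ResponderParams
    master_seed: int
    n_per_curriculum: int

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "learner": asdict(self.learner),
            "master_seed": self.master_seed,
            "n_per_curriculum": self.n_per_curriculum,
            "n_train": N_TRAIN,
            "n_test": N_TEST,
        }

    def write_metadata(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2)


def generate_study(
    n_per_curriculum: int = 50,
    learner: ResponderParams = ResponderParams(),
    master_seed: int = 0,
) -> HumanDataset:
    """Generate a full four-arm synthetic study (paper scale: 50 per arm)."""
    if n_per_curriculum < 1:
        raise ValueError("n_per_curriculum must be positive")
    frames = []
    pid = 0
    for arm_idx, curriculum in enumerate(CURRICULA):
        for i in range(n_per_curriculum):
            design = design_experiment(curriculum, participant_id=pid, seed=master_seed)
            rng = np.random.default_rng([master_seed, 10 + arm_idx, i])
            correct = simulate_participant(design, learner, seed=rng)
            frame = design.to_frame()[["participant", "curriculum", "phase", "trial"]].copy()
            frame["bin"] = np.where(
                frame["phase"] == "train", (frame["trial"] - 1) // TRAIN_BIN_SIZE + 1, 0
            )
            frame["correct"] = correct
            frames.append(frame)
            pid += 1
    return HumanDataset(
        frame=pd.concat(frames, ignore_index=True),
        learner=learner,
        master_seed=master_seed,
        n_per_curriculum=n_per_curriculum,
    )


def analyze_study(frame: pd.DataFrame, threshold: float = 0.65) -> dict:
    """End-to-end behavioral analysis of a trial-level study table.

    Returns binned training trajectories per curriculum, the achiever
    split (final training bin vs test accuracy) per curriculum, and the
    pairwise logistic contrasts on test-phase trials.
    """
    train = frame[frame["phase"] == "train"]
    test = frame[frame["phase"] == "test"]

    binned_rows = []
    split = {}
    for curriculum, group in frame.groupby("curriculum"):
        final_train, test_acc = [], []
        for _, ptable in group.sort_values("trial").groupby("participant"):
            tr = ptable[ptable["phase"] == "train"]["correct"].to_numpy()
            te = ptable[ptable["phase"] == "test"]["correct"].to_numpy()
            bins = bin_trajectory(tr, TRAIN_BIN_SIZE)
            binned_rows.extend(
                {"curriculum": curriculum, "bin": b + 1, "accuracy": acc}
                for b, acc in enumerate(bins)
            )
            final_train.append(bins[-1])
            test_acc.append(te.mean())
        s = achiever_split(np.array(final_train), np.array(test_acc), threshold)
        split[curriculum] = {
            "prop_above_train": s.prop_above_train,
            "prop_above_test": s.prop_above_test,
            "mean_test_acc": float(np.mean(test_acc)),
        }
    binned = (
        pd.DataFrame(binned_rows).groupby(["curriculum", "bin"])["accuracy"].mean().reset_index()
    )
    contrasts = pairwise_logistic_contrasts(test)
    return {"binned_training": binned, "achiever_split": split, "test_contrasts": contrasts}


def read_participant_csv(path) -> pd.DataFrame:
    """Optional loader for an externally collected trial-level CSV.

    Expects at least the columns (participant, curriculum, phase, trial,
    correct); ``bin`` is recomputed for training trials if absent.  Never
    required by the simulation pipeline.
    """
    frame = pd.read_csv(path)
    required = {"participant", "curriculum", "phase", "trial", "correct"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"participant CSV is missing columns: {sorted(missing)}")
    if not frame["phase"].isin(["train", "test"]).all():
        raise ValueError("phase must be 'train' or 'test'")
    if not frame["correct"].isin([0, 1]).all():
        raise ValueError("correct must be 0/1")
    if "bin" not in frame.columns:
        frame = frame.copy()
        frame["bin"] = np.where(
            frame["phase"] == "train", (frame["trial"] - 1) // TRAIN_BIN_SIZE + 1, 0
        )
    return frame
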