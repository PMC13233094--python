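"""Population simulations: many independently initialized networks, one curriculum.

Each network in a population shares the task geometry and the curriculum
schedule but has its own weight initialization and its own stimulus draws.
Training is strictly online: one fresh stimulus per SGD step.  Time is
measured in *time units* — online steps divided by the input dimension d —
so 10 time units at d = 100 means 1,000 steps.  The per-step learning rate
is eta / d under the same convention (the ``lr_scale="raw"`` escape hatch
uses eta unscaled).

Reproducibility contract: every network's stream is keyed by
(master_seed, seed_id), so results are independent of chunking or
execution order; the task geometry and the schedule permutation are keyed
by master_seed alone and shared across the population.  Per network the
draw order is: init weights, training labels, training subset uniforms,
training noise, then per time unit (eval labels, eval subset uniforms,
eval noise), then test labels, test signs, test noise.

After a recorded accuracy at the end of every time unit (fresh stimuli at
that unit's scheduled difficulty and subset mix) and a hard-trial test
(sigma = sigma_hard, both subsets), populations can be trained further on
hard trials to probe the long-term impact of the initial curriculum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numba
import numpy as np
import pandas as pd
from scipy.special import expit

from .curricula import CURRICULA, CurriculumSchedule, make_schedule
from .network import NetworkParams
from .task import TaskDistribution, make_task

__all__ = [
    "SimulationConfig",
    "TrajectoryRecord",
    "PopulationResult",
    "train_one",
    "run_population",
    "extend_on_hard",
    "extend_population",
]

# stream tags under the master seed; networks use (master_seed, _NET_STREAM, seed_id)
_AUX_STREAM = 0
_NET_STREAM = 1
_TASK_KEY = 0
_SCHEDULE_KEY = 1
_EXTENSION_KEY = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one population run (defaults follow the study conditions)."""

    curriculum_name: str
    n_networks: int = 10_000
    d: int = 100
    K: int = 4
    init_std: float = 0.05
    eta: float = 10.0
    lr_scale: str = "per_dim"  # per-step rate = eta / d ("raw": eta as-is)
    time_units_train: float = 10.0
    sigma_easy: float = 0.1
    sigma_hard: float = 0.65
    n_eval: int = 1_000
    n_test: int = 10_000
    extension_time_units: tuple[float, ...] = ()
    train_w2: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.curriculum_name not in CURRICULA:
            raise ValueError(
                f"unknown curriculum {self.curriculum_name!r}; expected one of {CURRICULA}"
            )
        for name in ("n_networks", "d", "K", "n_eval", "n_test"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.init_std <= 0:
            raise ValueError("init_std must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.lr_scale not in ("per_dim", "raw"):
            raise ValueError("lr_scale must be 'per_dim' or 'raw'")
        if self.sigma_easy < 0 or self.sigma_easy > self.sigma_hard:
            raise ValueError("need 0 <= sigma_easy <= sigma_hard")
        if self.T < 1:
            raise ValueError("time_units_train too small: zero training steps")
        if any(x < 0 for x in self.extension_time_units):
            raise ValueError("extension_time_units must be non-negative")
        object.__setattr__(self, "extension_time_units", tuple(self.extension_time_units))

    @property
    def T(self) -> int:
        return int(round(self.time_units_train * self.d))

    @property
    def eta_step(self) -> float:
        return self.eta / self.d if self.lr_scale == "per_dim" else self.eta

    @property
    def n_units(self) -> int:
        return int(np.ceil(self.time_units_train))

    def to_dict(self) -> dict:
        out = asdict(self)
        out["extension_time_units"] = list(self.extension_time_units)
        return out


@dataclass(frozen=True)
class TrajectoryRecord:
    """Per-network outcome: training trajectory, hard-test accuracy, extensions."""

    seed_id: int
    train_acc_per_unit: np.ndarray
    final_train_acc: float
    test_acc: float
    extended_test_acc: dict[float, float] = field(default_factory=dict)


@dataclass(frozen=True)
class PopulationResult:
    """All records of one curriculum's population plus the final weights."""

    config: SimulationConfig
    task: TaskDistribution
    schedule: CurriculumSchedule
    records: list[TrajectoryRecord]
    W1_all: np.ndarray  # (n_networks, K, d) final first-layer weights
    w2_all: np.ndarray  # (n_networks, K) final readout weights

    def __post_init__(self) -> None:
        if len(self.records) != self.config.n_networks:
            raise ValueError("record count must equal n_networks")
        ids = [r.seed_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("seed_ids must be unique")

    @property
    def test_accs(self) -> np.ndarray:
        return np.array([r.test_acc for r in self.records])

    @property
    def final_train_accs(self) -> np.ndarray:
        return np.array([r.final_train_acc for r in self.records])

    def final_params(self, i: int) -> NetworkParams:
        return NetworkParams(W1=self.W1_all[i], w2=self.w2_all[i])

    def to_frame(self) -> pd.DataFrame:
        n_units = self.config.n_units
        rows = []
        for r in self.records:
            row = {"seed_id": r.seed_id}
            for u in range(n_units):
                row[f"train_acc_unit_{u + 1}"] = r.train_acc_per_unit[u]
            row["final_train_acc"] = r.final_train_acc
            row["test_acc"] = r.test_acc
            for extra, acc in sorted(r.extended_test_acc.items()):
                row[f"test_acc_ext_{extra:g}"] = acc
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _net_rng(master_seed: int, seed_id: int) -> np.random.Generator:
    return np.random.default_rng([master_seed, _NET_STREAM, seed_id])


def _accuracy_from_logits(logits: np.ndarray, labels: np.ndarray) -> float:
    correct = ((logits > 0) & (labels == 1)) | ((logits < 0) & (labels == 0))
    return float(np.mean(correct))


def _eval_one(
    W1: np.ndarray,
    w2: np.ndarray,
    task: TaskDistribution,
    rng: np.random.Generator,
    sigma: float,
    p_plus: float,
    n: int,
) -> float:
    """Accuracy on n fresh stimuli at difficulty sigma and subset mix p_plus."""
    labels = rng.integers(0, 2, size=n)
    signs = np.where(rng.random(n) < p_plus, 1.0, -1.0)
    X = signs[:, None] * task.centers[labels] + sigma * rng.standard_normal((n, task.d))
    logits = np.maximum(X @ W1.T, 0.0) @ w2
    return _accuracy_from_logits(logits, labels)


def _run_seeds(
    task: TaskDistribution,
    schedule: CurriculumSchedule,
    config: SimulationConfig,
    seed_ids: np.ndarray,
) -> tuple[list[TrajectoryRecord], np.ndarray, np.ndarray]:
    """Train and evaluate one chunk of networks, vectorized across the chunk."""
    S = len(seed_ids)
    T, d, K = config.T, config.d, config.K
    if schedule.T != T:
        raise ValueError(f"schedule length {schedule.T} does not match config T={T}")
    eta = config.eta_step
    n_units = config.n_units
    unit_ends = [min((u + 1) * d, T) - 1 for u in range(n_units)]

    rngs = [_net_rng(config.master_seed, int(s)) for s in seed_ids]
    W1 = np.empty((S, K, d))
    w2 = np.empty((S, K))
    y_tr = np.empty((S, T), dtype=np.int64)
    u_tr = np.empty((S, T))
    noise = np.empty((S, T, d))
    for i, rng in enumerate(rngs):
        W1[i] = rng.normal(0.0, config.init_std, size=(K, d))
        w2[i] = rng.normal(0.0, config.init_std, size=K)
        y_tr[i] = rng.integers(0, 2, size=T)
        u_tr[i] = rng.random(T)
        noise[i] = rng.standard_normal((T, d))

    centers = task.centers  # (2, d)
    snapshots: list[tuple[np.ndarray, np.ndarray]] = []
    next_snap = 0
    for t in range(T):
        s = np.where(u_tr[:, t] < schedule.p_plus_t[t], 1.0, -1.0)
        x = s[:, None] * centers[y_tr[:, t]] + schedule.sigma_t[t] * noise[:, t, :]
        pre = np.einsum("skd,sd->sk", W1, x)
        h = np.maximum(pre, 0.0)
        logit = np.einsum("sk,sk->s", w2, h)
        delta = (expit(logit) - y_tr[:, t]) * eta
        gate_w2 = w2 * (pre > 0)  # pre-update readout in the W1 gradient
        if config.train_w2:
            w2 -= delta[:, None] * h
        W1 -= (delta[:, None] * gate_w2)[:, :, None] * x[:, None, :]
        if next_snap < n_units and t == unit_ends[next_snap]:
            snapshots.append((W1.copy(), w2.copy()))
            next_snap += 1
    del noise, y_tr, u_tr

    records: list[TrajectoryRecord] = []
    for i, rng in enumerate(rngs):
        per_unit = np.empty(n_units)
        for u, t_end in enumerate(unit_ends):
            W1_u, w2_u = snapshots[u]
            per_unit[u] = _eval_one(
                W1_u[i],
                w2_u[i],
                task,
                rng,
                sigma=float(schedule.sigma_t[t_end]),
                p_plus=float(schedule.p_plus_t[t_end]),
                n=config.n_eval,
            )
        test_acc = _eval_one(
            W1[i], w2[i], task, rng,
            sigma=config.sigma_hard, p_plus=0.5, n=config.n_test,
        )
        records.append(
            TrajectoryRecord(
                seed_id=int(seed_ids[i]),
                train_acc_per_unit=per_unit,
                final_train_acc=float(per_unit[-1]),
                test_acc=test_acc,
            )
        )
    return records, W1, w2


def population_task(config: SimulationConfig) -> TaskDistribution:
    """The task geometry shared by every network of a population run."""
    return make_task(config.d, seed=np.random.default_rng(
        [config.master_seed, _AUX_STREAM, _TASK_KEY]).integers(2**31))


def population_schedule(config: SimulationConfig) -> CurriculumSchedule:
    """The curriculum schedule shared by every network of a population run."""
    rng = np.random.default_rng([config.master_seed, _AUX_STREAM, _SCHEDULE_KEY])
    return make_schedule(
        config.curriculum_name, config.T, config.sigma_easy, config.sigma_hard, seed=rng
    )


def train_one(
    task: TaskDistribution,
    schedule: CurriculumSchedule,
    config: SimulationConfig,
    seed_id: int = 0,
) -> TrajectoryRecord:
    """Train and evaluate a single network (seed_id selects its stream)."""
    records, _, _ = _run_seeds(task, schedule, config, np.array([seed_id]))
    return records[0]


def run_population(config: SimulationConfig, chunk_size: int | None = None) -> PopulationResult:
    """Train config.n_networks independent networks under one curriculum.

    Networks are processed in chunks for memory, but every network's stream
    depends only on (master_seed, seed_id), so the result is invariant to
    the chunking.  If ``config.extension_time_units`` is non-empty the
    population is additionally trained on hard trials up to each requested
    extension (cumulative) and re-tested.
    """
    task = population_task(config)
    schedule = population_schedule(config)
    if chunk_size is None:
        # keep the pre-generated training noise below ~200 MB
        chunk_size = max(1, int(2.5e7 / (config.T * config.d)))
    records: list[TrajectoryRecord] = []
    W1_parts, w2_parts = [], []
    all_ids = np.arange(config.n_networks)
    for start in range(0, config.n_networks, chunk_size):
        chunk_records, W1, w2 = _run_seeds(
            task, schedule, config, all_ids[start : start + chunk_size]
        )
        records.extend(chunk_records)
        W1_parts.append(W1)
        w2_parts.append(w2)
    result = PopulationResult(
        config=config,
        task=task,
        schedule=schedule,
        records=sorted(records, key=lambda r: r.seed_id),
        W1_all=np.concatenate(W1_parts),
        w2_all=np.concatenate(w2_parts),
    )
    if config.extension_time_units:
        ext = extend_population(result, config.extension_time_units)
        result = replace(
            result,
            records=[
                replace(r, extended_test_acc={cp: float(ext[cp][idx]) for cp in ext})
                for idx, r in enumerate(result.records)
            ],
        )
    return result


@numba.njit(cache=False)
def _online_sgd_block(W1, w2, X, Y, eta, train_w2):  # pragma: no cover - jitted
    """Sequential online SGD over a pre-drawn block of stimuli.

    X is (B, S, d): B consecutive steps for S networks; Y is (B, S).
    Identical arithmetic to the numpy step (BCE gradient, ReLU gates,
    pre-update readout in the first-layer gradient), compiled for the
    long extension runs.
    """
    B, S, d = X.shape
    K = w2.shape[1]
    h = np.empty(K)
    gate = np.empty(K)
    for b in range(B):
        for i in range(S):
            logit = 0.0
            for k in range(K):
                pre = 0.0
                for j in range(d):
                    pre += W1[i, k, j] * X[b, i, j]
                if pre > 0.0:
                    h[k] = pre
                    gate[k] = w2[i, k]
                else:
                    h[k] = 0.0
                    gate[k] = 0.0
                logit += w2[i, k] * h[k]
            if logit >= 0.0:
                p = 1.0 / (1.0 + np.exp(-logit))
            else:
                ez = np.exp(logit)
                p = ez / (1.0 + ez)
            delta = (p - Y[b, i]) * eta
            for k in range(K):
                if train_w2:
                    w2[i, k] -= delta * h[k]
                if gate[k] != 0.0:
                    coef = delta * gate[k]
                    for j in range(d):
                        W1[i, k, j] -= coef * X[b, i, j]


def _extend_stack(
    W1: np.ndarray,
    w2: np.ndarray,
    task: TaskDistribution,
    config: SimulationConfig,
    checkpoints: tuple[float, ...],
    rng: np.random.Generator,
) -> dict[float, np.ndarray]:
    """Continue online SGD on hard trials for a stack of networks.

    Trains cumulatively to each checkpoint (in time units) and returns the
    fresh hard-test accuracy of every network at every checkpoint.
    """
    S, K, d = W1.shape
    eta = config.eta_step
    sigma = config.sigma_hard
    centers = task.centers
    out: dict[float, np.ndarray] = {}
    cps = sorted(set(checkpoints))
    done = 0
    block_size = max(1, int(2e6 / (S * d)))  # pre-draw stimuli in blocks
    for cp in cps:
        target = int(round(cp * d))
        remaining = target - done
        while remaining > 0:
            B = min(block_size, remaining)
            y_blk = rng.integers(0, 2, size=(B, S))
            s_blk = np.where(rng.random((B, S)) < 0.5, 1.0, -1.0)
            x_blk = rng.standard_normal((B, S, d))
            # build all stimuli of the block in one vectorized pass
            x_blk *= sigma
            x_blk += s_blk[:, :, None] * centers[y_blk]
            _online_sgd_block(W1, w2, x_blk, y_blk.astype(np.float64), eta,
                              config.train_w2)
            remaining -= B
        done = target
        accs = np.empty(S)
        for i in range(S):
            accs[i] = _eval_one(
                W1[i], w2[i], task, rng, sigma=sigma, p_plus=0.5, n=config.n_test
            )
        out[cp] = accs
    return out


def extend_population(
    result: PopulationResult,
    checkpoints: tuple[float, ...],
    seed: int | None = None,
) -> dict[float, np.ndarray]:
    """Hard-trial extension for a whole population; returns per-checkpoint accuracies."""
    config = result.config
    if seed is None:
        rng = np.random.default_rng([config.master_seed, _AUX_STREAM, _EXTENSION_KEY])
    else:
        rng = np.random.default_rng(seed)
    return _extend_stack(
        result.W1_all.copy(), result.w2_all.copy(), result.task, config, tuple(checkpoints), rng
    )


def extend_on_hard(
    params: NetworkParams,
    task: TaskDistribution,
    config: SimulationConfig,
    extra_time_units: float,
    seed: int | None = None,
) -> float:
    """Continue one network on hard trials and return its fresh hard-test accuracy."""
    if extra_time_units < 0:
        raise ValueError("extra_time_units must be non-negative")
    rng = np.random.default_rng(seed)
    out = _extend_stack(
        params.W1[None, :, :].copy(),
        params.w2[None, :].copy(),
        task,
        config,
        (float(extra_time_units),),
        rng,
    )
    return float(out[float(extra_time_units)][0])
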