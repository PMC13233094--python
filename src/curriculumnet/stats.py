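"""Population and behavioral statistics.

Covers the analysis layer shared by the network and human sides of the
study: pooled-SD Cohen's d between curriculum populations, the 65%
high-/low-achiever split on final-training vs test accuracy, binned
training trajectories, and pairwise curriculum contrasts from a
fixed-effects logistic regression fitted by iteratively reweighted least
squares (IRLS).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .curricula import CURRICULA

__all__ = [
    "EffectSizeReport",
    "AchieverSplit",
    "cohens_d",
    "achiever_split",
    "bin_trajectory",
    "fit_logistic_irls",
    "pairwise_logistic_contrasts",
]

ACHIEVER_THRESHOLD = 0.65


@dataclass(frozen=True)
class EffectSizeReport:
    """Absolute standardized mean difference between two groups."""

    pair: tuple[str, str]
    d_value: float
    n_A: int
    n_B: int
    mean_A: float
    mean_B: float
    pooled_sd: float


@dataclass(frozen=True)
class AchieverSplit:
    """High/low split at an accuracy threshold, on training and test accuracy.

    The per-unit group assignment follows the final *training* accuracy, as
    used to color training trajectories.
    """

    threshold: float
    prop_above_train: float
    prop_above_test: float
    high_achiever: np.ndarray


def cohens_d(
    acc_A: np.ndarray, acc_B: np.ndarray, pair: tuple[str, str] = ("A", "B")
) -> EffectSizeReport:
    """Absolute pooled-SD Cohen's d between two accuracy samples.

    Uses the pooled standard deviation
    s_p = sqrt(((n_A-1) s_A^2 + (n_B-1) s_B^2) / (n_A + n_B - 2)).
    A degenerate s_p = 0 gives d = 0 for equal means and inf otherwise.
    """
    a = np.asarray(acc_A, dtype=float)
    b = np.asarray(acc_B, dtype=float)
    n_A, n_B = a.size, b.size
    if n_A < 2 or n_B < 2:
        raise ValueError("each group needs at least 2 observations")
    m_A, m_B = float(a.mean()), float(b.mean())
    s2_A, s2_B = float(a.var(ddof=1)), float(b.var(ddof=1))
    pooled = math.sqrt(((n_A - 1) * s2_A + (n_B - 1) * s2_B) / (n_A + n_B - 2))
    if pooled > 0:
        d = abs(m_A - m_B) / pooled
    else:
        d = 0.0 if m_A == m_B else float("inf")
    return EffectSizeReport(
        pair=pair, d_value=d, n_A=n_A, n_B=n_B, mean_A=m_A, mean_B=m_B, pooled_sd=pooled
    )


def achiever_split(
    final_train_acc: np.ndarray,
    test_acc: np.ndarray,
    threshold: float = ACHIEVER_THRESHOLD,
) -> AchieverSplit:
    """Strict-threshold achiever proportions on training and test accuracy."""
    train = np.asarray(final_train_acc, dtype=float)
    test = np.asarray(test_acc, dtype=float)
    if train.shape != test.shape:
        raise ValueError("final_train_acc and test_acc must have equal length")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    high = train > threshold  # strict: "exceeding" the threshold
    return AchieverSplit(
        threshold=threshold,
        prop_above_train=float(np.mean(high)),
        prop_above_test=float(np.mean(test > threshold)),
        high_achiever=high,
    )


def bin_trajectory(trial_correct: np.ndarray, bin_size: int) -> np.ndarray:
    """Mean correctness per consecutive bin; a trailing partial bin is dropped."""
    if bin_size < 1:
        raise ValueError("bin_size must be positive")
    x = np.asarray(trial_correct, dtype=float)
    n_bins = x.size // bin_size
    if n_bins == 0:
        return np.empty(0)
    return x[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)


def fit_logistic_irls(
    X: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Binomial logistic regression by IRLS on aggregated counts.

    Returns (beta, covariance, converged).  ``ridge`` adds an L2 penalty on
    the coefficients (used as the separation fallback); the covariance is
    the inverse of the (penalized) Fisher information.
    """
    X = np.asarray(X, dtype=float)
    k = np.asarray(successes, dtype=float)
    m = np.asarray(trials, dtype=float)
    n_obs, p = X.shape
    beta = np.zeros(p)
    converged = False
    penalty = ridge * np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = m * mu * (1.0 - mu)
        grad = X.T @ (k - m * mu) - ridge * beta
        info = X.T @ (w[:, None] * X) + penalty
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = m * mu * (1.0 - mu)
    info = X.T @ (w[:, None] * X) + penalty
    cov = np.linalg.pinv(info)
    return beta, cov, converged


def _curriculum_order(names: list[str]) -> list[str]:
    known = [c for c in CURRICULA if c in names]
    extra = sorted(set(names) - set(CURRICULA))
    return known + extra


def pairwise_logistic_contrasts(
    trial_table: pd.DataFrame,
    ridge_fallback: float = 1e-4,
) -> pd.DataFrame:
    """All pairwise curriculum contrasts from a fixed-effects logistic fit.

    ``trial_table`` needs columns ``participant``, ``curriculum`` and
    ``correct`` (0/1).  A cell-means logistic model (one log-odds parameter
    per curriculum) is fitted by IRLS; each contrast is the difference of
    two curriculum log-odds with a Wald z and two-sided p.  Perfectly
    separated cells (all correct or all incorrect) make the unpenalized MLE
    diverge; those fits fall back to a small ridge penalty and the rows are
    flagged in the ``separated`` column.
    """
    required = {"participant", "curriculum", "correct"}
    missing = required - set(trial_table.columns)
    if missing:
        raise ValueError(f"trial_table is missing columns: {sorted(missing)}")
    groups = trial_table.groupby("curriculum")["correct"]
    counts = groups.agg(successes="sum", trials="count")
    names = _curriculum_order(list(counts.index))
    if len(names) < 2:
        raise ValueError("need at least two curricula")
    n_participants = trial_table.groupby("curriculum")["participant"].nunique()
    if (n_participants < 2).any():
        raise ValueError("need at least two participants per curriculum")

    k = counts.loc[names, "successes"].to_numpy(float)
    m = counts.loc[names, "trials"].to_numpy(float)
    X = np.eye(len(names))
    separated = bool(np.any(k == 0) or np.any(k == m))
    ridge = ridge_fallback if separated else 0.0
    beta, cov, converged = fit_logistic_irls(X, k, m, ridge=ridge)
    if not converged and ridge == 0.0:
        separated = True
        beta, cov, converged = fit_logistic_irls(X, k, m, ridge=ridge_fallback)

    rows = []
    index = {name: i for i, name in enumerate(names)}
    for a, b in itertools.combinations(names, 2):
        ia, ib = index[a], index[b]
        est = beta[ia] - beta[ib]
        se = math.sqrt(cov[ia, ia] + cov[ib, ib] - 2 * cov[ia, ib])
        z = est / se if se > 0 else float("nan")
        p = 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "curriculum_a": a,
                "curriculum_b": b,
                "beta": est,
                "se": se,
                "z": z,
                "p": p,
                "separated": separated,
            }
        )
    return pd.DataFrame(rows)
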