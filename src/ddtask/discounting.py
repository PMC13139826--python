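"""Per-subject delay-discounting measures from a choice log.

The chain is: validity filter on reaction times -> per-delay-level
indifference points -> hyperbolic fit of the discount rate k -> normalized
area under the indifference curve (AUC) and the raw smaller-sooner choice
proportion.

An indifference point theta at a given delay difference is the objective
value ratio r_ss / r_ll at which the subject chooses each side equally
often. Under hyperbolic discounting with the delay difference Delta as the
effective delay, theta(Delta) = 1 / (1 + k * Delta); fitting that curve to
the estimated points recovers k. AUC is the model-free companion: area
under theta versus normalized delay, anchored at (0, 1) because options
differing in reward only have a normative indifference ratio of 1. Lower
AUC = steeper discounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit

from .agents import RT_MAX, RT_MIN, SessionLog
from .errors import InsufficientDataError, ValidationError

K_FLOOR = 1e-4  # 1/s; floor applied before the log transform of k
K_MAX = 10.0    # 1/s; upper bound of the hyperbolic fit search

#: Minimum trials per delay level before a point is flagged low-n.
MIN_TRIALS_PER_LEVEL = 4


@dataclass(frozen=True)
class IndifferencePoint:
    delay_diff: float        # s
    theta: float             # r_ss / r_ll in [0, 1]
    n_trials: int
    clipped: bool
    low_n: bool = False
    se: float | None = None


@dataclass(frozen=True)
class DiscountResult:
    k: float
    log_k: float
    auc: float
    prop_ss: float
    n_valid_trials: int
    fit_sse: float
    points: tuple[IndifferencePoint, ...]


def filter_valid_trials(log: SessionLog) -> tuple[SessionLog, int]:
    """Drop trials with reaction time below 0.3 s or above 15 s.

    Bounds follow the published exclusion rule (< 0.3 s or exceeding 15 s),
    so both endpoints are retained. Idempotent. Returns the filtered log and
    the number of records removed.
    """
    if not log.records:
        raise ValidationError("cannot filter an empty session log")
    kept = [r for r in log.records if RT_MIN <= r.rt <= RT_MAX]
    removed = len(log.records) - len(kept)
    out = SessionLog(subject_id=log.subject_id, records=kept, group=log.group,
                     block_duration=log.block_duration, n_blocks=log.n_blocks,
                     total_points=log.total_points, total_euros=log.total_euros)
    return out, removed


def _logistic_nll(params: np.ndarray, v: np.ndarray, y: np.ndarray) -> float:
    b0, b1 = params
    z = b0 + b1 * v
    # -log L for y ~ Bernoulli(expit(z)), stable via logaddexp
    return float(np.sum(np.logaddexp(0.0, z)) - np.sum(y * z))


def _fit_level(v: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Crossing of a monotone logistic P(SS | v); returns (theta, clipped).

    The slope is constrained non-negative (P(SS) cannot fall as the SS
    option's relative value rises). Constant responses and crossings outside
    the observed ratio range clip to the corresponding endpoint of [0, 1]:
    always-SS implies indifference below every observed ratio (extreme
    discounting, theta -> 0); always-LL implies theta -> 1.
    """
    if y.all():
        return 0.0, True
    if not y.any():
        return 1.0, True
    res = minimize(_logistic_nll, x0=np.array([0.0, 10.0]), args=(v, y),
                   method="L-BFGS-B", bounds=[(-500.0, 500.0), (1e-6, 500.0)])
    b0, b1 = res.x
    crossing = -b0 / b1
    clipped = not (v.min() <= crossing <= v.max())
    return float(np.clip(crossing, 0.0, 1.0)), clipped


def estimate_indifference_points(
    log: SessionLog, min_trials: int = MIN_TRIALS_PER_LEVEL
) -> list[IndifferencePoint]:
    """One indifference point per delay-difference level in the log.

    Levels are the unique delay differences rounded to 0.1 s. Per level,
    P(choose SS) is fit as a logistic function of the value ratio
    v = r_ss / r_ll; theta is the ratio where the fitted probability is 0.5.
    """
    if not log.records:
        raise ValidationError("empty session log")
    levels: dict[float, list] = {}
    for rec in log.records:
        key = round(rec.trial.t_ll - rec.trial.t_ss, 1)
        levels.setdefault(key, []).append(rec)
    points = []
    for delay in sorted(levels):
        recs = levels[delay]
        v = np.array([r.trial.value_ratio for r in recs])
        y = np.array([1.0 if r.choice == "SS" else 0.0 for r in recs])
        theta, clipped = _fit_level(v, y)
        points.append(IndifferencePoint(
            delay_diff=delay, theta=theta, n_trials=len(recs),
            clipped=clipped, low_n=len(recs) < min_trials,
        ))
    return points


def fit_hyperbolic_k(points: list[IndifferencePoint],
                     k_max: float = K_MAX) -> tuple[float, float]:
    """Least-squares fit of theta(Delta) = 1 / (1 + k Delta) over [0, k_max].

    Coarse log-spaced grid (2000 points, plus k = 0) followed by bounded
    scalar refinement around the grid minimum; returns (k, SSE).
    """
    if len({p.delay_diff for p in points}) < 2:
        raise InsufficientDataError("hyperbolic fit needs >= 2 distinct delay levels")
    delays = np.array([p.delay_diff for p in points])
    thetas = np.array([p.theta for p in points])

    def sse(k: float) -> float:
        return float(np.sum((thetas - 1.0 / (1.0 + k * delays)) ** 2))

    grid = np.concatenate([[0.0], np.logspace(-4, np.log10(k_max), 2000)])
    losses = np.array([sse(k) for k in grid])
    i = int(losses.argmin())
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        if res.fun <= losses[i]:
            return float(res.x), float(res.fun)
    return float(grid[i]), float(losses[i])


def log_k(k: float, floor: float = K_FLOOR) -> float:
    """Natural log of k, floored at ``floor`` so k = 0 maps to ln(floor)."""
    if k < 0:
        raise ValidationError("k must be >= 0")
    return math.log(max(k, floor))


def compute_auc(points: list[IndifferencePoint]) -> float:
    """Trapezoid area under (normalized delay, theta) with anchor (0, 1).

    Delays are normalized by the maximum delay difference so the result is
    in [0, 1]; 1 means no discounting.
    """
    if not points:
        raise InsufficientDataError("AUC needs at least one indifference point")
    pts = sorted(points, key=lambda p: p.delay_diff)
    xmax = pts[-1].delay_diff
    if xmax <= 0:
        raise ValidationError("delay differences must be positive")
    x = np.concatenate([[0.0], [p.delay_diff / xmax for p in pts]])
    y = np.concatenate([[1.0], [p.theta for p in pts]])
    return float(np.trapezoid(y, x))


def proportion_ss(log: SessionLog) -> float:
    """Fraction of trials on which the smaller-sooner option was chosen."""
    if not log.records:
        raise ValidationError("empty session log")
    return float(np.mean([r.choice == "SS" for r in log.records]))


def analyze_subject(log: SessionLog, k_floor: float = K_FLOOR) -> DiscountResult:
    """Full discounting chain for one subject: filter, points, k, AUC."""
    filtered, _ = filter_valid_trials(log)
    if not filtered.records:
        raise InsufficientDataError(f"no valid trials for {log.subject_id}")
    points = estimate_indifference_points(filtered)
    k, sse = fit_hyperbolic_k(points)
    return DiscountResult(
        k=k, log_k=log_k(k, k_floor), auc=compute_auc(points),
        prop_ss=proportion_ss(filtered), n_valid_trials=len(filtered.records),
        fit_sse=sse, points=tuple(points),
    )
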