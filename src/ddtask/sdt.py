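"""Choice optimality and its signal-detection decomposition.

A choice is optimal when it takes the option with the higher reward per
second of travel time. Treating "LL is optimal" as the signal and "chose
LL" as the yes-response turns the session into a binary detection problem:
discriminability d' measures how well a subject separates optimal from
suboptimal options, and the likelihood-ratio criterion beta measures a
response bias toward one side independent of that ability (beta < 1 =
LL-leaning criterion is liberal, i.e. SS-avoiding; beta > 1 = LL-avoiding).
Trials whose two options tie in reward rate carry no optimality signal and
are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .agents import SessionLog
from .errors import InsufficientDataError, ValidationError
from .trials import label_optimal


@dataclass(frozen=True)
class OptimalityResult:
    prop_optimal: float
    prop_ss_given_ss_optimal: float  # NaN when no SS-optimal trials
    prop_ll_given_ll_optimal: float  # NaN when no LL-optimal trials
    n_ss_optimal: int
    n_ll_optimal: int
    n_ties_excluded: int


@dataclass(frozen=True)
class SDTResult:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    hit_rate: float
    fa_rate: float
    d_prime: float
    beta: float
    criterion_c: float
    correction_applied: bool


def _labels(log: SessionLog) -> list[tuple[str, str]]:
    """(optimal side or 'tie', chosen side) per record, relabeled from the
    raw offers so externally supplied logs are scored identically."""
    return [
        (label_optimal(r.trial.r_ss, r.trial.t_ss, r.trial.r_ll, r.trial.t_ll), r.choice)
        for r in log.records
    ]


def score_optimality(log: SessionLog) -> OptimalityResult:
    """Overall and side-conditional proportions of optimal choices."""
    if not log.records:
        raise ValidationError("empty session log")
    pairs = _labels(log)
    ties = sum(1 for opt, _ in pairs if opt == "tie")
    scored = [(opt, ch) for opt, ch in pairs if opt != "tie"]
    if not scored:
        raise InsufficientDataError("all trials are rate ties; optimality undefined")
    ss_opt = [(opt, ch) for opt, ch in scored if opt == "SS"]
    ll_opt = [(opt, ch) for opt, ch in scored if opt == "LL"]
    return OptimalityResult(
        prop_optimal=float(np.mean([ch == opt for opt, ch in scored])),
        prop_ss_given_ss_optimal=(float(np.mean([ch == "SS" for _, ch in ss_opt]))
                                  if ss_opt else float("nan")),
        prop_ll_given_ll_optimal=(float(np.mean([ch == "LL" for _, ch in ll_opt]))
                                  if ll_opt else float("nan")),
        n_ss_optimal=len(ss_opt),
        n_ll_optimal=len(ll_opt),
        n_ties_excluded=ties,
    )


def sdt_counts(log: SessionLog) -> tuple[int, int, int, int]:
    """(hits, misses, false alarms, correct rejections).

    Signal = LL-optimal trial, response = chose LL. Tie trials excluded.
    Raises when either signal class is absent, since d'/beta would be
    undefined.
    """
    if not log.records:
        raise ValidationError("empty session log")
    scored = [(opt, ch) for opt, ch in _labels(log) if opt != "tie"]
    hits = sum(1 for opt, ch in scored if opt == "LL" and ch == "LL")
    misses = sum(1 for opt, ch in scored if opt == "LL" and ch == "SS")
    fas = sum(1 for opt, ch in scored if opt == "SS" and ch == "LL")
    crs = sum(1 for opt, ch in scored if opt == "SS" and ch == "SS")
    if hits + misses == 0 or fas + crs == 0:
        raise InsufficientDataError(
            "both an LL-optimal and an SS-optimal trial are required; d'/beta undefined")
    return hits, misses, fas, crs


def normal_quantile(p: float) -> float:
    """Inverse standard normal CDF; domain (0, 1) exclusive."""
    if not (0.0 < p < 1.0):
        raise ValidationError(f"p must be in (0, 1), got {p}")
    return float(ndtri(p))


def _corrected_rate(successes: int, n: int) -> tuple[float, bool]:
    if n <= 0:
        raise InsufficientDataError("zero trials in a signal class")
    rate = successes / n
    if rate == 0.0:
        return 1.0 / (2 * n), True
    if rate == 1.0:
        return 1.0 - 1.0 / (2 * n), True
    return rate, False


def dprime_beta(hits: int, misses: int, false_alarms: int,
                correct_rejections: int) -> SDTResult:
    """d', likelihood-ratio beta, and criterion location c from raw counts.

    Extreme rates (0 or 1) are replaced by 1/(2N) or 1 - 1/(2N) for that
    class before the z-transform. d' = z(H) - z(F);
    beta = exp((z(F)^2 - z(H)^2) / 2); c = -(z(H) + z(F)) / 2.
    """
    for name, v in (("hits", hits), ("misses", misses),
                    ("false_alarms", false_alarms),
                    ("correct_rejections", correct_rejections)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0")
    hr, c1 = _corrected_rate(hits, hits + misses)
    fr, c2 = _corrected_rate(false_alarms, false_alarms + correct_rejections)
    zh, zf = normal_quantile(hr), normal_quantile(fr)
    return SDTResult(
        hits=hits, misses=misses, false_alarms=false_alarms,
        correct_rejections=correct_rejections,
        hit_rate=hr, fa_rate=fr,
        d_prime=zh - zf,
        beta=float(np.exp((zf ** 2 - zh ** 2) / 2.0)),
        criterion_c=-(zh + zf) / 2.0,
        correction_applied=c1 or c2,
    )


def analyze_sdt(log: SessionLog) -> SDTResult:
    """Convenience: counts then d'/beta for one session log."""
    return dprime_beta(*sdt_counts(log))
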