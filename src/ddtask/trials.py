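"""Trial-schedule generation for the gamified intertemporal-choice task.

Each trial offers a smaller-sooner (SS) coin and a larger-later (LL) coin on
a grid. The avatar travels at a fixed speed, so the delay of an option is its
distance in squares times ``seconds_per_square``. One option is objectively
optimal: because the session length is fixed in time, not in trials, the
option with the higher reward per second of travel maximises total earnings.

The generator samples the distance difference and the reward difference from
their design supports, draws the optimal-side label with a calibrated
probability, and then places the SS option (absolute distance and reward) in
the region of the offer space consistent with that label. Ties in reward rate
are never emitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, InvalidTrialError, ValidationError

Side = Literal["SS", "LL"]

#: Column order of the trial-schedule TSV interchange format.
TRIAL_COLUMNS = [
    "trial_id", "d_ss", "d_ll", "r_ss", "r_ll", "t_ss", "t_ll", "optimal_side",
]


@dataclass(frozen=True)
class TrialSpec:
    """A single SS/LL offer pair.

    Distances are in grid squares, rewards in abstract reward units
    (1 unit = ``euros_per_reward_unit`` euros), delays in seconds.
    """

    trial_id: int
    d_ss: int
    d_ll: int
    r_ss: int
    r_ll: int
    t_ss: float
    t_ll: float
    optimal_side: Side

    def __post_init__(self) -> None:
        if not (self.d_ll > self.d_ss >= 1):
            raise InvalidTrialError(f"require d_ll > d_ss >= 1, got {self.d_ss}, {self.d_ll}")
        if not (self.r_ll > self.r_ss >= 1):
            raise InvalidTrialError(f"require r_ll > r_ss >= 1, got {self.r_ss}, {self.r_ll}")

    @property
    def value_ratio(self) -> float:
        """Objective value ratio r_ss / r_ll, in (0, 1)."""
        return self.r_ss / self.r_ll


@dataclass(frozen=True)
class GeneratorConfig:
    """Design parameters of the trial schedule.

    Defaults reproduce the published design statistics: distance differences
    on {1, 2, 4, 7} squares at 1.3 s/square (delay difference mean 4.55 s,
    SD 2.98 s), reward differences uniform on {1, 3, 5, 7, 9} units (mean
    5.0, SD 2.83), and a 60% LL-optimal rate after calibration.

    ``ll_label_prob`` is the probability of drawing an LL-optimal label on
    trials whose (distance diff, reward diff) cell admits both labels; cells
    admitting only one label are forced. ``None`` means uncalibrated (the
    raw target rate is used as the label probability); ``calibrate`` solves
    for the value that makes the overall LL-optimal fraction hit the target.
    """

    distance_diff_support: tuple[int, ...] = (1, 2, 4, 7)
    distance_diff_weights: tuple[float, ...] | None = None
    ss_distance_support: tuple[int, ...] = (2, 3, 4, 5, 6)
    reward_diff_support: tuple[int, ...] = (1, 3, 5, 7, 9)
    reward_diff_weights: tuple[float, ...] | None = None
    ss_reward_support: tuple[int, ...] | None = None  # None: {1..max_total_reward - dr}
    max_total_reward: int = 10
    seconds_per_square: float = 1.3
    ll_optimal_target_rate: float = 0.60
    ll_label_prob: float | None = None
    euros_per_reward_unit: float = 0.005
    points_per_eurocent: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("distance_diff_support", "ss_distance_support", "reward_diff_support"):
            support = getattr(self, name)
            if len(support) == 0:
                raise ValidationError(f"{name} must be non-empty")
            if any(v < 1 for v in support):
                raise ValidationError(f"{name} values must be >= 1")
        for name in ("distance_diff_weights", "reward_diff_weights"):
            w = getattr(self, name)
            if w is not None:
                support = getattr(self, name.replace("_weights", "_support"))
                if len(w) != len(support):
                    raise ValidationError(f"{name} length must match its support")
                if any(x < 0 for x in w) or sum(w) <= 0:
                    raise ValidationError(f"{name} must be non-negative with positive sum")
        if self.seconds_per_square <= 0:
            raise ValidationError("seconds_per_square must be > 0")
        if not (0 < self.ll_optimal_target_rate < 1):
            raise ValidationError("ll_optimal_target_rate must be in (0, 1)")
        if self.ll_label_prob is not None and not (0 <= self.ll_label_prob <= 1):
            raise ValidationError("ll_label_prob must be in [0, 1]")

    @property
    def points_per_reward_unit(self) -> float:
        """Loot points awarded per reward unit."""
        return self.euros_per_reward_unit * 100 * self.points_per_eurocent

    def to_json(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        d = json.loads(text)
        if "seed" not in d:
            raise ValidationError("generator config file must carry an explicit seed")
        for k in ("distance_diff_support", "distance_diff_weights", "ss_distance_support",
                  "reward_diff_support", "reward_diff_weights", "ss_reward_support"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def label_optimal(r_ss: float, t_ss: float, r_ll: float, t_ll: float) -> str:
    """Return the side with the strictly higher reward rate, or ``"tie"``.

    Optimality is reward magnitude divided by the travel time needed to
    collect it; decision latency is not part of the denominator.
    """
    if min(r_ss, r_ll) <= 0 or min(t_ss, t_ll) <= 0:
        raise InvalidTrialError("rewards and delays must be positive")
    rate_ss = r_ss / t_ss
    rate_ll = r_ll / t_ll
    if rate_ll > rate_ss:
        return "LL"
    if rate_ss > rate_ll:
        return "SS"
    return "tie"


def _ss_reward_values(config: GeneratorConfig, dr: int) -> list[int]:
    if config.ss_reward_support is not None:
        return [r for r in config.ss_reward_support if r + dr <= config.max_total_reward]
    return list(range(1, config.max_total_reward - dr + 1))


def _regions(config: GeneratorConfig) -> dict[tuple[int, int], dict[str, list[tuple[int, int]]]]:
    """For each (distance diff, reward diff) cell, the (d_ss, r_ss) pairs
    yielding a strictly LL-optimal and strictly SS-optimal trial.

    LL is optimal iff (r_ss + dr)/(d_ss + dd) > r_ss/d_ss, i.e.
    dr * d_ss > r_ss * dd (exact in integers, so ties are exact too).
    """
    out: dict[tuple[int, int], dict[str, list[tuple[int, int]]]] = {}
    for dd in config.distance_diff_support:
        for dr in config.reward_diff_support:
            ll, ss = [], []
            for d_ss in config.ss_distance_support:
                for r_ss in _ss_reward_values(config, dr):
                    lhs, rhs = dr * d_ss, r_ss * dd
                    if lhs > rhs:
                        ll.append((d_ss, r_ss))
                    elif lhs < rhs:
                        ss.append((d_ss, r_ss))
            out[(dd, dr)] = {"LL": ll, "SS": ss}
    return out


def _cell_probs(config: GeneratorConfig) -> tuple[list[tuple[int, int]], np.ndarray]:
    dw = config.distance_diff_weights or tuple(1.0 for _ in config.distance_diff_support)
    rw = config.reward_diff_weights or tuple(1.0 for _ in config.reward_diff_support)
    cells, probs = [], []
    for dd, wd in zip(config.distance_diff_support, dw):
        for dr, wr in zip(config.reward_diff_support, rw):
            cells.append((dd, dr))
            probs.append(wd * wr)
    p = np.asarray(probs, dtype=float)
    return cells, p / p.sum()


def generate_trials(
    config: GeneratorConfig, n: int, rng: np.random.Generator | None = None
) -> list[TrialSpec]:
    """Generate ``n`` trials; deterministic given ``config.seed`` (or ``rng``).

    Every emitted trial has a strict optimal side. Cells whose offer space
    admits no trial for the drawn label are forced to the feasible label, so
    the marginal distributions of the distance and reward differences are
    exactly the configured ones.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    regions = _regions(config)
    cells, cell_p = _cell_probs(config)
    feasible = [c for c in cells if regions[c]["LL"] or regions[c]["SS"]]
    if not feasible:
        raise CalibrationError("no (distance diff, reward diff) cell admits a non-tie trial")
    p_ll = config.ll_label_prob if config.ll_label_prob is not None else config.ll_optimal_target_rate

    sps = config.seconds_per_square
    idx = rng.choice(len(cells), size=n, p=cell_p)
    want_ll = rng.random(n) < p_ll
    trials: list[TrialSpec] = []
    for i in range(n):
        cell = cells[idx[i]]
        reg = regions[cell]
        label = "LL" if want_ll[i] else "SS"
        if not reg[label]:
            label = "SS" if label == "LL" else "LL"
            if not reg[label]:
                # cell is all ties; redraw among feasible cells
                cell = feasible[rng.integers(len(feasible))]
                reg = regions[cell]
                label = "LL" if (want_ll[i] and reg["LL"]) or not reg["SS"] else "SS"
        d_ss, r_ss = reg[label][rng.integers(len(reg[label]))]
        dd, dr = cell
        trials.append(TrialSpec(
            trial_id=i, d_ss=d_ss, d_ll=d_ss + dd, r_ss=r_ss, r_ll=r_ss + dr,
            t_ss=d_ss * sps, t_ll=(d_ss + dd) * sps, optimal_side=label,
        ))
    return trials


def calibrate_generator(
    config: GeneratorConfig,
    tol: float = 0.02,
    pilot_n: int = 20_000,
    max_iter: int = 5,
) -> GeneratorConfig:
    """Solve for the label probability that hits ``ll_optimal_target_rate``.

    The overall LL-optimal fraction is P(LL forced) + P(both feasible) * p,
    where the forced probabilities follow from the cell supports. The
    analytic solution is refined by pilot simulation until the pilot
    fraction is within ``tol`` of the target.
    """
    target = config.ll_optimal_target_rate
    if not (0 < target < 1):
        raise CalibrationError(f"target rate must be in (0, 1), got {target}")
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    regions = _regions(config)
    cells, cell_p = _cell_probs(config)
    p_ll_forced = sum(p for c, p in zip(cells, cell_p) if not regions[c]["SS"] and regions[c]["LL"])
    p_ss_forced = sum(p for c, p in zip(cells, cell_p) if not regions[c]["LL"] and regions[c]["SS"])
    p_both = sum(p for c, p in zip(cells, cell_p) if regions[c]["LL"] and regions[c]["SS"])
    if p_both <= 0 and abs(p_ll_forced - target) > tol:
        raise CalibrationError(
            f"no free cells: LL-optimal rate is fixed at {p_ll_forced:.3f}, target {target}")
    lo, hi = p_ll_forced, p_ll_forced + p_both
    if not (lo - tol <= target <= hi + tol):
        raise CalibrationError(
            f"target {target} outside the reachable LL-optimal range "
            f"[{lo:.3f}, {hi:.3f}] given the offer supports")

    p = float(np.clip((target - p_ll_forced) / max(p_both, 1e-12), 0.0, 1.0))
    cand = replace(config, ll_label_prob=p)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xCA11B]))
    for _ in range(max_iter):
        pilot = generate_trials(cand, pilot_n, rng=rng)
        frac = float(np.mean([t.optimal_side == "LL" for t in pilot]))
        if abs(frac - target) <= tol:
            return cand
        p = float(np.clip(p + (target - frac) / max(p_both, 1e-12), 0.0, 1.0))
        cand = replace(cand, ll_label_prob=p)
    raise CalibrationError(
        f"calibration did not converge: pilot fraction {frac:.4f}, target {target}")


@dataclass(frozen=True)
class ScheduleSummary:
    """Design moments of a trial schedule. SDs are NaN below 2 trials."""

    n_trials: int
    delay_diff_mean: float
    delay_diff_sd: float
    reward_diff_mean: float
    reward_diff_sd: float
    ll_optimal_fraction: float
    ll_optimal_odds: float


def schedule_summary(trials: Sequence[TrialSpec]) -> ScheduleSummary:
    """Mean/SD of delay and reward differences and the LL-optimal rate."""
    if len(trials) == 0:
        raise ValidationError("cannot summarise an empty schedule")
    dt = np.array([t.t_ll - t.t_ss for t in trials])
    dr = np.array([t.r_ll - t.r_ss for t in trials])
    frac = float(np.mean([t.optimal_side == "LL" for t in trials]))
    sd_ok = len(trials) >= 2
    return ScheduleSummary(
        n_trials=len(trials),
        delay_diff_mean=float(dt.mean()),
        delay_diff_sd=float(dt.std(ddof=1)) if sd_ok else float("nan"),
        reward_diff_mean=float(dr.mean()),
        reward_diff_sd=float(dr.std(ddof=1)) if sd_ok else float("nan"),
        ll_optimal_fraction=frac,
        ll_optimal_odds=frac / (1 - frac) if frac < 1 else float("inf"),
    )


def trials_to_frame(trials: Iterable[TrialSpec]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(t, c) for c in TRIAL_COLUMNS} for t in trials],
                        columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialSpec]:
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"trial table missing columns: {sorted(missing)}")
    return [
        TrialSpec(trial_id=int(r.trial_id), d_ss=int(r.d_ss), d_ll=int(r.d_ll),
                  r_ss=int(r.r_ss), r_ll=int(r.r_ll), t_ss=float(r.t_ss),
                  t_ll=float(r.t_ll), optimal_side=str(r.optimal_side))
        for r in df.itertuples(index=False)
    ]


def write_trials(trials: Iterable[TrialSpec], path) -> None:
    trials_to_frame(trials).to_csv(path, sep="\t", index=False)


def read_trials(path) -> list[TrialSpec]:
    return frame_to_trials(pd.read_csv(path, sep="\t", float_precision="round_trip"))
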