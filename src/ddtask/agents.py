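"""Synthetic participants playing timed sessions of the task.

Agents are hyperbolic discounters: the subjective value of a reward of
amount A at delay D is A / (1 + kD), with k the per-second discount rate.
Choice is a logistic (softmax) function of the subjective-value difference,
optionally shifted by an additive smaller-sooner bias. The bias term is what
lets the analysis chain disentangle a true shift in discounting (k) from a
response preference for the sooner option — the dissociation the signal
detection analysis targets.

Sessions are time-limited, not trial-limited: three blocks of 8 minutes
each, a new trial starting only while block time remains, and an in-flight
trial always running to completion and scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import DDTaskError, ValidationError
from .trials import GeneratorConfig, TrialSpec, generate_trials

Group = Literal["HC", "AN"]

#: Reaction-time clamp (s); matches the analysis-side validity filter so the
#: filter removes nothing on simulated data.
RT_MIN, RT_MAX = 0.3, 15.0
BLOCK_DURATION = 480.0  # s (8 min)
N_BLOCKS = 3
FEEDBACK_DURATION = 0.8  # s between reward collection and next offer


@dataclass(frozen=True)
class AgentParams:
    """Generative model of one participant.

    k: hyperbolic discount rate (1/s); tau: choice sensitivity (inverse
    temperature, 1/reward-unit); ss_bias: additive preference for the
    smaller-sooner option on the decision variable (reward units).
    """

    subject_id: str
    group: Group
    k: float
    tau: float
    ss_bias: float = 0.0
    rt_meanlog: float = math.log(1.4)
    rt_sdlog: float = 0.35

    def __post_init__(self) -> None:
        if self.k < 0 or self.tau < 0:
            raise ValidationError("k and tau must be >= 0")


@dataclass(frozen=True)
class ChoiceRecord:
    trial: TrialSpec
    choice: Literal["SS", "LL"]
    rt: float
    trial_duration: float
    loot_after: float  # cumulative reward units
    block: int
    t_elapsed_at_start: float


@dataclass
class SessionLog:
    """Ordered choice records of one participant's full session."""

    subject_id: str
    records: list[ChoiceRecord]
    group: str = "HC"
    block_duration: float = BLOCK_DURATION
    n_blocks: int = N_BLOCKS
    total_points: float = 0.0
    total_euros: float = 0.0

    def __len__(self) -> int:
        return len(self.records)


def subjective_value(amount: float, delay: float, k: float) -> float:
    """Hyperbolic present value: amount / (1 + k * delay)."""
    if amount < 0 or delay < 0 or k < 0:
        raise ValidationError("amount, delay and k must be >= 0")
    return amount / (1.0 + k * delay)


def choice_probability(trial: TrialSpec, agent: AgentParams) -> float:
    """Probability that the agent chooses the larger-later option.

    logistic(tau * (V_LL - V_SS - ss_bias)) with hyperbolic V. Delays enter
    relative to the sooner option's arrival: the SS reward is the temporal
    reference (delay 0) and the LL reward is discounted by the delay
    difference. This matches the indifference-point definition, which is
    indexed by the LL-SS delay difference, so at indifference
    r_ss / r_ll = 1 / (1 + k * delta) exactly.
    """
    delta = trial.t_ll - trial.t_ss
    v_ll = subjective_value(trial.r_ll, delta, agent.k)
    v_ss = subjective_value(trial.r_ss, 0.0, agent.k)
    return float(expit(agent.tau * (v_ll - v_ss - agent.ss_bias)))


def _draw_rt(agent: AgentParams, rng: np.random.Generator) -> float:
    return float(np.clip(rng.lognormal(agent.rt_meanlog, agent.rt_sdlog), RT_MIN, RT_MAX))


class _TrialStream:
    """Chunked lazy draw from the trial generator sharing one RNG."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator, chunk: int = 64):
        self.config, self.rng, self.chunk = config, rng, chunk
        self.buf: list[TrialSpec] = []

    def next(self) -> TrialSpec:
        if not self.buf:
            self.buf = generate_trials(self.config, self.chunk, rng=self.rng)[::-1]
        return self.buf.pop()


def simulate_session(
    agent: AgentParams,
    config: GeneratorConfig,
    seed: int | np.random.Generator,
    block_duration: float = BLOCK_DURATION,
    n_blocks: int = N_BLOCKS,
    feedback_duration: float = FEEDBACK_DURATION,
    policy: Literal["agent", "always_ss", "always_ll"] = "agent",
) -> SessionLog:
    """Play ``n_blocks`` timed blocks; deterministic given the seed.

    A new trial starts only while the block clock is below
    ``block_duration``; a started trial runs to completion and scores even
    if it overruns the block. Trial duration is reaction time plus travel
    time of the chosen option plus the feedback interval.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stream = _TrialStream(config, rng)
    records: list[ChoiceRecord] = []
    loot = 0.0
    trial_counter = 0
    for block in range(1, n_blocks + 1):
        t = 0.0
        while t < block_duration:
            trial = stream.next()
            trial = TrialSpec(trial_id=trial_counter, d_ss=trial.d_ss, d_ll=trial.d_ll,
                              r_ss=trial.r_ss, r_ll=trial.r_ll, t_ss=trial.t_ss,
                              t_ll=trial.t_ll, optimal_side=trial.optimal_side)
            trial_counter += 1
            rt = _draw_rt(agent, rng)
            if policy == "always_ss":
                choose_ll = False
            elif policy == "always_ll":
                choose_ll = True
            else:
                choose_ll = rng.random() < choice_probability(trial, agent)
            choice = "LL" if choose_ll else "SS"
            travel = (trial.d_ll if choose_ll else trial.d_ss) * config.seconds_per_square
            reward = trial.r_ll if choose_ll else trial.r_ss
            duration = rt + travel + feedback_duration
            loot += reward
            records.append(ChoiceRecord(
                trial=trial, choice=choice, rt=rt, trial_duration=duration,
                loot_after=loot, block=block, t_elapsed_at_start=t,
            ))
            t += duration
    points = loot * config.points_per_reward_unit
    return SessionLog(
        subject_id=agent.subject_id, group=agent.group, records=records,
        block_duration=block_duration, n_blocks=n_blocks,
        total_points=points,
        total_euros=points / (config.points_per_eurocent * 100),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Two matched cohorts of agents with clinical covariates.

    Covariate means/SDs default to the demographic profile of an acutely
    underweight anorexia nervosa sample and age-matched healthy controls
    (age ~16 y, strongly reduced BMI-SDS and elevated depression and
    eating-disorder scores in the patient group). Discounting parameters are
    drawn identically in both groups; the patient group receives a positive
    smaller-sooner bias linked negatively to BMI-SDS and positively to
    depressive symptoms.
    """

    n_per_group: int = 80
    seed: int = 0
    # discounting model (lognormal across subjects, shared between groups)
    k_meanlog: float = math.log(0.15)
    k_sdlog: float = 0.5
    tau_meanlog: float = math.log(2.0)
    tau_sdlog: float = 0.4
    # group-dependent SS preference (reward units)
    ss_bias_hc_mean: float = 0.0
    ss_bias_hc_sd: float = 0.0
    ss_bias_an_mean: float = 0.30
    ss_bias_an_sd: float = 0.15
    ss_bias_bmi_coef: float = -0.10  # per SD of BMI-SDS within the AN group
    ss_bias_bdi_coef: float = 0.10   # per SD of BDI-II within the AN group
    # covariates: (HC mean, HC sd, AN mean, AN sd)
    age: tuple[float, float, float, float] = (16.27, 2.51, 16.26, 2.48)
    bmi_sds: tuple[float, float, float, float] = (0.05, 0.64, -3.24, 1.07)
    bdi: tuple[float, float, float, float] = (4.57, 5.05, 26.29, 10.61)
    edi: tuple[float, float, float, float] = (132.81, 25.35, 221.92, 44.18)
    age_range: tuple[float, float] = (12.0, 26.0)

    def __post_init__(self) -> None:
        if self.n_per_group < 0:
            raise ValidationError("n_per_group must be >= 0")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float = -np.inf, hi: float = np.inf) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


COHORT_COLUMNS = ["subject_id", "group", "age", "bmi_sds", "bdi", "edi",
                  "true_k", "true_tau", "true_ss_bias"]


def sample_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, list[AgentParams]]:
    """Draw agents and covariates without playing sessions."""
    rng = np.random.default_rng(spec.seed)
    rows, agents = [], []
    for group in ("HC", "AN"):
        m_i = 0 if group == "HC" else 2
        for i in range(spec.n_per_group):
            age = _truncnorm(rng, spec.age[m_i], spec.age[m_i + 1], *spec.age_range)
            bmi = rng.normal(spec.bmi_sds[m_i], spec.bmi_sds[m_i + 1])
            bdi = _truncnorm(rng, spec.bdi[m_i], spec.bdi[m_i + 1], lo=0.0)
            edi = _truncnorm(rng, spec.edi[m_i], spec.edi[m_i + 1], lo=64.0)
            k = float(rng.lognormal(spec.k_meanlog, spec.k_sdlog))
            tau = float(rng.lognormal(spec.tau_meanlog, spec.tau_sdlog))
            if group == "HC":
                bias = max(0.0, rng.normal(spec.ss_bias_hc_mean, spec.ss_bias_hc_sd))
            else:
                z_bmi = (bmi - spec.bmi_sds[2]) / spec.bmi_sds[3]
                z_bdi = (bdi - spec.bdi[2]) / spec.bdi[3]
                bias = max(0.0, spec.ss_bias_an_mean
                           + spec.ss_bias_bmi_coef * z_bmi
                           + spec.ss_bias_bdi_coef * z_bdi
                           + rng.normal(0.0, spec.ss_bias_an_sd))
            sid = f"{group}{i + 1:03d}"
            agents.append(AgentParams(subject_id=sid, group=group, k=k, tau=tau, ss_bias=bias))
            rows.append(dict(subject_id=sid, group=group, age=age, bmi_sds=bmi,
                             bdi=bdi, edi=edi, true_k=k, true_tau=tau, true_ss_bias=bias))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS), agents


def simulate_cohort(
    spec: CohortSpec, config: GeneratorConfig
) -> tuple[pd.DataFrame, dict[str, SessionLog]]:
    """Full synthetic study: cohort table plus one session log per subject.

    Reproducible: per-subject RNG streams are spawned from ``spec.seed``, so
    the same spec and config give byte-identical outputs.
    """
    table, agents = sample_cohort(spec)
    streams = np.random.SeedSequence(spec.seed).spawn(max(len(agents), 1))
    logs: dict[str, SessionLog] = {}
    for agent, ss in zip(agents, streams):
        logs[agent.subject_id] = simulate_session(agent, config, np.random.default_rng(ss))
    return table, logs
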