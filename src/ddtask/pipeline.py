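"""End-to-end pipeline: simulate (or ingest) -> filter -> discounting ->
optimality/SDT -> group tests with FDR, bundled with provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agents import CohortSpec, SessionLog, simulate_cohort
from .discounting import K_FLOOR, analyze_subject
from .errors import DDTaskError, ValidationError
from .sdt import analyze_sdt, score_optimality
from .stats import bh_fdr, binomial_group_model, gaussian_group_model
from .trials import GeneratorConfig, calibrate_generator
from .io import logs_to_frame, write_choice_log

log = logging.getLogger("ddtask")


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one pipeline run; the seed is mandatory and feeds every
    random stream (generator calibration pilot, cohort, sessions)."""

    seed: int
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    k_floor: float = K_FLOOR
    alpha: float = 0.05
    power_sided: str = "one"
    out_dir: str | None = None

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        d = {k: enc(v) for k, v in dataclasses.asdict(self).items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "seed" not in d:
            raise ValidationError("pipeline config must carry an explicit seed")
        gen = d.pop("generator", {})
        coh = d.pop("cohort", {})
        for key in list(gen):
            if isinstance(gen[key], list):
                gen[key] = tuple(gen[key])
        for key in list(coh):
            if isinstance(coh[key], list):
                coh[key] = tuple(coh[key])
        gen.setdefault("seed", d["seed"])
        coh.setdefault("seed", d["seed"])
        return cls(generator=GeneratorConfig(**gen), cohort=CohortSpec(**coh), **d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    cohort: pd.DataFrame
    subject_results: pd.DataFrame
    group_tests: list[dict]
    schedule_summary: dict
    provenance: dict


def _derive(config: PipelineConfig) -> PipelineConfig:
    """Propagate the run seed into sub-configs that still carry defaults."""
    gen = dataclasses.replace(config.generator, seed=config.seed)
    coh = dataclasses.replace(config.cohort, seed=config.seed + 1)
    return dataclasses.replace(config, generator=gen, cohort=coh)


def analyze_logs(logs: dict[str, SessionLog], k_floor: float = K_FLOOR) -> pd.DataFrame:
    """Per-subject discounting + optimality + SDT table from session logs."""
    rows = []
    for sid, slog in logs.items():
        try:
            disc = analyze_subject(slog, k_floor=k_floor)
            opt = score_optimality(slog)
            sdt = analyze_sdt(slog)
        except DDTaskError as e:
            raise type(e)(f"subject {sid}: {e}") from e
        row = dict(
            subject_id=sid, group=slog.group,
            k=disc.k, log_k=disc.log_k, auc=disc.auc, prop_ss=disc.prop_ss,
            n_valid_trials=disc.n_valid_trials, fit_sse=disc.fit_sse,
            prop_optimal=opt.prop_optimal,
            prop_ss_given_ss_optimal=opt.prop_ss_given_ss_optimal,
            prop_ll_given_ll_optimal=opt.prop_ll_given_ll_optimal,
            n_ss_optimal=opt.n_ss_optimal, n_ll_optimal=opt.n_ll_optimal,
            hits=sdt.hits, misses=sdt.misses, false_alarms=sdt.false_alarms,
            correct_rejections=sdt.correct_rejections,
            d_prime=sdt.d_prime, beta=sdt.beta, criterion_c=sdt.criterion_c,
            correction_applied=sdt.correction_applied,
        )
        for p in disc.points:
            tag = f"{p.delay_diff:g}s"
            row[f"theta_{tag}"] = p.theta
            row[f"clipped_{tag}"] = p.clipped
            row[f"n_{tag}"] = p.n_trials
        rows.append(row)
    return pd.DataFrame(rows)


def group_tests(results: pd.DataFrame, cohort: pd.DataFrame) -> list[dict]:
    """The co-reported family of group contrasts, FDR-corrected together:
    proportion SS, AUC, log k, proportion optimal, the two side-conditional
    proportions, d' and beta — each with age as a covariate."""
    df = results.merge(cohort[["subject_id", "age"]], on="subject_id")
    group, age = df["group"], df["age"]
    tests = []

    def binom(name, successes, totals):
        tests.append(binomial_group_model(successes, totals, group, age, name=name))

    n_valid = df["n_valid_trials"].to_numpy()
    binom("prop_ss", np.round(df["prop_ss"] * n_valid), n_valid)
    tests.append(gaussian_group_model(df["auc"], group, age, name="auc"))
    tests.append(gaussian_group_model(df["log_k"], group, age, name="log_k"))
    n_scored = (df["n_ss_optimal"] + df["n_ll_optimal"]).to_numpy()
    binom("prop_optimal", np.round(df["prop_optimal"] * n_scored), n_scored)
    binom("prop_ss_given_ss_optimal",
          np.round(df["prop_ss_given_ss_optimal"] * df["n_ss_optimal"]),
          df["n_ss_optimal"].to_numpy())
    binom("prop_ll_given_ll_optimal",
          np.round(df["prop_ll_given_ll_optimal"] * df["n_ll_optimal"]),
          df["n_ll_optimal"].to_numpy())
    tests.append(gaussian_group_model(df["d_prime"], group, age, name="d_prime"))
    tests.append(gaussian_group_model(df["beta"], group, age, name="beta"))

    qs = bh_fdr([t.p for t in tests])
    out = []
    for t, q in zip(tests, qs):
        d = dataclasses.asdict(t)
        d["q"] = float(q)
        d["family"] = "primary_outcomes"
        out.append(d)
    return out


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Simulate the default synthetic study and run the full analysis chain.

    Deterministic given (config, seed). If ``config.out_dir`` is set, the
    cohort table, choice log, per-subject results and group-test JSON are
    written there.
    """
    config = _derive(config)
    gen = calibrate_generator(config.generator)
    log.info("generator calibrated: label prob %.4f", gen.ll_label_prob)
    cohort, logs = simulate_cohort(config.cohort, gen)
    log.info("simulated %d subjects", len(logs))
    results = analyze_logs(logs, k_floor=config.k_floor)
    tests = group_tests(results, cohort) if cohort["group"].nunique() == 2 else []

    from .trials import generate_trials, schedule_summary  # local: avoids cycle at import
    sched = schedule_summary(generate_trials(gen, 20_000))
    bundle = ReportBundle(
        cohort=cohort, subject_results=results, group_tests=tests,
        schedule_summary=dataclasses.asdict(sched),
        provenance=dict(config_hash=config.config_hash(), seed=config.seed,
                        version=__version__,
                        calibrated_ll_label_prob=gen.ll_label_prob),
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out / "cohort.csv", index=False)
        write_choice_log(logs, out / "choice_log.csv")
        results.to_csv(out / "subject_results.csv", index=False)
        (out / "group_tests.json").write_text(json.dumps(
            dict(tests=tests, schedule_summary=bundle.schedule_summary,
                 provenance=bundle.provenance), indent=2))
        log.info("wrote outputs to %s", out)
    return bundle
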