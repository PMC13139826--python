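import numpy as np
import pytest

from ddtask import (
    AgentParams, GeneratorConfig, calibrate_generator, generate_trials,
)
from ddtask.agents import ChoiceRecord, SessionLog, choice_probability


@pytest.fixture(scope="session")
def calibrated_config() -> GeneratorConfig:
    return calibrate_generator(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def big_schedule(calibrated_config):
    """100k calibrated trials shared across statistical checks."""
    return generate_trials(calibrated_config, 100_000)


def make_log(trials, choices, subject_id="s1", rts=None) -> SessionLog:
    """Build a session log from trials and a choice sequence (no timing)."""
    rts = rts if rts is not None else [1.0] * len(trials)
    loot = 0.0
    records = []
    for t, ch, rt in zip(trials, choices, rts):
        loot += t.r_ll if ch == "LL" else t.r_ss
        records.append(ChoiceRecord(
            trial=t, choice=ch, rt=rt, trial_duration=rt + 5.0,
            loot_after=loot, block=1, t_elapsed_at_start=0.0,
        ))
    return SessionLog(subject_id=subject_id, records=records)


def play_agent(trials, agent: AgentParams, seed=0) -> SessionLog:
    """Choices from the agent's generative model on a fixed trial set."""
    rng = np.random.default_rng(seed)
    choices = ["LL" if rng.random() < choice_probability(t, agent) else "SS"
               for t in trials]
    return make_log(trials, choices, subject_id=agent.subject_id)
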