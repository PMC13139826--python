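"""Choice-log CSV interchange.

One row per trial. This is both the output format of the simulator and the
ingestion format for real data exported from the task software. Delays are
recomputed from distances on read (t = d * seconds_per_square) and
cross-checked against any t columns present in the file.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agents import BLOCK_DURATION, ChoiceRecord, N_BLOCKS, SessionLog
from .errors import ValidationError
from .trials import TrialSpec, label_optimal

CHOICE_LOG_COLUMNS = [
    "subject_id", "group", "block", "trial_id", "d_ss", "d_ll", "r_ss", "r_ll",
    "choice", "rt", "trial_duration", "t_elapsed_at_start", "loot_after",
]

_NUMERIC = ["block", "trial_id", "d_ss", "d_ll", "r_ss", "r_ll",
            "rt", "trial_duration", "t_elapsed_at_start", "loot_after"]


def logs_to_frame(logs: dict[str, SessionLog]) -> pd.DataFrame:
    rows = []
    for sid, log in logs.items():
        for rec in log.records:
            t = rec.trial
            rows.append(dict(
                subject_id=sid, group=log.group, block=rec.block,
                trial_id=t.trial_id, d_ss=t.d_ss, d_ll=t.d_ll,
                r_ss=t.r_ss, r_ll=t.r_ll, choice=rec.choice, rt=rec.rt,
                trial_duration=rec.trial_duration,
                t_elapsed_at_start=rec.t_elapsed_at_start,
                loot_after=rec.loot_after,
            ))
    return pd.DataFrame(rows, columns=CHOICE_LOG_COLUMNS)


def write_choice_log(logs: dict[str, SessionLog], path) -> None:
    logs_to_frame(logs).to_csv(path, index=False)


def frame_to_logs(df: pd.DataFrame, seconds_per_square: float = 1.3,
                  block_duration: float = BLOCK_DURATION) -> dict[str, SessionLog]:
    """Validate a choice-log table and rebuild per-subject session logs.

    Raises ``ValidationError`` naming the offending row for missing columns,
    non-numeric fields, or delay columns inconsistent with the distances.
    """
    missing = set(CHOICE_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"choice log missing columns: {sorted(missing)}")
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise ValidationError(
                f"non-numeric value in column '{col}' at row {int(bad.idxmax())}")
        if vals.isna().any():
            raise ValidationError(
                f"missing value in column '{col}' at row {int(vals.isna().idxmax())}")
        df = df.assign(**{col: vals})
    for tcol, dcol in (("t_ss", "d_ss"), ("t_ll", "d_ll")):
        if tcol in df.columns:
            expect = df[dcol] * seconds_per_square
            bad = ~np.isclose(pd.to_numeric(df[tcol], errors="coerce"), expect)
            if bad.any():
                row = int(np.argmax(np.asarray(bad)))
                raise ValidationError(
                    f"row {row}: {tcol} inconsistent with {dcol} * {seconds_per_square}")
    if not df["choice"].isin(["SS", "LL"]).all():
        row = int(np.argmax(~df["choice"].isin(["SS", "LL"]).to_numpy()))
        raise ValidationError(f"row {row}: choice must be 'SS' or 'LL'")

    logs: dict[str, SessionLog] = {}
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values(["block", "trial_id"])
        records = []
        for r in sub.itertuples(index=False):
            t_ss = r.d_ss * seconds_per_square
            t_ll = r.d_ll * seconds_per_square
            trial = TrialSpec(
                trial_id=int(r.trial_id), d_ss=int(r.d_ss), d_ll=int(r.d_ll),
                r_ss=int(r.r_ss), r_ll=int(r.r_ll), t_ss=t_ss, t_ll=t_ll,
                optimal_side=label_optimal(r.r_ss, t_ss, r.r_ll, t_ll),
            )
            records.append(ChoiceRecord(
                trial=trial, choice=str(r.choice), rt=float(r.rt),
                trial_duration=float(r.trial_duration),
                loot_after=float(r.loot_after), block=int(r.block),
                t_elapsed_at_start=float(r.t_elapsed_at_start),
            ))
        n_blocks = int(sub["block"].max()) if len(sub) else N_BLOCKS
        logs[str(sid)] = SessionLog(
            subject_id=str(sid), records=records,
            group=str(sub["group"].iloc[0]),
            block_duration=block_duration, n_blocks=n_blocks,
        )
    return logs


def read_choice_log(path, seconds_per_square: float = 1.3) -> dict[str, SessionLog]:
    return frame_to_logs(pd.read_csv(path, float_precision="round_trip"),
                         seconds_per_square=seconds_per_square)
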