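"""Behavioral metrics per session and trial type.

Percent correct, reaction time (odor-port exit to fluid-well entry; trials
without a well entry are assigned the full 2-s response window), poke
latency (light onset to odor-port entry), and the |S1 - S2| difference of
each metric at matched positions — a session-level index of how strongly
behavior distinguishes the two sequences.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .task import SessionRecord, TrialRecord, trial_type_label, trial_type_of

METRICS = ("percent_correct", "reaction_time", "poke_latency")


def percent_correct(trials: list[TrialRecord]) -> Optional[float]:
    """100 x correct / completed; aborted trials excluded; None if no trials."""
    completed = [t for t in trials if not t.aborted]
    if not completed:
        return None
    return 100.0 * sum(t.correct for t in completed) / len(completed)


def reaction_time(trial: TrialRecord, response_window: float = 2.0) -> Optional[float]:
    """Seconds from odor-port exit to well entry.

    Trials without a well entry (correct no-go, and also missed go
    responses) are assigned the full response window.  None when the trial
    has no port exit.
    """
    if trial.poke_out is None:
        return None
    if trial.well_entry is not None:
        return trial.well_entry - trial.poke_out
    return response_window


def poke_latency(trial: TrialRecord) -> Optional[float]:
    """Seconds from light onset to odor-port entry; None for missed trials."""
    if trial.poke_in is None:
        return None
    return trial.poke_in - trial.light_on


def behavior_table(sessions: list[SessionRecord]) -> pd.DataFrame:
    """Per (session, trial type): percent correct, mean RT, mean poke latency."""
    rows = []
    for session in sessions:
        window = session.task.response_window
        for tt in range(1, 9):
            trials = session.trials_of_type(tt)
            seq, pos = trial_type_label(tt)
            rts = [r for t in trials if (r := reaction_time(t, window)) is not None]
            lats = [l for t in trials if (l := poke_latency(t)) is not None]
            rows.append(
                {
                    "session": session.session_id,
                    "trial_type": tt,
                    "sequence": seq,
                    "position": pos,
                    "percent_correct": percent_correct(trials),
                    "reaction_time": float(np.mean(rts)) if rts else None,
                    "poke_latency": float(np.mean(lats)) if lats else None,
                }
            )
    return pd.DataFrame(rows)


def sequence_difference_scores(table: pd.DataFrame) -> pd.DataFrame:
    """|S1 - S2| of each metric per (session, position).

    Invariant to swapping the sequence labels; larger values mean behavior
    treats the two sequences more differently at that position.
    """
    rows = []
    for (session, pos), grp in table.groupby(["session", "position"]):
        s1 = grp[grp["sequence"] == "S1"]
        s2 = grp[grp["sequence"] == "S2"]
        if len(s1) != 1 or len(s2) != 1:
            continue
        for metric in METRICS:
            v1 = s1[metric].iloc[0]
            v2 = s2[metric].iloc[0]
            if v1 is None or v2 is None or pd.isna(v1) or pd.isna(v2):
                continue
            rows.append(
                {
                    "session": session,
                    "position": pos,
                    "metric": metric,
                    "difference": abs(float(v1) - float(v2)),
                }
            )
    return pd.DataFrame(rows)
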