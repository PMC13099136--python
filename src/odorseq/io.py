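"""Session container I/O.

A session is stored as a directory of plain-text files:

* ``session.json`` — manifest: task configuration and free-form metadata,
* ``trials.csv``   — one row per trial, columns exactly the trial fields,
  empty cell = absent timestamp,
* ``spikes.csv``   — long-form ``unit_id, spike_time`` rows (plus a
  ``units.csv`` table carrying unit order and group labels so that a unit
  with zero spikes survives the round trip).

All times are seconds from session start, written at microsecond precision
so writing is deterministic and the round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .task import SessionRecord, TaskConfig, TrialRecord, UnitSpikeTrain, ValidationError

_TRIAL_COLUMNS = [
    "trial_index", "sequence", "position", "odor_id", "rewarded", "response",
    "correct", "light_on", "poke_in", "odor_on", "poke_out", "well_entry",
    "reward_time", "aborted",
]
_TIME_COLUMNS = ["light_on", "poke_in", "odor_on", "poke_out", "well_entry", "reward_time"]
_FLOAT_FORMAT = "%.6f"


def write_session(session: SessionRecord, path: str | Path) -> Path:
    """Write ``session`` as a container directory at ``path`` (created if needed).

    The byte content is deterministic for identical input sessions.
    """
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    manifest = {
        "session_id": session.session_id,
        "task": {
            "odors_by_position_s1": list(session.task.odors_by_position_s1),
            "odors_by_position_s2": list(session.task.odors_by_position_s2),
            "reward_by_position": list(session.task.reward_by_position),
            "n_repeats_per_sequence": session.task.n_repeats_per_sequence,
            "response_window": session.task.response_window,
            "iti_correct": session.task.iti_correct,
            "iti_error": session.task.iti_error,
            "reward_delay_range": list(session.task.reward_delay_range),
            "odor_onset_delay": session.task.odor_onset_delay,
            "min_hold": session.task.min_hold,
            "light_timeout": session.task.light_timeout,
        },
        "metadata": session.metadata,
    }
    (path / "session.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    rows = []
    for t in session.trials:
        row = {c: getattr(t, c) for c in _TRIAL_COLUMNS}
        rows.append(row)
    trials = pd.DataFrame(rows, columns=_TRIAL_COLUMNS)
    trials.to_csv(path / "trials.csv", index=False, float_format=_FLOAT_FORMAT)

    units = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in session.units],
            "group_label": [u.group_label for u in session.units],
        }
    )
    units.to_csv(path / "units.csv", index=False)

    if session.units:
        spike_frames = [
            pd.DataFrame({"unit_id": u.unit_id, "spike_time": u.spike_times})
            for u in session.units
        ]
        spikes = pd.concat(spike_frames, ignore_index=True)
    else:
        spikes = pd.DataFrame(columns=["unit_id", "spike_time"])
    spikes.to_csv(path / "spikes.csv", index=False, float_format=_FLOAT_FORMAT)
    return path


def read_session(path: str | Path) -> SessionRecord:
    """Read a container written by :func:`write_session`, validating all invariants."""
    path = Path(path)
    manifest_path = path / "session.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no session manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    tc = manifest["task"]
    task = TaskConfig(
        odors_by_position_s1=tuple(tc["odors_by_position_s1"]),
        odors_by_position_s2=tuple(tc["odors_by_position_s2"]),
        reward_by_position=tuple(tc["reward_by_position"]),
        n_repeats_per_sequence=tc["n_repeats_per_sequence"],
        response_window=tc["response_window"],
        iti_correct=tc["iti_correct"],
        iti_error=tc["iti_error"],
        reward_delay_range=tuple(tc["reward_delay_range"]),
        odor_onset_delay=tc["odor_onset_delay"],
        min_hold=tc["min_hold"],
        light_timeout=tc["light_timeout"],
    )

    trials_df = pd.read_csv(path / "trials.csv")
    trials = []
    for _, row in trials_df.iterrows():
        kwargs = {
            "trial_index": int(row["trial_index"]),
            "sequence": str(row["sequence"]),
            "position": int(row["position"]),
            "odor_id": int(row["odor_id"]),
            "rewarded": bool(row["rewarded"]),
            "response": str(row["response"]),
            "correct": bool(row["correct"]),
            "aborted": bool(row["aborted"]),
        }
        for c in _TIME_COLUMNS:
            v = row[c]
            kwargs[c] = None if pd.isna(v) else float(v)
        trials.append(TrialRecord(**kwargs))

    units_df = pd.read_csv(path / "units.csv", dtype={"unit_id": str})
    units_df["group_label"] = units_df.get("group_label", "").fillna("")
    spikes_df = pd.read_csv(path / "spikes.csv", dtype={"unit_id": str})
    by_unit = dict(iter(spikes_df.groupby("unit_id"))) if len(spikes_df) else {}
    units = []
    for _, row in units_df.iterrows():
        uid = row["unit_id"]
        grp = by_unit.get(uid)
        times = grp["spike_time"].to_numpy(float) if grp is not None else np.empty(0)
        units.append(UnitSpikeTrain(unit_id=uid, spike_times=times, group_label=str(row["group_label"])))

    session = SessionRecord(
        session_id=manifest["session_id"],
        task=task,
        trials=trials,
        units=units,
        metadata=manifest.get("metadata", {}),
    )
    session.validate()
    return session
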