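"""Domain types for the figure-8 odor-sequence task.

The task interleaves two four-position odor sequences (S1, S2) that share
their middle odors: positions P2 and P3 present physically identical odors
in both sequences, while P1 and P4 carry sequence-unique odors.  Positions
P1 and P4 are rewarded (go trials), P2 and P3 are not (no-go trials).  A
complete session traverses S1 and S2 in alternation, 40 repeats of each
sequence, yielding 320 trials and 8 trial types (sequence x position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

SEQUENCES = ("S1", "S2")
POSITIONS = (1, 2, 3, 4)

#: Timestamp resolution in seconds; spikes closer than this are duplicates.
TIME_RESOLUTION = 1e-6


class ValidationError(ValueError):
    """A session, trial, or unit violates a structural invariant."""


@dataclass(frozen=True)
class TaskConfig:
    """Timing and odor layout of a figure-8 session.

    Defaults are the standard task values: sequences S1 = (5+, 0-, 1-, 2+)
    and S2 = (3+, 0-, 1-, 4+), a 2-s response window, 4-s / 8-s ITIs after
    correct / error trials, reward delivered 0.4-1.5 s after well entry,
    odor onset 0.5 s after port entry, a 0.5-s minimum odor-port hold, and
    a 5-s window to initiate the trial after light onset.
    """

    odors_by_position_s1: tuple[int, int, int, int] = (5, 0, 1, 2)
    odors_by_position_s2: tuple[int, int, int, int] = (3, 0, 1, 4)
    reward_by_position: tuple[bool, bool, bool, bool] = (True, False, False, True)
    n_repeats_per_sequence: int = 40
    response_window: float = 2.0
    iti_correct: float = 4.0
    iti_error: float = 8.0
    reward_delay_range: tuple[float, float] = (0.4, 1.5)
    odor_onset_delay: float = 0.5
    min_hold: float = 0.5
    light_timeout: float = 5.0

    def __post_init__(self) -> None:
        s1, s2 = self.odors_by_position_s1, self.odors_by_position_s2
        if len(s1) != 4 or len(s2) != 4 or len(self.reward_by_position) != 4:
            raise ValidationError("odor and reward layouts must have 4 positions")
        if s1[1] != s2[1] or s1[2] != s2[2]:
            raise ValidationError("P2 and P3 odors must be shared across sequences")
        if s1[0] == s2[0] or s1[3] == s2[3]:
            raise ValidationError("P1 and P4 odors must differ across sequences")
        if tuple(self.reward_by_position) != (True, False, False, True):
            raise ValidationError("exactly positions P1 and P4 are rewarded")
        if self.n_repeats_per_sequence < 1:
            raise ValidationError("n_repeats_per_sequence must be positive")

    def odor_at(self, sequence: str, position: int) -> int:
        odors = self.odors_by_position_s1 if sequence == "S1" else self.odors_by_position_s2
        return odors[position - 1]

    @property
    def n_trials_complete(self) -> int:
        return 2 * self.n_repeats_per_sequence * 4


# Order of optional event timestamps within a trial; present ones must be
# strictly increasing in this order.
_EVENT_ORDER = ("light_on", "poke_in", "odor_on", "poke_out", "well_entry", "reward_time")


@dataclass
class TrialRecord:
    """One behavioral trial with its event timestamps (seconds from session start)."""

    trial_index: int
    sequence: str
    position: int
    odor_id: int
    rewarded: bool
    response: str  # "go" | "no-go"
    correct: bool
    light_on: float
    poke_in: Optional[float] = None
    odor_on: Optional[float] = None
    poke_out: Optional[float] = None
    well_entry: Optional[float] = None
    reward_time: Optional[float] = None
    aborted: bool = False

    def validate(self) -> None:
        if self.sequence not in SEQUENCES:
            raise ValidationError(f"trial {self.trial_index}: bad sequence {self.sequence!r}")
        if self.position not in POSITIONS:
            raise ValidationError(f"trial {self.trial_index}: bad position {self.position!r}")
        if self.response not in ("go", "no-go"):
            raise ValidationError(f"trial {self.trial_index}: bad response {self.response!r}")
        events = [(name, getattr(self, name)) for name in _EVENT_ORDER]
        present = [(n, t) for n, t in events if t is not None]
        for (n0, t0), (n1, t1) in zip(present, present[1:]):
            if not t1 > t0:
                raise ValidationError(
                    f"trial {self.trial_index}: {n1} ({t1}) not after {n0} ({t0})"
                )
        if self.aborted:
            return
        expect_reward = self.rewarded and self.response == "go" and self.correct
        if expect_reward != (self.reward_time is not None):
            raise ValidationError(
                f"trial {self.trial_index}: reward_time present iff rewarded go correct"
            )
        correct_rule = (self.rewarded and self.response == "go") or (
            not self.rewarded and self.response == "no-go"
        )
        if self.correct != correct_rule:
            raise ValidationError(
                f"trial {self.trial_index}: correct flag inconsistent with "
                f"rewarded={self.rewarded}, response={self.response}"
            )


def trial_type_of(trial: TrialRecord) -> int:
    """Map (sequence, position) to a trial type in 1..8.

    Ordering: S1-P1 .. S1-P4 are types 1-4, S2-P1 .. S2-P4 are types 5-8.
    """
    return (0 if trial.sequence == "S1" else 4) + trial.position


def trial_type_label(trial_type: int) -> tuple[str, int]:
    """Inverse of :func:`trial_type_of`: trial type -> (sequence, position)."""
    if not 1 <= trial_type <= 8:
        raise ValueError(f"trial type must be 1..8, got {trial_type}")
    return ("S1" if trial_type <= 4 else "S2"), (trial_type - 1) % 4 + 1


@dataclass
class UnitSpikeTrain:
    """Spike timestamps of one isolated unit."""

    unit_id: str
    spike_times: np.ndarray
    group_label: str = ""

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)

    def validate(self, *, collapse_duplicates: bool = False) -> None:
        t = self.spike_times
        if t.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike_times must be 1-D")
        if t.size and t[0] < 0:
            raise ValidationError(f"unit {self.unit_id}: negative spike time")
        if np.any(np.diff(t) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike_times not sorted")
        # half the resolution: spikes a full resolution step apart are distinct
        dup = np.diff(t) < 0.5 * TIME_RESOLUTION
        if np.any(dup):
            if collapse_duplicates:
                keep = np.concatenate([[True], ~dup])
                n = int(np.sum(~keep))
                logger.warning("unit %s: collapsed %d duplicate spike(s)", self.unit_id, n)
                self.spike_times = t[keep]
            else:
                raise ValidationError(
                    f"unit {self.unit_id}: duplicate spikes within {TIME_RESOLUTION} s"
                )


@dataclass
class SessionRecord:
    """One recording session: task configuration, trials, and unit spike trains."""

    session_id: str
    task: TaskConfig
    trials: list[TrialRecord]
    units: list[UnitSpikeTrain]
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for trial in self.trials:
            trial.validate()
        for unit in self.units:
            unit.validate()
        counts: dict[int, int] = {}
        for trial in self.trials:
            if not trial.aborted:
                tt = trial_type_of(trial)
                counts[tt] = counts.get(tt, 0) + 1
        n = self.task.n_repeats_per_sequence
        if len(self.trials) == self.task.n_trials_complete:
            bad = {tt: c for tt, c in counts.items() if c != n}
            if bad and not any(t.aborted for t in self.trials):
                raise ValidationError(
                    f"session {self.session_id}: complete session must have "
                    f"{n} trials per type, got {bad}"
                )

    @property
    def is_complete(self) -> bool:
        """True when every trial type has the full repeat count of valid trials."""
        n = self.task.n_repeats_per_sequence
        counts: dict[int, int] = {}
        for trial in self.trials:
            if not trial.aborted:
                tt = trial_type_of(trial)
                counts[tt] = counts.get(tt, 0) + 1
        return all(counts.get(tt, 0) == n for tt in range(1, 9))

    def trials_of_type(self, trial_type: int, *, correct_only: bool = False) -> list[TrialRecord]:
        out = []
        for trial in self.trials:
            if trial.aborted:
                continue
            if trial_type_of(trial) != trial_type:
                continue
            if correct_only and not trial.correct:
                continue
            out.append(trial)
        return out
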