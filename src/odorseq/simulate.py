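"""Synthetic figure-8 sessions with planted population structure.

The generator produces complete :class:`~odorseq.task.SessionRecord` objects
— task schedule, behavioral event timestamps, and inhomogeneous-Poisson
spike trains — from population templates with known ground truth, so that
every downstream analysis (selectivity, decoding, tensor decomposition,
mutual information) can be scored against what was planted.

Two templates express the two population regimes the pipeline is designed
to distinguish:

* ``compressed`` — units respond identically on the two sequences at the
  shared-odor positions P2/P3 (and nearly so elsewhere, outside the Odor
  epoch where the physical odors differ at P1/P4); the population carries
  several *global* components: trial-wide temporal motifs whose amplitude
  drifts slowly over the session.
* ``differentiated`` — a configurable fraction of units fire differently
  on S1 versus S2 at P1, late P3, and P4 epochs; no global drift
  components; behavior shows sequence-dependent latency shifts.

Rate model per unit: a baseline rate multiplied by epoch/position/sequence
gain windows, plus the baseline-scaled sum of the population's global
motifs weighted by the unit's participation.  Gain windows are
flat over the post-event analysis interval [+0.1, +0.6) s around each
epoch anchor with 150-ms cosine tapers on both sides, so a planted gain g
equals the measured rate ratio in that epoch.  Spikes are drawn by
thinning a homogeneous Poisson process against the rate evaluated on a
10-ms grid (well below the 100-ms analysis bin).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .peth import EPOCHS, anchor_epochs
from .task import (
    SessionRecord,
    TaskConfig,
    TrialRecord,
    UnitSpikeTrain,
    trial_type_of,
)

_DT = 0.01  # rate-evaluation grid (s)
_TAPER = 0.15  # cosine taper width of the epoch gain window (s)

# Drift functions over normalized session time tau in [0, 1].
DRIFT_FUNCTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "const": lambda tau: np.ones_like(tau),
    "ramp": lambda tau: tau,
    "halfsine": lambda tau: np.sin(np.pi * tau),
}


@dataclass
class GlobalComponent:
    """A population-wide temporal motif with slow across-trial drift.

    ``profile`` gives the motif's strength at each of the 9 task epochs;
    ``drift`` names a function of normalized trial time scaling the motif
    over the session; ``amplitude`` is the peak fractional rate modulation.
    """

    profile: np.ndarray  # length 9, values in [0, 1]
    drift: str  # key in DRIFT_FUNCTIONS
    amplitude: float

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.shape != (9,):
            raise ValueError("global component profile must have 9 epoch values")
        if self.drift not in DRIFT_FUNCTIONS:
            raise ValueError(f"unknown drift {self.drift!r}")


@dataclass
class UnitTuningProfile:
    """Ground-truth firing-rate model of one unit.

    ``epoch_gains`` maps ``(position, epoch)`` to a multiplicative gain
    applied on both sequences; ``sequence_gain`` maps ``(position, epoch)``
    to an S1/S2 asymmetry (gain applied on S1; 1.0 = none).  The shared
    odors at P2/P3 are physically identical across sequences, so any
    template must keep ``sequence_gain == 1`` there.  ``global_weights``
    scales the unit's participation in each population-wide component.
    """

    baseline_rate: float
    epoch_gains: dict[tuple[int, str], float] = field(default_factory=dict)
    sequence_gain: dict[tuple[int, str], float] = field(default_factory=dict)
    global_components: list[GlobalComponent] = field(default_factory=list)
    global_weights: list[float] = field(default_factory=list)

    def gain_for(self, position: int, epoch: str, sequence: str) -> float:
        g = self.epoch_gains.get((position, epoch), 1.0)
        s = self.sequence_gain.get((position, epoch), 1.0)
        return g * (s if sequence == "S1" else 1.0)


@dataclass
class BehaviorProfile:
    """Per-trial-type accuracy and latency distributions.

    Latencies are lognormal; ``sequence_latency_shift`` is added to the
    log-mean of both latencies on S2 trials (0 = no sequence dependence).
    """

    accuracy_by_type: dict[int, float]
    poke_latency_log: tuple[float, float] = (np.log(0.4), 0.4)
    reaction_time_log: tuple[float, float] = (np.log(0.7), 0.35)
    hold_extra_log: tuple[float, float] = (np.log(0.15), 0.3)
    sequence_latency_shift: float = 0.0


# (position, epoch) cells where the differentiated template plants
# sequence selectivity: P1, late P3, and most of P4.
PLANTED_CELLS_DIFFERENTIATED: tuple[tuple[int, str], ...] = (
    (1, "Odor"), (1, "Unpoke"), (1, "Choice"),
    (3, "Outcome"), (3, "postOut"), (3, "ITI-b"),
    (4, "Poke"), (4, "Odor"), (4, "Unpoke"), (4, "Choice"), (4, "Outcome"),
)

_DEFAULT_GLOBAL_COMPONENTS = (
    # broad early motif, active on most trials, no drift
    GlobalComponent(np.array([1.0, 1.0, 0.8, 0.4, 0.2, 0.1, 0.1, 0.2, 0.4]), "const", 1.2),
    # mid-trial motif ramping up over the session
    GlobalComponent(np.array([0.1, 0.2, 0.5, 0.7, 1.0, 1.0, 0.8, 0.4, 0.2]), "ramp", 1.5),
    # late-trial motif with a slow half-period oscillation over the session
    GlobalComponent(np.array([0.1, 0.1, 0.2, 0.3, 0.5, 0.8, 1.0, 1.0, 0.8]), "halfsine", 1.5),
)


@dataclass
class PopulationTemplate:
    """Sampler of unit tuning profiles plus the behavioral regime.

    ``name`` selects the planted structure (``"compressed"`` or
    ``"differentiated"``); ``selective_fraction`` is the fraction of units
    given sequence selectivity at the planted cells (differentiated only);
    ``sequence_gain_mean`` the mean planted S1/S2 gain ratio.
    """

    name: str
    n_units: int = 300
    baseline_log_median: float = 2.0  # Hz, lognormal median
    baseline_log_sigma: float = 0.6
    epoch_active_prob: float = 0.6
    off_position_active_prob: float = 0.2
    selective_fraction: float = 0.3
    sequence_gain_mean: float = 2.0
    odor_selective_fraction: float = 0.5
    reward_responsive_prob: float = 0.5
    global_components: tuple[GlobalComponent, ...] = ()
    behavior_latency_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ("compressed", "differentiated"):
            raise ValueError(f"unknown template {self.name!r}")

    @classmethod
    def compressed(cls, n_units: int = 300, **kw) -> "PopulationTemplate":
        return cls(
            name="compressed",
            n_units=n_units,
            global_components=_DEFAULT_GLOBAL_COMPONENTS,
            behavior_latency_shift=0.0,
            **kw,
        )

    @classmethod
    def differentiated(cls, n_units: int = 300, **kw) -> "PopulationTemplate":
        return cls(
            name="differentiated",
            n_units=n_units,
            global_components=(),
            behavior_latency_shift=0.15,
            **kw,
        )

    def behavior_profile(self) -> BehaviorProfile:
        # go (rewarded) types are easier than no-go types, as in trained rats
        acc = {}
        for tt in range(1, 9):
            position = (tt - 1) % 4 + 1
            acc[tt] = 0.92 if position in (1, 4) else 0.85
        return BehaviorProfile(
            accuracy_by_type=acc,
            sequence_latency_shift=self.behavior_latency_shift,
        )

    def sample_unit(self, rng: np.random.Generator) -> tuple[UnitTuningProfile, dict]:
        """Draw one unit's tuning; returns (profile, ground-truth flags)."""
        baseline = float(np.exp(np.log(self.baseline_log_median)
                                + self.baseline_log_sigma * rng.standard_normal()))
        epoch_gains: dict[tuple[int, str], float] = {}
        preferred = int(rng.integers(1, 5))
        for epoch in EPOCHS:
            if rng.random() < self.epoch_active_prob:
                epoch_gains[(preferred, epoch)] = 1.0 + float(rng.gamma(2.0, 0.75))
        for position in (1, 2, 3, 4):
            for epoch in EPOCHS:
                if position == preferred or (position, epoch) in epoch_gains:
                    continue
                if rng.random() < self.off_position_active_prob:
                    epoch_gains[(position, epoch)] = 1.0 + float(rng.gamma(2.0, 0.4))
        # reward responses at the outcome epochs of the rewarded positions;
        # identical on both sequences, so they never masquerade as
        # sequence selectivity
        if rng.random() < self.reward_responsive_prob:
            for position in (1, 4):
                for epoch in ("Choice", "Outcome", "postOut"):
                    base = epoch_gains.get((position, epoch), 1.0)
                    epoch_gains[(position, epoch)] = base + float(rng.gamma(2.0, 1.0))

        sequence_gain: dict[tuple[int, str], float] = {}
        planted: list[tuple[int, str]] = []
        if self.name == "compressed":
            # Only the Odor epoch at the unique-odor positions can differ:
            # the stimuli themselves differ there.
            if rng.random() < self.odor_selective_fraction:
                for position in (1, 4):
                    g = 1.0 + float(rng.gamma(2.0, (self.sequence_gain_mean - 1.0) / 2.0))
                    if rng.random() < 0.5:
                        g = 1.0 / g
                    sequence_gain[(position, "Odor")] = g
                    planted.append((position, "Odor"))
        else:
            if rng.random() < self.selective_fraction:
                for cell in PLANTED_CELLS_DIFFERENTIATED:
                    g = 1.0 + float(rng.gamma(2.0, (self.sequence_gain_mean - 1.0) / 2.0))
                    if rng.random() < 0.5:
                        g = 1.0 / g
                    sequence_gain[cell] = g
                    planted.append(cell)

        weights = [float(np.exp(0.5 * rng.standard_normal()))
                   for _ in self.global_components]
        profile = UnitTuningProfile(
            baseline_rate=baseline,
            epoch_gains=epoch_gains,
            sequence_gain=sequence_gain,
            global_components=list(self.global_components),
            global_weights=weights,
        )
        truth = {
            "baseline_rate": baseline,
            "preferred_position": preferred,
            "sequence_selective_cells": planted,
            "sequence_selective": bool(planted),
            "global_weights": weights,
        }
        return profile, truth


@dataclass
class GroundTruth:
    """Everything planted by :func:`simulate_group`, for scoring recovery."""

    template_name: str
    seed: int
    units_per_session: list[list[dict]]
    global_components: list[dict]
    behavior: dict

    def selective_fraction_at(self, position: int, epoch: str, session: int = 0) -> float:
        units = self.units_per_session[session]
        flags = [(position, epoch) in {tuple(c) for c in u["sequence_selective_cells"]}
                 for u in units]
        return float(np.mean(flags))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "template_name": self.template_name,
            "seed": self.seed,
            "units_per_session": self.units_per_session,
            "global_components": self.global_components,
            "behavior": self.behavior,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def make_task_schedule(
    task: TaskConfig, seed: int | np.random.Generator
) -> list[tuple[str, int, int, bool]]:
    """Build the trial schedule: alternating S1/S2 blocks of positions 1-4.

    The starting sequence is drawn pseudorandomly from the seed.  Returns
    ``(sequence, position, odor_id, rewarded)`` per trial.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    first = "S1" if rng.random() < 0.5 else "S2"
    second = "S2" if first == "S1" else "S1"
    schedule = []
    for _ in range(task.n_repeats_per_sequence):
        for sequence in (first, second):
            for position in (1, 2, 3, 4):
                schedule.append(
                    (
                        sequence,
                        position,
                        task.odor_at(sequence, position),
                        task.reward_by_position[position - 1],
                    )
                )
    return schedule


def simulate_behavior(
    schedule: list[tuple[str, int, int, bool]],
    profile: BehaviorProfile,
    task: TaskConfig,
    seed: int | np.random.Generator,
) -> list[TrialRecord]:
    """Draw correctness and event timestamps for each scheduled trial.

    Timing follows the task rules: odor 0.5 s after port entry, a 0.5-s
    minimum hold, a 2-s response window after port exit, reward 0.4-1.5 s
    after well entry, and a 4-s (correct) or 8-s (error) inter-trial
    interval.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu_poke, sd_poke = profile.poke_latency_log
    mu_rt, sd_rt = profile.reaction_time_log
    mu_hold, sd_hold = profile.hold_extra_log
    trials: list[TrialRecord] = []
    t = 1.0
    for i, (sequence, position, odor, rewarded) in enumerate(schedule):
        shift = profile.sequence_latency_shift if sequence == "S2" else 0.0
        light_on = t
        poke_latency = float(np.exp(mu_poke + shift + sd_poke * rng.standard_normal()))
        poke_latency = min(max(poke_latency, 0.05), task.light_timeout - 0.1)
        poke_in = light_on + poke_latency
        odor_on = poke_in + task.odor_onset_delay
        hold_extra = float(np.exp(mu_hold + sd_hold * rng.standard_normal()))
        poke_out = odor_on + task.min_hold + min(hold_extra, 1.0)

        tt = (0 if sequence == "S1" else 4) + position
        correct = bool(rng.random() < profile.accuracy_by_type[tt])
        if rewarded:
            response = "go" if correct else "no-go"
        else:
            response = "no-go" if correct else "go"

        well_entry = reward_time = None
        if response == "go":
            rt = float(np.exp(mu_rt + shift + sd_rt * rng.standard_normal()))
            rt = min(max(rt, 0.1), task.response_window - 0.05)
            well_entry = poke_out + rt
            if rewarded and correct:
                reward_time = well_entry + float(rng.uniform(*task.reward_delay_range))
                end = reward_time + 1.0
            else:
                end = poke_out + task.response_window
        else:
            end = poke_out + task.response_window

        # quantize to the container's microsecond timestamp resolution
        us = lambda x: None if x is None else round(x, 6)
        trials.append(
            TrialRecord(
                trial_index=i,
                sequence=sequence,
                position=position,
                odor_id=odor,
                rewarded=rewarded,
                response=response,
                correct=correct,
                light_on=us(light_on),
                poke_in=us(poke_in),
                odor_on=us(odor_on),
                poke_out=us(poke_out),
                well_entry=us(well_entry),
                reward_time=us(reward_time),
            )
        )
        t = end + (task.iti_correct if correct else task.iti_error)
    return trials


def _epoch_window(grid: np.ndarray, anchor: float) -> np.ndarray:
    """Tapered gain window: flat over [anchor+0.1, anchor+0.6), cosine edges."""
    w = np.zeros_like(grid)
    lo, hi = anchor + 0.1, anchor + 0.6
    rise = (grid >= lo - _TAPER) & (grid < lo)
    fall = (grid >= hi) & (grid < hi + _TAPER)
    flat = (grid >= lo) & (grid < hi)
    w[flat] = 1.0
    w[rise] = 0.5 * (1.0 - np.cos(np.pi * (grid[rise] - (lo - _TAPER)) / _TAPER))
    w[fall] = 0.5 * (1.0 + np.cos(np.pi * (grid[fall] - hi) / _TAPER))
    return w


@dataclass
class _SessionDesign:
    """Precomputed epoch windows and shared component grids for one trial list.

    Computing the window geometry once per session (it is identical for
    every unit) keeps per-unit simulation cheap.
    """

    t_end: float
    n_grid: int
    # one entry per (trial, epoch): slice bounds, window, position, sequence, epoch name
    windows: list[tuple[int, int, np.ndarray, int, str, str]]
    component_grids: list[np.ndarray]  # amplitude-scaled grid per template component

    @classmethod
    def build(cls, trials: list[TrialRecord],
              components: Sequence[GlobalComponent] = ()) -> "_SessionDesign":
        t_end = max(
            t for trial in trials
            for t in (trial.reward_time, trial.well_entry, trial.poke_out, trial.light_on)
            if t is not None
        ) + 4.0
        grid = np.arange(0.0, t_end, _DT)
        n_trials = len(trials)
        drift_cache = {
            name: fn(np.arange(n_trials) / max(n_trials - 1, 1))
            for name, fn in DRIFT_FUNCTIONS.items()
        }
        windows = []
        comp_grids = [np.zeros_like(grid) for _ in components]
        for k, trial in enumerate(trials):
            anchors = anchor_epochs(trial)
            for e_idx, epoch in enumerate(EPOCHS):
                anchor = anchors[epoch]
                i0 = max(int((anchor + 0.1 - _TAPER) / _DT) - 1, 0)
                i1 = min(int((anchor + 0.6 + _TAPER) / _DT) + 2, grid.size)
                if i1 <= i0:
                    continue
                w = _epoch_window(grid[i0:i1], anchor)
                windows.append((i0, i1, w, trial.position, trial.sequence, epoch))
                for c, comp in enumerate(components):
                    amp = comp.amplitude * comp.profile[e_idx] * drift_cache[comp.drift][k]
                    if amp != 0.0:
                        comp_grids[c][i0:i1] += w * amp
        return cls(t_end=t_end, n_grid=grid.size, windows=windows,
                   component_grids=comp_grids)


def _rate_on_grid(profile: UnitTuningProfile, design: _SessionDesign) -> np.ndarray:
    """Evaluate the unit's rate (Hz) on the 10-ms session grid."""
    gain = np.ones(design.n_grid)
    for i0, i1, w, position, sequence, epoch in design.windows:
        g = profile.gain_for(position, epoch, sequence)
        if g != 1.0:
            gain[i0:i1] += w * (g - 1.0)
    global_mod = np.zeros(design.n_grid)
    weights = profile.global_weights or [1.0] * len(profile.global_components)
    for wgt, comp_grid in zip(weights, design.component_grids):
        global_mod += wgt * comp_grid
    # global motifs add to the tuned rate (scaled by the unit's baseline and
    # participation) rather than multiplying it, so each planted component
    # is a genuine rank-1 term: unit weight x epoch profile x trial drift
    rate = profile.baseline_rate * (gain + global_mod)
    return np.maximum(rate, 0.0)


def simulate_unit(
    profile: UnitTuningProfile,
    trials: list[TrialRecord],
    seed: int | np.random.Generator,
    unit_id: str = "u0",
    group_label: str = "",
    design: Optional[_SessionDesign] = None,
) -> UnitSpikeTrain:
    """Draw a spike train by thinning against the gridded rate function."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if not trials:
        return UnitSpikeTrain(unit_id=unit_id, spike_times=np.empty(0), group_label=group_label)
    if design is None:
        design = _SessionDesign.build(trials, profile.global_components)
    t_end = design.t_end
    rate = _rate_on_grid(profile, design)
    rmax = float(rate.max(initial=0.0))
    if rmax <= 0.0:
        return UnitSpikeTrain(unit_id=unit_id, spike_times=np.empty(0), group_label=group_label)
    n_cand = rng.poisson(rmax * t_end)
    times = rng.uniform(0.0, t_end, n_cand)
    accept = rng.uniform(0.0, rmax, n_cand) < rate[np.minimum((times / _DT).astype(int), design.n_grid - 1)]
    spikes = np.sort(times[accept])
    # enforce the timestamp resolution of the container format
    spikes = np.unique(np.round(spikes, 6))
    return UnitSpikeTrain(unit_id=unit_id, spike_times=spikes, group_label=group_label)


def simulate_session(
    template: PopulationTemplate,
    task: TaskConfig,
    seed: int | np.random.SeedSequence,
    session_id: str = "sim0",
) -> tuple[SessionRecord, list[dict]]:
    """Simulate one complete session from a template; returns unit ground truth too."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sched_ss, behav_ss, units_ss = ss.spawn(3)
    schedule = make_task_schedule(task, np.random.default_rng(sched_ss))
    trials = simulate_behavior(schedule, template.behavior_profile(), task,
                               np.random.default_rng(behav_ss))
    unit_seeds = units_ss.spawn(template.n_units)
    design = _SessionDesign.build(trials, template.global_components)
    units = []
    truths = []
    for i, u_ss in enumerate(unit_seeds):
        rng = np.random.default_rng(u_ss)
        profile, truth = template.sample_unit(rng)
        unit = simulate_unit(
            profile, trials, rng,
            unit_id=f"{session_id}_u{i:04d}", group_label=template.name,
            design=design,
        )
        units.append(unit)
        truth["unit_id"] = unit.unit_id
        truths.append(truth)
    session = SessionRecord(
        session_id=session_id,
        task=task,
        trials=trials,
        units=units,
        metadata={"template": template.name},
    )
    session.validate()
    return session, truths


def simulate_group(
    template: PopulationTemplate,
    n_sessions: int,
    seed: int,
    task: Optional[TaskConfig] = None,
) -> tuple[list[SessionRecord], GroundTruth]:
    """Simulate ``n_sessions`` independent sessions plus their ground truth."""
    task = task or TaskConfig()
    ss = np.random.SeedSequence(seed)
    session_seeds = ss.spawn(n_sessions)
    sessions = []
    units_per_session = []
    for s, s_ss in enumerate(session_seeds):
        session, truths = simulate_session(
            template, task, s_ss, session_id=f"{template.name}_s{s:02d}"
        )
        sessions.append(session)
        units_per_session.append(truths)
    truth = GroundTruth(
        template_name=template.name,
        seed=seed,
        units_per_session=units_per_session,
        global_components=[
            {"profile": c.profile.tolist(), "drift": c.drift, "amplitude": c.amplitude}
            for c in template.global_components
        ],
        behavior={
            "accuracy_by_type": template.behavior_profile().accuracy_by_type,
            "sequence_latency_shift": template.behavior_latency_shift,
        },
    )
    return sessions, truth
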