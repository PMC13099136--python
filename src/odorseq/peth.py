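"""Peri-event rate extraction: epoch anchors, binning, smoothing, matrices, tensor.

Each trial is divided into nine epochs — ITI-a, Light, Poke, Odor, Unpoke,
Choice, Outcome, postOut, ITI-b — anchored to behavioral events.  Around
each anchor, spikes are counted in eight 100-ms bins spanning -200 ms to
+600 ms, smoothed with a 50-ms Gaussian kernel, and the post-event bins
(+100 to +600 ms) are averaged into a single epoch rate per trial.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import SessionRecord, TrialRecord, trial_type_label, trial_type_of

EPOCHS = ("ITI-a", "Light", "Poke", "Odor", "Unpoke", "Choice", "Outcome", "postOut", "ITI-b")

#: Trial-type block order of the trial tensor: position-major, so rewarded
#: trials occupy trial slots 1-80 and 241-320 of a complete 320-trial group.
TENSOR_BLOCK_ORDER = tuple(
    (seq, pos) for pos in (1, 2, 3, 4) for seq in ("S1", "S2")
)


class AnchorError(ValueError):
    """Trial lacks a timestamp required to anchor its epochs."""


@dataclass(frozen=True)
class BinningParams:
    """PETH window: 200 ms pre, 600 ms post, 100-ms bins, 50-ms smoothing sigma."""

    pre_event: float = 0.2
    post_event: float = 0.6
    bin_width: float = 0.1
    smooth_sigma: float = 0.05

    def __post_init__(self) -> None:
        n = (self.pre_event + self.post_event) / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("window must be an integer number of bins")

    @property
    def n_bins(self) -> int:
        return int(round((self.pre_event + self.post_event) / self.bin_width))

    @property
    def post_bin_slice(self) -> slice:
        """Bins covering [+0.1, +0.6) s, averaged into the epoch rate."""
        first = int(round((self.pre_event + 0.1) / self.bin_width))
        return slice(first, self.n_bins)


def anchor_epochs(trial: TrialRecord) -> dict[str, float]:
    """Anchor timestamps of the nine epochs for one trial.

    ITI-a is 0.7 s before light onset.  Choice is the well entry on
    rewarded correct go trials, otherwise the end of the 2-s response
    window; Outcome is the reward delivery on rewarded trials, otherwise
    0.7 s after Choice; postOut and ITI-b follow at 0.7-s steps.
    """
    for name in ("light_on", "poke_in", "odor_on", "poke_out"):
        if getattr(trial, name) is None:
            raise AnchorError(f"trial {trial.trial_index}: missing {name}")
    anchors = {
        "ITI-a": trial.light_on - 0.7,
        "Light": trial.light_on,
        "Poke": trial.poke_in,
        "Odor": trial.odor_on,
        "Unpoke": trial.poke_out,
    }
    if trial.rewarded and trial.response == "go" and trial.correct:
        if trial.well_entry is None or trial.reward_time is None:
            raise AnchorError(f"trial {trial.trial_index}: missing well_entry/reward_time")
        choice = trial.well_entry
        outcome = trial.reward_time
    else:
        choice = trial.poke_out + 2.0
        outcome = choice + 0.7
    anchors["Choice"] = choice
    anchors["Outcome"] = outcome
    anchors["postOut"] = outcome + 0.7
    anchors["ITI-b"] = anchors["postOut"] + 0.7
    return anchors


def bin_spikes(
    spike_times: np.ndarray, anchor: float, params: BinningParams = BinningParams()
) -> np.ndarray:
    """Spike counts in the PETH bins around ``anchor``; bins are half-open
    [anchor - pre + i*w, anchor - pre + (i+1)*w).

    Spike times must be sorted ascending (the container invariant).
    """
    edges = anchor - params.pre_event + params.bin_width * np.arange(params.n_bins + 1)
    spike_times = np.asarray(spike_times, dtype=float)
    # side="left" makes every bin half-open on the right
    idx = np.searchsorted(spike_times, edges, side="left")
    return np.diff(idx).astype(float)


def gaussian_kernel(sigma_bins: float, truncate: float = 3.0) -> np.ndarray:
    """Discrete Gaussian kernel truncated at ±truncate·sigma, renormalized to sum 1."""
    if sigma_bins <= 0:
        return np.array([1.0])
    radius = int(np.floor(truncate * sigma_bins))
    k = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-0.5 * (k / sigma_bins) ** 2)
    return w / w.sum()


def smooth_counts(
    counts: np.ndarray, params: BinningParams = BinningParams()
) -> np.ndarray:
    """Convert counts to rates (Hz) and smooth with the Gaussian kernel.

    Mass is conserved except for truncation at the window edges (the
    convolution is zero-padded).
    """
    rates = np.asarray(counts, dtype=float) / params.bin_width
    kernel = gaussian_kernel(params.smooth_sigma / params.bin_width)
    return np.convolve(rates, kernel, mode="same")


def epoch_mean_rate(
    smoothed: np.ndarray, params: BinningParams = BinningParams()
) -> float:
    """Mean of the post-event bins ([+100, +600) ms) — one rate per trial/epoch."""
    return float(np.mean(smoothed[params.post_bin_slice]))


def trial_epoch_rates(
    spike_times: np.ndarray,
    anchors: dict[str, float],
    params: BinningParams = BinningParams(),
) -> np.ndarray:
    """Epoch rates (Hz) of one unit on one trial: length-9 vector."""
    return np.array(
        [
            epoch_mean_rate(smooth_counts(bin_spikes(spike_times, anchors[e], params), params), params)
            for e in EPOCHS
        ]
    )


@dataclass
class EpochRateMatrix:
    """Trials x units mean rates for one epoch, rows blocked by trial type."""

    epoch: str
    rates: np.ndarray  # (n_trials, n_units)
    labels: pd.DataFrame  # trial_type, sequence, position, rewarded, within_type_index
    unit_ids: list[str]
    unit_sessions: np.ndarray  # session index per unit column
    seed: Optional[int] = None

    def rows_of_types(self, types: Sequence[int]) -> np.ndarray:
        return self.labels["trial_type"].isin(list(types)).to_numpy()


@dataclass
class TrialTensor:
    """Units x time x trials array for CP decomposition.

    Time mode: 9 epochs x 8 smoothed bins = 72 samples in fixed epoch
    order.  Trial mode: 8 trial-type blocks of ``n_repeats`` trials each,
    ordered position-major (P1-S1, P1-S2, P2-S1, ... P4-S2) so rewarded
    trials occupy the first and last blocks.  Entries are smoothed rates
    soft-normalized per unit by (max rate + 1 Hz).
    """

    data: np.ndarray  # (N, 72, K)
    unit_ids: list[str]
    epoch_of_bin: np.ndarray  # (72,) epoch index 0..8
    trial_labels: pd.DataFrame  # sequence, position, trial_type, rewarded, trial_index, session

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _selection_rng(master_seed: int, session_id: str, trial_type: int) -> np.random.Generator:
    """Per-(session, type) RNG derived by hashing, independent of session order."""
    digest = hashlib.sha256(f"{master_seed}|{session_id}|{trial_type}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def select_trials(
    session: SessionRecord, n_per_type: int, seed: int
) -> dict[int, list[TrialRecord]]:
    """Reproducibly select ``n_per_type`` correct trials of each type."""
    chosen: dict[int, list[TrialRecord]] = {}
    for tt in range(1, 9):
        pool = session.trials_of_type(tt, correct_only=True)
        if len(pool) < n_per_type:
            raise ValueError(
                f"session {session.session_id}, trial type {tt}: "
                f"{len(pool)} correct trials < {n_per_type} required"
            )
        rng = _selection_rng(seed, session.session_id, tt)
        idx = rng.choice(len(pool), size=n_per_type, replace=False)
        chosen[tt] = [pool[i] for i in sorted(idx)]
    return chosen


def build_rate_matrices(
    sessions: Sequence[SessionRecord],
    n_per_type: int = 30,
    seed: int = 0,
    params: BinningParams = BinningParams(),
) -> dict[str, EpochRateMatrix]:
    """Per-epoch trials x units rate matrices over a pseudopopulation.

    Each session contributes its units as columns; rows are pseudo-trials
    aligned by (trial type, within-type selection index) across sessions.
    The same selected trials feed all nine epochs.
    """
    all_rates = {e: [] for e in EPOCHS}  # per epoch: list of per-session (240, n_units)
    unit_ids: list[str] = []
    unit_sessions: list[int] = []
    labels = None
    for s_idx, session in enumerate(sessions):
        chosen = select_trials(session, n_per_type, seed)
        # anchors once per selected trial
        anchors_by_type = {tt: [anchor_epochs(t) for t in chosen[tt]] for tt in chosen}
        n_units = len(session.units)
        per_epoch = {e: np.empty((8 * n_per_type, n_units)) for e in EPOCHS}
        label_rows = []
        row = 0
        for tt in range(1, 9):
            seqpos = trial_type_label(tt)
            for j, (trial, anchors) in enumerate(zip(chosen[tt], anchors_by_type[tt])):
                for u_idx, unit in enumerate(session.units):
                    rates9 = trial_epoch_rates(unit.spike_times, anchors, params)
                    for e_idx, e in enumerate(EPOCHS):
                        per_epoch[e][row, u_idx] = rates9[e_idx]
                if s_idx == 0:
                    label_rows.append(
                        {
                            "trial_type": tt,
                            "sequence": seqpos[0],
                            "position": seqpos[1],
                            "rewarded": trial.rewarded,
                            "within_type_index": j,
                        }
                    )
                row += 1
        for e in EPOCHS:
            all_rates[e].append(per_epoch[e])
        unit_ids.extend(u.unit_id for u in session.units)
        unit_sessions.extend([s_idx] * n_units)
        if s_idx == 0:
            labels = pd.DataFrame(label_rows)
    out = {}
    for e in EPOCHS:
        out[e] = EpochRateMatrix(
            epoch=e,
            rates=np.hstack(all_rates[e]),
            labels=labels.copy(),
            unit_ids=list(unit_ids),
            unit_sessions=np.array(unit_sessions),
            seed=seed,
        )
    return out


def build_trial_tensor(
    sessions: Sequence[SessionRecord],
    params: BinningParams = BinningParams(),
    normalize: bool = True,
) -> TrialTensor:
    """Assemble the N x 72 x K trial tensor from complete sessions.

    Every session must have the full repeat count for every trial type
    (error trials included).  Units from all sessions are stacked on the
    first mode; the trial mode is shared via (block, within-block index)
    alignment.
    """
    for session in sessions:
        if not session.is_complete:
            raise ValueError(f"session {session.session_id} is not complete")
    n_rep = sessions[0].task.n_repeats_per_sequence
    K = 8 * n_rep
    n_units_total = sum(len(s.units) for s in sessions)
    T = 8 * len(EPOCHS)
    data = np.empty((n_units_total, T, K))
    unit_ids: list[str] = []
    epoch_of_bin = np.repeat(np.arange(9), 8)
    label_rows = []

    u_off = 0
    for s_idx, session in enumerate(sessions):
        # trial-mode layout: position-major blocks of 2*n_rep (S1 then S2)
        order: list[TrialRecord] = []
        for seq, pos in TENSOR_BLOCK_ORDER:
            tt = (0 if seq == "S1" else 4) + pos
            block = sorted(session.trials_of_type(tt), key=lambda t: t.trial_index)
            if len(block) != n_rep:
                raise ValueError(
                    f"session {session.session_id}: type {tt} has {len(block)} trials"
                )
            order.extend(block)
        anchors = [anchor_epochs(t) for t in order]
        for u_idx, unit in enumerate(session.units):
            for k, (trial, anc) in enumerate(zip(order, anchors)):
                for e_idx, e in enumerate(EPOCHS):
                    counts = bin_spikes(unit.spike_times, anc[e], params)
                    data[u_off + u_idx, 8 * e_idx: 8 * (e_idx + 1), k] = smooth_counts(counts, params)
        unit_ids.extend(u.unit_id for u in session.units)
        u_off += len(session.units)
        if s_idx == 0:
            for trial in order:
                label_rows.append(
                    {
                        "sequence": trial.sequence,
                        "position": trial.position,
                        "trial_type": trial_type_of(trial),
                        "rewarded": trial.rewarded,
                        "trial_index": trial.trial_index,
                        "session": s_idx,
                    }
                )

    if normalize:
        peak = data.max(axis=(1, 2), keepdims=True)
        data = data / (peak + 1.0)

    return TrialTensor(
        data=data,
        unit_ids=unit_ids,
        epoch_of_bin=epoch_of_bin,
        trial_labels=pd.DataFrame(label_rows),
    )
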