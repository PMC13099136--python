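"""Pseudoensemble decoding with leave-one-out cross-validation and
label-shuffled nulls.

Pseudoensembles concatenate units recorded in different sessions, aligned
by trial type; independently permuting the within-type trial order of each
session's columns destroys spurious across-unit correlations while
preserving every unit's per-type rate marginal exactly.  Decoding uses a
linear soft-margin SVM (hinge loss, C = 1, one-vs-rest) with features
z-scored on the training fold only.  Chance and significance come from
re-running the identical pipeline with permuted labels and taking the
2.5/97.5 percentiles as the 95% confidence band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .peth import EpochRateMatrix

logger = logging.getLogger(__name__)


@dataclass
class DecodingResult:
    """Accuracy with its label-shuffled null distribution."""

    accuracy: float
    accuracies: np.ndarray  # per pseudoensemble
    null_accuracies: Optional[np.ndarray] = None
    chance: float = 0.5
    annotations: dict = field(default_factory=dict)

    @property
    def null_ci(self) -> Optional[tuple[float, float]]:
        if self.null_accuracies is None or self.null_accuracies.size == 0:
            return None
        if self.null_accuracies.size < 20:
            logger.warning("null CI from only %d shuffles", self.null_accuracies.size)
        lo, hi = np.percentile(self.null_accuracies, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def above_null(self) -> Optional[bool]:
        ci = self.null_ci
        return None if ci is None else self.accuracy > ci[1]


def shuffle_within_types(
    rates: np.ndarray,
    trial_types: np.ndarray,
    unit_sessions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permute within-type row order independently per unit-source session.

    Each unit's multiset of rates per trial type is unchanged; only the
    pairing of rows across sessions is scrambled.
    """
    out = rates.copy()
    sessions = np.unique(unit_sessions)
    for tt in np.unique(trial_types):
        rows = np.flatnonzero(trial_types == tt)
        for s in sessions:
            cols = np.flatnonzero(unit_sessions == s)
            perm = rng.permutation(rows.size)
            out[np.ix_(rows, cols)] = rates[np.ix_(rows[perm], cols)]
    return out


def assemble_pseudoensembles(
    matrix: EpochRateMatrix,
    n_pseudo: int,
    seed: int,
    row_mask: Optional[np.ndarray] = None,
    unit_subset: Optional[np.ndarray] = None,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield ``n_pseudo`` shuffled (rates, trial_types) pseudoensembles."""
    rng = np.random.default_rng(seed)
    rates = matrix.rates
    types = matrix.labels["trial_type"].to_numpy()
    sessions = matrix.unit_sessions
    if unit_subset is not None:
        rates = rates[:, unit_subset]
        sessions = sessions[unit_subset]
    if row_mask is not None:
        rates = rates[row_mask]
        types = types[row_mask]
    counts = np.bincount(types)
    present = counts[counts > 0]
    if present.size and not np.all(present == present[0]):
        raise ValueError("trial types must have equal row counts")
    for _ in range(n_pseudo):
        yield shuffle_within_types(rates, types, sessions, rng), types


def fit_linear_decoder(
    X: np.ndarray, y: np.ndarray, C: float = 1.0
) -> tuple[LinearSVC, np.ndarray, np.ndarray]:
    """Fit the linear SVM on standardized features; returns (model, mean, scale)."""
    if np.unique(y).size < 2:
        raise ValueError("training set must contain >= 2 classes")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    clf = LinearSVC(C=C, loss="hinge", max_iter=20000, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xs, y)
    return clf, mu, sd


def predict_linear_decoder(
    model: tuple[LinearSVC, np.ndarray, np.ndarray], X: np.ndarray
) -> np.ndarray:
    clf, mu, sd = model
    return clf.predict((X - mu) / sd)


def loo_accuracy(
    rates: np.ndarray,
    labels: np.ndarray,
    n_reps: int = 200,
    seed: int | np.random.Generator = 0,
    C: float = 1.0,
) -> float:
    """Leave-one-out-per-class accuracy, averaged over random repetitions.

    Each repetition withholds one randomly chosen trial from every class,
    trains on the rest, and scores the held-out set.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = np.unique(labels)
    idx_by_class = [np.flatnonzero(labels == c) for c in classes]
    correct = 0
    total = 0
    for _ in range(n_reps):
        held = np.array([idx[rng.integers(idx.size)] for idx in idx_by_class])
        mask = np.ones(labels.size, dtype=bool)
        mask[held] = False
        model = fit_linear_decoder(rates[mask], labels[mask], C=C)
        pred = predict_linear_decoder(model, rates[held])
        correct += int(np.sum(pred == labels[held]))
        total += held.size
    return correct / total


def shuffled_null(
    rates: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
    n_reps: int = 20,
    C: float = 1.0,
) -> np.ndarray:
    """Null accuracy distribution: the identical pipeline on permuted labels."""
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm = rng.permutation(labels.size)
        null[i] = loo_accuracy(rates, labels[perm], n_reps=n_reps, seed=rng, C=C)
    return null


def s1_vs_s2_decoding(
    matrix: EpochRateMatrix,
    position: int,
    ensemble_size: Optional[int] = None,
    n_pseudo: int = 50,
    n_shuffles: int = 100,
    n_reps: int = 20,
    seed: int = 0,
) -> DecodingResult:
    """Binary S1-vs-S2 decoding at one position from one epoch's matrix.

    Each pseudoensemble subsamples ``ensemble_size`` units (all units when
    None) and shuffles within-type trial order; chance is 0.5.
    """
    n_units = matrix.rates.shape[1]
    if ensemble_size is not None and ensemble_size > n_units:
        raise ValueError(f"ensemble_size {ensemble_size} > {n_units} available units")
    row_mask = (matrix.labels["position"] == position).to_numpy()
    types = matrix.labels["trial_type"].to_numpy()[row_mask]
    rng = np.random.default_rng(seed)
    accs = np.empty(n_pseudo)
    sub_rng = np.random.default_rng(rng.integers(2**31))
    for i, (rates, tt) in enumerate(
        assemble_pseudoensembles(
            matrix, n_pseudo, int(rng.integers(2**31)), row_mask=row_mask
        )
    ):
        if ensemble_size is not None:
            cols = sub_rng.choice(n_units, size=ensemble_size, replace=False)
            rates = rates[:, cols]
        accs[i] = loo_accuracy(rates, tt, n_reps=n_reps, seed=sub_rng)
    # null: identical pipeline with permuted labels (one pseudoensemble per shuffle)
    null = np.empty(n_shuffles)
    null_rng = np.random.default_rng(rng.integers(2**31))
    for i, (rates, tt) in enumerate(
        assemble_pseudoensembles(
            matrix, n_shuffles, int(rng.integers(2**31)), row_mask=row_mask
        )
    ):
        if ensemble_size is not None:
            cols = null_rng.choice(n_units, size=ensemble_size, replace=False)
            rates = rates[:, cols]
        perm = null_rng.permutation(tt.size)
        null[i] = loo_accuracy(rates, tt[perm], n_reps=n_reps, seed=null_rng)
    return DecodingResult(
        accuracy=float(accs.mean()),
        accuracies=accs,
        null_accuracies=null,
        chance=0.5,
        annotations={
            "epoch": matrix.epoch,
            "position": position,
            "ensemble_size": ensemble_size or n_units,
        },
    )


def _epoch_feature_stack(
    matrices: dict[str, EpochRateMatrix], epochs: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack per-epoch rates into trials x (units x 9 epochs) features."""
    first = matrices[epochs[0]]
    feats = np.stack([matrices[e].rates for e in epochs], axis=2)  # trials, units, epochs
    types = first.labels["trial_type"].to_numpy()
    positions = first.labels["position"].to_numpy()
    sequences = first.labels["sequence"].to_numpy()
    return feats, types, positions, sequences


def position_decoding(
    matrices: dict[str, EpochRateMatrix],
    mode: str = "within",
    n_iter: int = 200,
    ensemble_size: Optional[int] = None,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Four-class position decoding from 9-epoch rate profiles.

    Features per trial are each unit's rates over the nine epochs (a
    120-trial x 9-epoch matrix per unit and sequence, concatenated over
    the ensemble).  The decoder is trained on S1 trials minus one held-out
    trial per position; ``mode="within"`` scores the held-out S1 trials,
    ``mode="across"`` scores the index-matched S2 trials.  Returns the
    row-normalized 4x4 confusion matrix and the mean accuracy; chance is
    0.25.
    """
    if mode not in ("within", "across"):
        raise ValueError(f"mode must be 'within' or 'across', got {mode!r}")
    from .peth import EPOCHS

    feats, types, positions, sequences = _epoch_feature_stack(matrices, EPOCHS)
    n_units = feats.shape[1]
    rng = np.random.default_rng(seed)
    first = matrices[EPOCHS[0]]
    sess = first.unit_sessions

    s1_rows_by_pos = [np.flatnonzero((sequences == "S1") & (positions == p)) for p in (1, 2, 3, 4)]
    s2_rows_by_pos = [np.flatnonzero((sequences == "S2") & (positions == p)) for p in (1, 2, 3, 4)]
    n_per = s1_rows_by_pos[0].size

    confusion = np.zeros((4, 4))
    correct = 0
    total = 0
    for _ in range(n_iter):
        if ensemble_size is not None:
            cols = rng.choice(n_units, size=ensemble_size, replace=False)
        else:
            cols = np.arange(n_units)
        f = feats[:, cols, :].reshape(feats.shape[0], -1)
        # within-type shuffling per source session to build the pseudoensemble
        f = shuffle_within_types(
            f, types,
            np.repeat(sess[cols], feats.shape[2]),
            rng,
        )
        # hold out one within-type index per position; the S2 trial with the
        # corresponding index is the across-sequence probe
        held_idx = rng.integers(n_per, size=4)
        train_rows, test_rows, test_pos = [], [], []
        for p_idx in range(4):
            s1_rows = s1_rows_by_pos[p_idx]
            keep = np.ones(n_per, dtype=bool)
            keep[held_idx[p_idx]] = False
            train_rows.append(s1_rows[keep])
            if mode == "within":
                test_rows.append(s1_rows[held_idx[p_idx]])
            else:
                test_rows.append(s2_rows_by_pos[p_idx][held_idx[p_idx]])
            test_pos.append(p_idx + 1)
        train_rows = np.concatenate(train_rows)
        model = fit_linear_decoder(f[train_rows], positions[train_rows], C=C)
        pred = predict_linear_decoder(model, f[np.array(test_rows)])
        for actual, predicted in zip(test_pos, pred):
            confusion[actual - 1, predicted - 1] += 1
            correct += int(actual == predicted)
            total += 1
    confusion = confusion / confusion.sum(axis=1, keepdims=True)
    return confusion, correct / total


def ensemble_size_curve(
    matrix: EpochRateMatrix,
    position: int,
    sizes: Sequence[int] = (10, 20, 50, 100, 200, 500),
    n_pseudo: int = 20,
    n_reps: int = 20,
    seed: int = 0,
) -> dict[int, DecodingResult]:
    """S1-vs-S2 decoding accuracy as a function of pseudoensemble size."""
    n_units = matrix.rates.shape[1]
    usable = [s for s in sizes if s <= n_units]
    if len(usable) < len(sizes):
        logger.info("ensemble sizes truncated to <= %d units", n_units)
    out = {}
    for k, size in enumerate(usable):
        out[size] = s1_vs_s2_decoding(
            matrix, position,
            ensemble_size=size, n_pseudo=n_pseudo, n_shuffles=20,
            n_reps=n_reps, seed=seed + 7919 * k,
        )
    return out
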