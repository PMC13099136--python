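"""Mutual information between CP trial-factor loadings and trial labels.

For each component's trial factor (a loading per trial), MI is estimated
with the plug-in (histogram) estimator in bits: loadings are discretized
into equal-width bins and crossed with either the 8 trial types or the
trial index discretized into equal-count bins ("time").  Uncertainty is
reported over the restart ensemble after aligning each restart's
components to the best-fit model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tca import CPModel, RestartEnsemble, _congruence_matrix
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)


def _plugin_mi(joint: np.ndarray, miller_madow: bool = False) -> float:
    """MI in bits from a joint count table."""
    joint = np.asarray(joint, float)
    n = joint.sum()
    if n == 0:
        return 0.0
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))
    if miller_madow:
        # Miller-Madow bias correction on the three entropies
        kxy = int(np.count_nonzero(p))
        kx = int(np.count_nonzero(px))
        ky = int(np.count_nonzero(py))
        mi += (kx - 1 + ky - 1 - (kxy - 1)) / (2.0 * n * np.log(2.0))
    return max(mi, 0.0)


def _bin_equal_width(values: np.ndarray, n_bins: int) -> np.ndarray:
    values = np.asarray(values, float)
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.zeros(values.size, dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.digitize(values, edges[1:-1]), 0, n_bins - 1)


def mi_factor_vs_type(
    loadings: np.ndarray,
    trial_types: np.ndarray,
    n_bins: int = 8,
    miller_madow: bool = False,
) -> float:
    """Plug-in MI (bits) between binned trial loadings and trial type.

    Bounded by log2(number of types) = 3 bits for the 8-type task.
    """
    loadings = np.asarray(loadings, float)
    trial_types = np.asarray(trial_types)
    if loadings.shape != trial_types.shape:
        raise ValueError("loadings and labels must have equal length")
    b = _bin_equal_width(loadings, n_bins)
    types = np.unique(trial_types)
    joint = np.zeros((n_bins, types.size))
    for j, tt in enumerate(types):
        joint[:, j] = np.bincount(b[trial_types == tt], minlength=n_bins)
    return _plugin_mi(joint, miller_madow)


def mi_factor_vs_time(
    loadings: np.ndarray,
    trial_indices: np.ndarray | None = None,
    n_bins: int = 8,
    miller_madow: bool = False,
) -> float:
    """Plug-in MI (bits) between binned loadings and session time.

    Time is the trial index within the session, discretized into
    ``n_bins`` equal-count bins.
    """
    loadings = np.asarray(loadings, float)
    K = loadings.size
    if trial_indices is None:
        trial_indices = np.arange(K)
    order = np.argsort(np.argsort(trial_indices, kind="stable"), kind="stable")
    time_bin = np.minimum(order * n_bins // K, n_bins - 1)
    b = _bin_equal_width(loadings, n_bins)
    joint = np.zeros((n_bins, n_bins))
    for t in range(n_bins):
        joint[:, t] = np.bincount(b[time_bin == t], minlength=n_bins)
    return _plugin_mi(joint, miller_madow)


@dataclass
class MIResult:
    """Per-component MI with trial type and time, mean ± SEM over restarts."""

    mi_type_mean: np.ndarray
    mi_type_sem: np.ndarray
    mi_time_mean: np.ndarray
    mi_time_sem: np.ndarray
    n_models: int
    n_bins: int


def mi_profile(
    ensemble: RestartEnsemble,
    trial_types: np.ndarray,
    trial_indices: np.ndarray | None = None,
    n_bins: int = 8,
    congruence_threshold: float = 0.5,
) -> MIResult:
    """MI of every component's trial factor, aggregated over restart models.

    Each restart's components are matched to the best-fit model by maximum
    total congruence; restarts whose mean matched congruence falls below
    ``congruence_threshold`` are dropped.
    """
    if not ensemble.models:
        raise ValueError("empty restart ensemble")
    best = ensemble.best
    R = best.rank
    mi_type_rows, mi_time_rows = [], []
    for model in ensemble.models:
        C = _congruence_matrix(model, best)
        rows, cols = linear_sum_assignment(-C)
        if C[rows, cols].mean() < congruence_threshold:
            logger.info("dropping restart: mean congruence %.2f", C[rows, cols].mean())
            continue
        # component cols[j] of this model corresponds to best's component rows -> invert
        aligned = np.empty(R, dtype=int)
        aligned[cols] = rows  # best component c matched to model component aligned-index
        inv = np.empty(R, dtype=int)
        inv[rows] = cols
        trial_factors = model.factors[2]
        mi_type_rows.append(
            [mi_factor_vs_type(trial_factors[:, inv[r]], trial_types, n_bins) for r in range(R)]
        )
        mi_time_rows.append(
            [mi_factor_vs_time(trial_factors[:, inv[r]], trial_indices, n_bins) for r in range(R)]
        )
    if not mi_type_rows:
        raise ValueError("all restarts dropped during alignment")
    mt = np.asarray(mi_type_rows)
    mm = np.asarray(mi_time_rows)
    n = mt.shape[0]
    sem = lambda x: x.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(x.shape[1])
    return MIResult(
        mi_type_mean=mt.mean(axis=0),
        mi_type_sem=sem(mt),
        mi_time_mean=mm.mean(axis=0),
        mi_time_sem=sem(mm),
        n_models=n,
        n_bins=n_bins,
    )
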