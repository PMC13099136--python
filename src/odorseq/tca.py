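"""Canonical polyadic (CP) decomposition of the trial tensor.

A rank-R CP model approximates the units x time x trials tensor as a sum
of R rank-1 components, each the outer product of a unit factor, a
temporal factor (72 samples: 9 epochs x 8 bins), and a trial factor
(loadings over the session's trials).  Firing rates are nonnegative, so
the default fit constrains all factors to be nonnegative and updates them
by hierarchical alternating least squares (HALS); unconstrained ALS is
available by flag.

Because the optimization landscape is non-convex, stability is assessed by
refitting from many random initializations and scoring each model's
congruence with the minimum-error model; a well-determined decomposition
produces similarity scores near 1 across restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .peth import TrialTensor

_EPS = 1e-12


@dataclass
class CPModel:
    """Rank-R CP model with unit-norm factor columns and absorbed scales."""

    factors: list[np.ndarray]  # [(N,R), (T,R), (K,R)]
    scales: np.ndarray  # (R,)
    rank: int
    error: float  # normalized reconstruction error at convergence
    n_iter: int
    seed: Optional[int] = None
    nonneg: bool = True

    def reconstruct(self) -> np.ndarray:
        A, B, C = self.factors
        return np.einsum("ir,jr,kr,r->ijk", A, B, C, self.scales, optimize=True)

    def normalized(self) -> "CPModel":
        """Renormalize factor columns to unit Euclidean norm (idempotent)."""
        factors = []
        scales = self.scales.copy().astype(float)
        for F in self.factors:
            norms = np.linalg.norm(F, axis=0)
            norms = np.where(norms < _EPS, 1.0, norms)
            factors.append(F / norms)
            scales = scales * norms
        return CPModel(
            factors=factors, scales=scales, rank=self.rank,
            error=self.error, n_iter=self.n_iter, seed=self.seed, nonneg=self.nonneg,
        )


def _unfoldings(X: np.ndarray) -> list[np.ndarray]:
    N, T, K = X.shape
    return [
        X.reshape(N, T * K),
        np.ascontiguousarray(X.transpose(1, 0, 2)).reshape(T, N * K),
        np.ascontiguousarray(X.transpose(2, 0, 1)).reshape(K, N * T),
    ]


def _khatri_rao(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Khatri-Rao product; rows ordered with A's index slower."""
    return (A[:, None, :] * B[None, :, :]).reshape(A.shape[0] * B.shape[0], A.shape[1])


def cp_fit(
    tensor: np.ndarray | TrialTensor,
    rank: int,
    seed: int = 0,
    nonneg: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> CPModel:
    """Fit a rank-``rank`` CP model by ALS (HALS when ``nonneg``).

    Iterates mode-wise updates until the normalized reconstruction error
    changes by less than ``tol`` between sweeps or ``max_iter`` sweeps are
    reached.  The error is non-increasing across sweeps (asserted).
    """
    X = tensor.data if isinstance(tensor, TrialTensor) else np.asarray(tensor, float)
    if X.ndim != 3:
        raise ValueError("tensor must be 3-way")
    if not np.all(np.isfinite(X)):
        raise ValueError("tensor contains non-finite entries")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    rng = np.random.default_rng(seed)
    dims = X.shape
    if nonneg:
        factors = [rng.uniform(0.0, 1.0, size=(d, rank)) for d in dims]
    else:
        factors = [rng.standard_normal((d, rank)) for d in dims]
    unf = _unfoldings(X)
    norm_x = float(np.linalg.norm(X))
    if norm_x == 0:
        raise ValueError("zero tensor has no defined normalized error")
    grams = [F.T @ F for F in factors]

    prev_err = np.inf
    err = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        for mode in range(3):
            others = [i for i in range(3) if i != mode]
            kr = _khatri_rao(factors[others[0]], factors[others[1]])
            M = unf[mode] @ kr  # MTTKRP
            V = grams[others[0]] * grams[others[1]]
            A = factors[mode]
            if nonneg:
                for r in range(rank):
                    vrr = V[r, r]
                    if vrr < _EPS:
                        continue
                    num = M[:, r] - A @ V[:, r] + A[:, r] * vrr
                    col = np.maximum(num / vrr, 0.0)
                    if not np.any(col > 0):
                        col[:] = _EPS
                    A[:, r] = col
            else:
                try:
                    A = np.linalg.solve(V.T, M.T).T
                except np.linalg.LinAlgError:
                    A = M @ np.linalg.pinv(V)
                factors[mode] = A
            grams[mode] = factors[mode].T @ factors[mode]
        # error via the factored inner products; M, V refer to the last mode
        V_full = grams[0] * grams[1]
        A2 = factors[2]
        inner = float(np.sum(M * A2))
        model_norm2 = float(np.sum((A2.T @ A2) * V_full))
        resid2 = max(norm_x**2 - 2.0 * inner + model_norm2, 0.0)
        err = np.sqrt(resid2) / norm_x
        # slack covers cancellation in the factored error formula near exact fits
        assert err <= prev_err + 1e-7, "reconstruction error increased"
        if prev_err - err < tol:
            break
        prev_err = err

    model = CPModel(
        factors=[F.copy() for F in factors],
        scales=np.ones(rank),
        rank=rank,
        error=err,
        n_iter=it,
        seed=seed if isinstance(seed, int) else None,
        nonneg=nonneg,
    )
    return model.normalized()


def reconstruction_error(model: CPModel, tensor: np.ndarray | TrialTensor) -> float:
    """Frobenius norm of the residual over the Frobenius norm of the tensor."""
    X = tensor.data if isinstance(tensor, TrialTensor) else np.asarray(tensor, float)
    norm_x = np.linalg.norm(X)
    if norm_x == 0:
        raise ValueError("normalized error undefined for the zero tensor")
    return float(np.linalg.norm(X - model.reconstruct()) / norm_x)


def _congruence_matrix(a: CPModel, b: CPModel) -> np.ndarray:
    """Pairwise component congruence: product over modes of |cosine|."""
    C = np.ones((a.rank, b.rank))
    for Fa, Fb in zip(a.factors, b.factors):
        na = np.linalg.norm(Fa, axis=0)
        nb = np.linalg.norm(Fb, axis=0)
        na = np.where(na < _EPS, 1.0, na)
        nb = np.where(nb < _EPS, 1.0, nb)
        C *= np.abs((Fa / na).T @ (Fb / nb))
    return C


def similarity_score(a: CPModel, b: CPModel) -> float:
    """Scale-weighted congruence between two CP models of equal rank.

    Components are paired by the assignment maximizing total weighted
    congruence; each matched pair contributes its congruence weighted by
    the mean of the two models' normalized component scales.  Invariant to
    component permutation and rescaling; equals 1 for identical models.
    """
    if a.rank != b.rank:
        raise ValueError("models must have equal rank")
    a = a.normalized()
    b = b.normalized()
    C = _congruence_matrix(a, b)
    wa = a.scales / max(a.scales.sum(), _EPS)
    wb = b.scales / max(b.scales.sum(), _EPS)
    W = 0.5 * (wa[:, None] + wb[None, :])
    rows, cols = linear_sum_assignment(-(W * C))
    return float(np.sum(W[rows, cols] * C[rows, cols]))


@dataclass
class RestartEnsemble:
    """CP fits from independent random initializations, plus diagnostics."""

    models: list[CPModel]
    errors: np.ndarray
    similarities: np.ndarray  # each model vs the minimum-error model

    @property
    def best(self) -> CPModel:
        return self.models[int(np.argmin(self.errors))]

    @property
    def mean_similarity(self) -> float:
        return float(self.similarities.mean())


def restart_ensemble(
    tensor: np.ndarray | TrialTensor,
    rank: int,
    n_restarts: int = 100,
    seed: int = 0,
    nonneg: bool = True,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> RestartEnsemble:
    """Fit ``n_restarts`` CP models from independent seeded initializations.

    The similarity of every model to the minimum-error model is the
    stability diagnostic: consistently high values indicate a
    well-determined optimum rather than scattered local minima.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_restarts)]
    models = [
        cp_fit(tensor, rank, seed=s, nonneg=nonneg, tol=tol, max_iter=max_iter)
        for s in seeds
    ]
    errors = np.array([m.error for m in models])
    best = models[int(np.argmin(errors))]
    sims = np.array([similarity_score(m, best) for m in models])
    return RestartEnsemble(models=models, errors=errors, similarities=sims)


@dataclass
class ComponentAlignment:
    """Bijective component matching between two models via temporal factors."""

    permutation: np.ndarray  # component j of model B matches component permutation[j] of A
    congruences: np.ndarray  # |cosine| of the matched temporal factors
    low_congruence_threshold: float = 0.5

    @property
    def low_congruence(self) -> np.ndarray:
        return self.congruences < self.low_congruence_threshold


def align_across_groups(a: CPModel, b: CPModel) -> ComponentAlignment:
    """Match components of two models by their temporal factors.

    The assignment maximizes the summed absolute cosine similarity between
    temporal factors; pairs with congruence below 0.5 are flagged as
    unmatched in substance.
    """
    if a.rank != b.rank:
        raise ValueError("models must have equal rank")
    Ta, Tb = a.factors[1], b.factors[1]
    if Ta.shape[0] != Tb.shape[0]:
        raise ValueError("temporal modes must have equal length")
    na = np.linalg.norm(Ta, axis=0)
    nb = np.linalg.norm(Tb, axis=0)
    na = np.where(na < _EPS, 1.0, na)
    nb = np.where(nb < _EPS, 1.0, nb)
    C = np.abs((Ta / na).T @ (Tb / nb))
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(a.rank, dtype=int)
    cong = np.empty(a.rank)
    for r, c in zip(rows, cols):
        perm[c] = r
        cong[c] = C[r, c]
    return ComponentAlignment(permutation=perm, congruences=cong)


def component_summary(
    model: CPModel,
    epoch_of_bin: np.ndarray,
    n_blocks: int = 8,
    position_general_cv: float = 0.2,
    event_locked_ratio: float = 1.15,
) -> pd.DataFrame:
    """Per-component summary over epochs and trial-type blocks.

    Trial blocks follow the tensor's position-major order, so blocks 0, 1,
    6, 7 are the rewarded (P1/P4) trials.  A component is flagged
    *position-general* when it satisfies two artifact-defined conditions:

    * uniform recruitment across trial types — the coefficient of
      variation of its block-mean trial loadings is below
      ``position_general_cv``, and
    * event-locked dynamics — its mean temporal loading over the
      post-event bins (3-7 of each epoch) exceeds the pre-event bins
      (0-2) by at least ``event_locked_ratio``.

    The second condition excludes the ubiquitous mean-rate (offset)
    component, whose loadings are flat both across trials and within each
    peri-event window: a task motif responds to events, an offset does
    not.
    """
    epoch_of_bin = np.asarray(epoch_of_bin)
    T = model.factors[1].shape[0]
    if epoch_of_bin.shape != (T,) or T != 72:
        raise ValueError("expected the standard 72-sample time mode with its epoch map")
    K = model.factors[2].shape[0]
    if K % n_blocks:
        raise ValueError("trial mode not divisible into blocks")
    block = np.repeat(np.arange(n_blocks), K // n_blocks)
    rewarded_blocks = np.array([0, 1, n_blocks - 2, n_blocks - 1])
    bin_within_epoch = np.arange(T) % 8
    rows = []
    for r in range(model.rank):
        temporal = model.factors[1][:, r]
        trial = model.factors[2][:, r]
        epoch_means = np.array([temporal[epoch_of_bin == e].mean() for e in range(9)])
        block_means = np.array([trial[block == b].mean() for b in range(n_blocks)])
        rewarded_mean = block_means[rewarded_blocks].mean()
        nonrewarded_mean = np.delete(block_means, rewarded_blocks).mean()
        mu = block_means.mean()
        cv = float(block_means.std() / mu) if mu > _EPS else np.inf
        pre = float(temporal[bin_within_epoch < 3].mean())
        post = float(temporal[bin_within_epoch >= 3].mean())
        post_pre = post / pre if pre > _EPS else np.inf
        rows.append(
            {
                "component": r,
                "scale": float(model.scales[r]),
                "dominant_epoch": int(np.argmax(epoch_means)),
                "reward_contrast": float(rewarded_mean - nonrewarded_mean),
                "rewarded_preferring": bool(rewarded_mean > nonrewarded_mean),
                "block_cv": cv,
                "post_pre_ratio": float(post_pre),
                "position_general": bool(
                    cv < position_general_cv and post_pre >= event_locked_ratio
                ),
                **{f"epoch_mean_{e}": float(epoch_means[e]) for e in range(9)},
                **{f"block_mean_{b}": float(block_means[b]) for b in range(n_blocks)},
            }
        )
    return pd.DataFrame(rows)
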