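"""CP decomposition: recovery, error, similarity, restarts, alignment."""

import itertools

import numpy as np
import pytest

from odorseq.tca import (
    CPModel,
    align_across_groups,
    component_summary,
    cp_fit,
    reconstruction_error,
    restart_ensemble,
    similarity_score,
)


def _random_model(rng, dims=(6, 7, 8), rank=3, nonneg=True):
    draw = rng.uniform if nonneg else rng.standard_normal
    factors = [
        rng.uniform(0.1, 1.0, (d, rank)) if nonneg else rng.standard_normal((d, rank))
        for d in dims
    ]
    return CPModel(
        factors=factors, scales=rng.uniform(0.5, 2.0, rank), rank=rank,
        error=0.0, n_iter=0,
    ).normalized()


def _brute_force_similarity(a: CPModel, b: CPModel) -> float:
    """Independent oracle: enumerate all component permutations explicitly."""
    a = a.normalized()
    b = b.normalized()
    R = a.rank
    wa = a.scales / a.scales.sum()
    wb = b.scales / b.scales.sum()

    def congruence(i, j):
        c = 1.0
        for Fa, Fb in zip(a.factors, b.factors):
            va = Fa[:, i] / np.linalg.norm(Fa[:, i])
            vb = Fb[:, j] / np.linalg.norm(Fb[:, j])
            c *= abs(float(va @ vb))
        return c

    best = -np.inf
    for perm in itertools.permutations(range(R)):
        total = sum(
            0.5 * (wa[i] + wb[j]) * congruence(i, j) for i, j in enumerate(perm)
        )
        best = max(best, total)
    return best


class TestCpFit:
    def test_rank1_noiseless_exact_recovery(self, rng):
        a, b, c = (rng.uniform(0.5, 1.0, d) for d in (10, 12, 14))
        X = np.einsum("i,j,k->ijk", a, b, c)
        model = cp_fit(X, 1, seed=0)
        assert model.error < 1e-6
        cos = abs(model.factors[0][:, 0] @ (a / np.linalg.norm(a)))
        assert cos >= 0.9999

    def test_rank3_noisy_planted_recovery(self, rng):
        dims, R = (20, 25, 30), 3
        gen = [rng.uniform(0.0, 1.0, (d, R)) for d in dims]
        X = np.einsum("ir,jr,kr->ijk", *gen)
        X = X + 0.05 * X.std() * rng.standard_normal(X.shape)
        X = np.maximum(X, 0.0)
        ens = restart_ensemble(X, R, n_restarts=20, seed=1)
        best = ens.best
        truth = CPModel(
            factors=gen, scales=np.ones(R), rank=R, error=0.0, n_iter=0
        ).normalized()
        # per-mode congruence of matched components
        from odorseq.tca import _congruence_matrix
        from scipy.optimize import linear_sum_assignment

        C = _congruence_matrix(best, truth)
        rows, cols = linear_sum_assignment(-C)
        assert C[rows, cols].min() >= 0.95

    def test_overcomplete_rank_still_monotone(self, rng):
        X = rng.uniform(0, 1, (4, 5, 6))
        model = cp_fit(X, rank=25, seed=2, max_iter=60)  # > product of small modes
        assert model.error <= 1.0  # monotonicity asserted inside the fit loop

    def test_unconstrained_als_also_converges(self, rng):
        gen = [rng.standard_normal((d, 2)) for d in (8, 9, 10)]
        X = np.einsum("ir,jr,kr->ijk", *gen)
        model = cp_fit(X, 2, seed=3, nonneg=False)
        assert model.error < 1e-5

    def test_nonfinite_tensor_rejected(self):
        X = np.zeros((2, 2, 2))
        X[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            cp_fit(X, 1)


class TestReconstructionError:
    def test_exact_model_gives_zero(self, rng):
        model = _random_model(rng)
        X = model.reconstruct()
        assert reconstruction_error(model, X) < 1e-12

    def test_zero_model_on_nonzero_tensor_gives_one(self, rng):
        model = _random_model(rng)
        zero = CPModel(
            factors=[np.zeros_like(F) for F in model.factors],
            scales=np.zeros(model.rank), rank=model.rank, error=1.0, n_iter=0,
        )
        X = model.reconstruct()
        assert reconstruction_error(zero, X) == pytest.approx(1.0)

    def test_hand_built_2x2x2_arithmetic(self):
        """Oracle: residual norm computed by direct arithmetic."""
        model = CPModel(
            factors=[np.array([[1.0], [0.0]]), np.array([[1.0], [0.0]]),
                     np.array([[1.0], [0.0]])],
            scales=np.array([2.0]), rank=1, error=0.0, n_iter=0,
        )
        X = np.zeros((2, 2, 2))
        X[0, 0, 0] = 1.0
        X[1, 1, 1] = 2.0
        # residual: (2-1) at [0,0,0] and -2 at [1,1,1] -> norm sqrt(5); ||X|| = sqrt(5)
        assert reconstruction_error(model, X) == pytest.approx(1.0)

    def test_zero_tensor_undefined(self, rng):
        model = _random_model(rng)
        with pytest.raises(ValueError, match="zero tensor"):
            reconstruction_error(model, np.zeros((6, 7, 8)))


class TestSimilarityScore:
    def test_self_similarity_is_one(self, rng):
        model = _random_model(rng)
        assert similarity_score(model, model) == pytest.approx(1.0)

    def test_permutation_and_rescaling_invariance(self, rng):
        model = _random_model(rng, rank=4)
        perm = [2, 0, 3, 1]
        other = CPModel(
            factors=[F[:, perm] * 3.0 for F in model.factors],
            scales=model.scales[perm], rank=4, error=0.0, n_iter=0,
        )
        assert similarity_score(model, other) == pytest.approx(1.0)

    def test_independent_models_score_low(self, rng):
        scores = [
            similarity_score(
                _random_model(rng, dims=(30, 40, 50), rank=10),
                _random_model(rng, dims=(30, 40, 50), rank=10),
            )
            for _ in range(5)
        ]
        assert max(scores) < 0.8

    def test_matches_brute_force_enumeration(self, rng):
        """The assignment route must equal exhaustive permutation search."""
        for _ in range(10):
            a = _random_model(rng, rank=5)
            b = _random_model(rng, rank=5)
            assert similarity_score(a, b) == pytest.approx(
                _brute_force_similarity(a, b), abs=1e-6
            )

    def test_rank_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="rank"):
            similarity_score(_random_model(rng, rank=2), _random_model(rng, rank=3))


class TestRestartEnsemble:
    def test_structured_tensor_high_similarity(self, rng):
        gen = [rng.uniform(0, 1, (d, 4)) for d in (20, 25, 30)]
        X = np.einsum("ir,jr,kr->ijk", *gen)
        X += 0.02 * X.std() * rng.standard_normal(X.shape)
        X = np.maximum(X, 0)
        ens = restart_ensemble(X, 4, n_restarts=15, seed=0)
        assert np.mean(ens.similarities > 0.8) > 0.7

    def test_single_restart_trivial(self, rng):
        X = np.maximum(rng.standard_normal((5, 6, 7)), 0)
        ens = restart_ensemble(X, 2, n_restarts=1, seed=0)
        assert len(ens.models) == 1
        assert ens.similarities[0] == pytest.approx(1.0)

    def test_master_seed_reproducibility(self, rng):
        X = np.maximum(rng.standard_normal((5, 6, 7)), 0)
        a = restart_ensemble(X, 2, n_restarts=3, seed=11)
        b = restart_ensemble(X, 2, n_restarts=3, seed=11)
        np.testing.assert_array_equal(a.errors, b.errors)
        np.testing.assert_array_equal(a.similarities, b.similarities)


class TestAlignment:
    def test_recovers_component_shuffle(self, rng):
        model = _random_model(rng, rank=5)
        perm = np.array([3, 1, 4, 0, 2])
        other = CPModel(
            factors=[F[:, perm] for F in model.factors],
            scales=model.scales[perm], rank=5, error=0.0, n_iter=0,
        )
        alignment = align_across_groups(model, other)
        np.testing.assert_array_equal(alignment.permutation, perm)
        assert alignment.congruences.min() > 0.999

    def test_orthogonal_factors_flagged_low(self, rng):
        eye = np.eye(8)
        a = CPModel(
            factors=[rng.uniform(0, 1, (5, 4)), eye[:, :4], rng.uniform(0, 1, (6, 4))],
            scales=np.ones(4), rank=4, error=0.0, n_iter=0,
        )
        b = CPModel(
            factors=[rng.uniform(0, 1, (5, 4)), eye[:, 4:], rng.uniform(0, 1, (6, 4))],
            scales=np.ones(4), rank=4, error=0.0, n_iter=0,
        )
        alignment = align_across_groups(a, b)
        assert alignment.low_congruence.all()


class TestComponentSummary:
    def _model(self, temporal, trial):
        T, K = len(temporal), len(trial)
        return CPModel(
            factors=[np.ones((3, 1)), np.asarray(temporal, float).reshape(T, 1),
                     np.asarray(trial, float).reshape(K, 1)],
            scales=np.ones(1), rank=1, error=0.0, n_iter=0,
        )

    def test_uniform_trial_loadings_position_general(self):
        epoch_of_bin = np.repeat(np.arange(9), 8)
        # event-locked temporal profile: loading concentrated after each event
        temporal = np.tile([0.1, 0.1, 0.2, 0.8, 1.0, 1.0, 0.9, 0.6], 9)
        model = self._model(temporal, np.ones(320))
        summary = component_summary(model, epoch_of_bin)
        assert summary["position_general"].all()

    def test_flat_offset_component_not_position_general(self):
        """Uniform trials AND flat within-epoch dynamics = mean-rate offset."""
        epoch_of_bin = np.repeat(np.arange(9), 8)
        model = self._model(np.ones(72), np.ones(320))
        summary = component_summary(model, epoch_of_bin)
        assert not summary["position_general"].any()
        assert summary.loc[0, "block_cv"] < 0.2  # excluded by the ratio, not CV

    def test_reward_block_loading_classified(self):
        epoch_of_bin = np.repeat(np.arange(9), 8)
        trial = np.zeros(320)
        trial[:80] = 1.0
        trial[240:] = 1.0  # blocks 0,1,6,7 = P1 and P4 = rewarded
        model = self._model(np.ones(72), trial)
        summary = component_summary(model, epoch_of_bin)
        assert summary["rewarded_preferring"].all()
        assert not summary["position_general"].any()

    def test_choice_dominant_component_labeled(self):
        epoch_of_bin = np.repeat(np.arange(9), 8)
        temporal = np.zeros(72)
        temporal[40:48] = 1.0  # Choice epoch bins
        model = self._model(temporal, np.ones(320))
        summary = component_summary(model, epoch_of_bin)
        assert summary.loc[0, "dominant_epoch"] == 5  # Choice

    def test_nonstandard_time_mode_rejected(self):
        model = self._model(np.ones(10), np.ones(320))
        with pytest.raises(ValueError, match="72"):
            component_summary(model, np.repeat(np.arange(5), 2))
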