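"""Pseudoensemble decoding: shuffling invariants, SVM, LOO, and nulls."""

import numpy as np
import pandas as pd
import pytest

from odorseq.decoding import (
    assemble_pseudoensembles,
    ensemble_size_curve,
    fit_linear_decoder,
    loo_accuracy,
    position_decoding,
    predict_linear_decoder,
    s1_vs_s2_decoding,
    shuffle_within_types,
    shuffled_null,
)
from odorseq.peth import EPOCHS, EpochRateMatrix


def _matrix(rng, n_per=10, n_units=20, n_sessions=2, signal=0.0, epoch="Odor"):
    """Synthetic epoch matrix with optional S1/S2 separation at every position."""
    labels = pd.DataFrame(
        {
            "trial_type": np.repeat(np.arange(1, 9), n_per),
            "sequence": np.repeat(["S1"] * 4 + ["S2"] * 4, n_per),
            "position": np.repeat([1, 2, 3, 4] * 2, n_per),
            "rewarded": np.repeat([True, False, False, True] * 2, n_per),
            "within_type_index": np.tile(np.arange(n_per), 8),
        }
    )
    seq_boost = (labels["sequence"] == "S1").to_numpy()[:, None] * signal
    rates = 5 + rng.normal(0, 1, (80 * n_per // 10, n_units)) + seq_boost
    unit_sessions = np.repeat(np.arange(n_sessions), n_units // n_sessions)
    return EpochRateMatrix(
        epoch=epoch, rates=rates, labels=labels,
        unit_ids=[f"u{u}" for u in range(n_units)], unit_sessions=unit_sessions,
    )


class TestShuffling:
    def test_per_type_rate_multisets_preserved(self, rng):
        m = _matrix(rng)
        types = m.labels["trial_type"].to_numpy()
        shuffled = shuffle_within_types(m.rates, types, m.unit_sessions, rng)
        for tt in range(1, 9):
            rows = types == tt
            for u in range(m.rates.shape[1]):
                assert sorted(shuffled[rows, u]) == pytest.approx(
                    sorted(m.rates[rows, u])
                )

    def test_across_unit_correlation_destroyed(self, rng):
        """Two perfectly correlated units in one session decorrelate on average."""
        n_per = 30
        labels_types = np.repeat(np.arange(1, 9), n_per)
        shared = rng.normal(0, 1, labels_types.size)
        rates = np.column_stack([shared, shared])
        sessions = np.array([0, 1])  # pretend different sessions
        cors = []
        for _ in range(200):
            s = shuffle_within_types(rates, labels_types, sessions, rng)
            cors.append(np.corrcoef(s[:, 0], s[:, 1])[0, 1])
        assert abs(np.mean(cors)) < 0.05

    def test_stream_deterministic_from_seed(self, rng):
        m = _matrix(rng)
        a = [r for r, _ in assemble_pseudoensembles(m, 3, seed=9)]
        b = [r for r, _ in assemble_pseudoensembles(m, 3, seed=9)]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestLinearDecoder:
    def test_separable_clouds_perfectly_classified(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (20, 5)), rng.normal(3, 0.3, (20, 5))])
        y = np.repeat([0, 1], 20)
        model = fit_linear_decoder(X, y)
        assert (predict_linear_decoder(model, X) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_linear_decoder(np.ones((5, 2)), np.zeros(5))

    def test_agrees_with_dual_qp_oracle(self):
        """Oracle: the soft-margin dual solved directly with SLSQP."""
        from scipy.optimize import minimize

        X = np.array(
            [[0.0, 0.0], [1.0, 0.5], [0.5, 1.0], [0.2, 0.8],
             [4.0, 4.0], [5.0, 3.5], [3.5, 5.0], [4.5, 4.5]]
        )
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        # replicate the training-fold standardization
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        ysign = np.where(y == 1, 1.0, -1.0)
        K = (Xs @ Xs.T) * np.outer(ysign, ysign)
        C = 1.0

        res = minimize(
            lambda a: 0.5 * a @ K @ a - a.sum(),
            x0=np.full(8, 0.1),
            jac=lambda a: K @ a - 1,
            bounds=[(0, C)] * 8,
            constraints={"type": "eq", "fun": lambda a: a @ ysign},
            method="SLSQP",
        )
        alpha = res.x
        w = (alpha * ysign) @ Xs
        sv = (alpha > 1e-6) & (alpha < C - 1e-6)
        b = np.mean(ysign[sv] - Xs[sv] @ w)

        probes = np.array([[0.5, 0.5], [4.2, 4.2], [1.0, 1.0], [3.8, 4.1]])
        oracle_pred = (((probes - mu) / sd) @ w + b > 0).astype(int)
        model = fit_linear_decoder(X, y)
        np.testing.assert_array_equal(predict_linear_decoder(model, probes), oracle_pred)


class TestLooAccuracy:
    def test_perfect_separation_gives_one(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (15, 10)), rng.normal(4, 0.2, (15, 10))])
        y = np.repeat([0, 1], 15)
        assert loo_accuracy(X, y, n_reps=20, seed=rng) == 1.0

    def test_planted_separation_high_accuracy(self, rng):
        """2 classes, 30 trials each, 2-SD mean separation, 50 units."""
        X = np.vstack(
            [rng.normal(0, 1, (30, 50)), rng.normal(2, 1, (30, 50))]
        )
        y = np.repeat([0, 1], 30)
        assert loo_accuracy(X, y, n_reps=50, seed=rng) > 0.9

    def test_shuffled_labels_fall_inside_null_band(self, rng):
        X = rng.normal(0, 1, (40, 10))
        y = np.repeat([0, 1], 20)
        null = shuffled_null(X, y, n_shuffles=60, seed=3, n_reps=10)
        acc = loo_accuracy(X, y[rng.permutation(40)], n_reps=10, seed=rng)
        lo, hi = np.percentile(null, [2.5, 97.5])
        assert lo - 0.05 <= acc <= hi + 0.05


class TestShuffledNull:
    def test_null_centers_on_chance(self, rng):
        X = rng.normal(0, 1, (40, 15))
        y = np.repeat([0, 1], 20)
        null = shuffled_null(X, y, n_shuffles=60, seed=1, n_reps=10)
        se = null.std() / np.sqrt(null.size)
        assert abs(null.mean() - 0.5) < 3 * se + 0.02

    def test_informative_input_above_ci(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 30)), rng.normal(2, 1, (20, 30))])
        y = np.repeat([0, 1], 20)
        null = shuffled_null(X, y, n_shuffles=40, seed=1, n_reps=10)
        acc = loo_accuracy(X, y, n_reps=20, seed=rng)
        assert acc > np.percentile(null, 97.5)


class TestS1VsS2Decoding:
    def test_null_signal_at_chance(self, rng):
        m = _matrix(rng, signal=0.0)
        res = s1_vs_s2_decoding(m, 2, n_pseudo=5, n_shuffles=30, n_reps=10, seed=0)
        assert res.above_null is False or res.accuracy < 0.7

    def test_planted_signal_detected(self, rng):
        m = _matrix(rng, signal=2.0)
        res = s1_vs_s2_decoding(m, 4, n_pseudo=5, n_shuffles=30, n_reps=10, seed=0)
        assert res.above_null

    def test_oversized_ensemble_rejected(self, rng):
        m = _matrix(rng, n_units=20)
        with pytest.raises(ValueError, match="ensemble_size"):
            s1_vs_s2_decoding(m, 1, ensemble_size=21)


class TestPositionDecoding:
    def _matrices(self, rng, cross_transfer=True):
        """Per-epoch matrices with position signatures; optionally sequence-specific."""
        n_per, n_units = 8, 30
        labels = pd.DataFrame(
            {
                "trial_type": np.repeat(np.arange(1, 9), n_per),
                "sequence": np.repeat(["S1"] * 4 + ["S2"] * 4, n_per),
                "position": np.repeat([1, 2, 3, 4] * 2, n_per),
                "rewarded": np.repeat([True, False, False, True] * 2, n_per),
                "within_type_index": np.tile(np.arange(n_per), 8),
            }
        )
        pos = labels["position"].to_numpy()
        seq = labels["sequence"].to_numpy()
        pref = rng.integers(1, 5, n_units)
        pref2 = pref if cross_transfer else rng.integers(1, 5, n_units)
        matrices = {}
        for e in EPOCHS:
            rates = np.empty((8 * n_per, n_units))
            for u in range(n_units):
                target = np.where(seq == "S1", pref[u], pref2[u])
                rates[:, u] = 5 + (pos == target) * 10 + rng.normal(0, 1, 8 * n_per)
            matrices[e] = EpochRateMatrix(
                epoch=e, rates=rates, labels=labels,
                unit_ids=[f"u{u}" for u in range(n_units)],
                unit_sessions=np.zeros(n_units, dtype=int),
            )
        return matrices

    def test_within_high_and_confusion_rows_normalized(self, rng):
        matrices = self._matrices(rng)
        confusion, acc = position_decoding(matrices, "within", n_iter=30, seed=0)
        assert acc > 0.9
        np.testing.assert_allclose(confusion.sum(axis=1), 1.0)

    def test_shared_signatures_transfer_across_sequences(self, rng):
        matrices = self._matrices(rng, cross_transfer=True)
        _, acc_within = position_decoding(matrices, "within", n_iter=30, seed=0)
        _, acc_across = position_decoding(matrices, "across", n_iter=30, seed=0)
        assert abs(acc_within - acc_across) < 0.1

    def test_sequence_specific_signatures_do_not_transfer(self, rng):
        matrices = self._matrices(rng, cross_transfer=False)
        _, acc_within = position_decoding(matrices, "within", n_iter=30, seed=0)
        _, acc_across = position_decoding(matrices, "across", n_iter=30, seed=0)
        assert acc_within > acc_across + 0.3

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError, match="mode"):
            position_decoding(self._matrices(rng), "sideways")


class TestEnsembleSizeCurve:
    def test_noise_curve_flat_at_chance(self, rng):
        m = _matrix(rng, n_units=30, signal=0.0)
        curves = ensemble_size_curve(m, 2, sizes=(5, 20), n_pseudo=5, n_reps=10, seed=0)
        for res in curves.values():
            assert not res.above_null

    def test_planted_signal_grows_with_size(self, rng):
        m = _matrix(rng, n_units=60, signal=0.6)
        curves = ensemble_size_curve(m, 1, sizes=(5, 50), n_pseudo=8, n_reps=10, seed=0)
        assert curves[50].accuracy >= curves[5].accuracy

    def test_sizes_beyond_available_truncated(self, rng):
        m = _matrix(rng, n_units=20)
        curves = ensemble_size_curve(m, 1, sizes=(10, 500), n_pseudo=2, n_reps=5, seed=0)
        assert list(curves) == [10]
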