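"""Per-unit selectivity statistics: rank-sum, chi-squared, ANOVA, Fisher r-to-z."""

import numpy as np
import pytest
from scipy import stats

from odorseq.selectivity import (
    compare_fractions,
    fisher_r_to_z,
    preferred_position_analysis,
    selectivity_fraction_curve,
    selectivity_table,
    sequence_selectivity,
    two_way_anova_unit,
)


class TestSequenceSelectivity:
    def test_fully_separated_samples_detected(self):
        flag, _, p = sequence_selectivity(np.full(30, 10.0), np.zeros(30))
        assert flag and p < 1e-9

    def test_constant_equal_rates_not_selective(self):
        flag, stat, p = sequence_selectivity(np.full(10, 5.0), np.full(10, 5.0))
        assert not flag and p == 1.0 and stat == 0.0

    def test_type_one_error_rate_calibrated(self, rng):
        """Identical distributions: flags fire at ~alpha over 1000 null draws."""
        alpha = 0.05
        flags = [
            sequence_selectivity(rng.normal(5, 1, 30), rng.normal(5, 1, 30), alpha)[0]
            for _ in range(1000)
        ]
        se = np.sqrt(alpha * (1 - alpha) / 1000)
        assert abs(np.mean(flags) - alpha) < 3 * se

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="5 trials"):
            sequence_selectivity(np.ones(4), np.ones(10))


class TestCompareFractions:
    def test_equal_proportions_give_zero(self):
        chi2, p = compare_fractions(50, 1000, 50, 1000)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_chi_squared(self):
        """Oracle: brute-force sum of (O-E)^2/E on the 2x2 table."""
        table = np.array([[100, 800], [50, 900]], dtype=float)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected_counts = row @ col / table.sum()
        chi2_oracle = np.sum((table - expected_counts) ** 2 / expected_counts)
        chi2, p = compare_fractions(100, 900, 50, 950)
        assert chi2 == pytest.approx(chi2_oracle)
        assert p == pytest.approx(stats.chi2.sf(chi2_oracle, 1))

    def test_group_order_symmetry(self):
        a = compare_fractions(100, 900, 50, 950)
        b = compare_fractions(50, 950, 100, 900)
        assert a == pytest.approx(b)

    def test_zero_margin_logged_not_crashed(self):
        chi2, p = compare_fractions(0, 100, 0, 100)
        assert (chi2, p) == (0.0, 1.0)


class TestTwoWayAnova:
    def test_constant_cells_give_zero_f(self):
        seq = np.repeat(["S1", "S2"], 8)
        pos = np.tile(np.repeat([1, 2], 4), 2)
        res = two_way_anova_unit(np.full(16, 3.0), seq, pos)
        assert res.f_sequence == res.f_position == res.f_interaction == 0.0

    def test_additive_effects_interaction_calibrated(self, rng):
        """No planted interaction: interaction flags fire at ~alpha."""
        n, reps, alpha = 10, 400, 0.05
        seq = np.repeat(["S1", "S2"], 4 * n)
        pos = np.tile(np.repeat([1, 2, 3, 4], n), 2)
        seq_eff = (seq == "S2") * 2.0
        pos_eff = np.array([0, 1, 2, 3])[pos.astype(int) - 1] * 1.5
        flags = []
        for _ in range(reps):
            y = 5 + seq_eff + pos_eff + rng.normal(0, 1, seq.size)
            flags.append(two_way_anova_unit(y, seq, pos).p_interaction < alpha)
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(np.mean(flags) - alpha) < 3 * se

    def test_crossover_interaction_detected(self, rng):
        """5 Hz crossover vs 1 Hz noise at 30 trials/cell: p < 0.01."""
        n = 30
        seq = np.repeat(["S1", "S2"], 2 * n)
        pos = np.tile(np.repeat([1, 2], n), 2)
        effect = np.where((seq == "S1") == (pos == 1), 5.0, 0.0)
        y = 5 + effect + rng.normal(0, 1, seq.size)
        res = two_way_anova_unit(y, seq, pos)
        assert res.p_interaction < 0.01
        assert 0 <= res.eta_interaction <= 1

    def test_matches_statsmodels_oracle(self, rng):
        """Independent route: OLS ANOVA table from statsmodels."""
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        n = 6
        seq = np.repeat(["S1", "S2"], 4 * n)
        pos = np.tile(np.repeat([1, 2, 3, 4], n), 2)
        y = rng.normal(5, 2, seq.size) + (seq == "S1") * pos
        res = two_way_anova_unit(y, seq, pos)
        df = pd.DataFrame({"y": y, "seq": seq, "pos": pos.astype(str)})
        table = sm.stats.anova_lm(ols("y ~ C(seq) * C(pos)", df).fit(), typ=2)
        assert res.f_sequence == pytest.approx(table.loc["C(seq)", "F"])
        assert res.f_position == pytest.approx(table.loc["C(pos)", "F"])
        assert res.f_interaction == pytest.approx(table.loc["C(seq):C(pos)", "F"])
        assert res.p_interaction == pytest.approx(table.loc["C(seq):C(pos)", "PR(>F)"])


class TestSelectivityCurves:
    def test_all_flags_false_gives_zero_fractions(self, rng):
        from odorseq.peth import EPOCHS, EpochRateMatrix
        import pandas as pd

        n_per, n_units = 10, 15
        labels = pd.DataFrame(
            {
                "trial_type": np.repeat(np.arange(1, 9), n_per),
                "sequence": np.repeat(["S1"] * 4 + ["S2"] * 4, n_per),
                "position": np.repeat([1, 2, 3, 4] * 2, n_per),
                "rewarded": np.repeat([True, False, False, True] * 2, n_per),
                "within_type_index": np.tile(np.arange(n_per), 8),
            }
        )
        matrices = {
            e: EpochRateMatrix(
                epoch=e, rates=rng.normal(5, 1, (80, n_units)), labels=labels,
                unit_ids=[f"u{u}" for u in range(n_units)],
                unit_sessions=np.zeros(n_units, dtype=int),
            )
            for e in EPOCHS
        }
        table = selectivity_table(matrices, alpha=1e-12)  # nothing can pass
        curve = selectivity_fraction_curve(table)
        assert len(curve) == 36
        assert (curve["fraction"] == 0).all()


class TestPreferredPosition:
    def test_consistent_preferences_give_r_one(self, rng):
        """Units strongly tuned to the same position on both sequences."""
        from odorseq.peth import EPOCHS, EpochRateMatrix
        import pandas as pd

        n_per = 10
        labels = pd.DataFrame(
            {
                "trial_type": np.repeat(np.arange(1, 9), n_per),
                "sequence": np.repeat(["S1"] * 4 + ["S2"] * 4, n_per),
                "position": np.repeat([1, 2, 3, 4] * 2, n_per),
                "rewarded": np.repeat([True, False, False, True] * 2, n_per),
                "within_type_index": np.tile(np.arange(n_per), 8),
            }
        )
        n_units = 12
        pref = np.arange(n_units) % 4 + 1
        rates = np.empty((80, n_units))
        for u in range(n_units):
            boost = (labels["position"].to_numpy() == pref[u]) * 20.0
            rates[:, u] = 5 + boost + rng.normal(0, 0.5, 80)
        matrices = {
            e: EpochRateMatrix(
                epoch=e, rates=rates, labels=labels,
                unit_ids=[f"u{u}" for u in range(n_units)],
                unit_sessions=np.zeros(n_units, dtype=int),
            )
            for e in EPOCHS
        }
        result = preferred_position_analysis(matrices)
        assert result.r == pytest.approx(1.0)

    def test_independent_preferences_give_r_near_zero(self, rng):
        from odorseq.peth import EPOCHS, EpochRateMatrix
        import pandas as pd

        n_per = 10
        labels = pd.DataFrame(
            {
                "trial_type": np.repeat(np.arange(1, 9), n_per),
                "sequence": np.repeat(["S1"] * 4 + ["S2"] * 4, n_per),
                "position": np.repeat([1, 2, 3, 4] * 2, n_per),
                "rewarded": np.repeat([True, False, False, True] * 2, n_per),
                "within_type_index": np.tile(np.arange(n_per), 8),
            }
        )
        n_units = 200
        rates = np.empty((80, n_units))
        seq = labels["sequence"].to_numpy()
        pos = labels["position"].to_numpy()
        for u in range(n_units):
            p1, p2 = rng.integers(1, 5, 2)
            boost = np.where(seq == "S1", (pos == p1) * 20.0, (pos == p2) * 20.0)
            rates[:, u] = 5 + boost + rng.normal(0, 0.5, 80)
        matrices = {
            e: EpochRateMatrix(
                epoch=e, rates=rates, labels=labels,
                unit_ids=[f"u{u}" for u in range(n_units)],
                unit_sessions=np.zeros(n_units, dtype=int),
            )
            for e in EPOCHS
        }
        result = preferred_position_analysis(matrices)
        assert abs(result.r) < 0.1


class TestFisherRtoZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_r_to_z(0.4, 50, 0.4, 80)
        assert z == 0.0 and p == 1.0

    def test_closed_form_arithmetic(self):
        z, p = fisher_r_to_z(0.5, 103, 0.0, 103)
        assert z == pytest.approx(np.arctanh(0.5) * np.sqrt(50))
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_antisymmetry(self):
        z1, p1 = fisher_r_to_z(0.6, 40, 0.2, 60)
        z2, p2 = fisher_r_to_z(0.2, 60, 0.6, 40)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_r_to_z(1.0, 50, 0.0, 50)

    def test_agrees_with_permutation_comparison(self, rng):
        """Oracle: permutation of group labels on simulated paired data."""
        n = 60
        x1 = rng.normal(size=n)
        y1 = 0.6 * x1 + 0.8 * rng.normal(size=n)
        x2 = rng.normal(size=n)
        y2 = rng.normal(size=n)
        r1 = np.corrcoef(x1, y1)[0, 1]
        r2 = np.corrcoef(x2, y2)[0, 1]
        _, p_fisher = fisher_r_to_z(r1, n, r2, n)
        xs = np.concatenate([x1, x2])
        ys = np.concatenate([y1, y2])
        observed = abs(r1 - r2)
        n_perm = 2000
        hits = 0
        for _ in range(n_perm):
            idx = rng.permutation(2 * n)
            ra = np.corrcoef(xs[idx[:n]], ys[idx[:n]])[0, 1]
            rb = np.corrcoef(xs[idx[n:]], ys[idx[n:]])[0, 1]
            hits += abs(ra - rb) >= observed
        p_perm = (hits + 1) / (n_perm + 1)
        # Monte-Carlo agreement: both reject or both accept at 0.05, and the
        # p-values agree within a few MC standard errors
        mc_se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_fisher - p_perm) < 5 * mc_se + 0.02
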