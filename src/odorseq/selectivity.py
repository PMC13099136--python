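"""Per-unit selectivity statistics and group comparisons.

Covers the single-unit layer of the analysis: S1-vs-S2 rank-sum
selectivity per (epoch, position) with selective-fraction curves and
chi-squared group comparisons, per-unit two-way ANOVA (sequence x
position) with partial eta squared, preferred-position correlation across
sequences, and Fisher's r-to-z comparison of two correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peth import EPOCHS, EpochRateMatrix

logger = logging.getLogger(__name__)


def sequence_selectivity(
    rates_s1: np.ndarray,
    rates_s2: np.ndarray,
    alpha: float = 0.05,
    method: str = "ranksum",
) -> tuple[bool, float, float]:
    """Two-sided S1-vs-S2 test of one unit's epoch rates at one position.

    Default test is the Wilcoxon rank-sum (robust to non-normal rates); a
    Welch t-test is available via ``method="ttest"``.  Requires at least
    5 trials per side.
    """
    rates_s1 = np.asarray(rates_s1, float)
    rates_s2 = np.asarray(rates_s2, float)
    if rates_s1.size < 5 or rates_s2.size < 5:
        raise ValueError("need >= 5 trials per sequence")
    if method == "ranksum":
        stat, p = stats.ranksums(rates_s1, rates_s2)
    elif method == "ttest":
        stat, p = stats.ttest_ind(rates_s1, rates_s2, equal_var=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    if np.isnan(p):  # both sides constant and equal
        stat, p = 0.0, 1.0
    return bool(p < alpha), float(stat), float(p)


def selectivity_table(
    matrices: dict[str, EpochRateMatrix],
    alpha: float = 0.05,
    method: str = "ranksum",
) -> pd.DataFrame:
    """S1-vs-S2 selectivity of every unit at every (epoch, position) cell.

    Returns a long-form table: unit_id, epoch, position, statistic, p,
    selective.
    """
    rows = []
    for epoch in EPOCHS:
        m = matrices[epoch]
        for position in (1, 2, 3, 4):
            mask_s1 = ((m.labels["position"] == position) & (m.labels["sequence"] == "S1")).to_numpy()
            mask_s2 = ((m.labels["position"] == position) & (m.labels["sequence"] == "S2")).to_numpy()
            r1 = m.rates[mask_s1]
            r2 = m.rates[mask_s2]
            for u, unit_id in enumerate(m.unit_ids):
                flag, stat, p = sequence_selectivity(r1[:, u], r2[:, u], alpha, method)
                rows.append(
                    {
                        "unit_id": unit_id,
                        "epoch": epoch,
                        "position": position,
                        "statistic": stat,
                        "p": p,
                        "selective": flag,
                    }
                )
    return pd.DataFrame(rows)


def selectivity_fraction_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Fraction of selective units per (epoch, position): 36 cells."""
    out = (
        table.groupby(["epoch", "position"], sort=False)
        .agg(n_selective=("selective", "sum"), n_tested=("selective", "size"))
        .reset_index()
    )
    out["fraction"] = out["n_selective"] / out["n_tested"]
    return out


def compare_fractions(
    n_selective_a: int, n_total_a: int, n_selective_b: int, n_total_b: int
) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on a 2x2
    selective-by-group table."""
    table = np.array(
        [
            [n_selective_a, n_total_a - n_selective_a],
            [n_selective_b, n_total_b - n_selective_b],
        ],
        dtype=float,
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        logger.info("chi-squared: zero margin, returning chi2=0, p=1")
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def compare_fraction_curves(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell chi-squared comparison of two groups' selective fractions."""
    fa = selectivity_fraction_curve(table_a)
    fb = selectivity_fraction_curve(table_b)
    merged = fa.merge(fb, on=["epoch", "position"], suffixes=("_a", "_b"))
    chi2s, ps = [], []
    for _, row in merged.iterrows():
        chi2, p = compare_fractions(
            int(row["n_selective_a"]), int(row["n_tested_a"]),
            int(row["n_selective_b"]), int(row["n_tested_b"]),
        )
        chi2s.append(chi2)
        ps.append(p)
    merged["chi2"] = chi2s
    merged["p"] = ps
    return merged


@dataclass
class AnovaResult:
    """Balanced two-way fixed-effects ANOVA with partial eta squared."""

    f_sequence: float
    p_sequence: float
    eta_sequence: float
    f_position: float
    p_position: float
    eta_position: float
    f_interaction: float
    p_interaction: float
    eta_interaction: float


def two_way_anova_unit(
    rates: np.ndarray, sequence: np.ndarray, position: np.ndarray
) -> AnovaResult:
    """Sequence x position ANOVA on one unit's trial rates (balanced design).

    Sums of squares are computed directly from cell means, which is exact
    for the balanced design guaranteed by the trial-selection stage;
    partial eta squared = SS_effect / (SS_effect + SS_error).
    """
    rates = np.asarray(rates, float)
    seqs = np.unique(sequence)
    poss = np.unique(position)
    a, b = len(seqs), len(poss)
    cells = np.empty((a, b), dtype=object)
    n = None
    for i, s in enumerate(seqs):
        for j, p in enumerate(poss):
            cell = rates[(sequence == s) & (position == p)]
            if n is None:
                n = cell.size
            elif cell.size != n:
                raise ValueError("design must be balanced")
            if cell.size < 2:
                raise ValueError("need >= 2 trials per cell")
            cells[i, j] = cell
    cell_means = np.array([[c.mean() for c in row] for row in cells])
    grand = cell_means.mean()
    row_means = cell_means.mean(axis=1)
    col_means = cell_means.mean(axis=0)
    ss_a = n * b * np.sum((row_means - grand) ** 2)
    ss_b = n * a * np.sum((col_means - grand) ** 2)
    ss_ab = n * np.sum(
        (cell_means - row_means[:, None] - col_means[None, :] + grand) ** 2
    )
    ss_e = sum(np.sum((c - c.mean()) ** 2) for c in cells.ravel())
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (n - 1)
    ms_e = ss_e / df_e

    def f_p_eta(ss: float, df: int) -> tuple[float, float, float]:
        if ms_e == 0:
            f = 0.0 if ss == 0 else np.inf
            p = 1.0 if ss == 0 else 0.0
        else:
            f = (ss / df) / ms_e
            p = float(stats.f.sf(f, df, df_e))
        eta = ss / (ss + ss_e) if (ss + ss_e) > 0 else 0.0
        return float(f), p, float(eta)

    fa, pa, ea = f_p_eta(ss_a, df_a)
    fb, pb, eb = f_p_eta(ss_b, df_b)
    fab, pab, eab = f_p_eta(ss_ab, df_ab)
    return AnovaResult(fa, pa, ea, fb, pb, eb, fab, pab, eab)


def interaction_prevalence(
    matrices: dict[str, EpochRateMatrix], alpha: float = 0.05
) -> pd.DataFrame:
    """Fraction of units with a significant sequence x position interaction per epoch."""
    rows = []
    for epoch in EPOCHS:
        m = matrices[epoch]
        seq = m.labels["sequence"].to_numpy()
        pos = m.labels["position"].to_numpy()
        flags = []
        for u in range(m.rates.shape[1]):
            res = two_way_anova_unit(m.rates[:, u], seq, pos)
            flags.append(res.p_interaction < alpha)
        rows.append({"epoch": epoch, "fraction": float(np.mean(flags)), "n_units": len(flags)})
    return pd.DataFrame(rows)


@dataclass
class PreferredPositionPairs:
    """Preferred positions on the two sequences for doubly-selective units."""

    pairs: pd.DataFrame  # unit_id, epoch, preferred_s1, preferred_s2
    r: Optional[float]
    n: int


def preferred_position_analysis(
    matrices: dict[str, EpochRateMatrix],
    alpha: float = 0.01,
    method: str = "pearson",
) -> PreferredPositionPairs:
    """Cross-sequence consistency of position preference.

    A (unit, epoch) enters if a one-way ANOVA across the four positions is
    significant (p < alpha) independently on both sequences; its preferred
    position is the argmax of mean rate.  The correlation pools the
    included pairs over epochs, treating positions as ordinal codes 1-4.
    """
    rows = []
    for epoch in EPOCHS:
        m = matrices[epoch]
        seq = m.labels["sequence"].to_numpy()
        pos = m.labels["position"].to_numpy()
        for u, unit_id in enumerate(m.unit_ids):
            prefs = {}
            for s in ("S1", "S2"):
                groups = [m.rates[(seq == s) & (pos == p), u] for p in (1, 2, 3, 4)]
                if any(g.size < 2 for g in groups):
                    break
                f, p_val = stats.f_oneway(*groups)
                if np.isnan(p_val) or p_val >= alpha:
                    break
                prefs[s] = 1 + int(np.argmax([g.mean() for g in groups]))
            if len(prefs) == 2:
                rows.append(
                    {
                        "unit_id": unit_id,
                        "epoch": epoch,
                        "preferred_s1": prefs["S1"],
                        "preferred_s2": prefs["S2"],
                    }
                )
    pairs = pd.DataFrame(rows, columns=["unit_id", "epoch", "preferred_s1", "preferred_s2"])
    if len(pairs) < 5:
        logger.info("preferred-position correlation undefined: %d pairs", len(pairs))
        return PreferredPositionPairs(pairs=pairs, r=None, n=len(pairs))
    x = pairs["preferred_s1"].to_numpy(float)
    y = pairs["preferred_s2"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        r = 1.0 if np.array_equal(x, y) else None
    elif method == "pearson":
        r = float(stats.pearsonr(x, y)[0])
    elif method == "spearman":
        r = float(stats.spearmanr(x, y)[0])
    else:
        raise ValueError(f"unknown method {method!r}")
    return PreferredPositionPairs(pairs=pairs, r=r, n=len(pairs))


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two independent correlations via Fisher's variance-stabilizing
    transform: z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))."""
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both groups")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1 (transform diverges)")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
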