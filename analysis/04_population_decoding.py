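"""Pseudoensemble decoding: S1-vs-S2 by position and epoch with null bands,
ensemble-size curves, and within-/across-sequence position decoding.

Expects 01 and 02 to have run.  Desk-scale repeat counts (tens of
pseudoensembles, 100 shuffles) keep the stage minutes long; the full-scale
counts are plain function arguments.
"""

import sys

import numpy as np
import pandas as pd

from common import GROUPS, RESULTS, SEED, load_matrices

from odorseq.decoding import ensemble_size_curve, position_decoding, s1_vs_s2_decoding
from odorseq.peth import EPOCHS


def main() -> None:
    rows = []
    for name in GROUPS:
        matrices = load_matrices(name)
        n_units = matrices[EPOCHS[0]].rates.shape[1]
        size = min(100, n_units)
        for position in (1, 2, 3, 4):
            for epoch in EPOCHS:
                res = s1_vs_s2_decoding(
                    matrices[epoch], position, ensemble_size=size,
                    n_pseudo=10, n_shuffles=100, n_reps=10,
                    seed=SEED + 131 * position,
                )
                lo, hi = res.null_ci
                rows.append(
                    {
                        "group": name, "position": position, "epoch": epoch,
                        "accuracy": res.accuracy, "null_lo": lo, "null_hi": hi,
                        "above_null": res.above_null,
                    }
                )
        n_above = sum(
            r["above_null"] for r in rows
            if r["group"] == name and r["position"] in (2, 3)
        )
        print(f"{name}: {n_above}/18 P2/P3 cells decode S1 vs S2 above the null band")
    seq = pd.DataFrame(rows)
    seq.to_csv(RESULTS / "04_s1_vs_s2_decoding.csv", index=False)

    size_rows = []
    for name in GROUPS:
        matrices = load_matrices(name)
        curves = ensemble_size_curve(
            matrices["Choice"], 4, sizes=(10, 20, 50, 100),
            n_pseudo=10, n_reps=10, seed=SEED,
        )
        for size, res in curves.items():
            size_rows.append(
                {"group": name, "ensemble_size": size, "accuracy": res.accuracy}
            )
    pd.DataFrame(size_rows).to_csv(RESULTS / "04_ensemble_size_curve.csv", index=False)

    pos_rows = []
    for name in GROUPS:
        matrices = load_matrices(name)
        for mode in ("within", "across"):
            confusion, acc = position_decoding(
                matrices, mode=mode, n_iter=300, ensemble_size=5, seed=SEED
            )
            pd.DataFrame(
                confusion,
                index=[f"actual_P{p}" for p in (1, 2, 3, 4)],
                columns=[f"pred_P{p}" for p in (1, 2, 3, 4)],
            ).to_csv(RESULTS / f"04_confusion_{name}_{mode}.csv")
            pos_rows.append({"group": name, "mode": mode, "accuracy": acc})
        w = next(r["accuracy"] for r in pos_rows if r["group"] == name and r["mode"] == "within")
        a = next(r["accuracy"] for r in pos_rows if r["group"] == name and r["mode"] == "across")
        print(f"{name}: position decoding within {w:.3f}, across {a:.3f}, gap {w - a:+.3f}")
    pd.DataFrame(pos_rows).to_csv(RESULTS / "04_position_decoding.csv", index=False)


if __name__ == "__main__":
    sys.exit(main())
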