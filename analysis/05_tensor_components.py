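"""CP decomposition of the trial tensors: restart stability, component
summaries, and cross-group alignment by temporal factors.

Expects 01 and 02 to have run.  Uses 30 restarts of the rank-10
nonnegative fit per group (the full 100-restart diagnostic runs in
scripts/acceptance.py); saves the best-fit factors for stage 06.
"""

import sys

import numpy as np
import pandas as pd

from common import DERIVED, GROUPS, RESULTS, SEED, load_tensor

from odorseq.tca import align_across_groups, component_summary, restart_ensemble

RANK = 10
N_RESTARTS = 30


def main() -> None:
    best_models = {}
    for name in GROUPS:
        tensor = load_tensor(name)
        ens = restart_ensemble(tensor, RANK, n_restarts=N_RESTARTS, seed=SEED)
        best_models[name] = ens.best
        pd.DataFrame(
            {
                "restart": np.arange(N_RESTARTS),
                "error": ens.errors,
                "similarity_to_best": ens.similarities,
            }
        ).to_csv(RESULTS / f"05_tca_restarts_{name}.csv", index=False)
        summary = component_summary(ens.best, tensor.epoch_of_bin)
        summary.to_csv(RESULTS / f"05_tca_components_{name}.csv", index=False)
        np.savez_compressed(
            DERIVED / f"{name}_cp_best.npz",
            unit=ens.best.factors[0], temporal=ens.best.factors[1],
            trial=ens.best.factors[2], scales=ens.best.scales,
            errors=ens.errors,
        )
        n_pg = int(summary["position_general"].sum())
        print(
            f"{name}: best error {ens.best.error:.3f}, mean restart similarity "
            f"{ens.mean_similarity:.3f}, {n_pg} position-general component(s), "
            f"{int(summary['rewarded_preferring'].sum())} reward-preferring"
        )

    alignment = align_across_groups(
        best_models["compressed"], best_models["differentiated"]
    )
    pd.DataFrame(
        {
            "differentiated_component": np.arange(RANK),
            "matched_compressed_component": alignment.permutation,
            "temporal_congruence": alignment.congruences,
            "below_threshold": alignment.low_congruence,
        }
    ).to_csv(RESULTS / "05_cross_group_alignment.csv", index=False)
    print(
        f"cross-group temporal alignment: median congruence "
        f"{np.median(alignment.congruences):.2f}, "
        f"{int(alignment.low_congruence.sum())}/{RANK} pairs below 0.5"
    )


if __name__ == "__main__":
    sys.exit(main())
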