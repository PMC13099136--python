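"""Build epoch rate matrices and trial tensors from the simulated sessions.

Per group: nine 240 x N rate matrices (30 correct trials x 8 trial types)
and one N x 72 x 320 trial tensor.  Arrays go to scratch/derived/ for the
later stages; the structural summary goes to results/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from odorseq.io import read_session
from odorseq.peth import EPOCHS, build_rate_matrices, build_trial_tensor

SEED = 2024
ROOT = Path(__file__).resolve().parents[1]
SESSIONS = ROOT / "scratch" / "sessions"
DERIVED = ROOT / "scratch" / "derived"
RESULTS = ROOT / "results"


def main() -> None:
    DERIVED.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in ("compressed", "differentiated"):
        paths = sorted(SESSIONS.glob(f"{name}_s*"))
        sessions = [read_session(p) for p in paths]
        matrices = build_rate_matrices(sessions, n_per_type=30, seed=SEED)
        tensor = build_trial_tensor(sessions)

        payload = {f"rates_{e}": matrices[e].rates for e in EPOCHS}
        payload["tensor"] = tensor.data
        payload["unit_sessions"] = matrices[EPOCHS[0]].unit_sessions
        payload["epoch_of_bin"] = tensor.epoch_of_bin
        np.savez_compressed(DERIVED / f"{name}.npz", **payload)
        matrices[EPOCHS[0]].labels.to_csv(DERIVED / f"{name}_labels.csv", index=False)
        tensor.trial_labels.to_csv(DERIVED / f"{name}_tensor_trials.csv", index=False)
        (DERIVED / f"{name}_units.json").write_text(
            json.dumps(matrices[EPOCHS[0]].unit_ids)
        )
        rows.append(
            {
                "group": name,
                "epochs": len(EPOCHS),
                "matrix_rows": matrices[EPOCHS[0]].rates.shape[0],
                "matrix_units": matrices[EPOCHS[0]].rates.shape[1],
                "tensor_shape": "x".join(map(str, tensor.shape)),
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "02_rate_structures.csv", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
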