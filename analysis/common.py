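"""Shared loaders for the numbered analysis stages."""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from odorseq.peth import EPOCHS, EpochRateMatrix, TrialTensor

ROOT = Path(__file__).resolve().parents[1]
SESSIONS = ROOT / "scratch" / "sessions"
DERIVED = ROOT / "scratch" / "derived"
RESULTS = ROOT / "results"

SEED = 2024
GROUPS = ("compressed", "differentiated")


def load_matrices(name: str) -> dict[str, EpochRateMatrix]:
    data = np.load(DERIVED / f"{name}.npz")
    labels = pd.read_csv(DERIVED / f"{name}_labels.csv")
    unit_ids = json.loads((DERIVED / f"{name}_units.json").read_text())
    return {
        e: EpochRateMatrix(
            epoch=e,
            rates=data[f"rates_{e}"],
            labels=labels,
            unit_ids=unit_ids,
            unit_sessions=data["unit_sessions"],
            seed=SEED,
        )
        for e in EPOCHS
    }


def load_tensor(name: str) -> TrialTensor:
    data = np.load(DERIVED / f"{name}.npz")
    unit_ids = json.loads((DERIVED / f"{name}_units.json").read_text())
    return TrialTensor(
        data=data["tensor"],
        unit_ids=unit_ids,
        epoch_of_bin=data["epoch_of_bin"],
        trial_labels=pd.read_csv(DERIVED / f"{name}_tensor_trials.csv"),
    )
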