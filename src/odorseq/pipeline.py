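"""End-to-end pipeline: simulate -> rates -> selectivity -> decoding -> CP -> MI -> behavior.

One master seed drives every stage; per-stage seeds are derived by stable
hashing of (master seed, stage name) so any stage can be rerun
independently with identical results.  Every run writes the fully
resolved configuration next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import decoding, mi as mi_mod, selectivity, tca
from .peth import EPOCHS, BinningParams, build_rate_matrices, build_trial_tensor
from .simulate import PopulationTemplate, simulate_group
from .task import TaskConfig

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}|{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults.

    Decoding repeat counts default to desk-scale values; the full-scale
    counts used for publication-grade runs (10,000 pseudoensembles, 200
    leave-one-out repetitions) are available by overriding ``n_pseudo``
    and ``n_loo_reps``.
    """

    seed: int = 0
    templates: tuple[str, ...] = ("compressed", "differentiated")
    n_units: int = 300
    n_sessions: int = 1
    n_per_type: int = 30
    n_pseudo: int = 50
    n_shuffles: int = 100
    n_loo_reps: int = 20
    ensemble_size: Optional[int] = 100
    rank: int = 10
    n_restarts: int = 20
    mi_bins: int = 8
    decode_positions: tuple[int, ...] = (1, 2, 3, 4)
    decode_epochs: tuple[str, ...] = EPOCHS

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write CSV outputs plus the resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json() + "\n")
    task = TaskConfig()

    groups = {}
    for name in config.templates:
        template = (
            PopulationTemplate.compressed(config.n_units)
            if name == "compressed"
            else PopulationTemplate.differentiated(config.n_units)
        )
        sessions, truth = simulate_group(
            template, config.n_sessions, stage_seed(config.seed, f"simulate/{name}"), task
        )
        truth.to_json(out / f"ground_truth_{name}.json")
        logger.info("simulated %d %s session(s)", len(sessions), name)
        matrices = build_rate_matrices(
            sessions, config.n_per_type, stage_seed(config.seed, f"peth/{name}")
        )
        tensor = build_trial_tensor(sessions)
        groups[name] = {"sessions": sessions, "matrices": matrices, "tensor": tensor}

    # selectivity
    tables = {}
    for name, g in groups.items():
        table = selectivity.selectivity_table(g["matrices"])
        table.to_csv(out / f"selectivity_{name}.csv", index=False)
        selectivity.selectivity_fraction_curve(table).to_csv(
            out / f"selectivity_fractions_{name}.csv", index=False
        )
        tables[name] = table
    if len(tables) == 2:
        a, b = (tables[n] for n in config.templates)
        selectivity.compare_fraction_curves(a, b).to_csv(
            out / "selectivity_group_comparison.csv", index=False
        )

    # decoding
    decode_rows = []
    for name, g in groups.items():
        dseed = stage_seed(config.seed, f"decode/{name}")
        for position in config.decode_positions:
            for epoch in config.decode_epochs:
                res = decoding.s1_vs_s2_decoding(
                    g["matrices"][epoch], position,
                    ensemble_size=min(config.ensemble_size or 10**9,
                                      g["matrices"][epoch].rates.shape[1]),
                    n_pseudo=config.n_pseudo, n_shuffles=config.n_shuffles,
                    n_reps=config.n_loo_reps, seed=dseed + 131 * position,
                )
                lo, hi = res.null_ci
                decode_rows.append(
                    {
                        "group": name, "position": position, "epoch": epoch,
                        "accuracy": res.accuracy, "null_lo": lo, "null_hi": hi,
                        "above_null": res.above_null,
                    }
                )
        for mode in ("within", "across"):
            _, acc = decoding.position_decoding(
                g["matrices"], mode=mode, n_iter=config.n_pseudo,
                ensemble_size=config.ensemble_size, seed=dseed,
            )
            decode_rows.append(
                {
                    "group": name, "position": 0, "epoch": f"position-{mode}",
                    "accuracy": acc, "null_lo": None, "null_hi": None,
                    "above_null": None,
                }
            )
    pd.DataFrame(decode_rows).to_csv(out / "decoding.csv", index=False)

    # tensor decomposition + MI
    for name, g in groups.items():
        ens = tca.restart_ensemble(
            g["tensor"], config.rank, n_restarts=config.n_restarts,
            seed=stage_seed(config.seed, f"tca/{name}"),
        )
        pd.DataFrame(
            {"restart": np.arange(len(ens.models)),
             "error": ens.errors, "similarity": ens.similarities}
        ).to_csv(out / f"tca_restarts_{name}.csv", index=False)
        summary = tca.component_summary(ens.best, g["tensor"].epoch_of_bin)
        summary.to_csv(out / f"tca_components_{name}.csv", index=False)
        types = g["tensor"].trial_labels["trial_type"].to_numpy()
        indices = g["tensor"].trial_labels["trial_index"].to_numpy()
        prof = mi_mod.mi_profile(ens, types, indices, n_bins=config.mi_bins)
        pd.DataFrame(
            {
                "component": np.arange(config.rank),
                "mi_type_bits": prof.mi_type_mean,
                "mi_type_sem": prof.mi_type_sem,
                "mi_time_bits": prof.mi_time_mean,
                "mi_time_sem": prof.mi_time_sem,
            }
        ).to_csv(out / f"mi_{name}.csv", index=False)

    # behavior
    behav_frames = []
    for name, g in groups.items():
        t = behavior_mod.behavior_table(g["sessions"])
        t.insert(0, "group", name)
        behav_frames.append(t)
    behav = pd.concat(behav_frames, ignore_index=True)
    behav.to_csv(out / "behavior.csv", index=False)
    diffs = []
    for name in groups:
        d = behavior_mod.sequence_difference_scores(behav[behav["group"] == name])
        d.insert(0, "group", name)
        diffs.append(d)
    pd.concat(diffs, ignore_index=True).to_csv(out / "behavior_differences.csv", index=False)

    make_report(out)
    return out


def make_report(out_dir: str | Path) -> list[Path]:
    """Render figure-style panels from the pipeline's CSV outputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    figures = []

    frac_files = sorted(out.glob("selectivity_fractions_*.csv"))
    if frac_files:
        fig, ax = plt.subplots(figsize=(8, 3))
        for f in frac_files:
            df = pd.read_csv(f)
            label = f.stem.replace("selectivity_fractions_", "")
            df = df.sort_values(["position", "epoch"], kind="stable")
            ax.plot(np.arange(len(df)), df["fraction"], marker="o", ms=3, label=label)
        ax.set_xlabel("(position, epoch) cell")
        ax.set_ylabel("fraction selective")
        ax.legend()
        fig.tight_layout()
        p = out / "fig_selectivity.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        figures.append(p)

    decode_file = out / "decoding.csv"
    if decode_file.exists():
        df = pd.read_csv(decode_file)
        seq = df[df["position"] > 0]
        if len(seq):
            fig, axes = plt.subplots(1, 4, figsize=(14, 3), sharey=True)
            for position, ax in zip((1, 2, 3, 4), axes):
                for name, grp in seq[seq["position"] == position].groupby("group"):
                    ax.plot(grp["epoch"], grp["accuracy"], marker="o", ms=3, label=name)
                    ax.fill_between(grp["epoch"], grp["null_lo"], grp["null_hi"], alpha=0.2)
                ax.set_title(f"P{position}")
                ax.tick_params(axis="x", rotation=60)
            axes[0].set_ylabel("S1 vs S2 accuracy")
            if axes[0].get_legend_handles_labels()[0]:
                axes[0].legend()
            fig.tight_layout()
            p = out / "fig_decoding.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            figures.append(p)
        else:
            logger.info("report: decoding stage empty, panel skipped")

    mi_files = sorted(out.glob("mi_*.csv"))
    if mi_files:
        fig, ax = plt.subplots(figsize=(6, 3))
        width = 0.8 / len(mi_files)
        for i, f in enumerate(mi_files):
            df = pd.read_csv(f)
            label = f.stem.replace("mi_", "")
            ax.bar(df["component"] + i * width, df["mi_time_bits"], width,
                   yerr=df["mi_time_sem"], label=f"{label} (time)")
        ax.set_xlabel("component")
        ax.set_ylabel("MI (bits)")
        ax.legend()
        fig.tight_layout()
        p = out / "fig_mi.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        figures.append(p)

    return figures
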