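"""Behavioral metrics per trial type and the |S1 - S2| difference scores.

Expects 01 to have run.  The two templates share accuracy profiles but the
differentiated one plants a sequence-dependent latency shift, which should
surface as larger difference scores.  Because difference scores are a
session-level statistic, each group gets a cohort of additional
behavior-only sessions (no spiking) for the rank test.
"""

import sys

import pandas as pd
from scipy.stats import mannwhitneyu

from common import GROUPS, RESULTS, SEED, SESSIONS

from odorseq.behavior import behavior_table, sequence_difference_scores
from odorseq.io import read_session
from odorseq.simulate import PopulationTemplate, make_task_schedule, simulate_behavior
from odorseq.task import SessionRecord, TaskConfig

N_BEHAVIOR_SESSIONS = 10


def _behavior_cohort(name: str, task: TaskConfig) -> list[SessionRecord]:
    template = getattr(PopulationTemplate, name)(n_units=1)
    profile = template.behavior_profile()
    out = []
    base = SEED + (0 if name == "compressed" else 10_000)
    for i in range(N_BEHAVIOR_SESSIONS):
        schedule = make_task_schedule(task, seed=base + i)
        out.append(
            SessionRecord(
                session_id=f"{name}_beh{i:02d}", task=task,
                trials=simulate_behavior(schedule, profile, task, seed=base + 500 + i),
                units=[],
            )
        )
    return out


def main() -> None:
    task = TaskConfig()
    tables = []
    diffs = []
    for name in GROUPS:
        sessions = [read_session(p) for p in sorted(SESSIONS.glob(f"{name}_s*"))]
        sessions += _behavior_cohort(name, task)
        table = behavior_table(sessions)
        table.insert(0, "group", name)
        tables.append(table)
        d = sequence_difference_scores(table)
        d.insert(0, "group", name)
        diffs.append(d)
        print(
            f"{name}: % correct {table['percent_correct'].mean():.1f}, "
            f"RT {table['reaction_time'].mean():.2f} s, "
            f"poke latency {table['poke_latency'].mean():.2f} s"
        )
    behavior = pd.concat(tables, ignore_index=True)
    behavior.to_csv(RESULTS / "07_behavior.csv", index=False)
    scores = pd.concat(diffs, ignore_index=True)
    scores.to_csv(RESULTS / "07_behavior_differences.csv", index=False)

    lat = scores[scores["metric"] == "poke_latency"]
    lat_c = lat[lat["group"] == "compressed"]["difference"]
    lat_d = lat[lat["group"] == "differentiated"]["difference"]
    if len(lat_c) >= 3 and len(lat_d) >= 3:
        _, p = mannwhitneyu(lat_d, lat_c, alternative="greater")
        print(
            f"latency |S1-S2| difference: differentiated {lat_d.mean():.3f} s vs "
            f"compressed {lat_c.mean():.3f} s (one-sided rank-sum p = {p:.3g})"
        )
    else:
        print(
            f"latency |S1-S2| difference: differentiated {lat_d.mean():.3f} s vs "
            f"compressed {lat_c.mean():.3f} s (too few sessions for a rank test)"
        )


if __name__ == "__main__":
    sys.exit(main())
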