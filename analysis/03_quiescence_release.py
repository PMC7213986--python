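#!/usr/bin/env python
"""Quiescence-release analysis: event landmarks, fates, cumulative curves.

Detects CDK4/6-on, CDK2-on and APC/C-off per cell in a mitogen-released
cohort, classifies CDK4/6^high vs ^low fates, and computes the cumulative
activation curves whose ordering shows the sequential progression
CDK4/6 -> CDK2 -> S-phase entry.  Writes results/release_*.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import ktrcycle as k
from ktrcycle.classify import classify_release
from ktrcycle.events import events_table


def main() -> None:
    cohort = k.simulate_quiescence_release(
        k.GeneratorParams(n_cells=1000, p_activate=0.54, seed=7)
    )
    records = k.detect_events(cohort)
    fates = [classify_release(tr, records[tr.cell_id]) for tr in cohort.traces]
    frac_high = np.mean([f.label == "high" for f in fates])
    true_frac = (cohort.ground_truth["true_fate"] == "high").mean()
    print(
        f"{len(cohort)} cells: {100 * frac_high:.1f}% classified CDK4/6-high "
        f"(generator truth {100 * true_frac:.1f}%)"
    )

    grid = np.arange(0.0, 24.01, 0.2)
    curves = {
        ev: k.cumulative_fraction(records, ev, grid).fraction
        for ev in ("cdk46_on", "cdk2_on", "apc_off")
    }
    dominated = np.all(curves["cdk46_on"] >= curves["cdk2_on"]) and np.all(
        curves["cdk2_on"] >= curves["apc_off"]
    )
    print(f"cumulative-curve ordering CDK4/6-on >= CDK2-on >= APC/C-off: {dominated}")

    out = Path("results")
    out.mkdir(exist_ok=True)
    events_table(records).to_csv(out / "release_events.csv", index=False)
    pd.DataFrame({"time_h": grid, **curves}).to_csv(
        out / "release_cumulative_curves.csv", index=False
    )
    pd.DataFrame(
        [{"n_cells": len(cohort), "frac_high": frac_high, "frac_high_truth": true_frac}]
    ).to_csv(out / "release_summary.csv", index=False)


if __name__ == "__main__":
    main()
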