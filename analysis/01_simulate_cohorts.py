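#!/usr/bin/env python
"""Generate the study cohorts used by the downstream analyses.

Writes the track tables (with ground-truth sidecars) under scratch/cohorts/
— these are bulky intermediates regenerated on demand; the analyses
themselves resimulate with the same seeds, so this script is primarily a
demonstration of the on-disk format.
"""

from pathlib import Path

import ktrcycle as k

OUT = Path("scratch/cohorts")

RECIPES = {
    "release": lambda: k.simulate_quiescence_release(
        k.GeneratorParams(n_cells=1000, p_activate=0.54, seed=7)
    ),
    "cycling": lambda: k.simulate_cycling(
        k.GeneratorParams(n_cells=2000, duration=14.0, seed=11)
    ),
    "sg2_inhibited": lambda: k.simulate_sg2_inhibited(200, noise_sd=0.02, seed=42),
    "stress_h2o2_like": lambda: k.apply_perturbation(
        k.simulate_quiescence_release(k.GeneratorParams(n_cells=4000, seed=1)),
        k.PerturbationSpec(kind="stress", t_add=11.0),
    ),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, make in RECIPES.items():
        cohort = make()
        path = OUT / f"{name}.csv"
        k.write_cohort(cohort, path)
        print(f"{name}: {len(cohort)} cells, {cohort.traces[0].n_frames} frames -> {path}")


if __name__ == "__main__":
    main()
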