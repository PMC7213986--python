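#!/usr/bin/env python
"""Validate the CDK2-contribution correction of the CDK4/6 reporter.

Fits the contamination fraction by regression on a synthetic S/G2 cohort
acutely treated with a CDK4/6 inhibitor, and measures the unsuppressible
raw-signal percentage when the true CDK4/6 component is fully nulled.
Writes results/correction_fit.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import ktrcycle as k


def main() -> None:
    cohort = k.simulate_sg2_inhibited(200, noise_sd=0.02, seed=42)
    fit = k.estimate_correction_factor(cohort, window=4.0)
    print(
        f"contamination fraction: f_hat = {fit.f_hat:.4f} +- {fit.stderr:.4f} "
        f"({fit.n_points} pooled frames); corrected-signal trend "
        f"{fit.flatness:.2e} activity/h post-inhibition"
    )

    flat = k.simulate_sg2_inhibited(
        100, raw_plateau=1.0, cdk2_start_range=(1.0, 1.0), cdk2_slope=0.0,
        noise_sd=0.02, seed=43,
    )
    t_add = flat.perturbation.t_add
    pre = np.mean([
        tr.cdk46_raw[(tr.times >= t_add - 2.0) & (tr.times <= t_add - 2 * tr.dt)].mean()
        for tr in flat.traces
    ])
    post = np.mean([tr.cdk46_raw[tr.times >= t_add + 2 * tr.dt].mean() for tr in flat.traces])
    residual_pct = 100.0 * post / pre
    print(f"unsuppressible raw signal: {residual_pct:.1f}% of the pre-inhibition plateau")

    out = Path("results")
    out.mkdir(exist_ok=True)
    pd.DataFrame(
        [{
            "f_hat": fit.f_hat,
            "stderr": fit.stderr,
            "n_points": fit.n_points,
            "flatness_per_h": fit.flatness,
            "residual_raw_percent": residual_pct,
        }]
    ).to_csv(out / "correction_fit.csv", index=False)


if __name__ == "__main__":
    main()
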