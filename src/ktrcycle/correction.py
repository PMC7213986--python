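"""CDK2-contribution correction of the raw CDK4/6 reporter signal.

The raw CDK4/6 reporter ratio contains an additive contribution from CDK2
activity (both kinases phosphorylate the reporter's sensor region, CDK2
with lower efficiency).  The corrected activity is

    corrected CDK4/6 = raw CDK4/6 reporter - f * CDK2 reporter,

with f ~ 0.35 estimated by linear regression of the post-CDK4/6-inhibition
raw signal on simultaneous CDK2 activity: with the CDK4/6-specific
component nulled by an acute inhibitor, whatever raw signal tracks CDK2 is
the contamination, and subtracting the fitted fraction leaves a near
constant residual signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import InsufficientDataError, ParameterError, ProtocolError
from .trace_model import Cohort, smooth_trace


@dataclass
class CorrectionFit:
    """Result of the contamination-fraction regression.

    flatness is the absolute slope (activity/hour) of the corrected signal
    versus time over the fitting window — near zero when the correction
    removes the CDK2 trend.
    """

    f_hat: float
    stderr: float
    n_points: int
    flatness: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_hat <= 1.0:
            raise ParameterError(f"f_hat out of [0,1]: {self.f_hat}")
        if self.n_points < 10:
            raise ParameterError("CorrectionFit requires n_points >= 10")


def corrected_cdk46(
    cdk46_raw: np.ndarray, cdk2: np.ndarray, f: float
) -> np.ndarray:
    """Elementwise ``raw - f * cdk2``; NaN (masked) samples propagate."""
    cdk46_raw = np.asarray(cdk46_raw, dtype=float)
    cdk2 = np.asarray(cdk2, dtype=float)
    if cdk46_raw.shape != cdk2.shape:
        raise ParameterError(
            f"series length mismatch: {cdk46_raw.shape} vs {cdk2.shape}"
        )
    if not 0.0 <= f <= 1.0:
        raise ParameterError(f"correction fraction must be in [0,1], got {f}")
    return cdk46_raw - f * cdk2


def estimate_correction_factor(
    cohort: Cohort,
    t_add: float | None = None,
    window: float = 4.0,
    smooth_window: int = 3,
) -> CorrectionFit:
    """Estimate the CDK2-contamination fraction from an inhibited cohort.

    Pools all (cell, frame) points within ``[t_add + 2 frames,
    t_add + window]`` from cells whose APC/C degron was already rising
    before ``t_add`` (S/G2 cells, where CDK2 activity is high and the
    contamination dominates the post-inhibition signal), and fits

        raw CDK4/6 ~ intercept + f * CDK2

    by ordinary least squares.  The first two frames after ``t_add`` are
    excluded to let the inhibition equilibrate.  A free intercept absorbs
    any residual reporter floor.
    """
    if cohort.perturbation is None or cohort.perturbation.kind != "cdk46_inhibitor":
        raise ProtocolError(
            "estimate_correction_factor requires a cohort perturbed with a "
            "CDK4/6 inhibitor"
        )
    if t_add is None:
        t_add = cohort.perturbation.t_add
    from .events import detect_apc_off  # deferred: events also uses correction

    raw_pts, cdk2_pts, time_pts = [], [], []
    for tr in cohort.traces:
        sm_tr = smooth_trace(tr, smooth_window)
        t_apc = detect_apc_off(sm_tr.apc_degron, sm_tr.times, missing=sm_tr.missing)
        if t_apc is None or t_apc >= t_add:
            continue  # G1 cell at the time of inhibition: excluded
        lo = t_add + 2 * tr.dt
        sel = (tr.times >= lo) & (tr.times <= t_add + window) & ~tr.missing
        raw_pts.append(tr.cdk46_raw[sel])
        cdk2_pts.append(tr.cdk2[sel])
        time_pts.append(tr.times[sel])
    if not raw_pts:
        raise InsufficientDataError("no S/G2 cells with degron rising before t_add")
    raw = np.concatenate(raw_pts)
    cdk2 = np.concatenate(cdk2_pts)
    tt = np.concatenate(time_pts)
    if raw.size < 10:
        raise InsufficientDataError(
            f"only {raw.size} eligible (cell, frame) points; need >= 10"
        )

    fit = sm.OLS(raw, sm.add_constant(cdk2)).fit()
    f_hat = float(np.clip(fit.params[1], 0.0, 1.0))
    corrected = corrected_cdk46(raw, cdk2, f_hat)
    trend = sm.OLS(corrected, sm.add_constant(tt)).fit()
    return CorrectionFit(
        f_hat=f_hat,
        stderr=float(fit.bse[1]),
        n_points=int(raw.size),
        flatness=float(abs(trend.params[1])),
    )
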