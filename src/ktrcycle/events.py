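"""Per-cell activation/inactivation landmark detection.

Three landmarks are detected on each (smoothed) trace:

* CDK4/6-on — corrected CDK4/6 activity first exceeds its threshold (0.7)
  and stays above it for a persistence horizon (2 h);
* CDK2-on — CDK2 activity first exceeds 0.76 with 1 h persistence;
* APC/C-off — the APC/C-degron intensity first rises above its estimated
  baseline band and keeps increasing for 1 h, marking the G1/S transition.

Onsets are threshold crossings with persistence rather than derivative
change points: the fate definitions downstream are threshold-based, and the
persistence horizon guards against noise excursions.  Detected times lie on
the trace's time grid (first above-threshold frame, not interpolated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correction import corrected_cdk46
from .errors import InsufficientDataError, ParameterError
from .trace_model import (
    DEFAULT_THRESHOLDS,
    Cohort,
    Thresholds,
    Trace,
    smooth_series,
)

__all__ = [
    "EventRecord",
    "detect_onset",
    "detect_apc_off",
    "detect_events",
    "phase_at_time",
    "events_table",
]


@dataclass
class EventRecord:
    """Detected landmark times for one cell (hours; None if not detected)."""

    cell_id: str
    t_cdk46_on: float | None = None
    t_cdk2_on: float | None = None
    t_apc_off: float | None = None
    t_anaphase_ref: float | None = None


def detect_onset(
    series: np.ndarray,
    times: np.ndarray,
    theta: float,
    persistence: float,
    missing: np.ndarray | None = None,
) -> float | None:
    """First time the series exceeds ``theta`` and stays above it.

    Returns the first unmasked time ``t`` such that the series exceeds
    ``theta`` at ``t`` and at every unmasked sample in
    ``[t, t + persistence]`` (the window truncates at the trace end), or
    None if no such time exists.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if missing is None:
        missing = np.isnan(series)
    else:
        missing = np.asarray(missing, dtype=bool) | np.isnan(series)
    if times.size >= 2:
        dt = times[1] - times[0]
        if persistence < dt - 1e-12:
            raise ParameterError(f"persistence {persistence} smaller than dt {dt}")
    if persistence > times[-1] - times[0] + 1e-12:
        raise ParameterError("persistence exceeds the trace time span")

    above = np.where(missing, False, series > theta)
    ok = ~missing
    for i in np.flatnonzero(above & ok):
        in_win = (times >= times[i]) & (times <= times[i] + persistence + 1e-12)
        if np.all(above[in_win & ok]):
            return float(times[i])
    return None


def detect_apc_off(
    degron: np.ndarray,
    times: np.ndarray,
    k_sigma: float = 3.0,
    missing: np.ndarray | None = None,
    min_baseline: int = 10,
    rise_window: float = 1.0,
) -> float | None:
    """Onset of APC/C-degron accumulation (G1/S transition).

    Scans candidate onsets left to right; at each candidate the baseline
    mean/sd are estimated from all preceding unmasked samples (expanding
    from the start).  The onset is the first time the degron exceeds
    ``baseline + k_sigma * sd`` and the signal keeps rising over the
    following ``rise_window`` hours: nondecreasing within a noise
    allowance, the excursion above baseline at least doubling by the end
    of the window, and the signal never returning into the baseline band
    afterwards (degron accumulation is monotone once APC/C is off, so a
    genuine onset never relapses).  Returns None if the degron never
    rises.
    """
    degron = np.asarray(degron, dtype=float)
    times = np.asarray(times, dtype=float)
    if missing is None:
        missing = np.isnan(degron)
    else:
        missing = np.asarray(missing, dtype=bool) | np.isnan(degron)
    ok = ~missing
    if ok.sum() < 10:
        raise InsufficientDataError("detect_apc_off needs >= 10 unmasked samples")

    eps = 1e-9
    idx_ok = np.flatnonzero(ok)
    vals_ok = degron[idx_ok]
    # expanding baseline mean/sd via cumulative sums
    csum = np.cumsum(vals_ok)
    csum2 = np.cumsum(vals_ok**2)
    for pos in range(min_baseline, idx_ok.size):
        i = idx_ok[pos]
        mu = csum[pos - 1] / pos
        var = max(csum2[pos - 1] / pos - mu**2, 0.0)
        sd = float(np.sqrt(var))
        if degron[i] <= mu + k_sigma * sd + eps:
            continue
        if times[i] + rise_window > times[-1] + 1e-9:
            break  # not enough follow-up left to confirm a sustained rise
        win = ok & (times >= times[i]) & (times <= times[i] + rise_window + 1e-12)
        vals = degron[win]
        if vals.size >= 2:
            slack = max(2.0 * sd, eps)
            if np.any(np.diff(vals) < -slack):
                continue
            # a true rise keeps growing: the excursion above baseline must
            # at least double across the confirmation window
            if vals[-1] < vals[0] or (vals[-1] - mu) < 2.0 * (degron[i] - mu):
                continue
        # no relapse below the baseline band for the rest of the trace
        tail = degron[idx_ok[pos:]]
        if np.any(tail <= mu + k_sigma * sd + eps):
            continue
        return float(times[i])
    return None


def _slice_from(trace: Trace, t0: float | None) -> slice:
    if t0 is None:
        return slice(0, trace.n_frames)
    start = int(np.searchsorted(trace.times, t0 - 1e-9))
    return slice(start, trace.n_frames)


def detect_events(
    cohort: Cohort,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    smooth_window: int = 3,
) -> dict[str, EventRecord]:
    """Detect all three landmarks for every trace in a cohort.

    Traces are median-smoothed before detection.  For cycling cohorts
    (anaphase annotations present) detection is restricted to the
    post-anaphase segment and the first anaphase becomes the alignment
    anchor ``t_anaphase_ref``.
    """
    records: dict[str, EventRecord] = {}
    for tr in cohort.traces:
        ana = float(tr.anaphase_times[0]) if tr.anaphase_times.size else None
        sl = _slice_from(tr, ana)
        raw = smooth_series(tr.cdk46_raw, tr.missing, smooth_window)
        cdk2 = smooth_series(tr.cdk2, tr.missing, smooth_window)
        degron = smooth_series(tr.apc_degron, tr.missing, smooth_window)
        corr = corrected_cdk46(raw, cdk2, thresholds.f_correction)
        t = tr.times[sl]
        m = tr.missing[sl]

        span = t[-1] - t[0]
        p46 = min(thresholds.persistence_window, span)
        p2 = min(thresholds.persistence_window_cdk2, span)
        t46 = detect_onset(corr[sl], t, thresholds.theta_cdk46, p46, missing=m)
        t2 = detect_onset(cdk2[sl], t, thresholds.theta_cdk2, p2, missing=m)
        try:
            tapc = detect_apc_off(degron[sl], t, missing=m)
        except InsufficientDataError:
            tapc = None
        records[tr.cell_id] = EventRecord(
            cell_id=tr.cell_id,
            t_cdk46_on=t46,
            t_cdk2_on=t2,
            t_apc_off=tapc,
            t_anaphase_ref=ana,
        )
    return records


def phase_at_time(record: EventRecord, trace: Trace, t: float) -> str:
    """Coarse cell-cycle phase at time ``t``.

    ``post_G1S`` iff ``t >= t_apc_off``; ``G1_active`` iff CDK4/6 switched
    on by ``t`` and the G1/S transition has not yet happened; otherwise
    ``pre_activation``.
    """
    if t < trace.times[0] - 1e-9 or t > trace.times[-1] + 1e-9:
        raise ParameterError(f"t={t} outside the trace span of {trace.cell_id}")
    if record.t_apc_off is not None and t >= record.t_apc_off:
        return "post_G1S"
    if record.t_cdk46_on is not None and record.t_cdk46_on <= t:
        return "G1_active"
    return "pre_activation"


def events_table(records: dict[str, EventRecord]) -> pd.DataFrame:
    """Event records as a tidy table (CSV-ready)."""
    return pd.DataFrame(
        {
            "cell_id": list(records),
            "t_cdk46_on": [r.t_cdk46_on for r in records.values()],
            "t_cdk2_on": [r.t_cdk2_on for r in records.values()],
            "t_apc_off": [r.t_apc_off for r in records.values()],
            "t_anaphase_ref": [r.t_anaphase_ref for r in records.values()],
        }
    )
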