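"""Population-level statistics over cohorts of reporter traces.

Event alignment, cumulative activation curves, bootstrap medians, binned
stress dose-response, phase-plane trajectories and live-fixed Rb-phospho
fraction matching — the figure-level computations of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import FateLabel
from .correction import corrected_cdk46
from .errors import FormatError, InsufficientDataError, ParameterError, ProtocolError
from .events import EventRecord
from .trace_model import DEFAULT_THRESHOLDS, Cohort, Thresholds, smooth_trace

__all__ = [
    "AlignedMatrix",
    "CumulativeCurve",
    "align_to_event",
    "cumulative_fraction",
    "median_with_ci",
    "stress_exit_by_cdk2_bin",
    "phase_trajectory",
    "fraction_rb_phospho_by_class",
    "classify_terminal_cdk46",
]

_EVENT_ATTRS = {
    "cdk46_on": "t_cdk46_on",
    "cdk2_on": "t_cdk2_on",
    "apc_off": "t_apc_off",
}


@dataclass
class AlignedMatrix:
    """Cells x timepoints activity matrix on a common event-relative grid."""

    relative_times: np.ndarray
    values: np.ndarray  # NaN where a cell has no sample at that relative time
    anchor_kind: str
    cell_ids: list[str]
    n_dropped: int = 0

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class CumulativeCurve:
    """Fraction of cells having reached an event by each time."""

    times: np.ndarray
    fraction: np.ndarray
    n_total: int
    event_name: str

    def __post_init__(self) -> None:
        f = np.asarray(self.fraction, dtype=float)
        if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
            raise ParameterError("cumulative fractions must lie in [0,1]")
        if np.any(np.diff(f) < -1e-12):
            raise ParameterError("cumulative fraction must be nondecreasing")


def _channel_series(trace, channel: str, thresholds: Thresholds) -> np.ndarray:
    if channel == "cdk46_corrected":
        return corrected_cdk46(trace.cdk46_raw, trace.cdk2, thresholds.f_correction)
    if channel == "cdk46_raw":
        return trace.cdk46_raw
    if channel == "cdk2":
        return trace.cdk2
    if channel == "apc_degron":
        return trace.apc_degron
    raise ParameterError(f"unknown channel {channel!r}")


def align_to_event(
    cohort: Cohort,
    records: dict[str, EventRecord],
    anchor_kind: str,
    channel: str = "cdk46_corrected",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    smooth_window: int = 1,
) -> AlignedMatrix:
    """Shift each cell's series so its anchor maps to relative time 0.

    ``anchor_kind`` is one of ``mitogen_release`` (t = 0), ``anaphase`` or
    ``cdk2_on``.  Cells lacking the anchor are dropped and counted in
    ``n_dropped``.  The common grid spans the union of the shifted spans.
    """
    rows, ids, anchors = [], [], []
    n_dropped = 0
    for tr in cohort.traces:
        rec = records.get(tr.cell_id)
        if anchor_kind == "mitogen_release":
            anchor = 0.0
        elif anchor_kind == "anaphase":
            anchor = (
                rec.t_anaphase_ref
                if rec is not None and rec.t_anaphase_ref is not None
                else (float(tr.anaphase_times[0]) if tr.anaphase_times.size else None)
            )
        elif anchor_kind == "cdk2_on":
            anchor = rec.t_cdk2_on if rec is not None else None
        else:
            raise ParameterError(f"unknown anchor_kind {anchor_kind!r}")
        if anchor is None:
            n_dropped += 1
            continue
        st = smooth_trace(tr, smooth_window) if smooth_window > 1 else tr
        series = _channel_series(st, channel, thresholds).copy()
        series[tr.missing] = np.nan
        rows.append((tr.times - anchor, series, tr.dt))
        ids.append(tr.cell_id)
    if not rows:
        raise InsufficientDataError(f"no cell has the anchor {anchor_kind!r}")

    dt = rows[0][2]
    lo = min(r[0][0] for r in rows)
    hi = max(r[0][-1] for r in rows)
    rel = np.round(np.arange(np.round(lo / dt), np.round(hi / dt) + 1)) * dt
    values = np.full((len(rows), rel.size), np.nan)
    for k, (t_rel, series, _) in enumerate(rows):
        j0 = int(np.round((t_rel[0] - rel[0]) / dt))
        values[k, j0 : j0 + series.size] = series
    return AlignedMatrix(rel, values, anchor_kind, ids, n_dropped)


def cumulative_fraction(
    records: dict[str, EventRecord],
    event_name: str,
    times: np.ndarray,
    anchor_kind: str = "t_zero",
) -> CumulativeCurve:
    """Fraction of all cells whose event happened by each time.

    The denominator is every tracked cell; cells without the event are
    right-censored and never counted.  With ``anchor_kind='anaphase'``
    event times are taken relative to each cell's anaphase.
    """
    if event_name not in _EVENT_ATTRS:
        raise ParameterError(f"unknown event_name {event_name!r}")
    if not records:
        raise InsufficientDataError("no event records")
    attr = _EVENT_ATTRS[event_name]
    times = np.asarray(times, dtype=float)
    evts = []
    for rec in records.values():
        t = getattr(rec, attr)
        if t is None:
            evts.append(np.inf)
        elif anchor_kind == "anaphase":
            if rec.t_anaphase_ref is None:
                evts.append(np.inf)
            else:
                evts.append(t - rec.t_anaphase_ref)
        else:
            evts.append(t)
    evts = np.asarray(evts)
    frac = (evts[None, :] <= times[:, None]).mean(axis=1)
    return CumulativeCurve(times, frac, n_total=len(records), event_name=event_name)


def median_with_ci(
    aligned: AlignedMatrix, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Per-timepoint median with a bootstrap 95% confidence band.

    Bootstraps over cells (rows), not frames: samples within a cell are
    dependent.  Columns with no unmasked cells yield NaN.
    """
    if aligned.n_cells < 10:
        raise InsufficientDataError("median_with_ci needs >= 10 cells")
    vals = aligned.values
    rng = np.random.default_rng(seed)
    med = np.nanmedian(vals, axis=0)
    idx = rng.integers(0, vals.shape[0], size=(n_boot, vals.shape[0]))
    boots = np.nanmedian(vals[idx, :], axis=1)  # n_boot x n_times
    lo = np.nanpercentile(boots, 2.5, axis=0)
    hi = np.nanpercentile(boots, 97.5, axis=0)
    return pd.DataFrame(
        {
            "relative_time": aligned.relative_times,
            "median": med,
            "ci_lo": lo,
            "ci_hi": hi,
            "n_cells": np.sum(np.isfinite(vals), axis=0),
        }
    )


def stress_exit_by_cdk2_bin(
    cohort: Cohort,
    records: dict[str, EventRecord],
    fates: dict[str, FateLabel],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    bin_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fraction of cells losing CDK2 activity, binned by CDK2 at stress.

    ``fates`` holds stress-outcome labels for the eligible cells; each is
    binned by its pre-stress-window CDK2 activity.
    Default bins are 0.1 wide from the CDK2 activation threshold up to 1.2
    plus an open top bin.  Bins with fewer than 5 cells are flagged
    low-confidence.
    """
    if cohort.perturbation is None or cohort.perturbation.kind != "stress":
        raise ProtocolError("cohort has no stress perturbation")
    if not fates:
        raise InsufficientDataError("empty eligible set")
    if bin_edges is None:
        bin_edges = np.concatenate(
            [np.arange(thresholds.theta_cdk2, 1.2, 0.1), [1.2, np.inf]]
        )
    bin_edges = np.asarray(bin_edges, dtype=float)
    t_add = cohort.perturbation.t_add

    from .classify import activity_at

    cdk2_at_add, is_low = [], []
    for tr in cohort.traces:
        fate = fates.get(tr.cell_id)
        if fate is None:
            continue
        c = activity_at(tr.cdk2, tr, t_add)
        if not np.isfinite(c):
            continue
        cdk2_at_add.append(c)
        is_low.append(fate.label == "low")
    cdk2_at_add = np.asarray(cdk2_at_add)
    is_low = np.asarray(is_low)

    rows = []
    which = np.digitize(cdk2_at_add, bin_edges) - 1
    for b in range(bin_edges.size - 1):
        sel = which == b
        n = int(sel.sum())
        rows.append(
            {
                "bin_lo": bin_edges[b],
                "bin_hi": bin_edges[b + 1],
                "bin_center": (
                    (bin_edges[b] + bin_edges[b + 1]) / 2
                    if np.isfinite(bin_edges[b + 1])
                    else bin_edges[b]
                ),
                "n": n,
                "cdk2_mean": float(cdk2_at_add[sel].mean()) if n else np.nan,
                "fraction_low": float(is_low[sel].mean()) if n else np.nan,
                "low_confidence": n < 5,
            }
        )
    return pd.DataFrame(rows)


def phase_trajectory(
    cohort: Cohort,
    cell_ids: list[str],
    t_start: float,
    t_end: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    smooth_window: int = 3,
) -> pd.DataFrame:
    """Group-median (corrected CDK4/6, CDK2) trajectory over [t_start, t_end].

    Suitable for phase-plane plots of CDK2 versus CDK4/6 activity with time
    as the parameter.  Requires >= 10 cells on a shared time grid.
    """
    group = [tr for tr in cohort.traces if tr.cell_id in set(cell_ids)]
    if len(group) < 10:
        raise InsufficientDataError(f"phase_trajectory needs >= 10 cells, got {len(group)}")
    t0 = group[0].times
    for tr in group[1:]:
        if tr.times.size != t0.size or not np.allclose(tr.times, t0):
            raise FormatError(
                "phase_trajectory requires all group traces on one time grid"
            )
    sel = (t0 >= t_start - 1e-9) & (t0 <= t_end + 1e-9)
    c46 = np.full((len(group), sel.sum()), np.nan)
    c2 = np.full_like(c46, np.nan)
    for k, tr in enumerate(group):
        st = smooth_trace(tr, smooth_window)
        corr = corrected_cdk46(st.cdk46_raw, st.cdk2, thresholds.f_correction)
        c46[k] = corr[sel]
        c2[k] = st.cdk2[sel]
    return pd.DataFrame(
        {
            "time": t0[sel],
            "cdk46_corrected_median": np.nanmedian(c46, axis=0),
            "cdk2_median": np.nanmedian(c2, axis=0),
            "n_cells": np.sum(np.isfinite(c46), axis=0),
        }
    )


def classify_terminal_cdk46(
    cohort: Cohort,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    smooth_window: int = 3,
) -> dict[str, str]:
    """'high'/'low' per cell from corrected CDK4/6 at the terminal frame.

    The live-cell side of live-fixed matching: the activity state at the
    moment of fixation.
    """
    out: dict[str, str] = {}
    for tr in cohort.traces:
        st = smooth_trace(tr, smooth_window)
        corr = corrected_cdk46(st.cdk46_raw, st.cdk2, thresholds.f_correction)
        ok = np.flatnonzero(~tr.missing & np.isfinite(corr))
        if ok.size == 0:
            continue
        out[tr.cell_id] = "high" if corr[ok[-1]] > thresholds.theta_cdk46 else "low"
    return out


def fraction_rb_phospho_by_class(
    cohort: Cohort,
    fates: dict[str, str],
    rb_threshold: float,
    time_bins_post_anaphase: np.ndarray,
) -> pd.DataFrame:
    """Fraction of Rb-phospho-positive cells per CDK4/6 class and time bin.

    Requires ``cohort.fixed_cells`` with per-cell terminal ``rb_phospho``
    intensities and ``time_since_anaphase`` at fixation.  Rows are emitted
    for the 'high' and 'low' classes and for 'all' cells pooled.
    """
    if cohort.fixed_cells is None:
        raise ProtocolError("cohort has no fixed-cell (rb_phospho) table")
    fx = cohort.fixed_cells
    edges = np.asarray(time_bins_post_anaphase, dtype=float)
    rows = []
    tb = fx["time_since_anaphase"].to_numpy()
    rb_pos = fx["rb_phospho"].to_numpy() > rb_threshold
    cls = np.array([fates.get(c, "unknown") for c in fx["cell_id"].astype(str)])
    for klass in ("high", "low", "all"):
        in_class = np.ones(len(fx), dtype=bool) if klass == "all" else cls == klass
        for b in range(edges.size - 1):
            sel = in_class & (tb >= edges[b]) & (tb < edges[b + 1])
            n = int(sel.sum())
            rows.append(
                {
                    "class": klass,
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "n": n,
                    "fraction_phospho": float(rb_pos[sel].mean()) if n else np.nan,
                }
            )
    return pd.DataFrame(rows)
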