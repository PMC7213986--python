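"""Domain types for single-cell reporter traces and cohorts, plus CSV I/O.

A :class:`Trace` holds one cell's sampled kinase-translocation-reporter (KTR)
time series on a uniform time grid: the raw CDK4/6 reporter
cytoplasmic:nuclear ratio, the CDK2 reporter ratio, and the APC/C-degron
nuclear intensity, together with anaphase annotations and a missing-sample
mask.  A :class:`Cohort` is a set of traces sharing an experimental protocol
(quiescence release or asynchronous cycling), optionally with a perturbation
and — for synthetic cohorts — generator ground truth.

On disk a cohort is a long (tidy) CSV track table, one row per cell per
frame, with metadata in a small YAML sidecar and ground truth in a second
CSV sidecar.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ParameterError, SchemaError

#: Default frame interval in hours (12-minute frames).
DEFAULT_DT = 0.2

#: Canonical column names of the on-disk track table.
TRACK_COLUMNS = (
    "cell_id",
    "time_h",
    "cdk46_raw",
    "cdk2",
    "apc_degron",
    "is_anaphase",
    "treatment",
    "dose",
)
REQUIRED_COLUMNS = TRACK_COLUMNS[:6]

GROUND_TRUTH_COLUMNS = (
    "cell_id",
    "true_fate",
    "true_t_cdk46_on",
    "true_t_cdk2_on",
    "true_t_apc_off",
    "responded_to_stress",
)

_GRID_RTOL = 1e-6


@dataclass
class Thresholds:
    """Fixed analysis constants.

    Attributes
    ----------
    theta_cdk46 : float
        Corrected CDK4/6 activity threshold separating active from inactive
        cells (default 0.7).
    theta_cdk2 : float
        CDK2 activity threshold for CDK2 activation (default 0.76).
    theta_cdk2_sphase : float
        CDK2 activity level characteristic of S phase (default 1.0).
    f_correction : float
        Fraction of the CDK2 reporter signal subtracted from the raw CDK4/6
        reporter signal to obtain corrected CDK4/6 activity (default 0.35).
    t_check_early, t_check_late : float
        Hours after anaphase at which post-mitotic fates are scored
        (defaults 2 and 10).
    persistence_window : float
        Hours a signal must stay above threshold for an onset call on the
        CDK4/6 channel (default 2).
    persistence_window_cdk2 : float
        Persistence horizon for the CDK2 channel (default 1).
    t_perturb : float
        Hours after mitogen release at which acute perturbations are added
        (default 11).
    t_outcome : float
        Hours at which the stress outcome is scored (default 15).
    """

    theta_cdk46: float = 0.7
    theta_cdk2: float = 0.76
    theta_cdk2_sphase: float = 1.0
    f_correction: float = 0.35
    t_check_early: float = 2.0
    t_check_late: float = 10.0
    persistence_window: float = 2.0
    persistence_window_cdk2: float = 1.0
    t_perturb: float = 11.0
    t_outcome: float = 15.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (np.isfinite(v) and v > 0):
                raise ParameterError(f"{f.name} must be strictly positive, got {v!r}")
        if not self.t_check_early < self.t_check_late:
            raise ParameterError("t_check_early must be < t_check_late")
        if not self.t_perturb < self.t_outcome:
            raise ParameterError("t_perturb must be < t_outcome")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class Trace:
    """One cell's reporter time series on a uniform grid.

    ``missing`` marks samples that were lost (segmentation/tracking gaps);
    masked samples carry NaN in the activity arrays and are skipped by all
    downstream detectors.
    """

    cell_id: str
    times: np.ndarray
    cdk46_raw: np.ndarray
    cdk2: np.ndarray
    apc_degron: np.ndarray
    anaphase_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    missing: np.ndarray | None = None
    treatment: str = "none"
    dose: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cdk46_raw = np.asarray(self.cdk46_raw, dtype=float)
        self.cdk2 = np.asarray(self.cdk2, dtype=float)
        self.apc_degron = np.asarray(self.apc_degron, dtype=float)
        self.anaphase_times = np.asarray(self.anaphase_times, dtype=float)
        n = self.times.size
        for name in ("cdk46_raw", "cdk2", "apc_degron"):
            if getattr(self, name).size != n:
                raise FormatError(
                    f"cell {self.cell_id}: series {name!r} has length "
                    f"{getattr(self, name).size}, expected {n}"
                )
        if self.missing is None:
            self.missing = np.zeros(n, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.size != n:
                raise FormatError(f"cell {self.cell_id}: missing-mask length mismatch")
        if n >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise FormatError(f"cell {self.cell_id}: times not strictly increasing")
            dt = steps[0]
            if not np.allclose(steps, dt, rtol=_GRID_RTOL, atol=0.0):
                raise FormatError(f"cell {self.cell_id}: non-uniform time grid")
        if self.anaphase_times.size:
            if np.any(np.diff(self.anaphase_times) <= 0):
                raise FormatError(f"cell {self.cell_id}: anaphase_times not increasing")
            lo, hi = self.times[0], self.times[-1]
            if self.anaphase_times[0] < lo - 1e-9 or self.anaphase_times[-1] > hi + 1e-9:
                raise FormatError(
                    f"cell {self.cell_id}: anaphase time outside the trace span"
                )

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            return DEFAULT_DT
        return float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    def corrected_cdk46(self, f: float) -> np.ndarray:
        """Raw CDK4/6 reporter minus ``f`` times the CDK2 reporter."""
        return self.cdk46_raw - f * self.cdk2

    def index_at(self, t: float) -> int:
        """Grid index nearest to time ``t`` (must lie within the span)."""
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise ParameterError(f"time {t} outside trace span of cell {self.cell_id}")
        return int(np.argmin(np.abs(self.times - t)))

    def value_at(self, series: np.ndarray, t: float) -> float:
        """Series value at the grid point nearest ``t`` (NaN if masked)."""
        return float(series[self.index_at(t)])


@dataclass
class Cohort:
    """A collection of traces plus experiment metadata.

    ``ground_truth`` (synthetic cohorts only) is a DataFrame with one row
    per cell: true fate, true event times, stress response.  ``fixed_cells``
    optionally carries a matched fixed-cell readout (terminal Rb pS807/811
    intensity per cell), emulating live-fixed experiments.  ``latent`` holds
    the generator's noise-free per-cell kinetics and is never persisted.
    """

    traces: list[Trace]
    protocol: str = "quiescence_release"
    perturbation: Any = None
    t_zero_meaning: str = "mitogen release"
    ground_truth: pd.DataFrame | None = None
    fixed_cells: pd.DataFrame | None = None
    seed: int | None = None
    latent: list | None = None

    def __post_init__(self) -> None:
        if self.protocol not in ("quiescence_release", "cycling"):
            raise ParameterError(f"unknown protocol {self.protocol!r}")
        ids = [t.cell_id for t in self.traces]
        if len(set(ids)) != len(ids):
            raise FormatError("cell_ids not unique within cohort")
        if self.ground_truth is not None and len(self.traces):
            gt_ids = set(self.ground_truth["cell_id"].astype(str))
            if gt_ids != set(ids):
                raise FormatError("ground_truth cell_ids do not match traces")

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def cell_ids(self) -> list[str]:
        return [t.cell_id for t in self.traces]

    def trace(self, cell_id: str) -> Trace:
        for t in self.traces:
            if t.cell_id == cell_id:
                return t
        raise KeyError(cell_id)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _sidecar_paths(path: Path) -> tuple[Path, Path, Path]:
    stem = path.with_suffix("")
    return (
        stem.parent / (stem.name + "_truth.csv"),
        stem.parent / (stem.name + "_meta.yaml"),
        stem.parent / (stem.name + "_fixed.csv"),
    )


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> Cohort:
    """Read a long-format track table into a :class:`Cohort`.

    Parameters
    ----------
    path : path to the track CSV.
    schema : optional map from canonical column names
        (``cell_id, time_h, cdk46_raw, cdk2, apc_degron, is_anaphase, ...``)
        to the file's column names.

    Rows with missing activity values become masked samples.  Metadata and
    ground truth are read from sidecar files written by :func:`write_cohort`
    when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in TRACK_COLUMNS if schema.get(c, c) in df.columns}
    df = df.rename(columns=rename)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path.name}")
    if "treatment" not in df.columns:
        df["treatment"] = "none"
    if "dose" not in df.columns:
        df["dose"] = 0.0

    df = df.sort_values(["cell_id", "time_h"], kind="mergesort")
    if df.duplicated(subset=["cell_id", "time_h"]).any():
        dup = df[df.duplicated(subset=["cell_id", "time_h"])].iloc[0]
        raise FormatError(
            f"duplicate (cell, frame) row: cell {dup['cell_id']!r} at t={dup['time_h']}"
        )

    traces: list[Trace] = []
    for cell_id, g in df.groupby("cell_id", sort=True):
        times = g["time_h"].to_numpy(dtype=float)
        if times.size >= 2:
            steps = np.diff(times)
            if np.any(steps <= 0) or not np.allclose(
                steps, steps[0], rtol=_GRID_RTOL, atol=0.0
            ):
                raise FormatError(f"cell {cell_id!r}: non-uniform time grid in file")
        activity = g[["cdk46_raw", "cdk2", "apc_degron"]].to_numpy(dtype=float)
        mask = np.isnan(activity).any(axis=1)
        ana = times[g["is_anaphase"].astype(bool).to_numpy()]
        traces.append(
            Trace(
                cell_id=str(cell_id),
                times=times,
                cdk46_raw=activity[:, 0],
                cdk2=activity[:, 1],
                apc_degron=activity[:, 2],
                anaphase_times=ana,
                missing=mask,
                treatment=str(g["treatment"].iloc[0]),
                dose=float(g["dose"].iloc[0]),
            )
        )

    truth_path, meta_path, fixed_path = _sidecar_paths(path)
    ground_truth = pd.read_csv(truth_path) if truth_path.exists() else None
    if ground_truth is not None:
        ground_truth["cell_id"] = ground_truth["cell_id"].astype(str)
    fixed_cells = pd.read_csv(fixed_path) if fixed_path.exists() else None
    if fixed_cells is not None:
        fixed_cells["cell_id"] = fixed_cells["cell_id"].astype(str)

    kwargs: dict[str, Any] = {}
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text()) or {}
        kwargs["protocol"] = meta.get("protocol", "quiescence_release")
        kwargs["t_zero_meaning"] = meta.get("t_zero_meaning", "mitogen release")
        kwargs["seed"] = meta.get("seed")
        pert = meta.get("perturbation")
        if pert is not None:
            from .synth_cohort import PerturbationSpec

            kwargs["perturbation"] = PerturbationSpec(**pert)
    return Cohort(
        traces=traces, ground_truth=ground_truth, fixed_cells=fixed_cells, **kwargs
    )


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as a track CSV plus sidecar metadata/ground-truth files.

    ``read_cohort(write_cohort(c))`` reproduces every unmasked value up to
    floating-point round-trip; masked samples are stored as empty fields.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in cohort.traces:
        ana = np.zeros(tr.n_frames, dtype=bool)
        for t_a in tr.anaphase_times:
            ana[tr.index_at(float(t_a))] = True
        block = pd.DataFrame(
            {
                "cell_id": tr.cell_id,
                "time_h": tr.times,
                "cdk46_raw": np.where(tr.missing, np.nan, tr.cdk46_raw),
                "cdk2": np.where(tr.missing, np.nan, tr.cdk2),
                "apc_degron": np.where(tr.missing, np.nan, tr.apc_degron),
                "is_anaphase": ana,
                "treatment": tr.treatment,
                "dose": tr.dose,
            }
        )
        rows.append(block)
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=list(TRACK_COLUMNS))
    )
    table.to_csv(path, index=False, float_format="%.9g")

    truth_path, meta_path, fixed_path = _sidecar_paths(path)
    if cohort.ground_truth is not None:
        cohort.ground_truth.to_csv(truth_path, index=False, float_format="%.9g")
    if cohort.fixed_cells is not None:
        cohort.fixed_cells.to_csv(fixed_path, index=False, float_format="%.9g")
    meta: dict[str, Any] = {
        "protocol": cohort.protocol,
        "t_zero_meaning": cohort.t_zero_meaning,
        "seed": cohort.seed,
    }
    if cohort.perturbation is not None:
        meta["perturbation"] = dataclasses.asdict(cohort.perturbation)
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def smooth_series(
    values: np.ndarray, missing: np.ndarray, window: int
) -> np.ndarray:
    """Running median with nearest-edge padding, skipping masked samples.

    Masked samples stay NaN in the output; they contribute nothing to their
    neighbours' windows.
    """
    if window % 2 == 0:
        raise ParameterError(f"smoothing window must be odd, got {window}")
    if window < 1 or window > values.size:
        raise ParameterError(
            f"smoothing window {window} outside [1, {values.size}]"
        )
    if window == 1:
        return values.copy()
    half = window // 2
    n = values.size
    padded = np.concatenate(
        [np.repeat(values[0], half), values, np.repeat(values[-1], half)]
    )
    windows = np.lib.stride_tricks.sliding_window_view(padded, window)
    if not missing.any():
        out = np.median(windows, axis=1)
    else:
        pad_miss = np.concatenate(
            [np.repeat(missing[0], half), missing, np.repeat(missing[-1], half)]
        )
        wmiss = np.lib.stride_tricks.sliding_window_view(pad_miss, window)
        masked = np.where(wmiss, np.nan, windows)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            out = np.nanmedian(masked, axis=1)
        out[missing] = np.nan
    return out


def smooth_trace(trace: Trace, window: int = 3) -> Trace:
    """Running-median-filtered copy of a trace (all three channels).

    ``window`` must be odd; ``window=1`` returns an identical copy.  Masked
    samples are excluded from each window and remain masked.
    """
    return Trace(
        cell_id=trace.cell_id,
        times=trace.times.copy(),
        cdk46_raw=smooth_series(trace.cdk46_raw, trace.missing, window),
        cdk2=smooth_series(trace.cdk2, trace.missing, window),
        apc_degron=smooth_series(trace.apc_degron, trace.missing, window),
        anaphase_times=trace.anaphase_times.copy(),
        missing=trace.missing.copy(),
        treatment=trace.treatment,
        dose=trace.dose,
    )
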