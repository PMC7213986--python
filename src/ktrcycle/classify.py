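"""Categorical cell-fate classification and bimodal thresholding.

Fates are deterministic functions of (trace, detected events, thresholds):

* quiescence release — CDK4/6^high (persistent activation) vs CDK4/6^low;
* mitotic exit — CDK4/6^high (above 0.7 throughout the first 2 h after
  anaphase), CDK4/6^low (below threshold at 2 and 10 h, no onset), or
  CDK4/6^delay (onset after a transient G0, with the G0 duration);
* stress outcome — CDK2^inc vs CDK2^low scored at a fixed outcome time.

Also provides mixture-based thresholding of bimodal fixed-cell intensities
(e.g. Rb pS807/811 immunofluorescence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

from .correction import corrected_cdk46
from .errors import (
    DegeneracyWarning,
    EligibilityError,
    InsufficientDataError,
    ParameterError,
    ProtocolError,
)
from .events import EventRecord
from .trace_model import DEFAULT_THRESHOLDS, Thresholds, Trace

__all__ = [
    "FateLabel",
    "classify_release",
    "classify_postmitotic",
    "classify_stress_outcome",
    "bimodal_threshold",
    "is_bimodal",
    "ashman_d",
]


@dataclass
class FateLabel:
    """Per-cell categorical fate.

    label is context-dependent: {high, low} for quiescence_release,
    {high, low, delay} for mitotic_exit, {inc, low} for stress_outcome.
    ``t_delay`` is the transient-G0 duration for delay fates.  ``truncated``
    flags mitotic-exit labels scored on fewer than 10 h of post-anaphase
    recording.
    """

    cell_id: str
    context: str
    label: str
    t_delay: float | None = None
    truncated: bool = False

    _ALLOWED = {
        "quiescence_release": {"high", "low"},
        "mitotic_exit": {"high", "low", "delay"},
        "stress_outcome": {"inc", "low"},
    }

    def __post_init__(self) -> None:
        if self.context not in self._ALLOWED:
            raise ParameterError(f"unknown context {self.context!r}")
        if self.label not in self._ALLOWED[self.context]:
            raise ParameterError(
                f"label {self.label!r} invalid for context {self.context!r}"
            )


def _corrected(trace: Trace, th: Thresholds) -> np.ndarray:
    return corrected_cdk46(trace.cdk46_raw, trace.cdk2, th.f_correction)


def _robust_value(series: np.ndarray, trace: Trace, t: float, halfwidth: int = 2) -> float:
    """Median of unmasked samples within +-halfwidth frames of time t."""
    i = trace.index_at(t)
    lo, hi = max(0, i - halfwidth), min(trace.n_frames, i + halfwidth + 1)
    vals = series[lo:hi][~trace.missing[lo:hi]]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return np.nan
    return float(np.median(vals))


def classify_release(
    trace: Trace, record: EventRecord, th: Thresholds = DEFAULT_THRESHOLDS
) -> FateLabel:
    """CDK4/6^high vs ^low for a quiescence-release cell.

    high iff a CDK4/6 onset was detected and corrected CDK4/6 stays above
    the threshold from the onset through the G1/S transition (or the trace
    end for cells that never reach it) — the operational meaning of
    "persistently increased CDK4/6 activity".
    """
    corr = _corrected(trace, th)
    label = "low"
    if record.t_cdk46_on is not None:
        i0 = trace.index_at(record.t_cdk46_on)
        i1 = trace.n_frames
        if record.t_apc_off is not None:
            i1 = trace.index_at(record.t_apc_off) + 1
        seg = corr[i0:i1]
        ok = ~trace.missing[i0:i1] & np.isfinite(seg)
        if ok.any() and np.all(seg[ok] > th.theta_cdk46):
            label = "high"
    return FateLabel(trace.cell_id, "quiescence_release", label)


def classify_postmitotic(
    trace: Trace, record: EventRecord, th: Thresholds = DEFAULT_THRESHOLDS
) -> FateLabel:
    """CDK4/6^high / ^low / ^delay for a cell exiting mitosis.

    high — corrected CDK4/6 above threshold at every unmasked frame in
    (anaphase, anaphase + 2 h]; delay — a later onset was detected, with
    ``t_delay = onset - anaphase``; low — no onset, below threshold at both
    the 2 h and 10 h checks.  Labels form a partition.  When less than 10 h
    of post-anaphase recording exists the label carries ``truncated=True``.
    """
    if record.t_anaphase_ref is None and trace.anaphase_times.size == 0:
        raise ProtocolError(f"cell {trace.cell_id} has no anaphase annotation")
    ana = (
        record.t_anaphase_ref
        if record.t_anaphase_ref is not None
        else float(trace.anaphase_times[0])
    )
    truncated = trace.times[-1] - ana < th.t_check_late
    corr = _corrected(trace, th)

    win = (trace.times > ana + 1e-9) & (trace.times <= ana + th.t_check_early + 1e-9)
    ok = win & ~trace.missing & np.isfinite(corr)
    if ok.any() and np.all(corr[ok] > th.theta_cdk46):
        return FateLabel(trace.cell_id, "mitotic_exit", "high", truncated=truncated)
    if record.t_cdk46_on is not None and record.t_cdk46_on > ana:
        return FateLabel(
            trace.cell_id,
            "mitotic_exit",
            "delay",
            t_delay=float(record.t_cdk46_on - ana),
            truncated=truncated,
        )
    return FateLabel(trace.cell_id, "mitotic_exit", "low", truncated=truncated)


def activity_at(series: np.ndarray, trace: Trace, t: float) -> float:
    """Robust activity estimate at time ``t``: median of +-2 frames.

    On a linear ramp the symmetric median is unbiased, and it tolerates up
    to two contaminated frames (e.g. the first frames of an acute
    perturbation response starting at ``t``).
    """
    return _robust_value(series, trace, t, halfwidth=2)


def stress_eligible(
    trace: Trace, record: EventRecord, th: Thresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Active CDK4/6 and CDK2 and a flat degron when the stress is added.

    Activity is judged from the instantaneous corrected CDK4/6 and CDK2
    levels at ``t_perturb`` against their thresholds, mirroring selection
    on the activity state at the moment of perturbation.
    """
    corr = activity_at(_corrected(trace, th), trace, th.t_perturb)
    c2 = activity_at(trace.cdk2, trace, th.t_perturb)
    return (
        np.isfinite(corr)
        and corr > th.theta_cdk46
        and np.isfinite(c2)
        and c2 > th.theta_cdk2
        and (record.t_apc_off is None or record.t_apc_off > th.t_perturb)
    )


def classify_stress_outcome(
    trace: Trace, record: EventRecord, th: Thresholds = DEFAULT_THRESHOLDS
) -> FateLabel:
    """CDK2^inc vs CDK2^low after a stress added at ``th.t_perturb``.

    Only cells with both CDK activities on and a flat degron at the moment
    of stress are scoreable.  low iff CDK2 at ``th.t_outcome`` is below the
    CDK2 threshold or has declined by more than 20% from its value when the
    stress was added; inc otherwise.
    """
    if not stress_eligible(trace, record, th):
        raise EligibilityError(
            f"cell {trace.cell_id} not eligible at t={th.t_perturb} "
            "(needs CDK4/6 and CDK2 on and degron flat)"
        )
    c_add = activity_at(trace.cdk2, trace, th.t_perturb)
    c_out = _robust_value(trace.cdk2, trace, th.t_outcome)
    low = c_out < th.theta_cdk2 or (np.isfinite(c_add) and c_out < 0.8 * c_add)
    return FateLabel(trace.cell_id, "stress_outcome", "low" if low else "inc")


# ---------------------------------------------------------------------------
# Bimodality
# ---------------------------------------------------------------------------

def ashman_d(mu1: float, mu2: float, sd1: float, sd2: float) -> float:
    """Ashman's D mode-separation statistic; D > 2 indicates clean bimodality."""
    return float(np.sqrt(2.0) * abs(mu1 - mu2) / np.sqrt(sd1**2 + sd2**2))


def _fit_gmm(x: np.ndarray, k: int) -> GaussianMixture:
    return GaussianMixture(n_components=k, n_init=3, random_state=0).fit(
        x.reshape(-1, 1)
    )


def is_bimodal(values: np.ndarray, min_separation: float = 2.0) -> bool:
    """Whether a sample of activities has two well-separated modes.

    A 2-component Gaussian mixture must beat the single Gaussian by BIC
    *and* the fitted components must be separated by Ashman's D >=
    ``min_separation``.  The separation requirement prevents calling a
    gradually spreading unimodal distribution bimodal merely because it is
    non-Gaussian.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise InsufficientDataError("is_bimodal needs >= 50 values")
    if np.ptp(x) == 0:
        return False
    g1, g2 = _fit_gmm(x, 1), _fit_gmm(x, 2)
    if g2.bic(x.reshape(-1, 1)) >= g1.bic(x.reshape(-1, 1)):
        return False
    mus = g2.means_.ravel()
    sds = np.sqrt(g2.covariances_.ravel())
    return ashman_d(mus[0], mus[1], sds[0], sds[1]) >= min_separation


def bimodal_threshold(values: np.ndarray) -> float:
    """Boundary between the two modes of a bimodal intensity distribution.

    Fits a 2-component Gaussian mixture to log-transformed intensities and
    returns the equal-posterior boundary between the components, mapped
    back to intensity units.  Falls back to the inter-mode KDE minimum when
    the mixture boundary is degenerate; emits a :class:`DegeneracyWarning`
    and returns the global median when the fitted components are not
    separated (within one pooled sd) or the data are constant.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise InsufficientDataError(
            f"bimodal_threshold needs >= 50 values, got {x.size}"
        )
    if np.any(x <= 0):
        raise ParameterError("intensities must be positive for log-thresholding")
    if np.ptp(x) == 0:
        warnings.warn(
            "all intensities identical; returning the median", DegeneracyWarning,
            stacklevel=2,
        )
        return float(np.median(x))

    lx = np.log(x)
    gm = _fit_gmm(lx, 2)
    (m1, m2) = gm.means_.ravel()
    (s1, s2) = np.sqrt(gm.covariances_.ravel())
    (w1, w2) = gm.weights_.ravel()
    if m1 > m2:
        m1, m2, s1, s2, w1, w2 = m2, m1, s2, s1, w2, w1
    pooled = np.sqrt((s1**2 + s2**2) / 2.0)
    if (m2 - m1) < pooled:
        warnings.warn(
            "mixture components overlap within one pooled sd; distribution "
            "treated as unimodal, returning the median",
            DegeneracyWarning,
            stacklevel=2,
        )
        return float(np.median(x))

    # equal-posterior boundary: w1 N(t|m1,s1) = w2 N(t|m2,s2), quadratic in t
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m2**2 / s2**2 - m1**2 / s1**2 + 2.0 * np.log((w2 * s1) / (w1 * s2))
    if abs(a) < 1e-12:
        roots = np.array([-c / b]) if abs(b) > 1e-12 else np.array([])
    else:
        disc = b**2 - 4 * a * c
        roots = (
            np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
            if disc >= 0
            else np.array([])
        )
    between = roots[(roots > m1) & (roots < m2)] if roots.size else roots
    if between.size:
        return float(np.exp(between[0]))

    # degenerate boundary: inter-mode minimum of a kernel density estimate
    kde = gaussian_kde(lx)
    grid = np.linspace(m1, m2, 512)
    return float(np.exp(grid[np.argmin(kde(grid))]))
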