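"""Synthetic single-cell reporter trace generator with ground truth.

The generator emulates the statistical structure of dual CDK4/6 + CDK2
kinase-translocation-reporter live-cell imaging experiments in epithelial
cells released from quiescence or cycling asynchronously:

* quiescence-release cohorts in which a fraction of cells switches CDK4/6
  on rapidly (rise over ~1 h) after a long, variable delay (5-13 h), with a
  gradual CDK2 ramp starting shortly after and an APC/C-degron rise once
  CDK2 reaches the S-phase level;
* mitotic-exit cohorts with trimodal fates: CDK4/6 already active at
  anaphase (high), persistently inactive (low), or reactivating after a
  transient G0 of a few hours (delay);
* acute perturbations: CDK4/6 inhibitors (true activity nulled; the raw
  reporter keeps an additive CDK2-proportional term), CDK2 inhibitors, and
  stresses whose probability of reverting cell-cycle entry decreases with
  CDK2 activity at the time of stress and never affects post-G1/S cells.

The observed raw CDK4/6 reporter is composed as
``true activity + f_true * CDK2 + noise``, the additive CDK2 contamination
that the correction module removes.  Each cohort carries per-cell ground
truth (fate, continuous-time event landmarks, stress response) and the
latent noise-free kinetics, so every downstream detector and classifier can
be validated by recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ParameterError, ProtocolError
from .trace_model import Cohort, Trace

__all__ = [
    "GeneratorParams",
    "PerturbationSpec",
    "CellLatent",
    "simulate_quiescence_release",
    "simulate_cycling",
    "simulate_sg2_inhibited",
    "apply_perturbation",
]


@dataclass
class GeneratorParams:
    """Parameters of the synthetic trace generator.

    Times are hours, activities are unitless reporter ratios.  Defaults
    encode the study conditions: 12-min frames, a 5-13 h uniform activation
    delay after mitogen release, 54% of released cells activating, a rapid
    (1 h) CDK4/6 rise to a ~0.9 plateau, a gradual CDK2 ramp from a ~0.5
    post-mitotic baseline, APC/C-degron accumulation once CDK2 reaches 1.0,
    2-9 h transient-G0 periods after mitosis, and an additive 35% CDK2
    contamination of the raw CDK4/6 reporter.
    """

    n_cells: int = 200
    dt: float = 0.2
    duration: float = 24.0
    p_activate: float = 0.54
    delay_range: tuple[float, float] = (5.0, 13.0)
    rise_time_cdk46: float = 1.0
    plateau_cdk46: float = 0.9
    plateau_sd: float = 0.05
    baseline_cdk46: float = 0.2
    cdk2_baseline: float = 0.5
    cdk2_baseline_sd: float = 0.08
    cdk2_lag: float = 1.0
    cdk2_lag_rel_jitter: float = 0.5
    cdk2_slope: float = 0.1
    cdk2_max: float = 1.5
    apc_trigger_cdk2: float = 1.0
    degron_rate: float = 1.0
    mitotic_fate_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)
    delay_fate_range: tuple[float, float] = (2.0, 9.0)
    anaphase_range: tuple[float, float] = (0.5, 2.0)
    mother_cdk2: float = 1.2
    mother_degron: float = 1.0
    rb_log_medians: tuple[float, float] = (1.0, 10.0)
    rb_log_sd: float = 0.3
    noise_sd: float = 0.03
    f_true: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_activate <= 1.0:
            raise ParameterError(f"p_activate must be in [0,1], got {self.p_activate}")
        probs = np.asarray(self.mitotic_fate_probs, dtype=float)
        if np.any(probs < 0) or np.any(probs > 1):
            raise ParameterError("mitotic_fate_probs must lie in [0,1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ParameterError("mitotic_fate_probs must sum to 1")
        if not self.rise_time_cdk46 < self.delay_range[0]:
            raise ParameterError(
                "rise_time_cdk46 must be smaller than the delay_range low bound "
                "(activation is fast relative to the delay)"
            )
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.dt <= 0 or self.duration <= self.dt:
            raise ParameterError("need dt > 0 and duration > dt")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0.0 <= self.f_true <= 1.0:
            raise ParameterError("f_true must be in [0,1]")


@dataclass
class PerturbationSpec:
    """An acute perturbation added at ``t_add`` hours.

    kind: ``cdk46_inhibitor`` | ``cdk2_inhibitor`` | ``stress``.
    ``exit_logistic = (midpoint, steepness)`` parameterizes the decreasing
    probability that stress reverts cell-cycle entry as a function of CDK2
    activity when the stress is added.  ``cdk46_to_cdk2_lag`` is the delay
    between CDK4/6 and CDK2 inactivation in exiting cells (0 for
    osmotic/NaCl-like stresses, which suppress both at a similar rate).
    """

    kind: str = "stress"
    t_add: float = 11.0
    residual_fraction: float = 0.0
    cdk2_reduction: float = 0.15
    exit_logistic: tuple[float, float] = (0.9, 10.0)
    cdk46_to_cdk2_lag: float = 1.0
    g1_cdk2_reversal_lag: float = 1.0
    fall_time: float = 0.4

    def __post_init__(self) -> None:
        if self.kind not in ("cdk46_inhibitor", "cdk2_inhibitor", "stress"):
            raise ParameterError(f"unknown perturbation kind {self.kind!r}")
        if self.cdk46_to_cdk2_lag < 0 or self.g1_cdk2_reversal_lag < 0:
            raise ParameterError("lags must be >= 0")
        if self.exit_logistic[1] < 0:
            raise ParameterError(
                "exit_logistic steepness must be >= 0 so that the exit "
                "probability is nonincreasing in CDK2 activity"
            )
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ParameterError("residual_fraction must be in [0,1]")

    def exit_probability(self, cdk2_at_add: float) -> float:
        """P(stress reverts cell-cycle entry | CDK2 activity at t_add)."""
        mid, steep = self.exit_logistic
        if np.isinf(steep):
            return 1.0 if cdk2_at_add < mid else 0.0
        return float(expit(-steep * (cdk2_at_add - mid)))


@dataclass
class CellLatent:
    """Noise-free per-cell kinetics kept alongside a synthetic cohort."""

    cell_id: str
    fate: str
    cdk46_true: np.ndarray
    cdk2_true: np.ndarray
    degron_true: np.ndarray
    plateau: float
    cdk2_base: float
    cdk2_lag: float
    t_on: float = np.nan          # start of the rapid CDK4/6 rise
    t_cross_cdk46: float = np.nan  # corrected CDK4/6 crosses 0.7
    t_cross_cdk2: float = np.nan   # CDK2 crosses 0.76
    t_apc_off: float = np.nan      # degron rise onset (CDK2 reaches trigger)
    anaphase: float = np.nan
    t_delay: float = np.nan
    truncated: bool = False
    responded_to_stress: bool | None = None


@dataclass
class Latent:
    cells: list[CellLatent]
    params: GeneratorParams


# thresholds at which ground-truth crossing times are recorded; these are
# the field-standard activity gates used by the analysis side
_GT_THETA_CDK46 = 0.7
_GT_THETA_CDK2 = 0.76


def _time_grid(params: GeneratorParams) -> np.ndarray:
    n = int(round(params.duration / params.dt)) + 1
    return np.arange(n) * params.dt


def _activation_kinetics(
    times: np.ndarray,
    params: GeneratorParams,
    t_on: float,
    plateau: float,
    cdk2_base: float,
    lag: float,
    rise_time: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, float]:
    """Latent series for a cell that activates CDK4/6 at ``t_on``.

    Returns (cdk46_true, cdk2_true, degron_true, t_cross46, t_cross2, t_apc).
    """
    rise = params.rise_time_cdk46 if rise_time is None else rise_time
    b46 = params.baseline_cdk46
    if rise > 0:
        frac = np.clip((times - t_on) / rise, 0.0, 1.0)
    else:
        frac = (times >= t_on).astype(float)
    cdk46 = b46 + (plateau - b46) * frac

    t_cdk2_start = t_on + lag
    cdk2 = cdk2_base + params.cdk2_slope * np.clip(times - t_cdk2_start, 0.0, None)
    cdk2 = np.minimum(cdk2, params.cdk2_max)

    if params.cdk2_slope > 0 and params.apc_trigger_cdk2 > cdk2_base:
        t_apc = t_cdk2_start + (params.apc_trigger_cdk2 - cdk2_base) / params.cdk2_slope
    else:
        t_apc = t_cdk2_start
    degron = params.degron_rate * np.clip(times - t_apc, 0.0, None)

    if rise > 0:
        t_cross46 = t_on + rise * (_GT_THETA_CDK46 - b46) / (plateau - b46)
    else:
        t_cross46 = t_on
    t_cross2 = t_cdk2_start + max(_GT_THETA_CDK2 - cdk2_base, 0.0) / params.cdk2_slope
    return cdk46, cdk2, degron, t_cross46, t_cross2, t_apc


def _observe(
    latents: Sequence[CellLatent],
    params: GeneratorParams,
    rng: np.random.Generator,
    treatment: str = "none",
    dose: float = 0.0,
    anaphase: bool = False,
) -> list[Trace]:
    """Add measurement noise and compose the observed raw reporter signals."""
    times = None
    traces = []
    for lat in latents:
        n = lat.cdk46_true.size
        if times is None or times.size != n:
            times = np.arange(n) * params.dt
        eps = rng.normal(0.0, params.noise_sd, size=(3, n)) if params.noise_sd > 0 else np.zeros((3, n))
        raw46 = np.clip(lat.cdk46_true + params.f_true * lat.cdk2_true + eps[0], 0.0, None)
        cdk2 = np.clip(lat.cdk2_true + eps[1], 0.0, None)
        degron = np.clip(lat.degron_true + eps[2], 0.0, None)
        ana = np.array([lat.anaphase]) if anaphase and np.isfinite(lat.anaphase) else np.empty(0)
        traces.append(
            Trace(
                cell_id=lat.cell_id,
                times=times,
                cdk46_raw=raw46,
                cdk2=cdk2,
                apc_degron=degron,
                anaphase_times=ana,
                treatment=treatment,
                dose=dose,
            )
        )
    return traces


def _ground_truth_frame(latents: Sequence[CellLatent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [l.cell_id for l in latents],
            "true_fate": [l.fate for l in latents],
            "true_t_cdk46_on": [l.t_cross_cdk46 for l in latents],
            "true_t_cdk2_on": [l.t_cross_cdk2 for l in latents],
            "true_t_apc_off": [l.t_apc_off for l in latents],
            "responded_to_stress": [l.responded_to_stress for l in latents],
            "true_t_delay": [l.t_delay for l in latents],
            "truncated": [l.truncated for l in latents],
        }
    )


def _draw_cell_params(
    params: GeneratorParams, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Per-cell plateau, CDK2 baseline and CDK2 lag with biological scatter."""
    plateau = params.plateau_cdk46 + np.clip(
        rng.normal(0.0, params.plateau_sd), -2.5 * params.plateau_sd, 2.5 * params.plateau_sd
    )
    base2 = params.cdk2_baseline + np.clip(
        rng.normal(0.0, params.cdk2_baseline_sd),
        -2.5 * params.cdk2_baseline_sd,
        2.5 * params.cdk2_baseline_sd,
    )
    j = params.cdk2_lag_rel_jitter
    lag = params.cdk2_lag * rng.uniform(1.0 - j, 1.0 + j)
    return float(plateau), float(base2), float(lag)


def simulate_quiescence_release(params: GeneratorParams) -> Cohort:
    """Simulate serum-starved cells released with mitogens at t = 0.

    With probability ``p_activate`` a cell switches corrected CDK4/6
    activity from the ~0.2 baseline to its plateau within
    ``rise_time_cdk46`` starting at a delay drawn uniformly from
    ``delay_range``; CDK2 then ramps from its baseline after ``cdk2_lag``
    and the APC/C degron rises once CDK2 reaches ``apc_trigger_cdk2``.
    Non-activating cells keep all three signals at baseline throughout.
    """
    rng = np.random.default_rng(params.seed)
    times = _time_grid(params)
    if params.duration < params.delay_range[1]:
        warnings.warn(
            "duration shorter than the delay_range high bound; late-activating "
            "cells are truncated and flagged in ground_truth",
            UserWarning,
            stacklevel=2,
        )
    latents: list[CellLatent] = []
    for i in range(params.n_cells):
        cell_id = f"cell{i:05d}"
        plateau, base2, lag = _draw_cell_params(params, rng)
        activate = rng.uniform() < params.p_activate
        t_on = rng.uniform(*params.delay_range)
        if activate:
            c46, c2, deg, x46, x2, xapc = _activation_kinetics(
                times, params, t_on, plateau, base2, lag
            )
            truncated = xapc > times[-1]
            latents.append(
                CellLatent(
                    cell_id, "high", c46, c2, deg, plateau, base2, lag,
                    t_on=t_on, t_cross_cdk46=x46, t_cross_cdk2=x2,
                    t_apc_off=xapc if not truncated else np.nan,
                    truncated=bool(truncated),
                )
            )
        else:
            flat46 = np.full_like(times, params.baseline_cdk46)
            flat2 = np.full_like(times, base2)
            latents.append(
                CellLatent(
                    cell_id, "low", flat46, flat2, np.zeros_like(times),
                    plateau, base2, lag,
                )
            )
    traces = _observe(latents, params, rng)
    return Cohort(
        traces=traces,
        protocol="quiescence_release",
        t_zero_meaning="mitogen release",
        ground_truth=_ground_truth_frame(latents),
        seed=params.seed,
        latent=Latent(latents, params),
    )


def simulate_cycling(params: GeneratorParams) -> Cohort:
    """Simulate asynchronously cycling cells with one anaphase per trace.

    Before anaphase the mother cell is in S/G2/M: CDK4/6 at plateau, CDK2
    high, degron accumulated.  At anaphase everything resets and the
    daughter's fate is drawn from ``mitotic_fate_probs``:

    * ``high`` — CDK4/6 stays at plateau from anaphase on, CDK2 ramps after
      a short lag;
    * ``low`` — both CDK activities stay at baseline for the remainder;
    * ``delay`` — baseline for a transient-G0 period drawn from
      ``delay_fate_range``, then the quiescence-release kinetics.

    A terminal Rb pS807/811 intensity is drawn per cell from the high
    mixture component iff corrected CDK4/6 is above 0.7 at the terminal
    frame (live-fixed emulation); it is stored in ``cohort.fixed_cells``
    together with the terminal time since anaphase.
    """
    rng = np.random.default_rng(params.seed)
    times = _time_grid(params)
    latents: list[CellLatent] = []
    rb_rows = []
    fate_names = np.array(["high", "low", "delay"])
    for i in range(params.n_cells):
        cell_id = f"cell{i:05d}"
        plateau, base2, lag = _draw_cell_params(params, rng)
        ana = params.dt * round(rng.uniform(*params.anaphase_range) / params.dt)
        ana = float(np.clip(ana, times[0], times[-1]))
        fate = str(rng.choice(fate_names, p=np.asarray(params.mitotic_fate_probs)))
        t_delay = np.nan
        if fate == "high":
            c46, c2, deg, x46, x2, xapc = _activation_kinetics(
                times, params, ana, plateau, base2, lag, rise_time=0.0
            )
        elif fate == "delay":
            t_delay = rng.uniform(*params.delay_fate_range)
            c46, c2, deg, x46, x2, xapc = _activation_kinetics(
                times, params, ana + t_delay, plateau, base2, lag
            )
        else:
            c46 = np.full_like(times, params.baseline_cdk46)
            c2 = np.full_like(times, base2)
            deg = np.zeros_like(times)
            x46 = x2 = xapc = np.nan
        # mother-cell segment before anaphase
        pre = times < ana
        c46 = np.where(pre, plateau, c46)
        c2 = np.where(pre, params.mother_cdk2, c2)
        deg = np.where(pre, params.mother_degron, deg)
        truncated = bool(np.isfinite(xapc) and xapc > times[-1])
        lat = CellLatent(
            cell_id, fate, c46, c2, deg, plateau, base2, lag,
            t_on=ana if fate == "high" else (ana + t_delay if fate == "delay" else np.nan),
            t_cross_cdk46=x46, t_cross_cdk2=x2,
            t_apc_off=np.nan if truncated else xapc,
            anaphase=ana, t_delay=t_delay, truncated=truncated,
        )
        latents.append(lat)
        high_component = lat.cdk46_true[-1] > _GT_THETA_CDK46
        mu = np.log(params.rb_log_medians[1] if high_component else params.rb_log_medians[0])
        rb = float(np.exp(rng.normal(mu, params.rb_log_sd)))
        rb_rows.append(
            {
                "cell_id": cell_id,
                "rb_phospho": rb,
                "time_since_anaphase": float(times[-1] - ana),
            }
        )
    traces = _observe(latents, params, rng, anaphase=True)
    return Cohort(
        traces=traces,
        protocol="cycling",
        t_zero_meaning="recording start",
        ground_truth=_ground_truth_frame(latents),
        fixed_cells=pd.DataFrame(rb_rows),
        seed=params.seed,
        latent=Latent(latents, params),
    )


def simulate_sg2_inhibited(
    n_cells: int = 200,
    *,
    t_add: float = 8.0,
    duration: float = 14.0,
    dt: float = 0.2,
    f_true: float = 0.35,
    noise_sd: float = 0.02,
    cdk2_start_range: tuple[float, float] = (0.8, 1.6),
    cdk2_slope: float = 0.15,
    plateau_cdk46: float = 0.9,
    plateau_sd: float = 0.05,
    raw_plateau: float | None = None,
    residual_fraction: float = 0.0,
    degron_rate: float = 1.0,
    seed: int = 0,
) -> Cohort:
    """S/G2 cells acutely treated with a CDK4/6 inhibitor at ``t_add``.

    Every cell passed the G1/S transition before the inhibitor: its degron
    has been rising since an S-entry time drawn from U(3, 6) h, corrected
    CDK4/6 sits at a per-cell plateau, and CDK2 ramps linearly from a
    per-cell starting level drawn from ``cdk2_start_range``.  At ``t_add``
    the true CDK4/6 activity decays to ``residual_fraction * plateau``
    within 2 frames; the observed raw reporter keeps the additive
    ``f_true * CDK2`` term.

    If ``raw_plateau`` is given, the per-cell true activity is instead set
    so that the noise-free pre-inhibition *raw* signal equals
    ``raw_plateau`` (used to measure the unsuppressible signal fraction).
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt)) + 1
    times = np.arange(n) * dt
    spec = PerturbationSpec(
        kind="cdk46_inhibitor", t_add=t_add, residual_fraction=residual_fraction
    )
    params = GeneratorParams(
        n_cells=n_cells, dt=dt, duration=duration, noise_sd=noise_sd,
        f_true=f_true, cdk2_slope=max(cdk2_slope, 0.0) or 0.15, seed=seed,
    )
    latents: list[CellLatent] = []
    for i in range(n_cells):
        cell_id = f"cell{i:05d}"
        c2_start = rng.uniform(*cdk2_start_range)
        cdk2 = c2_start + cdk2_slope * times
        if raw_plateau is not None:
            c46_level = raw_plateau - f_true * np.interp(t_add, times, cdk2)
        else:
            c46_level = plateau_cdk46 + np.clip(
                rng.normal(0.0, plateau_sd), -2.5 * plateau_sd, 2.5 * plateau_sd
            )
        cdk46 = np.full(n, c46_level)
        target = residual_fraction * c46_level
        after = times >= t_add
        ramp = np.clip((times - t_add) / (2 * dt), 0.0, 1.0)
        cdk46 = np.where(after, c46_level + (target - c46_level) * ramp, cdk46)
        t_s_entry = rng.uniform(3.0, 6.0)
        degron = degron_rate * np.clip(times - t_s_entry, 0.0, None)
        latents.append(
            CellLatent(
                cell_id, "high", cdk46, cdk2, degron,
                float(c46_level), float(c2_start), 0.0,
                t_apc_off=t_s_entry,
            )
        )
    traces = _observe(latents, params, rng, treatment="cdk46_inhibitor", dose=1.0)
    return Cohort(
        traces=traces,
        protocol="cycling",
        perturbation=spec,
        t_zero_meaning="recording start",
        ground_truth=_ground_truth_frame(latents),
        seed=seed,
        latent=Latent(latents, params),
    )


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def _ramp_down(
    series: np.ndarray, times: np.ndarray, t_start: float, target: float, fall_time: float
) -> np.ndarray:
    """Linear decay from the series value at ``t_start`` to ``target``."""
    v0 = float(np.interp(t_start, times, series))
    frac = np.clip((times - t_start) / max(fall_time, 1e-9), 0.0, 1.0)
    out = series.copy()
    after = times >= t_start
    out[after] = (v0 + (target - v0) * frac)[after]
    return out


def apply_perturbation(cohort: Cohort, spec: PerturbationSpec) -> Cohort:
    """Return a new cohort with an acute perturbation applied at ``spec.t_add``.

    Requires a synthetic cohort that still carries its latent noise-free
    kinetics (perturbations modify the latent series and the observed
    traces are re-noised from a derived random stream).

    * ``cdk46_inhibitor`` — true CDK4/6 decays to
      ``residual_fraction * plateau`` within 2 frames; the observed raw
      reporter keeps the additive CDK2 term.  G1 cells (degron still flat)
      slowly reverse their CDK2 ramp after ``g1_cdk2_reversal_lag``; cells
      past G1/S keep ramping CDK2 and accumulating degron.
    * ``cdk2_inhibitor`` — CDK2 falls toward its baseline and the raw
      CDK4/6 reporter settles ``cdk2_reduction`` below its pre-treatment
      level.
    * ``stress`` — each cell with a flat degron at ``t_add`` reverts
      cell-cycle entry with probability ``exit_probability(CDK2(t_add))``;
      exiting cells inactivate CDK4/6 first and CDK2 after
      ``cdk46_to_cdk2_lag``.  Cells whose degron is already rising never
      respond.
    """
    if cohort.latent is None:
        raise ProtocolError(
            "apply_perturbation needs a synthetic cohort carrying latent kinetics"
        )
    params: GeneratorParams = cohort.latent.params
    t_add = spec.t_add
    for tr in cohort.traces:
        if t_add < tr.times[0] or t_add > tr.times[-1]:
            raise ParameterError(
                f"t_add={t_add} outside the time span of cell {tr.cell_id}"
            )
    rng = np.random.default_rng([int(cohort.seed or 0) % (2**31), 9173])
    two_frames = 2 * params.dt
    new_latents: list[CellLatent] = []
    for lat in cohort.latent.cells:
        times = np.arange(lat.cdk46_true.size) * params.dt
        c46, c2, deg = lat.cdk46_true.copy(), lat.cdk2_true.copy(), lat.degron_true.copy()
        in_g1 = not (np.isfinite(lat.t_apc_off) and lat.t_apc_off <= t_add)
        responded: bool | None = lat.responded_to_stress

        if spec.kind == "cdk46_inhibitor":
            target = spec.residual_fraction * lat.plateau
            c46 = _ramp_down(c46, times, t_add, target, two_frames)
            if in_g1:
                t_rev = t_add + spec.g1_cdk2_reversal_lag
                v0 = float(np.interp(t_rev, times, c2))
                decline = v0 - params.cdk2_slope * np.clip(times - t_rev, 0.0, None)
                c2 = np.where(times >= t_rev, np.maximum(decline, lat.cdk2_base), c2)
                deg = np.where(times >= t_add, 0.0, deg)

        elif spec.kind == "cdk2_inhibitor":
            raw_pre = float(np.interp(t_add, times, c46 + params.f_true * c2))
            c2 = _ramp_down(c2, times, t_add, lat.cdk2_base, 0.5)
            target_raw = (1.0 - spec.cdk2_reduction) * raw_pre
            want46 = np.clip(target_raw - params.f_true * c2, 0.0, None)
            frac = np.clip((times - t_add) / two_frames, 0.0, 1.0)
            after = times >= t_add
            c46 = np.where(after, c46 * (1 - frac) + want46 * frac, c46)
            if in_g1:
                deg = np.where(times >= t_add, 0.0, deg)

        elif spec.kind == "stress":
            if in_g1:
                c_at_add = float(np.interp(t_add, times, c2))
                responded = bool(rng.uniform() < spec.exit_probability(c_at_add))
                if responded:
                    c46 = _ramp_down(c46, times, t_add, params.baseline_cdk46, spec.fall_time)
                    t_c2 = t_add + spec.cdk46_to_cdk2_lag
                    c2 = _ramp_down(c2, times, t_c2, lat.cdk2_base, spec.fall_time)
                    deg = np.where(times >= t_add, 0.0, deg)
            else:
                responded = False

        new_latents.append(
            replace(
                lat,
                cdk46_true=c46,
                cdk2_true=c2,
                degron_true=deg,
                responded_to_stress=responded,
            )
        )

    traces = _observe(
        new_latents, params, rng,
        treatment=spec.kind, dose=1.0,
        anaphase=cohort.protocol == "cycling",
    )
    return Cohort(
        traces=traces,
        protocol=cohort.protocol,
        perturbation=spec,
        t_zero_meaning=cohort.t_zero_meaning,
        ground_truth=_ground_truth_frame(new_latents),
        fixed_cells=cohort.fixed_cells,
        seed=cohort.seed,
        latent=Latent(new_latents, params),
    )
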