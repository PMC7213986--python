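"""Alignment, cumulative curves, bootstrap medians, binned stress response."""

import numpy as np
import pandas as pd
import pytest

import ktrcycle as k
from ktrcycle.classify import classify_stress_outcome, stress_eligible
from ktrcycle.cohort_stats import classify_terminal_cdk46
from ktrcycle.errors import InsufficientDataError, ParameterError, ProtocolError


def _simple_trace(cell_id, n=20, dt=0.2, anaphase=None, value=1.0):
    t = np.arange(n) * dt
    ana = np.array([anaphase]) if anaphase is not None else np.empty(0)
    return k.Trace(cell_id, t, np.full(n, value), np.full(n, 0.5),
                   np.zeros(n), anaphase_times=ana)


class TestAlignToEvent:
    def test_single_cell_shift(self):
        tr = _simple_trace("a", anaphase=4.0, n=40)
        co = k.Cohort([tr], protocol="cycling")
        rec = {"a": k.EventRecord("a", t_anaphase_ref=4.0)}
        al = k.align_to_event(co, rec, "anaphase", channel="cdk2")
        assert al.relative_times[0] == pytest.approx(-4.0)
        i0 = np.argmin(np.abs(al.relative_times))
        assert al.values[0, i0] == pytest.approx(0.5)

    def test_two_cells_overlap_region(self):
        co = k.Cohort(
            [_simple_trace("a", anaphase=4.0, n=40), _simple_trace("b", anaphase=6.0, n=40)],
            protocol="cycling",
        )
        rec = {c: k.EventRecord(c, t_anaphase_ref=t) for c, t in (("a", 4.0), ("b", 6.0))}
        al = k.align_to_event(co, rec, "anaphase", channel="cdk2")
        i0 = np.argmin(np.abs(al.relative_times))
        assert np.isfinite(al.values[:, i0]).all()

    def test_cells_without_anchor_dropped(self):
        co = k.Cohort([_simple_trace("a", anaphase=4.0, n=40), _simple_trace("b", n=40)],
                      protocol="cycling")
        rec = {
            "a": k.EventRecord("a", t_anaphase_ref=4.0),
            "b": k.EventRecord("b"),
        }
        al = k.align_to_event(co, rec, "anaphase", channel="cdk2")
        assert al.n_cells == 1 and al.n_dropped == 1

    def test_no_anchor_at_all_rejected(self):
        co = k.Cohort([_simple_trace("a", n=40)])
        with pytest.raises(InsufficientDataError):
            k.align_to_event(co, {"a": k.EventRecord("a")}, "cdk2_on")

    def test_fate_separation_at_two_hours(self, cycling_cohort, cycling_records):
        """High-fate rows sit above threshold at +2 h; low-fate rows below."""
        gt = cycling_cohort.ground_truth.set_index("cell_id")
        al = k.align_to_event(
            cycling_cohort, cycling_records, "anaphase", channel="cdk46_corrected",
            smooth_window=3,
        )
        i2 = np.argmin(np.abs(al.relative_times - 2.0))
        fates = np.array([gt.loc[c, "true_fate"] for c in al.cell_ids])
        col = al.values[:, i2]
        assert np.nanmean(col[fates == "high"]) > 0.7
        assert np.nanmean(col[fates == "low"]) < 0.7


class TestCumulativeFraction:
    def test_simple_counting(self):
        recs = {
            "a": k.EventRecord("a", t_cdk46_on=5.0),
            "b": k.EventRecord("b", t_cdk46_on=8.0),
            "c": k.EventRecord("c"),
        }
        cur = k.cumulative_fraction(recs, "cdk46_on", np.array([0.0, 6.0, 10.0]))
        np.testing.assert_allclose(cur.fraction, [0.0, 1 / 3, 2 / 3])
        assert cur.n_total == 3

    def test_unknown_event_rejected(self):
        with pytest.raises(ParameterError):
            k.cumulative_fraction({"a": k.EventRecord("a")}, "nonsense", np.array([1.0]))

    def test_dominance_chain_on_release_cohort(self, release_records):
        """CDK4/6-on dominates CDK2-on dominates APC/C-off at every time."""
        grid = np.arange(0.0, 24.01, 0.2)
        c46 = k.cumulative_fraction(release_records, "cdk46_on", grid).fraction
        c2 = k.cumulative_fraction(release_records, "cdk2_on", grid).fraction
        apc = k.cumulative_fraction(release_records, "apc_off", grid).fraction
        assert np.all(c46 >= c2 - 1e-12)
        assert np.all(c2 >= apc - 1e-12)
        # monotone and bounded by construction of the container
        assert np.all(np.diff(c46) >= 0) and c46[-1] <= 1.0


class TestMedianWithCI:
    def _aligned(self, rows):
        vals = np.asarray(rows, float)
        rel = np.arange(vals.shape[1]) * 0.2
        return k.AlignedMatrix(rel, vals, "mitogen_release", [str(i) for i in range(vals.shape[0])])

    def test_identical_rows_zero_width(self):
        al = self._aligned(np.tile(np.linspace(0, 1, 8), (12, 1)))
        out = k.median_with_ci(al, n_boot=200, seed=1)
        np.testing.assert_allclose(out["ci_hi"] - out["ci_lo"], 0.0, atol=1e-12)

    def test_median_of_constant_rows(self):
        al = self._aligned([[float(v)] * 5 for v in range(1, 12)])
        out = k.median_with_ci(al, n_boot=100, seed=1)
        np.testing.assert_allclose(out["median"], 6.0)

    def test_bootstrap_stability(self, rng):
        al = self._aligned(rng.normal(1.0, 0.3, size=(60, 6)))
        a = k.median_with_ci(al, n_boot=1000, seed=7)
        b = k.median_with_ci(al, n_boot=2000, seed=7)
        np.testing.assert_allclose(a["ci_lo"], b["ci_lo"], rtol=0.05, atol=0.02)
        np.testing.assert_allclose(a["ci_hi"], b["ci_hi"], rtol=0.05, atol=0.02)

    def test_too_few_rows_rejected(self):
        with pytest.raises(InsufficientDataError):
            k.median_with_ci(self._aligned(np.ones((4, 5))), n_boot=10, seed=0)


@pytest.fixture(scope="module")
def binned(stress_cohort, stress_records):
    fates = {
        tr.cell_id: classify_stress_outcome(tr, stress_records[tr.cell_id])
        for tr in stress_cohort.traces
        if stress_eligible(tr, stress_records[tr.cell_id])
    }
    return stress_cohort, stress_records, fates


class TestStressBins:
    def test_requires_stress_perturbation(self, release_cohort, release_records):
        with pytest.raises(ProtocolError):
            k.stress_exit_by_cdk2_bin(release_cohort, release_records, {"x": None})

    def test_empty_eligible_set_rejected(self, stress_cohort, stress_records):
        with pytest.raises(InsufficientDataError):
            k.stress_exit_by_cdk2_bin(stress_cohort, stress_records, {})

    def test_order_invariance(self, binned):
        cohort, records, fates = binned
        a = k.stress_exit_by_cdk2_bin(cohort, records, fates)
        rev = k.Cohort(
            traces=list(reversed(cohort.traces)),
            protocol=cohort.protocol,
            perturbation=cohort.perturbation,
            seed=cohort.seed,
        )
        b = k.stress_exit_by_cdk2_bin(rev, records, fates)
        pd.testing.assert_frame_equal(a, b)

    def test_split_and_pool_consistency(self, binned):
        cohort, records, fates = binned
        full = k.stress_exit_by_cdk2_bin(cohort, records, fates)
        half = len(cohort.traces) // 2
        parts = []
        for chunk in (cohort.traces[:half], cohort.traces[half:]):
            sub = k.Cohort(traces=list(chunk), protocol=cohort.protocol,
                           perturbation=cohort.perturbation, seed=cohort.seed)
            parts.append(k.stress_exit_by_cdk2_bin(sub, records, fates))
        pooled_n = parts[0]["n"] + parts[1]["n"]
        np.testing.assert_array_equal(pooled_n, full["n"])
        counts = sum(p["n"] * p["fraction_low"].fillna(0) for p in parts)
        np.testing.assert_allclose(
            counts, full["n"] * full["fraction_low"].fillna(0), atol=1e-9
        )

    def test_low_count_bins_flagged(self, binned):
        cohort, records, fates = binned
        out = k.stress_exit_by_cdk2_bin(cohort, records, fates)
        assert (out.loc[out["n"] < 5, "low_confidence"]).all()


class TestPhaseTrajectory:
    def test_unperturbed_high_group_shape(self, release_cohort, release_records):
        gt = release_cohort.ground_truth.set_index("cell_id")
        group = [
            c for c in release_cohort.cell_ids
            if gt.loc[c, "true_fate"] == "high" and gt.loc[c, "true_t_cdk46_on"] < 10
        ]
        traj = k.phase_trajectory(release_cohort, group, 12.0, 20.0)
        assert (traj["cdk46_corrected_median"] > 0.7).all()
        assert traj["cdk2_median"].iloc[-1] > traj["cdk2_median"].iloc[0]

    def test_too_small_group_rejected(self, release_cohort):
        with pytest.raises(InsufficientDataError):
            k.phase_trajectory(release_cohort, release_cohort.cell_ids[:3], 0.0, 5.0)


class TestRbPhosphoFractions:
    def test_class_fractions_reflect_mixture_tails(self, cycling_cohort):
        fates = classify_terminal_cdk46(cycling_cohort)
        thr = k.bimodal_threshold(cycling_cohort.fixed_cells["rb_phospho"].to_numpy())
        tab = k.fraction_rb_phospho_by_class(
            cycling_cohort, fates, thr, np.array([0.0, 20.0])
        )
        hi = tab[(tab["class"] == "high")]["fraction_phospho"].iloc[0]
        lo = tab[(tab["class"] == "low")]["fraction_phospho"].iloc[0]
        assert hi >= 0.95
        assert lo <= 0.05

    def test_missing_fixed_cells_rejected(self, release_cohort):
        with pytest.raises(ProtocolError):
            k.fraction_rb_phospho_by_class(release_cohort, {}, 1.0, np.array([0.0, 1.0]))
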