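"""Generator semantics: kinetics, fates, perturbations, determinism."""

import numpy as np
import pytest

import ktrcycle as k
from ktrcycle.errors import ParameterError, ProtocolError


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_activate": 2.0},
            {"mitotic_fate_probs": (0.5, 0.5, 0.5)},
            {"rise_time_cdk46": 6.0},  # must be < delay_range low bound
            {"n_cells": 0},
            {"f_true": 1.5},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            k.GeneratorParams(**kwargs)

    def test_short_duration_warns_and_flags_truncation(self):
        params = k.GeneratorParams(
            n_cells=40, duration=10.0, p_activate=1.0, seed=5
        )
        with pytest.warns(UserWarning, match="truncated"):
            co = k.simulate_quiescence_release(params)
        assert co.ground_truth["truncated"].any()


class TestReleaseKinetics:
    def test_event_ordering_holds_by_construction(self, noisefree_release):
        gt = noisefree_release.ground_truth
        done = gt[~gt["truncated"]]
        assert len(done) > 0
        assert (done["true_t_cdk46_on"] <= done["true_t_cdk2_on"]).all()
        assert (done["true_t_cdk2_on"] <= done["true_t_apc_off"]).all()

    def test_null_cohort_stays_at_baseline(self):
        co = k.simulate_quiescence_release(
            k.GeneratorParams(n_cells=30, p_activate=0.0, noise_sd=0.0, seed=2)
        )
        for tr in co.traces:
            assert np.ptp(tr.cdk46_raw) < 1e-9
            assert np.all(tr.apc_degron == 0)
        assert (co.ground_truth["true_fate"] == "low").all()

    def test_activation_fraction_within_binomial_band(self):
        n = 2000
        co = k.simulate_quiescence_release(
            k.GeneratorParams(n_cells=n, p_activate=0.54, seed=9)
        )
        frac = (co.ground_truth["true_fate"] == "high").mean()
        band = 1.96 * np.sqrt(0.54 * 0.46 / n)
        assert abs(frac - 0.54) <= band

    def test_activities_nonnegative_after_noise(self, release_cohort):
        for tr in release_cohort.traces:
            assert np.all(tr.cdk46_raw >= 0)
            assert np.all(tr.cdk2 >= 0)
            assert np.all(tr.apc_degron >= 0)

    def test_degron_nondecreasing_once_triggered(self, release_cohort):
        for lat in release_cohort.latent.cells:
            rising = lat.degron_true > 0
            if rising.any():
                seg = lat.degron_true[rising]
                assert np.all(np.diff(seg) >= -1e-12)


class TestCyclingFates:
    def test_all_high_cells_active_after_anaphase(self):
        co = k.simulate_cycling(
            k.GeneratorParams(
                n_cells=30, duration=14.0, noise_sd=0.0,
                mitotic_fate_probs=(1.0, 0.0, 0.0), seed=3,
            )
        )
        for tr, lat in zip(co.traces, co.latent.cells):
            i = tr.index_at(lat.anaphase + 2.0)
            corr = tr.cdk46_raw[i] - 0.35 * tr.cdk2[i]
            assert corr > 0.7

    def test_all_low_cells_never_accumulate_degron(self):
        co = k.simulate_cycling(
            k.GeneratorParams(
                n_cells=30, duration=14.0, mitotic_fate_probs=(0.0, 1.0, 0.0), seed=4,
            )
        )
        for tr, lat in zip(co.traces, co.latent.cells):
            post = tr.times >= lat.anaphase
            assert np.all(lat.degron_true[post] == 0)

    def test_delay_durations_within_configured_range(self, cycling_cohort):
        gt = cycling_cohort.ground_truth
        delays = gt.loc[gt["true_fate"] == "delay", "true_t_delay"]
        assert len(delays) > 0
        assert delays.between(2.0, 9.0).all()

    def test_rb_phospho_tracks_terminal_cdk46_state(self, cycling_cohort):
        gt = cycling_cohort.ground_truth.set_index("cell_id")
        fx = cycling_cohort.fixed_cells.set_index("cell_id")
        for lat in cycling_cohort.latent.cells:
            expect_high = lat.cdk46_true[-1] > 0.7
            rb = fx.loc[lat.cell_id, "rb_phospho"]
            # components at medians 1 and 10 (log-sd 0.3): 3.16 separates them
            assert (rb > 3.16) == expect_high or abs(np.log(rb) - np.log(3.16)) < 1.0


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        p = k.GeneratorParams(n_cells=20, seed=42)
        a = k.simulate_quiescence_release(p)
        b = k.simulate_quiescence_release(p)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.cdk46_raw, tb.cdk46_raw)
            np.testing.assert_array_equal(ta.cdk2, tb.cdk2)

    def test_different_seed_different_noise(self):
        a = k.simulate_quiescence_release(k.GeneratorParams(n_cells=5, seed=1))
        b = k.simulate_quiescence_release(k.GeneratorParams(n_cells=5, seed=2))
        assert not np.array_equal(a.traces[0].cdk46_raw, b.traces[0].cdk46_raw)


class TestPerturbations:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            k.PerturbationSpec(kind="sorbitol_bath")

    def test_perturbation_requires_latent(self, tmp_path, release_cohort):
        path = tmp_path / "c.csv"
        k.write_cohort(release_cohort, path)
        reread = k.read_cohort(path)
        with pytest.raises(ProtocolError):
            k.apply_perturbation(reread, k.PerturbationSpec(kind="stress"))

    def test_inhibitor_leaves_exact_cdk2_term_at_zero_noise(self):
        p = k.GeneratorParams(
            n_cells=10, noise_sd=0.0, p_activate=1.0, delay_range=(5, 6), seed=3
        )
        co = k.apply_perturbation(
            k.simulate_quiescence_release(p),
            k.PerturbationSpec(kind="cdk46_inhibitor", t_add=11.0, residual_fraction=0.0),
        )
        for tr in co.traces:
            after = tr.times >= 11.0 + 2 * tr.dt
            np.testing.assert_allclose(
                tr.cdk46_raw[after], 0.35 * tr.cdk2[after], atol=1e-12
            )

    def test_cdk2_inhibitor_reduces_raw_reporter_by_configured_fraction(self):
        p = k.GeneratorParams(
            n_cells=10, noise_sd=0.0, p_activate=1.0, delay_range=(5, 6), seed=3
        )
        base = k.simulate_quiescence_release(p)
        co = k.apply_perturbation(
            base, k.PerturbationSpec(kind="cdk2_inhibitor", t_add=11.0, cdk2_reduction=0.15)
        )
        for tr0, tr in zip(base.traces, co.traces):
            pre = np.interp(11.0, tr0.times, tr0.cdk46_raw)
            post = tr.cdk46_raw[tr.times >= 13.0].mean()
            assert 1 - post / pre == pytest.approx(0.15, abs=0.02)

    def test_stress_step_function_limit(self):
        base = k.simulate_quiescence_release(k.GeneratorParams(n_cells=400, seed=8))
        spec = k.PerturbationSpec(
            kind="stress", t_add=11.0, exit_logistic=(0.9, np.inf)
        )
        stressed = k.apply_perturbation(base, spec)
        gt = stressed.ground_truth.set_index("cell_id")
        for lat in base.latent.cells:
            g1 = not (np.isfinite(lat.t_apc_off) and lat.t_apc_off <= 11.0)
            c = float(np.interp(11.0, np.arange(lat.cdk2_true.size) * 0.2, lat.cdk2_true))
            resp = gt.loc[lat.cell_id, "responded_to_stress"]
            if g1:
                assert bool(resp) == (c < 0.9)
            else:
                assert not bool(resp)

    def test_stress_response_fraction_nonincreasing_in_cdk2(self, stress_cohort):
        """Ground-truth responder fraction falls with CDK2 at stress addition."""
        gt = stress_cohort.ground_truth.set_index("cell_id")
        cs, resp = [], []
        for lat in stress_cohort.latent.cells:
            if np.isfinite(lat.t_apc_off) and lat.t_apc_off <= 11.0:
                continue
            if not np.isfinite(lat.t_cross_cdk2) or lat.t_cross_cdk2 > 11.0:
                continue
            cs.append(float(np.interp(11.0, np.arange(lat.cdk2_true.size) * 0.2, lat.cdk2_true)))
            resp.append(bool(gt.loc[lat.cell_id, "responded_to_stress"]))
        cs, resp = np.asarray(cs), np.asarray(resp)
        edges = np.array([0.76, 0.86, 0.96, 1.06])
        fracs = [
            resp[(cs >= lo) & (cs < hi)].mean()
            for lo, hi in zip(edges[:-1], edges[1:])
            if ((cs >= lo) & (cs < hi)).sum() >= 10
        ]
        assert all(b <= a + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_exit_probability_monotone_and_limits(self):
        spec = k.PerturbationSpec(kind="stress", exit_logistic=(0.9, 10.0))
        grid = np.linspace(0.3, 1.3, 21)
        ps = [spec.exit_probability(c) for c in grid]
        assert all(b <= a for a, b in zip(ps, ps[1:]))
        assert spec.exit_probability(0.3) > 0.99
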