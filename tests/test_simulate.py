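"""Mechanistic simulator: ODE correctness, invariants, reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hyperkinetics as hk
from hyperkinetics.simulate import ph_time_course, simulate_trajectory


def held_pulse_schedule(conc=500.0, start=1.0, duration=29.0, dt_s=20.0):
    return hk.ProtocolSchedule(
        (hk.Event(start, "pulse_start", conc_uM=conc),
         hk.Event(start + duration, "pulse_end")),
        duration_min=start + duration, sample_interval_s=dt_s,
    )


class TestIntracellularH2O2:
    def test_decoupled_cell_stays_at_zero(self):
        kin = hk.KineticParams(k_ox=0.01, k_red=1.0, perm=0.0, prod=0.0, cons=0.0)
        t, hi = hk.simulate_h2o2_intracellular(held_pulse_schedule(), kin, h0=0.0)
        assert np.allclose(hi, 0.0, atol=1e-12)

    def test_prod_cons_steady_state(self):
        # closed cell (perm=0): Hi -> prod/cons = 1.0 µM
        kin = hk.KineticParams(k_ox=0.01, k_red=1.0, perm=0.0, prod=0.1, cons=0.1)
        sch = hk.ProtocolSchedule((), duration_min=300.0, sample_interval_s=60.0)
        t, hi = hk.simulate_h2o2_intracellular(sch, kin, h0=0.0)
        assert hi[-1] == pytest.approx(1.0, rel=1e-4)

    def test_held_pulse_plateau_matches_linear_ode(self):
        # plateau Hi = perm*He/(perm+cons) = 10*500/12
        kin = hk.KineticParams(k_ox=0.01, k_red=1.0, perm=10.0, prod=0.0, cons=2.0)
        t, hi = hk.simulate_h2o2_intracellular(held_pulse_schedule(), kin, h0=0.0)
        assert hi[-1] == pytest.approx(10 * 500 / 12, rel=1e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(hk.ParameterError):
            hk.KineticParams(k_ox=-0.01, k_red=1.0, perm=0.0, prod=0.0, cons=0.0)

    def test_h2o2_never_negative(self, two_pulse_schedule):
        kin = hk.compartment_preset("mitochondrion").kinetics
        _, hi = hk.simulate_h2o2_intracellular(two_pulse_schedule, kin)
        assert np.all(hi >= 0.0)


class TestOxidizedFraction:
    def test_pure_decay_matches_closed_form(self):
        t = np.linspace(0.0, 10.0, 301)
        kin = hk.KineticParams(k_ox=0.01, k_red=1.0, perm=0.0, prod=0.0, cons=0.0)
        theta = hk.simulate_oxidized_fraction(t, np.zeros_like(t), kin, theta0=0.8)
        expected = 0.8 * np.exp(-1.0 * t)
        assert np.allclose(theta, expected, rtol=1e-6, atol=1e-12)

    def test_constant_h2o2_steady_state(self):
        # θ_ss = k_ox·H/(k_ox·H + k_red) = 5/6 at H=500, k_ox=0.01, k_red=1
        t = np.linspace(0.0, 20.0, 601)
        kin = hk.KineticParams(k_ox=0.01, k_red=1.0, perm=0.0, prod=0.0, cons=0.0)
        theta = hk.simulate_oxidized_fraction(t, np.full_like(t, 500.0), kin, 0.0)
        assert theta[-1] == pytest.approx(5.0 / 6.0, rel=1e-6)

    def test_theta0_out_of_range_rejected(self):
        kin = hk.KineticParams(k_ox=0.01, k_red=1.0, perm=0.0, prod=0.0, cons=0.0)
        with pytest.raises(hk.ParameterError):
            hk.simulate_oxidized_fraction(np.arange(5.0), np.zeros(5), kin, 1.2)

    def test_mitochondrial_theta_declines_during_sustained_pulse(self):
        kin = hk.compartment_preset("mitochondrion").kinetics
        sch = held_pulse_schedule(conc=500.0, start=2.0, duration=20.0)
        t, _, theta = simulate_trajectory(sch, kin)
        in_pulse = (t >= 2.0) & (t <= 22.0)
        th = theta[in_pulse]
        ipk = int(np.argmax(th))
        assert ipk < len(th) - 1  # peak occurs before the pulse ends
        assert th[-1] < 0.9 * th[ipk]  # then clearly declines under oxidant

    @given(
        k_ox=st.floats(0.001, 0.1),
        k_red=st.floats(0.05, 5.0),
        perm=st.floats(0.0, 50.0),
        prod=st.floats(0.0, 5.0),
        cons=st.floats(0.1, 20.0),
        theta0=st.floats(0.0, 1.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_trajectory_invariants(self, k_ox, k_red, perm, prod, cons, theta0):
        """θ stays in [0,1] and Hi stays >= 0 for arbitrary viable kinetics."""
        kin = hk.KineticParams(k_ox=k_ox, k_red=k_red, perm=perm, prod=prod, cons=cons)
        sch = hk.default_two_pulse_schedule(baseline_min=2.0, washout_min=3.0,
                                            recovery_min=5.0, sample_interval_s=30.0)
        _, hi, theta = simulate_trajectory(sch, kin, theta0=theta0)
        assert np.all(hi >= 0.0)
        assert np.all((theta >= 0.0) & (theta <= 1.0))


class TestRenderFluorescence:
    def test_constant_state_renders_constant_channels(self):
        fluor = hk.compartment_preset("cytosol").without_noise().fluor
        f420, f490 = hk.render_fluorescence(np.zeros(10), 7.2, fluor)
        assert np.ptp(f420) == 0 and np.ptp(f490) == 0
        assert np.all(f420 > 0) and np.all(f490 > 0)

    def test_reciprocal_response_to_oxidation_step(self):
        fluor = hk.compartment_preset("cytosol").without_noise().fluor
        theta = np.array([0.0, 1.0])
        f420, f490 = hk.render_fluorescence(theta, 7.2, fluor)
        assert f420[1] < f420[0]  # 420-nm signal drops on oxidation
        assert f490[1] > f490[0]  # 490-nm signal rises simultaneously

    def test_noise_seed_reproducibility(self):
        fluor = hk.compartment_preset("cytosol").fluor
        theta = np.linspace(0, 1, 50)
        a = hk.render_fluorescence(theta, 7.2, fluor, seed=42)
        b = hk.render_fluorescence(theta, 7.2, fluor, seed=42)
        c = hk.render_fluorescence(theta, 7.2, fluor, seed=43)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert not np.array_equal(a[0], c[0])


class TestSimulateExperiment:
    def test_two_pulse_trace_morphology(self, cytosol_noiseless_experiment,
                                        two_pulse_schedule):
        """Baseline, submaximal plateau, saturating peak, spontaneous decay."""
        rt = hk.compute_ratio(cytosol_noiseless_experiment.traces[0])
        seg = hk.segment_phases(two_pulse_schedule, rt.time_min)
        t, r = rt.time_min, rt.ratio

        def win(iv):
            return r[(t >= iv[0]) & (t < iv[1])]

        base, p1, p2, rec = win(seg.baseline), win(seg.pulse1), win(seg.pulse2), \
            win(seg.recovery)
        assert np.ptp(base) < 0.01 * base.mean()  # flat baseline
        assert p1.max() > base.mean() * 1.5  # submaximal response
        assert p2.max() > p1.max()  # saturating peak is larger
        # spontaneous decay back toward baseline after washout
        assert rec[-1] - base.mean() < 0.1 * (p2.max() - base.mean())

    def test_zero_cell_cv_gives_identical_traces(self, two_pulse_schedule):
        pre = hk.compartment_preset("cytosol").without_noise()
        exp = hk.simulate_experiment(pre, None, two_pulse_schedule, n_cells=5,
                                     cell_cv=0.0, seed=7)
        ref = exp.traces[0]
        for tr in exp.traces[1:]:
            assert np.array_equal(tr.f420, ref.f420)
            assert np.array_equal(tr.f490, ref.f490)

    def test_equal_seeds_bitwise_identical(self, two_pulse_schedule):
        pre = hk.compartment_preset("cytosol")
        a = hk.simulate_experiment(pre, None, two_pulse_schedule, n_cells=3, seed=11)
        b = hk.simulate_experiment(pre, None, two_pulse_schedule, n_cells=3, seed=11)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.f420, tb.f420)
            assert np.array_equal(ta.f490, tb.f490)
        assert a.truth.equals(b.truth)

    def test_perturbation_recorded_in_truth(self, two_pulse_schedule):
        pre = hk.compartment_preset("cytosol")
        pert = hk.perturbation_preset("auranofin100")
        exp = hk.simulate_experiment(pre, pert, two_pulse_schedule, n_cells=2,
                                     cell_cv=0.0, seed=0)
        expected = pre.kinetics.k_red * pert.k_red_scale
        assert exp.truth["k_red"].to_numpy() == pytest.approx(expected)
        assert (exp.truth["perturbation"] == "auranofin100").all()

    def test_washout_only_perturbation_spares_the_pulse_phase(self,
                                                              two_pulse_schedule):
        """PX-12 scales k_red only after the final washout: the in-pulse
        trajectory must match control, the recovery must be slower."""
        pre = hk.compartment_preset("cytosol").without_noise()
        pert = hk.perturbation_preset("px12_10uM")
        ctrl = hk.simulate_experiment(pre, None, two_pulse_schedule, 1, 0.0, 0)
        trt = hk.simulate_experiment(pre, pert, two_pulse_schedule, 1, 0.0, 0)
        t_end = two_pulse_schedule.final_pulse_end
        t = ctrl.traces[0].time_min
        pre_mask = t <= t_end
        assert np.allclose(ctrl.traces[0].f490[pre_mask],
                           trt.traces[0].f490[pre_mask], rtol=1e-9)
        k_ctrl = hk.analyze_trace(ctrl.traces[0], two_pulse_schedule).fit.k
        k_trt = hk.analyze_trace(trt.traces[0], two_pulse_schedule).fit.k
        assert k_trt < k_ctrl
        assert k_trt == pytest.approx(k_ctrl * pert.k_red_scale, rel=0.05)

    def test_increasing_k_red_increases_fitted_rate(self, two_pulse_schedule):
        rates = []
        for k in (0.4, 0.8, 1.6):
            pre = hk.compartment_preset("cytosol").with_k_red(k).without_noise()
            exp = hk.simulate_experiment(pre, None, two_pulse_schedule, 1, 0.0, 0)
            rates.append(hk.analyze_trace(exp.traces[0], two_pulse_schedule).fit.k)
        assert rates[0] < rates[1] < rates[2]

    def test_increasing_consumption_lowers_peak_theta(self):
        sch = hk.single_pulse_schedule()
        peaks = []
        for cons in (2.0, 8.0, 32.0):
            kin = hk.KineticParams(k_ox=0.04, k_red=1.0, perm=15.0, prod=0.5,
                                   cons=cons)
            _, _, theta = simulate_trajectory(sch, kin)
            peaks.append(theta.max())
        assert peaks[0] > peaks[1] > peaks[2]


class TestPhClamp:
    def test_clamp_shifts_baseline_but_not_rate(self):
        fits, basals = [], []
        for ph in (6.5, 7.0, 7.5):
            sch = hk.ph_clamp_schedule(ph)
            pre = hk.fast_kinetics_preset(50.7, noise_cv=0.0)
            exp = hk.simulate_ph_clamp(pre, sch, n_cells=1, cell_cv=0.0, seed=0)
            rec = hk.analyze_trace(exp.traces[0], sch)
            fits.append(rec.fit.k)
            basals.append(rec.r_basal)
        assert basals[0] < basals[1] < basals[2]  # baseline rises with pH
        assert (max(fits) - min(fits)) / min(fits) < 0.03  # one underlying k_red

    def test_clamp_to_resting_ph_leaves_baseline_unchanged(self):
        pre = hk.fast_kinetics_preset(50.7, noise_cv=0.0)
        sch_free = hk.fine_sampling_schedule(baseline_min=3.0)
        sch_clamp = hk.ph_clamp_schedule(pre.ph)
        b_free = hk.analyze_trace(
            hk.simulate_experiment(pre, None, sch_free, 1, 0.0, 0).traces[0],
            sch_free).r_basal
        b_clamp = hk.analyze_trace(
            hk.simulate_ph_clamp(pre, sch_clamp, 1, 0.0, 0).traces[0],
            sch_clamp).r_basal
        assert b_clamp == pytest.approx(b_free, rel=1e-9)

    def test_schedule_without_clamp_rejected(self):
        with pytest.raises(hk.ScheduleError):
            hk.simulate_ph_clamp(hk.fast_kinetics_preset(50.0),
                                 hk.fine_sampling_schedule())

    def test_ph_time_course_relaxes_to_target(self):
        sch = hk.ph_clamp_schedule(6.5)
        ph = ph_time_course(sch, resting_ph=7.2)
        assert ph[0] == pytest.approx(7.2)
        assert ph[-1] == pytest.approx(6.5, abs=1e-3)


class TestMigrationCohort:
    def test_noise_free_cohort_is_perfectly_correlated(self):
        rec = hk.simulate_migration_cohort(noise_sd=0.0, seed=0)
        prof = [(m.recovery_rate, m.migration_efficiency) for m in rec]
        x, y = zip(*prof)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_slope_decorrelates(self):
        rs = []
        for seed in range(200):
            rec = hk.simulate_migration_cohort(coupling_slope=0.0, seed=seed)
            x = [m.recovery_rate for m in rec]
            y = [m.migration_efficiency for m in rec]
            rs.append(np.corrcoef(x, y)[0, 1])
        assert abs(np.mean(rs)) < 0.08

    def test_cohort_needs_three_lines(self):
        with pytest.raises(hk.ParameterError):
            hk.simulate_migration_cohort(lines=[("a", 1.0), ("b", 2.0)])

    def test_efficiencies_bounded(self):
        for seed in range(20):
            for m in hk.simulate_migration_cohort(seed=seed, noise_sd=50.0):
                assert 0.0 <= m.migration_efficiency <= 100.0
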