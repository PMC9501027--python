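"""Simulator unit and property tests: schedules, dosing, curves, noise, cohorts."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dynpet.kinetics_sim import (
    CohortSpec,
    FrameSchedule,
    InputFunctionParams,
    PlasmaInputFunction,
    TissueKinetics,
    add_noise,
    as_curve,
    bmi_adapted_dose,
    build_phantom,
    generate_cohort,
    lognormal_sigma,
    macro_patlak_curve,
    make_study_schedule,
    plasma_curve,
    sample_frames,
    solve_2tc_irreversible,
)


class TestSchedule:
    def test_study_protocol_layout(self):
        s = make_study_schedule(5, 11, 5, 35)
        # early cardiac segment: 12x5 + 4x10 + 8x25 + 5x60 s = 10 min
        assert s.n_frames == 24 + 5 + 11
        early_end = s.frame_start[29]
        assert early_end == pytest.approx(10.0)
        # first whole-body frame starts immediately after the early segment
        assert s.frame_start[29] == pytest.approx(10.0)
        # revisit gap of the tracked bed = n_beds * sec_per_bed
        gaps = np.diff(s.frame_start[29:]) * 60.0
        assert gaps == pytest.approx(175.0)
        assert s.bed_label[0] == "cardiac" and s.bed_label[-1] == "wb"

    def test_early_only_schedule(self):
        s = make_study_schedule(0, 0, 5, 35)
        assert s.n_frames == 24
        assert s.end_times[-1] == pytest.approx(5.0)

    def test_frames_validated(self):
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0, 0.5]), np.array([1.0, 1.0]))  # overlap
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0]), np.array([0.0]))  # zero duration
        with pytest.raises(ValueError):
            make_study_schedule(-1, 0, 1, 35)

    def test_mid_times(self):
        s = FrameSchedule(np.array([0.0, 2.0]), np.array([2.0, 4.0]))
        assert s.mid_times == pytest.approx([1.0, 4.0])


class TestDose:
    @pytest.mark.parametrize(
        "weight,height,expected",
        [
            (55, 1.72, 82.5),  # BMI 18.6 -> 1.5 MBq/kg
            (146, 1.86, 320.0),  # BMI 42.2 -> 3.1 MBq/kg capped at 320
            (60, 1.73, 120.0),  # BMI 20.0 boundary -> 2 MBq/kg
            (82, 1.71, pytest.approx(254.2)),  # BMI 28 -> 3.1 MBq/kg
        ],
    )
    def test_bands_and_cap(self, weight, height, expected):
        assert bmi_adapted_dose(weight, height) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            bmi_adapted_dose(0, 1.7)
        with pytest.raises(ValueError):
            bmi_adapted_dose(70, -1)


class TestPlasmaCurve:
    def test_zero_at_injection_and_peak_continuity(self, if_params):
        assert plasma_curve(if_params, 0.0) == 0.0
        assert plasma_curve(if_params, if_params.peak_time) == pytest.approx(
            if_params.peak_amplitude
        )

    def test_equal_rates_collapse_to_single_exponential(self):
        lam = 0.2
        p = InputFunctionParams(A1=1.0, A2=1.0, lambda1=lam, lambda2=lam,
                                peak_time=0.5, peak_amplitude=10.0)
        t = p.peak_time + 1.0 / lam
        assert plasma_curve(p, t) == pytest.approx(p.peak_amplitude / np.e)

    def test_nonnegative_everywhere(self, if_params):
        t = np.linspace(0, 70, 2000)
        assert np.all(plasma_curve(if_params, t) >= 0)

    def test_cached_integral_matches_closed_form(self, if_params):
        cp = PlasmaInputFunction.from_params(if_params, t_end=70.0)
        p = if_params
        scale = p.peak_amplitude / (p.A1 + p.A2)
        for t in (10.0, 30.0, 60.0):
            dt = t - p.peak_time
            closed = (
                p.peak_amplitude * p.peak_time / 2
                + scale * p.A1 / p.lambda1 * (1 - np.exp(-p.lambda1 * dt))
                + scale * p.A2 / p.lambda2 * (1 - np.exp(-p.lambda2 * dt))
            )
            assert cp.cumint(t) == pytest.approx(closed, rel=1e-5)


class TestTwoTissueCompartment:
    def test_matches_high_resolution_ode_oracle(self, cp_fine):
        kin = TissueKinetics.micro(K1=0.1, k2=0.15, k3=0.05, vb=0.05)

        def rhs(t, y):
            c = cp_fine(t)
            return [kin.K1 * c - (kin.k2 + kin.k3) * y[0], kin.k3 * y[0]]

        t_eval = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 60.0])
        sol = solve_ivp(rhs, (0.0, 70.0), [0.0, 0.0], t_eval=t_eval,
                        rtol=1e-10, atol=1e-12, method="LSODA")
        oracle = sol.y[0] + sol.y[1] + kin.vb * cp_fine(t_eval)
        mine = solve_2tc_irreversible(kin, cp_fine, t_eval)
        assert np.all(np.abs(mine - oracle) / oracle < 1e-4)

    def test_no_influx_means_no_tissue_activity(self, cp_fine):
        kin = TissueKinetics.micro(K1=0.0, k2=0.3, k3=0.1)
        assert np.all(solve_2tc_irreversible(kin, cp_fine) == 0)

    def test_pure_accumulation_with_constant_input(self):
        grid = np.arange(0.0, 50.0 + 0.005, 0.01)
        cp = PlasmaInputFunction(grid=grid, values=np.ones_like(grid))
        kin = TissueKinetics.micro(K1=0.1, k2=0.0, k3=0.4)
        ct = solve_2tc_irreversible(kin, cp, np.array([10.0, 30.0]))
        assert ct == pytest.approx([1.0, 3.0], rel=1e-6)

    def test_divided_patlak_plot_slope_approaches_ki(self, cp_fine):
        kin = TissueKinetics.micro(K1=0.1, k2=0.15, k3=0.05, vb=0.0)
        ct = as_curve(cp_fine.grid, solve_2tc_irreversible(kin, cp_fine))
        t1, t2 = 45.0, 50.0
        num = ct(t2) / cp_fine(t2) - ct(t1) / cp_fine(t1)
        den = cp_fine.cumint(t2) / cp_fine(t2) - cp_fine.cumint(t1) / cp_fine(t1)
        assert num / den == pytest.approx(kin.ki_macro, rel=0.02)

    def test_nonnegative(self, cp_fine):
        kin = TissueKinetics.micro(K1=0.3, k2=0.5, k3=0.02, vb=0.03)
        assert np.all(solve_2tc_irreversible(kin, cp_fine) >= 0)


class TestMacroCurve:
    def test_pure_blood_pool_equals_cp(self, cp_fine):
        kin = TissueKinetics.macro(Ki=0.0, Vd=1.0)
        t = np.linspace(0, 60, 500)
        assert macro_patlak_curve(kin, cp_fine, t) == pytest.approx(cp_fine(t))

    def test_pure_trapping_with_unit_input(self):
        grid = np.arange(0.0, 40.0 + 0.005, 0.01)
        cp = PlasmaInputFunction(grid=grid, values=np.ones_like(grid))
        kin = TissueKinetics.macro(Ki=0.03, Vd=0.0)
        assert macro_patlak_curve(kin, cp, 20.0) == pytest.approx(0.6, rel=1e-9)


class TestFrameSampling:
    def test_constant_curve_is_exact(self, study_schedule):
        frames = sample_frames(lambda t: np.full_like(np.asarray(t, float), 3.5),
                               study_schedule)
        assert frames == pytest.approx(3.5)

    def test_ramp_mean(self):
        s = FrameSchedule(np.array([0.0]), np.array([10.0]))
        assert sample_frames(lambda t: np.asarray(t, float), s) == pytest.approx([5.0])

    def test_exponential_closed_form(self):
        s = FrameSchedule(np.array([0.0]), np.array([1.0]))
        val = sample_frames(lambda t: np.exp(-np.asarray(t, float)), s, n_sub=256)
        assert val == pytest.approx([1 - np.exp(-1)], rel=1e-5)

    def test_error_beyond_support(self, cp_fine):
        s = FrameSchedule(np.array([65.0]), np.array([10.0]))
        with pytest.raises(ValueError, match="support"):
            sample_frames(cp_fine, s)


class TestNoise:
    def test_zero_scale_is_identity(self, study_schedule):
        frames = np.linspace(0, 5, study_schedule.n_frames)
        out = add_noise(frames, study_schedule, 0.0, seed=3)
        assert np.array_equal(out, frames)

    def test_seed_determinism(self, study_schedule):
        frames = np.ones(study_schedule.n_frames)
        a = add_noise(frames, study_schedule, 0.1, seed=42)
        b = add_noise(frames, study_schedule, 0.1, seed=42)
        assert np.array_equal(a, b)
        c = add_noise(frames, study_schedule, 0.1, seed=43)
        assert not np.array_equal(a, c)

    def test_monte_carlo_standard_deviation(self):
        s = FrameSchedule(np.array([0.0]), np.array([1.0]))
        reps = add_noise(np.ones((10_000, 1)), s, 0.05, seed=0)
        assert reps.std() == pytest.approx(0.05, rel=0.05)

    def test_negative_scale_rejected(self, study_schedule):
        with pytest.raises(ValueError):
            add_noise(np.ones(study_schedule.n_frames), study_schedule, -0.1, 0)


class TestPhantom:
    def test_aorta_tac_equals_whole_blood_curve(self, small_phantom):
        ph = small_phantom
        wb_true = sample_frames(
            lambda t: ph.cp_truth(t) / np.asarray(ph.partition(t), float),
            ph.schedule, support=(0, ph.cp_truth.grid[-1]),
        )
        voxels = ph.activity[ph.labels == 1]
        assert voxels == pytest.approx(np.tile(wb_true, (voxels.shape[0], 1)))

    def test_shapes_consistent(self, small_phantom):
        assert small_phantom.activity.shape[:3] == small_phantom.labels.shape
        assert small_phantom.activity.shape[3] == small_phantom.schedule.n_frames

    def test_unknown_label_rejected(self, if_params, study_schedule):
        truth = {1: TissueKinetics.macro(0.0, 1.0), 2: TissueKinetics.macro(0.01, 1.0)}
        labels = np.zeros((8, 8, 8), dtype=int)
        labels[0] = 1
        labels[1] = 2
        labels[2] = 9  # no kinetics for label 9
        with pytest.raises(ValueError, match="9"):
            build_phantom((8, 8, 8), 4.0, truth, if_params, study_schedule,
                          labels=labels)


class TestCohort:
    def test_counts_and_reproducibility(self):
        spec = CohortSpec(seed=123)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        assert len(a.records) == 77
        assert (a.records.group == "cancer").sum() == 60
        assert a.records.equals(b.records)
        assert np.array_equal(a.lesion_tacs, b.lesion_tacs)

    def test_zero_spread_collapses_to_medians(self):
        spec = CohortSpec(ki_iqr_cancer=0.0, ki_iqr_inflammatory=0.0, seed=1)
        coh = generate_cohort(spec)
        cancer = coh.records[coh.records.group == "cancer"]
        assert np.all(cancer.true_ki == spec.ki_median_cancer)

    def test_median_ratio_at_large_n(self):
        spec = CohortSpec(n_cancer=10_000, n_inflammatory=10_000, noise_scale=0.0,
                          seed=2024)
        coh = generate_cohort(spec)
        med_c = coh.records[coh.records.group == "cancer"].true_ki.median()
        med_i = coh.records[coh.records.group == "inflammatory"].true_ki.median()
        expected = spec.ki_median_cancer / spec.ki_median_inflammatory
        assert med_c / med_i == pytest.approx(expected, rel=0.05)

    def test_lognormal_sigma_zero_iqr(self):
        assert lognormal_sigma(3.0, 0.0) == 0.0
        with pytest.raises(ValueError):
            lognormal_sigma(-1.0, 0.5)
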