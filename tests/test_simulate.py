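"""Phantom generators and the synthetic cohort's statistical structure."""

import numpy as np
import pytest
from scipy.special import expit

from xerograd import (
    CohortSimConfig,
    CourseTrajectory,
    PhantomSpec,
    make_gland_mask,
    make_phantom_dose,
    simulate_cohort,
    simulate_course,
)
from xerograd.evaluate import kendall_concordance
from xerograd.grids import GridValidationError
from xerograd.simulate import SimulationError


class TestPhantomDose:
    def test_half_dose_at_falloff_center(self, small_phantom):
        dose = make_phantom_dose(small_phantom)
        i_center = int(round(small_phantom.falloff_center_mm / small_phantom.spacing_mm[0]))
        assert dose.values[i_center, 0, 0] == pytest.approx(
            small_phantom.plateau_dose_gy / 2
        )

    def test_large_falloff_scale_approaches_uniform_half_plateau(self, small_phantom):
        spec = PhantomSpec(**{**small_phantom.__dict__, "falloff_scale_mm": 1e9})
        dose = make_phantom_dose(spec)
        assert np.allclose(dose.values, spec.plateau_dose_gy / 2, atol=1e-6)

    def test_logistic_value_one_scale_from_center(self, small_phantom):
        dose = make_phantom_dose(small_phantom)
        x = small_phantom.falloff_center_mm + 5.0  # one falloff scale medially
        i = int(round(x / small_phantom.spacing_mm[0]))
        assert dose.values[i, 0, 0] == pytest.approx(40 * expit(1.0), abs=1e-9)

    def test_bounded_by_plateau(self, small_phantom):
        dose = make_phantom_dose(small_phantom)
        assert dose.values.min() >= 0 and dose.values.max() <= 40

    def test_degenerate_spec_rejected(self):
        with pytest.raises(GridValidationError):
            PhantomSpec(grid_shape=(2, 5, 5))
        with pytest.raises(GridValidationError):
            PhantomSpec(falloff_scale_mm=0.0)


class TestGlandMask:
    def test_sphere_matches_brute_force_voxel_enumeration(self):
        spec = PhantomSpec(
            grid_shape=(21, 21, 21),
            spacing_mm=(2.0, 2.0, 2.0),
            falloff_center_mm=30.0,
            gland_center_mm=(20.0, 20.0, 20.0),
            gland_radii_mm=(10.0, 10.0, 10.0),
        )
        mask = make_gland_mask(spec)
        count = 0
        for i in range(21):
            for j in range(21):
                for k in range(21):
                    c = np.array([i, j, k]) * 2.0
                    if np.sum((c - 20.0) ** 2) <= 100.0:
                        count += 1
        assert mask.n_voxels == count

    def test_single_voxel_mask_at_center(self):
        spec = PhantomSpec(
            grid_shape=(11, 11, 11),
            spacing_mm=(2.0, 2.0, 2.0),
            falloff_center_mm=10.0,
            gland_center_mm=(10.0, 10.0, 10.0),
            gland_radii_mm=(1.0, 1.0, 1.0),
        )
        assert make_gland_mask(spec).n_voxels == 1

    def test_oversized_gland_rejected(self):
        with pytest.raises(GridValidationError):
            PhantomSpec(
                grid_shape=(11, 11, 11),
                spacing_mm=(1.0, 1.0, 1.0),
                gland_center_mm=(5.0, 5.0, 5.0),
                gland_radii_mm=(50.0, 5.0, 5.0),
            )


class TestCourse:
    def test_zero_rate_keeps_all_masks_identical(self, small_phantom):
        mask = make_gland_mask(small_phantom)
        masks = simulate_course(
            mask, CourseTrajectory((0, 10, 20), 0.0), small_phantom.spacing_mm, 0
        )
        for m in masks:
            assert np.array_equal(m.values, mask.values)

    def test_rate_times_day_translates_whole_voxels(self, small_phantom):
        mask = make_gland_mask(small_phantom)
        masks = simulate_course(
            mask, CourseTrajectory((0, 20), 0.05), small_phantom.spacing_mm, 0
        )
        assert np.array_equal(masks[1].values[1:], mask.values[:-1])  # 1 voxel medial

    def test_voxel_count_conserved_over_course(self, small_phantom):
        mask = make_gland_mask(small_phantom)
        masks = simulate_course(
            mask, CourseTrajectory(tuple(range(0, 31, 5)), 0.3),
            small_phantom.spacing_mm, 0,
        )
        assert {m.n_voxels for m in masks} == {mask.n_voxels}

    def test_mask_leaving_grid_rejected(self, small_phantom):
        mask = make_gland_mask(small_phantom)
        with pytest.raises(SimulationError):
            simulate_course(
                mask, CourseTrajectory((0, 40), 2.0), small_phantom.spacing_mm, 0
            )

    def test_invalid_days_rejected(self):
        with pytest.raises(SimulationError):
            CourseTrajectory((1, 2), 0.1)
        with pytest.raises(SimulationError):
            CourseTrajectory((0, 5, 5), 0.1)


class TestCohort:
    def test_seed_determinism_is_byte_identical(self, tmp_path):
        a = simulate_cohort(CohortSimConfig(seed=9))
        b = simulate_cohort(CohortSimConfig(seed=9))
        pa = a.write(tmp_path / "a")
        pb = b.write(tmp_path / "b")
        for name in pa:
            assert pa[name].read_bytes() == pb[name].read_bytes()

    def test_distribution_recovery_at_large_n(self):
        cfg = CohortSimConfig(n_patients=10_000, seed=3)
        cohort = simulate_cohort(cfg).cohort
        for col, (mean, sd) in (
            ("md_contra_gy", cfg.md_contra_mean_sd),
            ("md_ipsi_gy", cfg.md_ipsi_mean_sd),
        ):
            se = sd / np.sqrt(len(cohort))
            assert abs(cohort[col].mean() - mean) < 3 * se
            assert abs(cohort[col].std() - sd) < 3 * sd / np.sqrt(2 * len(cohort))
        # log-normal gradient: median recovery
        assert np.median(cohort["gradx_contra_gypermm"]) == pytest.approx(
            cfg.gradx_median, rel=0.05
        )

    def test_copula_recovers_kendall_tau(self):
        cohort = simulate_cohort(CohortSimConfig(n_patients=5_000, seed=4)).cohort
        tau = kendall_concordance(
            cohort["md_contra_gy"], cohort["md_ipsi_gy"]
        ).tau
        assert tau == pytest.approx(0.5, abs=0.05)
        assert tau > 0.4  # the ipsi/contra concordance screen threshold

    def test_zero_coefficients_hit_configured_prevalence(self):
        cfg = CohortSimConfig(
            n_patients=50_000,
            coefficients={"md": 0.0, "gradx": 0.0, "dose_increment": 0.0},
            seed=5,
        )
        cohort = simulate_cohort(cfg).cohort
        assert cohort["label"].mean() == pytest.approx(0.114, abs=0.005)

    def test_mechanism_partial_association(self):
        # positive generating weight on the delivered-dose increment must
        # surface as a positive outcome association of GRADX*PGM given MD
        cohort = simulate_cohort(CohortSimConfig(n_patients=20_000, seed=6)).cohort
        inc = cohort["gradx_contra_gypermm"] * cohort["pgm_mm"]
        hi = cohort[inc > inc.median()]["label"].mean()
        lo = cohort[inc <= inc.median()]["label"].mean()
        assert hi > lo

    def test_both_classes_guaranteed_or_error(self):
        cohort = simulate_cohort(CohortSimConfig(n_patients=30, seed=11)).cohort
        assert 0 < cohort["label"].sum() < 30

    def test_reports_stay_in_window_and_valid_grades(self):
        sim = simulate_cohort(CohortSimConfig(seed=12))
        r = sim.reports
        assert (r["months_after_rt"] >= 6).all() and (r["months_after_rt"] <= 24).all()
        assert r["grade"].between(0, 4).all()
        assert set(r["patient_id"]) == set(sim.cohort["patient_id"])

    def test_volume_series_reproduces_configured_change(self):
        cfg = CohortSimConfig(n_patients=2000, seed=13)
        vols = simulate_cohort(cfg).volumes
        wide = vols.pivot(index="patient_id", columns="day", values="vc2_ml")
        first = wide[0].to_numpy()
        control = wide.drop(columns=0).stack().groupby("patient_id").first()
        dv = 100 * (control.to_numpy() / first - 1)
        assert np.nanmean(dv) == pytest.approx(-2.0, abs=3 * 4.2 / np.sqrt(2000))

    def test_invalid_configs_rejected(self):
        with pytest.raises(SimulationError):
            CohortSimConfig(n_patients=2)
        with pytest.raises(SimulationError):
            CohortSimConfig(ipsi_contra_tau=1.0)
        with pytest.raises(SimulationError):
            CohortSimConfig(coefficients={"nope": 1.0})
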