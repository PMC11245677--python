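"""First-exit-time simulations against the analytic sphere-exit oracle."""

import numpy as np
import pytest

from segclock.errors import DomainError
from segclock.nuclear_export import (
    DiffusionSettings,
    calibrate_scale,
    export_delay,
    first_exit_steps,
    generate_path_increments,
    mfet_analytic,
    radius_sweep,
    sweep_frame,
)

REF_RADIUS = 3.0
REF_TIME = 3.36  # minutes; zebrafish her1 export time


@pytest.fixture(scope="module")
def bm_settings():
    return DiffusionSettings(mode="normal", n_trajectories=4000, rng_seed=11)


@pytest.fixture(scope="module")
def bm_scale(bm_settings):
    return calibrate_scale(bm_settings, REF_RADIUS, REF_TIME)


class TestAnalyticMfet:
    @pytest.mark.parametrize(
        "radius, expected", [(3.0, 3.0**2 / (6 * 0.45)), (6.0, 6.0**2 / (6 * 0.45))]
    )
    def test_direct_evaluation(self, radius, expected):
        assert mfet_analytic(radius, 0.45) == pytest.approx(expected)

    def test_quadratic_scaling(self):
        assert mfet_analytic(8.0, 0.45) == pytest.approx(4 * mfet_analytic(4.0, 0.45))

    def test_domain(self):
        with pytest.raises(DomainError):
            mfet_analytic(-1.0, 0.45)
        with pytest.raises(DomainError):
            mfet_analytic(3.0, 0.0)


class TestIncrements:
    def test_normal_increments_uncorrelated(self, rng):
        inc = generate_path_increments(
            DiffusionSettings(mode="normal"), 4000, rng, n_paths=4
        )
        for p in range(4):
            x = inc[p, :, 0]
            r = np.corrcoef(x[:-1], x[1:])[0, 1]
            assert abs(r) < 0.05

    def test_fractional_increments_anticorrelated(self, rng):
        settings = DiffusionSettings(mode="fractional", hurst=0.25)
        inc = generate_path_increments(settings, 2048, rng, n_paths=20)
        r = np.mean(
            [np.corrcoef(inc[p, :-1, a], inc[p, 1:, a])[0, 1] for p in range(20) for a in range(3)]
        )
        assert r == pytest.approx(2 ** (2 * 0.25 - 1) - 1, abs=0.03)

    def test_axes_independent(self, rng):
        inc = generate_path_increments(
            DiffusionSettings(mode="fractional", hurst=0.25), 2048, rng, n_paths=10
        )
        r = np.mean([np.corrcoef(inc[p, :, 0], inc[p, :, 1])[0, 1] for p in range(10)])
        assert abs(r) < 0.05


class TestFirstExit:
    def test_tiny_radius_exits_first_step(self):
        settings = DiffusionSettings(mode="normal", n_trajectories=200, rng_seed=3)
        steps, excluded = first_exit_steps(1e-9, settings, scale_factor=0.1)
        assert excluded == 0
        assert np.all(steps == 1)

    def test_exit_steps_scale_with_radius_squared(self):
        """Mean exit steps follow the diffusive r² law at fixed scale."""
        settings = DiffusionSettings(mode="normal", n_trajectories=4000, rng_seed=5)
        means = {}
        for i, radius in enumerate((3.0, 4.5, 6.0)):
            steps, _ = first_exit_steps(
                radius, settings, 0.125, np.random.default_rng([5, i])
            )
            means[radius] = steps.mean()
        assert means[6.0] / means[3.0] == pytest.approx(4.0, rel=0.1)
        assert means[4.5] / means[3.0] == pytest.approx(2.25, rel=0.1)

    def test_bit_reproducible_for_fixed_seed(self, bm_settings, bm_scale):
        a, _ = first_exit_steps(4.0, bm_settings, bm_scale)
        b, _ = first_exit_steps(4.0, bm_settings, bm_scale)
        np.testing.assert_array_equal(a, b)

    def test_domain_errors(self, bm_settings):
        with pytest.raises(DomainError):
            first_exit_steps(-1.0, bm_settings, 0.1)
        with pytest.raises(DomainError):
            first_exit_steps(3.0, bm_settings, 0.0)


class TestCalibration:
    def test_calibrated_mean_hits_reference_on_fresh_seed(self, bm_settings, bm_scale):
        res = export_delay(REF_RADIUS, bm_settings, bm_scale, np.random.default_rng(2026))
        assert res.mean_time == pytest.approx(REF_TIME, abs=0.07)

    def test_doubling_reference_time_doubles_exit_time(self, bm_settings, bm_scale):
        scale2 = calibrate_scale(bm_settings, REF_RADIUS, 2 * REF_TIME)
        res = export_delay(REF_RADIUS, bm_settings, scale2, np.random.default_rng(7))
        assert res.mean_time == pytest.approx(2 * REF_TIME, rel=0.04)

    def test_fractional_calibration_by_construction(self):
        settings = DiffusionSettings(mode="fractional", hurst=0.25,
                                     n_trajectories=4000, rng_seed=13)
        scale = calibrate_scale(settings, REF_RADIUS, REF_TIME)
        res = export_delay(REF_RADIUS, settings, scale, np.random.default_rng(31))
        assert res.mean_time == pytest.approx(REF_TIME, abs=0.07)


class TestEnsembles:
    def test_mean_time_increases_with_radius(self, bm_settings, bm_scale):
        results = radius_sweep([3.0, 4.0, 5.0, 6.0], bm_settings, bm_scale)
        means = [r.mean_time for r in results]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_exit_distribution_right_skewed(self, bm_settings, bm_scale):
        res = export_delay(4.0, bm_settings, bm_scale, np.random.default_rng(17))
        assert res.median_time < res.mean_time

    def test_obstructed_slower_than_normal_at_axolotl_radius(self, bm_settings, bm_scale):
        fbm = DiffusionSettings(mode="fractional", hurst=0.25,
                                n_trajectories=1500, rng_seed=19)
        fbm_scale = calibrate_scale(fbm, REF_RADIUS, REF_TIME, n_pilot=3000)
        res_f = export_delay(5.5, fbm, fbm_scale, np.random.default_rng(23))
        res_b = export_delay(5.5, bm_settings, bm_scale, np.random.default_rng(29))
        assert res_f.mean_time > res_b.mean_time
        assert res_f.n_excluded < 0.01 * fbm.n_trajectories

    def test_uniform_start_faster_than_center(self):
        fbm_kwargs = dict(mode="fractional", hurst=0.25, n_trajectories=1500)
        center = DiffusionSettings(start_rule="center", rng_seed=37, **fbm_kwargs)
        uniform = DiffusionSettings(start_rule="uniform_three_quarter", rng_seed=37,
                                    **fbm_kwargs)
        scale = calibrate_scale(center, REF_RADIUS, REF_TIME, n_pilot=3000)
        res_c = export_delay(4.0, center, scale, np.random.default_rng(41))
        res_u = export_delay(4.0, uniform, scale, np.random.default_rng(43))
        assert res_u.mean_time < res_c.mean_time

    def test_single_radius_sweep_matches_export_delay(self, bm_settings, bm_scale):
        sweep = radius_sweep([4.0], bm_settings, bm_scale)
        direct = export_delay(4.0, bm_settings, bm_scale, np.random.default_rng([11, 1]))
        assert sweep[0].mean_time == direct.mean_time
        frame = sweep_frame(sweep)
        assert list(frame.columns[:2]) == ["radius_um", "mode"]

    def test_sweep_rejects_bad_radii(self, bm_settings, bm_scale):
        with pytest.raises(DomainError):
            radius_sweep([], bm_settings, bm_scale)
        with pytest.raises(DomainError):
            radius_sweep([3.0, -1.0], bm_settings, bm_scale)
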