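"""Forward viscoplastic growth simulation, self-similarity and optimization."""

import numpy as np
import pytest
from dataclasses import replace

from tipwall.mechanics import ViscoplasticParams
from tipwall.profile import MeridionalProfile, extend_with_cylinder
from tipwall.simulator import (
    SimulationConfig,
    StalledGrowthError,
    _normal_velocity,
    optimize_parameters,
    residual_distance,
    scan_parameters,
    simulate,
    steady_state_profile,
    step,
)
from tipwall.synthetic import cap_blend_profile
from tipwall.thickness import WallGradient


@pytest.fixture(scope="module")
def fast_cfg(gradient, params):
    return SimulationConfig(
        params=params, gradient=gradient, spacing=0.15,
        tip_step=0.04, record_every=1.0, target_distance=2.0, s_window=14.0,
    )


def spherical_cap_profile(R=3.0, spacing=0.05, span=0.45 * np.pi):
    s = np.arange(0.0, span * R, spacing)
    phi = s / R
    return MeridionalProfile(
        s=s, x=-R * (1 - np.cos(phi)), r=R * np.sin(phi), phi=phi,
        kappa_s=np.full(len(s), 1 / R), kappa_theta=np.full(len(s), 1 / R),
        spacing=spacing,
    )


class TestStep:
    def test_uniform_sphere_has_uniform_velocity(self):
        prof = spherical_cap_profile(R=3.0)
        const = WallGradient("pearson", 0.1 * (1 - 1e-9), 0.1, 1e3)
        p = ViscoplasticParams(P=0.5, sigma_y=2.0)
        V = _normal_velocity(prof, const, p)
        assert np.allclose(V, V[0], rtol=1e-6)
        # displaced points stay on a sphere of larger radius
        cfg = SimulationConfig(params=p, gradient=const, tip_step=0.01,
                               record_every=0.01, target_distance=0.02)
        new, dt = step(prof, cfg)
        grown = 3.0 + V[0] * dt  # dt may be shortened by the stability cap
        center_x = new.x[0] - grown
        radii = np.hypot(new.x[: len(new) // 2] - center_x, new.r[: len(new) // 2])
        assert np.allclose(radii, grown, atol=1e-4)

    def test_stall_when_yield_exceeds_stress(self, gradient):
        prof = spherical_cap_profile(R=3.0)
        p = ViscoplasticParams(P=0.5, sigma_y=1e4)
        cfg = SimulationConfig(params=p, gradient=gradient, tip_step=0.01,
                               record_every=0.01, target_distance=0.02)
        with pytest.raises(StalledGrowthError):
            step(prof, cfg)

    def test_selfsimilar_velocity_matches_translation(
        self, trumpet, gradient, params
    ):
        V = _normal_velocity(trumpet, gradient, params)
        expected = params.v_tip * np.cos(trumpet.phi)
        interior = trumpet.s < trumpet.s[-1] - 1.0
        dev = np.abs(V[interior] - expected[interior]) / params.v_tip
        assert np.percentile(dev, 95) < 0.05


class TestResidualDistance:
    def test_translated_copy_has_zero_distance(self, trumpet):
        rD, log_rD = residual_distance(trumpet.translated(3.0), trumpet, 3.0)
        assert rD == 0.0
        assert log_rD == -np.inf

    def test_uniform_offset_is_weight_free(self, trumpet):
        shifted = trumpet.translated(0.01)
        rD, _ = residual_distance(shifted, trumpet, 0.0)
        assert rD == pytest.approx(0.01, rel=1e-9)

    def test_partial_overlap_uses_common_range(self, trumpet):
        short = trumpet.truncated(2.0)
        rD, _ = residual_distance(trumpet.translated(0.02), short, 0.0)
        assert rD == pytest.approx(0.02, rel=1e-9)


class TestSimulate:
    def test_selfsimilar_run_stays_selfsimilar(self, trumpet_coarse, fast_cfg):
        res = simulate(trumpet_coarse, fast_cfg)
        assert res.log_rD < -3.0
        assert not res.stalled

    def test_growth_rate_matches_tip_speed(self, trumpet_coarse, fast_cfg, params):
        res = simulate(trumpet_coarse, fast_cfg)
        rate = res.tip_positions[-1] / res.elapsed
        assert rate == pytest.approx(params.v_tip, rel=0.05)

    def test_frames_are_recorded_on_schedule(self, trumpet_coarse, fast_cfg):
        res = simulate(trumpet_coarse, fast_cfg)
        assert len(res.frames) == 3  # initial + 2 recordings over 2 um
        assert np.all(np.diff(res.tip_positions) > 0)

    def test_step_size_convergence(self, trumpet_coarse, fast_cfg):
        res1 = simulate(trumpet_coarse, fast_cfg)
        res2 = simulate(trumpet_coarse, replace(fast_cfg, tip_step=0.02))
        assert res2.log_rD == pytest.approx(res1.log_rD, rel=0.05)

    def test_stalled_run_returns_inf_residual(self, trumpet_coarse, fast_cfg):
        cfg = replace(
            fast_cfg, params=replace(fast_cfg.params, sigma_y=1e4)
        )
        res = simulate(trumpet_coarse, cfg)
        assert res.stalled
        assert np.isinf(res.rD)


class TestPerturbations:
    def test_extensibility_changes_rate_not_shape(
        self, trumpet_coarse, fast_cfg, params
    ):
        res1 = simulate(trumpet_coarse, fast_cfg)
        res2 = simulate(
            trumpet_coarse,
            replace(fast_cfg, params=replace(params, Phi=2 * params.Phi)),
        )
        assert res2.elapsed == pytest.approx(res1.elapsed / 2, rel=0.01)
        shape_rd, _ = residual_distance(
            res2.final, res1.final, res2.final.tip_x - res1.final.tip_x, 1.0
        )
        assert shape_rd < 2e-3

    def test_yield_threshold_changes_shape_and_rate(
        self, trumpet_coarse, fast_cfg, params
    ):
        res1 = simulate(trumpet_coarse, fast_cfg)
        for dsy in (-1.0, 1.0):
            res = simulate(
                trumpet_coarse,
                replace(fast_cfg, params=replace(params, sigma_y=params.sigma_y + dsy)),
            )
            shape_rd, _ = residual_distance(
                res.final, res1.final, res.final.tip_x - res1.final.tip_x, 1.0
            )
            assert shape_rd > 5e-3
            assert abs(res.elapsed / res1.elapsed - 1.0) > 0.1

    def test_gradient_steepness_changes_shape_and_rate(
        self, trumpet_coarse, fast_cfg, gradient
    ):
        from tipwall.synthetic import make_variants

        res1 = simulate(trumpet_coarse, fast_cfg)
        for kind in ("steep", "gentle"):
            res = simulate(
                trumpet_coarse, replace(fast_cfg, gradient=make_variants(gradient, kind))
            )
            shape_rd, _ = residual_distance(
                res.final, res1.final, res.final.tip_x - res1.final.tip_x, 1.0
            )
            assert shape_rd > 5e-3

    def test_initial_shapes_converge_to_gradient_set_shape(self, fast_cfg):
        finals = []
        cfg = replace(fast_cfg, target_distance=8.0, record_every=4.0)
        for factor in (0.8, 1.2):  # flat and sharp domes
            prof = cap_blend_profile(
                0.27 * factor, 3.27, s_max=14.0, spacing=0.15, blend_width=5.0
            )
            finals.append(simulate(prof, cfg).final)
        rd, _ = residual_distance(
            finals[0], finals[1], finals[0].tip_x - finals[1].tip_x, 1.0
        )
        assert rd < 0.05


class TestOptimization:
    def test_known_optimum_is_a_fixed_point(self, trumpet_coarse, fast_cfg, params):
        cfg = replace(fast_cfg, target_distance=4.0, record_every=2.0)
        phi, sy, log_rd = optimize_parameters(
            trumpet_coarse, cfg, start=(params.Phi, params.sigma_y),
            max_evals=10,
        )
        assert phi == pytest.approx(params.Phi, rel=0.06)
        assert sy == pytest.approx(params.sigma_y, rel=0.06)
        assert log_rd <= simulate(trumpet_coarse, cfg).log_rD + 1e-9

    def test_lockhart_start_is_already_optimal(
        self, trumpet_coarse, fast_cfg, params
    ):
        cfg = replace(fast_cfg, target_distance=4.0, record_every=2.0)
        phi, sy, log_rd = optimize_parameters(trumpet_coarse, cfg, max_evals=12)
        assert phi == pytest.approx(params.Phi, rel=0.06)
        assert sy == pytest.approx(params.sigma_y, rel=0.06)
        assert log_rd < -3.0

    def test_scan_grid_minimum_at_center(self, trumpet_coarse, fast_cfg, params):
        cfg = replace(fast_cfg, target_distance=2.0, record_every=1.0)
        phis = params.Phi * np.array([0.8, 1.0, 1.25])
        sys_ = params.sigma_y + np.array([-1.0, 0.0, 1.0])
        mat = scan_parameters(trumpet_coarse, cfg, phis, sys_)
        assert mat.shape == (3, 3)
        assert np.unravel_index(np.argmin(mat), mat.shape) == (1, 1)

    def test_scan_reports_stalls_as_inf(self, trumpet_coarse, fast_cfg, params):
        cfg = replace(fast_cfg, target_distance=2.0, record_every=1.0)
        mat = scan_parameters(
            trumpet_coarse, cfg, [params.Phi], [1e4]
        )
        assert np.isinf(mat[0, 0])
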