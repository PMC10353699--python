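"""Physics primitives, trajectory integration and rendering."""

import numpy as np
import pytest

from ptep import (
    FlowField,
    FluidSpec,
    ParticleSpec,
    SceneSpec,
    particle_flux,
    render_frames,
    seebeck_field_sign,
    settling_velocity,
    simulate_trajectories,
    thermophoretic_drift,
)
from ptep.scenarios import accumulation_scenario, brownian_scenario


class TestParticleFlux:
    def test_zero_gradients_give_zero_flux(self):
        assert np.allclose(particle_flux(1e12, [0, 0], 1e-12, 1e-12, [0, 0]), 0)

    def test_thermal_term_pushes_toward_cold(self):
        # c=1e12, DT=1e-12, ∇T=+x·1e5 → j = −1e5 along x (toward cold)
        j = particle_flux(1e12, [0.0, 0.0], 1e-12, 0.0, [1e5, 0.0])
        assert np.allclose(j, [-1e5, 0.0])

    def test_zero_concentration_leaves_fickian_term(self):
        j = particle_flux(0.0, [2e6, 0.0], 1e-12, 1e-11, [1e5, 0.0])
        assert np.allclose(j, [-1e-11 * 2e6, 0.0])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            particle_flux(-1.0, [0, 0], 0, 0, [0, 0])


class TestThermophoreticDrift:
    def test_zero_mobility(self):
        assert np.allclose(thermophoretic_drift(0.0, [1e6, -1e6]), 0)

    def test_hand_value(self):
        assert np.allclose(thermophoretic_drift(1e-12, [1e5, 0.0]),
                           [-1e-7, 0.0])

    def test_negative_mobility_drifts_toward_hot(self):
        grad = np.array([1e5, 0.0])
        v = thermophoretic_drift(-1e-12, grad)
        assert np.dot(v, grad) > 0  # parallel to ∇T


class TestSettlingVelocity:
    def test_neutral_buoyancy(self, fluid):
        p = ParticleSpec(diameter_um=5.0, density=fluid.density)
        assert settling_velocity(p, fluid) == 0.0

    def test_hand_value_15um(self, fluid, ps_sizes):
        # (1050-997)*9.81*(15e-6)^2/(18e-3) ≈ 6.5 µm/s downward
        vt = settling_velocity(ps_sizes[15.0], fluid)
        assert vt == pytest.approx(6.5e-6, rel=0.01)

    def test_quadratic_diameter_scaling(self, fluid):
        v1 = settling_velocity(ParticleSpec(diameter_um=2, density=1050), fluid)
        v2 = settling_velocity(ParticleSpec(diameter_um=4, density=1050), fluid)
        assert v2 == pytest.approx(4 * v1)


class TestSeebeckSign:
    def test_equal_coefficients_no_field(self):
        assert seebeck_field_sign(1e-3, 1e-3) == 0

    def test_pbs_ion_pair_positive(self, fluid):
        assert seebeck_field_sign(fluid.soret_cation, fluid.soret_anion) == 1

    def test_antisymmetric(self, fluid):
        assert (seebeck_field_sign(fluid.soret_anion, fluid.soret_cation)
                == -seebeck_field_sign(fluid.soret_cation, fluid.soret_anion))


def _still_scene(**kw):
    defaults = dict(image_shape=(100, 100), frame_rate=10.0,
                    fiber_tip_px=(-5.0, 0.0), orientation="vertical")
    defaults.update(kw)
    return SceneSpec(**defaults)


class TestSimulateTrajectories:
    def test_no_forces_stationary(self, fluid):
        p = ParticleSpec(diameter_um=2, density=fluid.density, diffusion=0.0)
        flow = FlowField(convection="none", grad_T0=0.0, attraction_per_mv=0.0)
        truth = simulate_trajectories([p], 5, flow, fluid, _still_scene(),
                                      duration_s=1.0, seed=1, medium="DIW")
        assert np.all(truth.positions_um == truth.positions_um[0])

    def test_uniform_flow_exact_per_frame_displacement(self, fluid):
        p = ParticleSpec(diameter_um=2, density=fluid.density, diffusion=0.0)
        flow = FlowField(u0=5e-5, decay_length_um=1e15, convection="plume",
                         grad_T0=0.0, attraction_per_mv=0.0)
        scene = _still_scene()
        truth = simulate_trajectories([p], 3, flow, fluid, scene,
                                      duration_s=1.0, seed=1, medium="DIW")
        step = np.diff(truth.positions_um, axis=0)
        assert np.allclose(step[..., 0], 0.0)
        assert np.allclose(step[..., 1], 50.0 / scene.frame_rate)  # µm/frame

    def test_particle_count_conserved_and_seed_reproducible(self):
        t1 = brownian_scenario(seed=9, n_particles=20, n_frames=15)
        t2 = brownian_scenario(seed=9, n_particles=20, n_frames=15)
        assert t1.positions_um.shape == (15, 20, 2)
        assert np.array_equal(t1.positions_um, t2.positions_um)
        t3 = brownian_scenario(seed=10, n_particles=20, n_frames=15)
        assert not np.array_equal(t1.positions_um, t3.positions_um)

    def test_deterministic_drift_recovered_by_finite_difference(self, fluid):
        p = ParticleSpec(diameter_um=2, density=1050.0, diffusion=0.0)
        flow = FlowField(tip_um=(40.0, 40.0), u0=2e-5, decay_length_um=100.0,
                         convection="inflow", grad_T0=0.0,
                         attraction_per_mv=0.0)
        truth = simulate_trajectories([p], 8, flow, fluid, _still_scene(),
                                      duration_s=2.0, seed=3, medium="DIW")
        fd = np.diff(truth.positions_um, axis=0) * 10.0  # frame rate
        scale = np.abs(truth.velocities_um_s[:-1]).max()
        err = np.abs(fd - truth.velocities_um_s[:-1]).max() / scale
        assert err <= 1e-9

    def test_brownian_msd_matches_diffusion_law(self):
        truth = brownian_scenario(seed=4, n_particles=300, n_frames=60)
        disp = np.diff(truth.positions_um, axis=0)
        sq = disp ** 2  # per-axis squared step displacements
        expected = 2.0 * 1.0 * (1.0 / 30.0)  # 2 D Δt in µm²
        se = sq.std(ddof=1) / np.sqrt(sq.size)
        assert abs(sq.mean() - expected) <= 3 * se
        mean_disp = disp.mean(axis=(0, 1))
        se_mean = disp.std(ddof=1) / np.sqrt(disp.size / 2)
        assert np.all(np.abs(mean_disp) <= 3 * se_mean)

    def test_pbs_accumulates_at_least_as_much_as_diw(self):
        _, _, _ = accumulation_scenario(seed=5)  # warm cache path
        pbs, _, _ = accumulation_scenario(seed=5, n_particles=40,
                                          duration_s=6.0)
        diw, _, _ = accumulation_scenario(seed=5, n_particles=40,
                                          duration_s=6.0, medium="DIW")
        assert pbs.captured[-1].sum() >= diw.captured[-1].sum()
        assert diw.captured[-1].sum() == 0

    def test_capture_count_monotone_in_zeta(self):
        counts = []
        for zeta in (-5.0, -12.0, -24.0):
            truth, _, _ = accumulation_scenario(seed=6, zeta_mv=zeta,
                                                n_particles=60,
                                                duration_s=8.0)
            counts.append(int(truth.captured[-1].sum()))
        assert counts == sorted(counts)

    def test_invalid_inputs_rejected(self, fluid):
        p = ParticleSpec(diameter_um=2, density=1050)
        flow = FlowField()
        with pytest.raises(ValueError):
            simulate_trajectories([p], 2, flow, fluid, _still_scene(),
                                  duration_s=0.0, seed=1)
        with pytest.raises(ValueError):
            ParticleSpec(diameter_um=2, density=1050, diffusion=-1e-12)


class TestRenderFrames:
    def test_blank_scene_is_background(self, fluid):
        p = ParticleSpec(diameter_um=2, density=fluid.density)
        flow = FlowField(convection="none", grad_T0=0.0, attraction_per_mv=0.0)
        scene = _still_scene(noise_sd=0.0)
        truth = simulate_trajectories([p], 1, flow, fluid, scene,
                                      duration_s=0.5, seed=1, medium="DIW",
                                      init_positions_um=np.array([[-500.0, -500.0]]))
        stack = render_frames(truth, scene)
        assert np.all(stack.frames == scene.background_intensity)

    def test_disk_diameter_matches_physical_size(self, fluid):
        # 15 µm sphere at 0.89 µm/px → ≈ 17 px wide silhouette
        p = ParticleSpec(diameter_um=15.0, density=fluid.density)
        flow = FlowField(convection="none", grad_T0=0.0, attraction_per_mv=0.0)
        scene = _still_scene(pixel_size_um=0.89)
        center_um = scene.px_to_um(np.array([50.0, 50.0]))
        truth = simulate_trajectories([p], 1, flow, fluid, scene,
                                      duration_s=0.5, seed=1, medium="DIW",
                                      init_positions_um=center_um[None, :])
        frame = render_frames(truth, scene).frames[0]
        dark_cols = np.flatnonzero((frame < 200).any(axis=0))
        width = dark_cols[-1] - dark_cols[0] + 1
        assert width in (17, 18)  # 15/0.89 = 16.9 px plus the soft rim

    def test_accumulating_run_darkens_tip_windows(self):
        truth, stack, scene = accumulation_scenario(
            seed=7, n_particles=80, duration_s=8.0, particle_intensity=60.0)
        tip_x, tip_y = (int(v) for v in scene.fiber_tip_px)
        window = stack.frames[:, tip_y - 20:tip_y + 20, tip_x:tip_x + 25]
        means = window.mean(axis=(1, 2))
        occluded = truth.captured.sum(axis=1)
        assert occluded[-1] > 10
        # swarm growth darkens the tip: strong anticorrelation with the
        # captured count (free transiting particles add small jitter)
        from scipy import stats

        rho = stats.spearmanr(means, occluded).statistic
        assert rho < -0.9
        assert means[-1] < means[0] - 5

    def test_shape_unions_render_larger_than_single_disk(self, fluid):
        flow = FlowField(convection="none", grad_T0=0.0, attraction_per_mv=0.0)
        scene = _still_scene()
        areas = {}
        for shape in ("sphere", "cocci", "rod", "chain"):
            p = ParticleSpec(diameter_um=6.0, density=fluid.density,
                             shape=shape)
            center_um = scene.px_to_um(np.array([50.0, 50.0]))
            truth = simulate_trajectories([p], 1, flow, fluid, scene,
                                          duration_s=0.3, seed=2, medium="DIW",
                                          init_positions_um=center_um[None, :])
            frame = render_frames(truth, scene).frames[0]
            areas[shape] = int((frame < 150).sum())
        assert areas["chain"] > areas["rod"] > areas["sphere"]
        assert areas["cocci"] > 0
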