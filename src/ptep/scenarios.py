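"""Canonical synthetic study scenarios.

These builders freeze the conditions the analyses are validated under:
a side-view (vertical) convection/tracking recording, a top-view
(horizontal) tip-accumulation recording, and a Brownian-only control.
Parameters mirror the experimental geometry where stated — 0.89 µm/px
pixels, a 220 µm fiber, dark particles on a bright background — and are
order-of-magnitude physical choices elsewhere (plume speed tens of µm/s,
near-field range tens of µm).
"""

from __future__ import annotations

import numpy as np

from .simulate import GroundTruth, render_frames, simulate_trajectories
from .specs import FlowField, FluidSpec, ParticleSpec, SceneSpec
from .io import ImageStack

__all__ = [
    "tracking_scenario",
    "accumulation_scenario",
    "brownian_scenario",
    "DEFAULT_FLUID",
]

DEFAULT_FLUID = FluidSpec()


def _jittered_grid(n: int, x_range: tuple[float, float],
                   y_range: tuple[float, float], jitter_um: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Roughly uniform, non-overlapping starting positions (µm)."""
    nx = int(np.ceil(np.sqrt(n * (x_range[1] - x_range[0])
                             / max(y_range[1] - y_range[0], 1e-9))))
    nx = max(nx, 1)
    ny = int(np.ceil(n / nx))
    xs = np.linspace(*x_range, nx)
    ys = np.linspace(*y_range, ny)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])[:n]
    return pts + rng.uniform(-jitter_um, jitter_um, size=pts.shape)


def tracking_scenario(seed: int, n_particles: int = 24, n_frames: int = 200,
                      u0_um_s: float = 15.0, radius_px: float = 5.0,
                      noise_sd: float = 0.0,
                      ) -> tuple[GroundTruth, ImageStack, SceneSpec]:
    """Side-view recording of spheres advected by a uniform upward plume.

    Neutrally buoyant, diffusionless spheres in a spatially uniform
    convection current, so every ground-truth velocity equals the injected
    plume speed exactly — the oracle for detection/linking/velocity
    recovery.  Geometry keeps all particles in frame for the whole
    recording.
    """
    scene = SceneSpec(image_shape=(360, 240), pixel_size_um=0.89,
                      frame_rate=30.0, fiber_tip_px=(-10.0, 0.0),
                      background_intensity=220.0, particle_intensity=60.0,
                      noise_sd=noise_sd, orientation="vertical")
    dp_um = 2.0 * radius_px * scene.pixel_size_um
    particle = ParticleSpec(diameter_um=dp_um, density=DEFAULT_FLUID.density,
                            thermo_mobility=0.0, diffusion=0.0, shape="sphere")
    flow = FlowField(tip_um=(0.0, 0.0), u0=u0_um_s * 1e-6,
                     decay_length_um=1e12, convection="plume",
                     grad_T0=0.0, attraction_per_mv=0.0)
    rng = np.random.default_rng(seed)
    w_um, h_um = scene.extent_um
    travel = u0_um_s * n_frames / scene.frame_rate
    margin = dp_um
    init = _jittered_grid(
        n_particles,
        (margin + 5.0, w_um - margin - 5.0),
        (margin + 5.0, h_um - margin - travel - 5.0),
        jitter_um=2.0, rng=rng)
    truth = simulate_trajectories(
        [particle], n_particles, flow, DEFAULT_FLUID, scene,
        duration_s=n_frames / scene.frame_rate, seed=seed, medium="DIW",
        init_positions_um=init)
    stack = render_frames(truth, scene)
    return truth, stack, scene


def accumulation_scenario(seed: int, attraction_per_mv: float = 1e-6,
                          medium: str = "PBS", zeta_mv: float = -20.0,
                          n_particles: int = 120, duration_s: float = 13.0,
                          frame_rate: float = 14.0,
                          capture_radius_um: float = 12.0,
                          diffusion_um2_s: float = 0.05,
                          noise_sd: float = 0.0,
                          particle_intensity: float = 150.0,
                          ) -> tuple[GroundTruth, ImageStack, SceneSpec]:
    """Top-view recording of zeta-gated accumulation at the fiber tip.

    Bacteria-sized particles drift toward the tip under the near-field
    attraction (disabled in distilled water) and immobilize on entering
    the capture radius, where their multiplicative overlap renders the
    growing swarm progressively darker than any single transiting cell.
    Starting positions form a non-overlapping jittered grid that leaves
    the capture zone clear, so darkening near the tip is transported
    there by the physics rather than placed by the initial condition.
    """
    scene = SceneSpec(image_shape=(200, 200), pixel_size_um=0.89,
                      frame_rate=frame_rate, fiber_tip_px=(100.0, 100.0),
                      fiber_diameter_um=40.0,
                      background_intensity=220.0,
                      particle_intensity=particle_intensity,
                      noise_sd=noise_sd, orientation="horizontal")
    particle = ParticleSpec(diameter_um=2.0, density=1050.0,
                            diffusion=diffusion_um2_s * 1e-12,
                            zeta_mv=zeta_mv, shape="sphere")
    tip_um = scene.fiber_tip_um
    flow = FlowField(tip_um=tip_um, convection="none", grad_T0=0.0,
                     attraction_per_mv=attraction_per_mv,
                     attraction_range_um=150.0)
    rng = np.random.default_rng(seed)
    w_um, h_um = scene.extent_um
    clear_um = capture_radius_um + 5.0
    init = _jittered_grid(n_particles + 12, (4.0, w_um - 4.0),
                          (4.0, h_um - 4.0), jitter_um=1.5, rng=rng)
    d = np.hypot(init[:, 0] - tip_um[0], init[:, 1] - tip_um[1])
    init = init[d >= clear_um][:n_particles]
    if len(init) < n_particles:
        raise ValueError("could not place all particles outside the capture "
                         "zone; reduce n_particles")
    truth = simulate_trajectories(
        [particle], n_particles, flow, DEFAULT_FLUID, scene,
        duration_s=duration_s, seed=seed, medium=medium,
        capture_radius_um=capture_radius_um, init_positions_um=init)
    stack = render_frames(truth, scene)
    return truth, stack, scene


def brownian_scenario(seed: int, n_particles: int = 500, n_frames: int = 100,
                      diffusion_um2_s: float = 1.0, frame_rate: float = 30.0,
                      ) -> GroundTruth:
    """Brownian-only control: no flow, no settling, no attraction.

    Per-axis squared frame-to-frame displacements have expectation 2·D·Δt
    — the analytic diffusion law the simulator must reproduce.
    """
    scene = SceneSpec(image_shape=(512, 512), pixel_size_um=0.89,
                      frame_rate=frame_rate, fiber_tip_px=(-10.0, 0.0),
                      orientation="vertical")
    particle = ParticleSpec(diameter_um=1.0, density=DEFAULT_FLUID.density,
                            diffusion=diffusion_um2_s * 1e-12)
    flow = FlowField(convection="none", grad_T0=0.0, attraction_per_mv=0.0)
    return simulate_trajectories(
        [particle], n_particles, flow, DEFAULT_FLUID, scene,
        duration_s=n_frames / frame_rate, seed=seed, medium="DIW")
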