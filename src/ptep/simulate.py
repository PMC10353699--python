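"""Physics primitives, Brownian-dynamics trajectory simulation and rendering.

The simulator produces ground-truth particle trajectories under the forces
the analysis assumes — thermal convection, thermophoretic drift in a
temperature gradient, gravitational settling at terminal velocity,
zeta-gated near-field attraction and Brownian noise — and renders them
into microscopy-like image stacks (dark quasi-circular particles on a
bright background beside a dark fiber silhouette).  Every analysis stage
can therefore be validated against exact ground truth.

Model
-----
Overdamped forward-Euler stepping, one step per frame (optionally
sub-stepped).  At each step the deterministic drift is

    v = u_conv(x) + vD(x) + vT * g_hat + v_attr(ζ) * r_hat_tip

with ``vD = −DT ∇T`` (thermophoretic drift), ``vT`` the Stokes terminal
velocity, and the attraction active only in an electrolyte medium (the
ionic Seebeck field vanishes in distilled water).  Brownian displacement
per axis is ``sqrt(2 D Δt) η`` with standard-normal η.  This is the
creeping-flow regime (Re ≪ 1, Stokes number ≪ 1), where inertia is
negligible and particles track the local drift exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ImageStack
from .specs import FlowField, FluidSpec, ParticleSpec, SceneSpec

__all__ = [
    "GroundTruth",
    "particle_flux",
    "thermophoretic_drift",
    "settling_velocity",
    "seebeck_field_sign",
    "simulate_trajectories",
    "render_frames",
]


# ---------------------------------------------------------------------------
# closed-form physics primitives
# ---------------------------------------------------------------------------

def particle_flux(c: float, grad_c, DT: float, D: float, grad_T) -> np.ndarray:
    """Particle flux j = −c·DT·∇T − D·∇c  [1/(m²·s)].

    First term: transport down (for DT > 0) the temperature gradient;
    second term: Fickian flux down the concentration gradient.  A positive
    Soret coefficient ST = DT/D pushes particles toward the cold side.
    """
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    if D < 0:
        raise ValueError(f"diffusion coefficient must be >= 0, got {D}")
    grad_T = np.asarray(grad_T, dtype=float)
    grad_c = np.asarray(grad_c, dtype=float)
    return -c * DT * grad_T - D * grad_c


def thermophoretic_drift(DT: float, grad_T) -> np.ndarray:
    """Thermophoretic drift velocity vD = −DT·∇T  [m/s].

    For DT > 0 the particle drifts toward cold; a negative thermophoretic
    mobility (negative Soret coefficient at fixed D > 0) reverses the
    drift toward the hot region.
    """
    return -DT * np.asarray(grad_T, dtype=float)


def settling_velocity(particle: ParticleSpec, fluid: FluidSpec) -> float:
    """Stokes terminal velocity vT = (ρp − ρf)·g·dp² / (18 μ)  [m/s].

    Positive means downward settling (particle denser than fluid); the
    sign follows the density difference, so buoyant particles rise.
    """
    dp = particle.diameter_um * 1e-6
    return ((particle.density - fluid.density) * fluid.gravity * dp ** 2
            / (18.0 * fluid.viscosity))


def seebeck_field_sign(soret_cation: float, soret_anion: float) -> int:
    """Sign of the ionic thermoelectric (Seebeck) field along ∇T.

    Differential ion thermophoresis separates charge when the cation and
    anion Soret coefficients differ.  Convention: +1 when the cation is
    the more thermophoretically responsive ion (``ST_cation > ST_anion``),
    in which case cations deplete the hot region faster and a field
    pointing up the temperature gradient (toward hot) results; −1 for the
    reverse; 0 when the coefficients are equal (no separation, no field).
    """
    if not (np.isfinite(soret_cation) and np.isfinite(soret_anion)):
        raise ValueError("Soret coefficients must be finite")
    return int(np.sign(soret_cation - soret_anion))


# ---------------------------------------------------------------------------
# trajectory simulation
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact per-frame particle state in physical coordinates (µm, y up).

    ``velocities_um_s[i]`` is the deterministic drift evaluated at the
    frame-``i`` positions (the Brownian kick is excluded), so with D = 0
    finite differencing of consecutive positions recovers it exactly.
    Captured (accumulated) particles have zero drift and frozen positions.
    """

    positions_um: np.ndarray      # (T, N, 2)
    velocities_um_s: np.ndarray   # (T, N, 2)
    captured: np.ndarray          # (T, N) bool
    particle_ids: np.ndarray      # (N,)
    spec_index: np.ndarray        # (N,) index into the specs list
    specs: Sequence[ParticleSpec]
    frame_rate: float
    seed: int

    @property
    def n_frames(self) -> int:
        return self.positions_um.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions_um.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: frame, particle_id, x_um, y_um, vx_um_s, vy_um_s."""
        t, n = self.n_frames, self.n_particles
        frames = np.repeat(np.arange(t), n)
        ids = np.tile(self.particle_ids, t)
        pos = self.positions_um.reshape(t * n, 2)
        vel = self.velocities_um_s.reshape(t * n, 2)
        return pd.DataFrame({
            "frame": frames, "particle_id": ids,
            "x_um": pos[:, 0], "y_um": pos[:, 1],
            "vx_um_s": vel[:, 0], "vy_um_s": vel[:, 1],
        })


def _drift_um_s(pos_um: np.ndarray, spec_idx: np.ndarray,
                specs: Sequence[ParticleSpec], flow: FlowField,
                fluid: FluidSpec, scene: SceneSpec, medium: str) -> np.ndarray:
    """Deterministic drift (µm/s) for every particle at ``pos_um``."""
    v = flow.convection_velocity(pos_um[:, 0], pos_um[:, 1]) * 1e6

    grad_t = flow.temperature_gradient(pos_um[:, 0], pos_um[:, 1])
    dt_coef = np.array([specs[i].thermo_mobility for i in spec_idx])
    v += -dt_coef[:, None] * grad_t * 1e6

    if scene.orientation == "vertical":
        # settling acts in the image plane only in the side-view geometry
        vt = np.array([settling_velocity(specs[i], fluid) for i in spec_idx])
        v[:, 1] -= vt * 1e6

    if medium.upper() != "DIW":
        tip = np.asarray(flow.tip_um)
        delta = tip[None, :] - pos_um
        r = np.hypot(delta[:, 0], delta[:, 1])
        r_safe = np.where(r > 0, r, 1.0)
        speed = np.array([flow.attraction_strength(specs[i].zeta_mv)
                          for i in spec_idx])
        speed = speed * np.exp(-r / flow.attraction_range_um) * 1e6
        v += speed[:, None] * delta / r_safe[:, None]
    return v


def simulate_trajectories(
    specs: Sequence[ParticleSpec],
    n_each: int,
    flow: FlowField,
    fluid: FluidSpec,
    scene: SceneSpec,
    duration_s: float,
    seed: int,
    medium: str = "PBS",
    capture_radius_um: float | None = None,
    substeps: int = 1,
    init_positions_um: np.ndarray | None = None,
) -> GroundTruth:
    """Integrate particle motion and return exact ground truth.

    Parameters
    ----------
    specs, n_each:
        ``n_each`` particles are instantiated per :class:`ParticleSpec`.
    medium:
        ``"PBS"`` (electrolyte; zeta-gated attraction active) or ``"DIW"``
        (distilled water; no ions, no Seebeck field, attraction disabled).
    capture_radius_um:
        In horizontal orientation, a particle entering this radius of the
        tip is immobilised (accumulates).  Default 2·dp per particle.
    init_positions_um:
        Optional (N, 2) starting positions; by default uniform over the
        field of view, excluding the capture zone.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if scene.frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    for s in specs:
        if s.diffusion < 0:
            raise ValueError("diffusion must be >= 0")

    rng = np.random.default_rng(seed)
    n = len(specs) * n_each
    spec_idx = np.repeat(np.arange(len(specs)), n_each)
    ids = np.arange(n)

    cap_r = np.array([
        capture_radius_um if capture_radius_um is not None
        else 2.0 * specs[i].diameter_um
        for i in spec_idx])
    tip = np.asarray(flow.tip_um, dtype=float)

    w_um, h_um = scene.extent_um
    if init_positions_um is not None:
        pos = np.array(init_positions_um, dtype=float)
        if pos.shape != (n, 2):
            raise ValueError(f"init_positions_um must have shape {(n, 2)}")
    else:
        pos = rng.uniform([0.0, 0.0], [w_um, h_um], size=(n, 2))
        # re-draw anything born inside the capture zone
        for _ in range(100):
            inside = np.hypot(*(pos - tip).T) < cap_r
            if not inside.any():
                break
            pos[inside] = rng.uniform([0.0, 0.0], [w_um, h_um],
                                      size=(int(inside.sum()), 2))

    n_frames = int(np.floor(duration_s * scene.frame_rate))
    dt = 1.0 / scene.frame_rate
    sub_dt = dt / substeps
    diff_um2_s = np.array([specs[i].diffusion for i in spec_idx]) * 1e12
    brownian_sd = np.sqrt(2.0 * diff_um2_s * sub_dt)   # µm per substep axis

    positions = np.empty((n_frames, n, 2))
    velocities = np.empty((n_frames, n, 2))
    captured = np.zeros((n_frames, n), dtype=bool)
    is_captured = np.zeros(n, dtype=bool)

    capture_active = scene.orientation == "horizontal"

    for f in range(n_frames):
        if capture_active:
            dist = np.hypot(*(pos - tip).T)
            is_captured |= dist < cap_r
        positions[f] = pos
        captured[f] = is_captured
        drift = _drift_um_s(pos, spec_idx, specs, flow, fluid, scene, medium)
        drift[is_captured] = 0.0
        velocities[f] = drift
        if f == n_frames - 1:
            break
        new = pos.copy()
        for _ in range(substeps):
            step_drift = _drift_um_s(new, spec_idx, specs, flow, fluid,
                                     scene, medium)
            kick = rng.standard_normal((n, 2)) * brownian_sd[:, None]
            upd = step_drift * sub_dt + kick
            upd[is_captured] = 0.0
            new += upd
        pos = new

    return GroundTruth(positions_um=positions, velocities_um_s=velocities,
                       captured=captured, particle_ids=ids,
                       spec_index=spec_idx, specs=list(specs),
                       frame_rate=scene.frame_rate, seed=seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _shape_offsets(shape: str, radius_px: float, angle: float) -> list[tuple[float, float, float]]:
    """Sub-disk (dx, dy, r) decomposition for non-spherical shapes.

    Rods, cocci and chains are drawn as unions of 2–12 overlapping disks;
    the shape affects rendering only.
    """
    c, s = np.cos(angle), np.sin(angle)
    if shape == "sphere":
        return [(0.0, 0.0, radius_px)]
    if shape == "cocci":
        r = radius_px * 0.8
        d = r * 0.9
        return [(-d / 2 * c, -d / 2 * s, r), (d / 2 * c, d / 2 * s, r)]
    if shape == "rod":
        r = radius_px * 0.6
        n_sub = 5
        span = radius_px * 2.2
        return [((i / (n_sub - 1) - 0.5) * span * c,
                 (i / (n_sub - 1) - 0.5) * span * s, r) for i in range(n_sub)]
    if shape == "chain":
        r = radius_px * 0.55
        n_sub = 10
        span = radius_px * 4.0
        return [((i / (n_sub - 1) - 0.5) * span * c,
                 (i / (n_sub - 1) - 0.5) * span * s, r) for i in range(n_sub)]
    raise ValueError(f"unknown shape {shape!r}")


def _paint_disk(coverage: np.ndarray, cx: float, cy: float, r: float) -> None:
    """Accumulate anti-aliased disk coverage into ``coverage`` (max-combined).

    Edge softness: per-pixel coverage = clip(r + 0.5 − dist_to_center, 0, 1),
    i.e. pixels whose center lies more than half a pixel inside the rim are
    fully covered.
    """
    h, w = coverage.shape
    x0, x1 = int(np.floor(cx - r - 1)), int(np.ceil(cx + r + 2))
    y0, y1 = int(np.floor(cy - r - 1)), int(np.ceil(cy + r + 2))
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    cov = np.clip(r + 0.5 - dist, 0.0, 1.0)
    np.maximum(coverage[y0:y1, x0:x1], cov, out=coverage[y0:y1, x0:x1])


def _particle_patch(offsets, cx: float, cy: float, shape_hw: tuple[int, int]):
    """Coverage patch (max over a particle's sub-disks) and its bbox."""
    h, w = shape_hw
    rmax = max(np.hypot(dx, dy) + r for dx, dy, r in offsets)
    x0, x1 = int(np.floor(cx - rmax - 1)), int(np.ceil(cx + rmax + 2))
    y0, y1 = int(np.floor(cy - rmax - 1)), int(np.ceil(cy + rmax + 2))
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    patch = np.zeros((y1 - y0, x1 - x0))
    for dx, dy, r in offsets:
        dist = np.hypot(xx - (cx + dx), yy - (cy + dy))
        np.maximum(patch, np.clip(r + 0.5 - dist, 0.0, 1.0), out=patch)
    return patch, (y0, y1, x0, x1)


def render_frames(truth: GroundTruth, scene: SceneSpec,
                  noise_seed: int | None = None) -> ImageStack:
    """Render ground-truth trajectories into an 8-bit grayscale stack.

    Particles are anti-aliased dark disks at their physical radius
    converted to pixels (radius_px = (dp/2)/pixel_size; a 15 µm sphere at
    0.89 µm/px spans ≈ 17 px).  Overlapping particles attenuate the
    transmitted light multiplicatively (Beer–Lambert-like): each particle
    scales the local intensity by ``particle_intensity/background`` over
    its covered pixels, so a single particle renders exactly at
    ``particle_intensity`` while stacked particles in a swarm get
    progressively darker — the basis of the concentration proxy.  The
    fiber is a dark rectangle of width equal to its diameter, entering
    from the left edge and ending at the tip.  Additive Gaussian noise of
    sd ``scene.noise_sd`` is applied and the result clipped to [0, 255].
    """
    if scene.pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    h, w = scene.image_shape
    rng = np.random.default_rng(truth.seed + 1 if noise_seed is None
                                else noise_seed)

    # per-particle fixed orientation for non-spherical shapes
    angle_rng = np.random.default_rng(truth.seed + 2)
    angles = angle_rng.uniform(0, np.pi, size=truth.n_particles)

    fiber = np.zeros((h, w), dtype=bool)
    tip_x, tip_y = scene.fiber_tip_px
    half = 0.5 * scene.fiber_diameter_um / scene.pixel_size_um
    y_lo = max(int(np.floor(tip_y - half)), 0)
    y_hi = min(int(np.ceil(tip_y + half)) + 1, h)
    x_hi = min(int(np.round(tip_x)) + 1, w)
    if x_hi > 0 and y_hi > y_lo:
        fiber[y_lo:y_hi, :x_hi] = True

    frames = np.empty((truth.n_frames, h, w), dtype=np.uint8)
    radii_px = np.array([
        0.5 * truth.specs[i].diameter_um / scene.pixel_size_um
        for i in truth.spec_index])
    bg, fg = scene.background_intensity, scene.particle_intensity

    alpha = 1.0 - fg / bg     # per-particle attenuation of the backlight
    for f in range(truth.n_frames):
        attenuation = np.ones((h, w))
        pos_px = scene.um_to_px(truth.positions_um[f])
        for p in range(truth.n_particles):
            shape = truth.specs[truth.spec_index[p]].shape
            offsets = _shape_offsets(shape, radii_px[p], angles[p])
            patch = _particle_patch(offsets, pos_px[p, 0], pos_px[p, 1], (h, w))
            if patch is None:
                continue
            cov, (y0, y1, x0, x1) = patch
            attenuation[y0:y1, x0:x1] *= 1.0 - alpha * cov
        img = bg * attenuation
        img[fiber] = fg
        if scene.noise_sd > 0:
            img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return ImageStack(frames=frames, frame_rate=scene.frame_rate,
                      pixel_size_um=scene.pixel_size_um)
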