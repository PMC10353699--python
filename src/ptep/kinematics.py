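"""Trajectory kinematics, dimensionless numbers and Stokes-regime forces.

Velocities come from finite differences of tracked positions (travel
distance per inter-frame interval), converted to physical µm/s with the
image-to-physical y-axis flip.  Forces use the creeping-flow closed forms:
Stokes drag ``FD = 3πμ·dp·v``, gravity-minus-buoyancy
``(ρp−ρf)·g·(π/6)·dp³`` and the terminal-velocity balance between the two.
The Reynolds number uses the tracked ensemble particle speed as the fluid
speed and the fiber diameter (220 µm by default) as the characteristic
length.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np

from .simulate import settling_velocity
from .specs import FluidSpec, ParticleSpec
from .track import Trajectory

__all__ = [
    "KinematicsSummary",
    "step_velocities",
    "trajectory_mean_speed",
    "average_velocity",
    "reynolds_number",
    "stokes_number",
    "stokes_drag",
    "net_gravity_buoyancy",
    "classify_motion",
    "y_displacement_change",
    "summarize",
]

DEFAULT_CHARACTERISTIC_LENGTH_UM = 220.0   # optical fiber diameter


def step_velocities(traj: Trajectory, frame_rate: float,
                    pixel_size_um: float) -> np.ndarray:
    """Per-step physical velocity vectors (µm/s), shape (L−1, 2).

    v_i = (pos_{i+1} − pos_i) · pixel_size · frame_rate, with the image
    y-down axis flipped to physical y-up (a particle moving up the image,
    decreasing y_px, has positive physical vy).
    """
    if len(traj) < 2:
        raise ValueError("trajectory must contain at least 2 detections")
    centers = traj.centers
    frames = traj.frames
    d_px = np.diff(centers, axis=0)
    d_frames = np.diff(frames)[:, None]
    v = d_px * pixel_size_um * frame_rate / d_frames
    v[:, 1] *= -1.0
    return v


def trajectory_mean_speed(traj: Trajectory, frame_rate: float,
                          pixel_size_um: float) -> float:
    """Speed averaged along the whole trajectory (µm/s)."""
    v = step_velocities(traj, frame_rate, pixel_size_um)
    return float(np.mean(np.hypot(v[:, 0], v[:, 1])))


def average_velocity(trajectories: Sequence[Trajectory], frame_rate: float,
                     pixel_size_um: float) -> tuple[float, float, int]:
    """Ensemble (mean, sd, n) of per-trajectory mean speeds in µm/s.

    Per-trajectory means first, then mean and sample sd across
    trajectories; sd is reported as 0.0 when only one trajectory is
    available (n flags the degenerate case).
    """
    if len(trajectories) == 0:
        raise ValueError("no trajectories")
    means = np.array([trajectory_mean_speed(t, frame_rate, pixel_size_um)
                      for t in trajectories])
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return float(np.mean(means)), sd, len(means)


def reynolds_number(rho_f: float, u: float, L: float, mu: float) -> float:
    """Re = ρf·u·L/μ (SI inputs).  Re ≪ 1 ⇒ laminar creeping flow."""
    if mu <= 0:
        raise ValueError("viscosity must be > 0")
    return rho_f * u * L / mu


def stokes_number(rho_p: float, dp: float, u: float, mu: float, L: float) -> float:
    """Stk = ρp·dp²·u / (18·μ·L) — particle relaxation time over flow time.

    Stk < 1 means particles follow the flow streamlines.  (Standard
    relaxation-time definition.)
    """
    if mu <= 0 or L <= 0:
        raise ValueError("viscosity and characteristic length must be > 0")
    return rho_p * dp ** 2 * u / (18.0 * mu * L)


def stokes_drag(mu: float, dp: float, v: float) -> float:
    """|FD| = 3πμ·dp·|v| in N; the drag opposes the relative velocity."""
    if mu <= 0 or dp <= 0:
        raise ValueError("viscosity and diameter must be > 0")
    return 3.0 * np.pi * mu * dp * abs(v)


def net_gravity_buoyancy(particle: ParticleSpec, fluid: FluidSpec) -> float:
    """Fg − Fb = (ρp − ρf)·g·(π/6)·dp³ in N, downward positive."""
    dp = particle.diameter_um * 1e-6
    return ((particle.density - fluid.density) * fluid.gravity
            * (np.pi / 6.0) * dp ** 3)


def classify_motion(drag_up: float, net_weight: float,
                    rtol: float = 1e-6) -> Literal["settling", "rising", "equilibrium"]:
    """Motion class from the vertical force balance: an upward drag
    exceeding the net weight lifts the particle; equality (within rtol)
    is terminal-velocity equilibrium."""
    scale = max(abs(drag_up), abs(net_weight), 1e-300)
    if abs(drag_up - net_weight) <= rtol * scale:
        return "equilibrium"
    return "rising" if drag_up > net_weight else "settling"


@dataclass
class KinematicsSummary:
    """Ensemble kinematics and forces for one tracked recording."""

    mean_speed_um_s: float
    sd_speed_um_s: float
    n_trajectories: int
    reynolds: float
    stokes: float
    drag_N: float
    net_gravity_buoyancy_N: float
    motion_class: str

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(trajectories: Sequence[Trajectory], frame_rate: float,
              pixel_size_um: float, particle: ParticleSpec, fluid: FluidSpec,
              characteristic_length_um: float = DEFAULT_CHARACTERISTIC_LENGTH_UM,
              ) -> KinematicsSummary:
    """Full kinematics summary of length-filtered trajectories.

    The tracked ensemble mean speed stands in for the fluid speed u in both
    Re and Stk; drag is evaluated at the same speed.
    """
    mean_u, sd_u, n = average_velocity(trajectories, frame_rate, pixel_size_um)
    u_si = mean_u * 1e-6
    dp_si = particle.diameter_um * 1e-6
    L_si = characteristic_length_um * 1e-6
    drag = stokes_drag(fluid.viscosity, dp_si, u_si)
    net = net_gravity_buoyancy(particle, fluid)

    # vertical force balance: drag from the flow (taken as the upward drag
    # at speed u) against the net weight decides the motion class
    vy = np.concatenate([
        step_velocities(t, frame_rate, pixel_size_um)[:, 1]
        for t in trajectories])
    mean_vy = float(np.mean(vy))
    vt = settling_velocity(particle, fluid)
    flow_up_si = mean_vy * 1e-6 + vt     # fluid speed implied by v = u - vT
    drag_up = stokes_drag(fluid.viscosity, dp_si, flow_up_si) * np.sign(flow_up_si)
    cls = classify_motion(drag_up=drag_up, net_weight=net)

    return KinematicsSummary(
        mean_speed_um_s=mean_u, sd_speed_um_s=sd_u, n_trajectories=n,
        reynolds=reynolds_number(fluid.density, u_si, L_si, fluid.viscosity),
        stokes=stokes_number(particle.density, dp_si, u_si, fluid.viscosity, L_si),
        drag_N=drag, net_gravity_buoyancy_N=net, motion_class=cls)


def y_displacement_change(trajectories: Sequence[Trajectory],
                          laser_on_time_s: float, frame_rate: float,
                          pixel_size_um: float, interval_s: float = 5.0,
                          total_frames: int | None = None,
                          ) -> tuple[float, float, float]:
    """Mean physical y-displacement (µm) over the ``interval_s`` windows
    immediately before and after laser-on, and their difference (after −
    before).  A flow that flips from settling to rising across laser-on
    yields a positive difference.

    Only trajectories covering both windows contribute.  Raises if the
    windows extend outside the recording.
    """
    on_frame = int(round(laser_on_time_s * frame_rate))
    win = int(round(interval_s * frame_rate))
    start, stop = on_frame - win, on_frame + win
    if start < 0:
        raise ValueError("pre-laser window extends before the recording")
    if total_frames is not None and stop > total_frames - 1:
        raise ValueError("post-laser window extends past the recording")

    before, after = [], []
    for traj in trajectories:
        frames = traj.frames
        if frames[0] > start or frames[-1] < stop:
            continue
        y = dict(zip(frames.tolist(), traj.centers[:, 1].tolist()))
        try:
            dy_before = -(y[on_frame] - y[start]) * pixel_size_um
            dy_after = -(y[stop] - y[on_frame]) * pixel_size_um
        except KeyError:
            continue
        before.append(dy_before)
        after.append(dy_after)
    if not before:
        raise ValueError("no trajectory spans both windows")
    mb, ma = float(np.mean(before)), float(np.mean(after))
    return mb, ma, ma - mb
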