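"""Physical parameter containers for particles, fluid, flow/temperature fields and scenes.

Units are SI unless a field name carries an explicit unit suffix
(``*_um`` = micrometres, ``*_mv`` = millivolts, ``*_px`` = pixels).
Positions handed to the field callables are in micrometres, physical
frame (y up, gravity along -y); the returned vectors are SI (m/s, K/m).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Tuple

import numpy as np

__all__ = ["ParticleSpec", "FluidSpec", "FlowField", "SceneSpec"]

ShapeLabel = Literal["sphere", "rod", "cocci", "chain"]


@dataclass(frozen=True)
class ParticleSpec:
    """A single particle species.

    Parameters
    ----------
    diameter_um:
        Particle diameter ``dp`` in µm (equivalent-sphere diameter for
        non-spherical shapes).
    density:
        Particle mass density ``ρp`` in kg/m³.
    thermo_mobility:
        Thermophoretic mobility ``DT`` in m²/(s·K).  Together with the
        diffusion coefficient it sets the Soret coefficient ``ST = DT/D``;
        positive ``ST`` drives particles toward cold.
    diffusion:
        Brownian diffusion coefficient ``D`` in m²/s.
    zeta_mv:
        Zeta potential in mV (negative for every species studied here).
    shape:
        One of ``sphere``, ``rod``, ``cocci``, ``chain``; affects rendering
        only, never the equations of motion.
    motile:
        Whether the organism self-propels (metadata; not simulated).
    """

    diameter_um: float
    density: float
    thermo_mobility: float = 0.0
    diffusion: float = 0.0
    zeta_mv: float = 0.0
    shape: ShapeLabel = "sphere"
    motile: bool = False

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError(f"diameter_um must be > 0, got {self.diameter_um}")
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.diffusion < 0:
            raise ValueError(f"diffusion must be >= 0, got {self.diffusion}")
        if self.shape not in ("sphere", "rod", "cocci", "chain"):
            raise ValueError(f"unknown shape label {self.shape!r}")

    @property
    def soret_coefficient(self) -> float:
        """``ST = DT / D`` in 1/K (``inf`` when D == 0 and DT != 0)."""
        if self.diffusion == 0:
            return 0.0 if self.thermo_mobility == 0 else float("inf")
        return self.thermo_mobility / self.diffusion


@dataclass(frozen=True)
class FluidSpec:
    """Suspending medium.  Defaults are distilled water at room temperature.

    ``soret_cation``/``soret_anion`` default to Na+ and Cl-, the dominant
    ion pair of phosphate-buffered saline; their inequality is what
    generates the ionic Seebeck field near a heated tip.
    """

    density: float = 997.0          # kg/m^3
    viscosity: float = 1e-3         # Pa.s
    soret_cation: float = 4.69e-3   # 1/K (Na+)
    soret_anion: float = 7.18e-4    # 1/K (Cl-)
    gravity: float = 9.81           # m/s^2

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be > 0, got {self.viscosity}")
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")


@dataclass(frozen=True)
class FlowField:
    """Parametrized convection plume, temperature-gradient field and
    near-field attraction around a heated fiber tip.

    These are phenomenological stand-ins, not CFD/heat-transfer solutions:
    the plume magnitude decays exponentially from the tip with a range of a
    few hundred µm (the scale of thermal convection), the temperature
    gradient decays with a range of a few tens of µm (the thermophoretic
    near field), and the zeta-gated attraction is a linear map
    ``v = attraction_per_mv * |ζ|`` sharing the near-field range.

    ``convection`` selects the plume geometry: ``"plume"`` (buoyant upward
    flow, vertical setups), ``"inflow"`` (radial flow toward the tip) or
    ``"none"``.
    """

    tip_um: Tuple[float, float] = (0.0, 0.0)
    u0: float = 5e-5                    # m/s, plume magnitude at the tip
    decay_length_um: float = 300.0      # convection range
    convection: Literal["plume", "inflow", "none"] = "plume"
    grad_T0: float = 1e5                # K/m at the tip
    grad_T_range_um: float = 30.0       # thermophoretic near-field range
    attraction_per_mv: float = 5e-7     # (m/s) per mV of |zeta|
    attraction_range_um: float = 50.0

    def __post_init__(self) -> None:
        for name in ("decay_length_um", "grad_T_range_um", "attraction_range_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.convection not in ("plume", "inflow", "none"):
            raise ValueError(f"unknown convection kind {self.convection!r}")

    # -- field callables ---------------------------------------------------
    def _radial(self, x_um, y_um):
        dx = np.asarray(x_um, dtype=float) - self.tip_um[0]
        dy = np.asarray(y_um, dtype=float) - self.tip_um[1]
        r = np.hypot(dx, dy)
        safe = np.where(r > 0, r, 1.0)
        return dx / safe, dy / safe, r

    def convection_velocity(self, x_um, y_um) -> np.ndarray:
        """Convective fluid velocity in m/s at physical positions (µm)."""
        ux_hat, uy_hat, r = self._radial(x_um, y_um)
        mag = self.u0 * np.exp(-r / self.decay_length_um)
        if self.convection == "plume":
            vx = np.zeros_like(mag)
            vy = mag                      # buoyant plume rises (+y physical)
        elif self.convection == "inflow":
            vx = -mag * ux_hat
            vy = -mag * uy_hat
        else:
            vx = np.zeros_like(mag)
            vy = np.zeros_like(mag)
        return np.stack(np.broadcast_arrays(vx, vy), axis=-1)

    def temperature_gradient(self, x_um, y_um) -> np.ndarray:
        """∇T in K/m; points toward the tip (temperature rises toward it)."""
        ux_hat, uy_hat, r = self._radial(x_um, y_um)
        mag = self.grad_T0 * np.exp(-r / self.grad_T_range_um)
        return np.stack(np.broadcast_arrays(-mag * ux_hat, -mag * uy_hat), axis=-1)

    def attraction_strength(self, zeta_mv: float) -> float:
        """Near-field inward drift speed (m/s) for a surface potential ζ.

        Linear in ``|ζ|`` so that more negatively charged particles are
        pulled harder, matching the observed ordering of accumulation
        strength with zeta potential.
        """
        return self.attraction_per_mv * abs(zeta_mv)


@dataclass(frozen=True)
class SceneSpec:
    """Imaging geometry and rendering parameters.

    Image frame is y-down with 0-based indices and pixel centers at integer
    coordinates; the physical frame is y-up.  ``render_frames`` owns the
    conversion and the analysis inverts it.
    """

    image_shape: Tuple[int, int] = (256, 256)       # (H, W)
    pixel_size_um: float = 0.89
    frame_rate: float = 30.0
    fiber_tip_px: Tuple[float, float] = (128.0, 128.0)   # (x, y), image frame
    fiber_diameter_um: float = 220.0
    background_intensity: float = 220.0
    particle_intensity: float = 60.0
    noise_sd: float = 0.0
    orientation: Literal["vertical", "horizontal"] = "vertical"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not (0 <= self.particle_intensity <= 255
                and 0 <= self.background_intensity <= 255):
            raise ValueError("intensities must lie in [0, 255]")
        if self.background_intensity <= self.particle_intensity:
            raise ValueError("dark particles on a bright field require "
                             "background_intensity > particle_intensity")
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    # -- coordinate conversions -------------------------------------------
    @property
    def extent_um(self) -> Tuple[float, float]:
        """Physical (width, height) of the field of view in µm."""
        h, w = self.image_shape
        return w * self.pixel_size_um, h * self.pixel_size_um

    def px_to_um(self, xy_px: np.ndarray) -> np.ndarray:
        """Image (x, y) pixels -> physical (x, y) µm (flips the y axis)."""
        xy = np.asarray(xy_px, dtype=float)
        h = self.image_shape[0]
        out = np.empty_like(xy)
        out[..., 0] = xy[..., 0] * self.pixel_size_um
        out[..., 1] = ((h - 1) - xy[..., 1]) * self.pixel_size_um
        return out

    def um_to_px(self, xy_um: np.ndarray) -> np.ndarray:
        """Physical (x, y) µm -> image (x, y) pixels (flips the y axis)."""
        xy = np.asarray(xy_um, dtype=float)
        h = self.image_shape[0]
        out = np.empty_like(xy)
        out[..., 0] = xy[..., 0] / self.pixel_size_um
        out[..., 1] = (h - 1) - xy[..., 1] / self.pixel_size_um
        return out

    @property
    def fiber_tip_um(self) -> Tuple[float, float]:
        """Tip position in the physical frame (µm)."""
        x, y = self.px_to_um(np.array(self.fiber_tip_px))
        return float(x), float(y)
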