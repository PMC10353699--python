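"""Stokes-regime forces and dimensionless numbers for the studied microspheres.

Builds the three polystyrene sphere sizes used in the side-view
experiments, computes their terminal settling velocities, the
gravity-minus-buoyancy force each must balance, the Stokes drag at a
typical convection speed, and the Reynolds/Stokes numbers that justify
the creeping-flow analysis.
"""

import numpy as np

from ptep import (FluidSpec, ParticleSpec, net_gravity_buoyancy,
                  reynolds_number, settling_velocity, stokes_drag,
                  stokes_number)

fluid = FluidSpec()          # distilled water: 997 kg/m³, 1e-3 Pa·s
L = 220e-6                   # characteristic length = fiber diameter

print(f"{'dp (µm)':>8} {'vT (µm/s)':>10} {'Fg−Fb (N)':>11} "
      f"{'FD@vT (N)':>11} {'Re@100µm/s':>11} {'Stk@100µm/s':>12}")
for dp in (1.1, 5.0, 15.0):
    p = ParticleSpec(diameter_um=dp, density=1050.0)
    vt = settling_velocity(p, fluid)
    net = net_gravity_buoyancy(p, fluid)
    drag = stokes_drag(fluid.viscosity, dp * 1e-6, vt)
    re = reynolds_number(fluid.density, 100e-6, L, fluid.viscosity)
    stk = stokes_number(p.density, dp * 1e-6, 100e-6, fluid.viscosity, L)
    print(f"{dp:8.1f} {vt * 1e6:10.3f} {net:11.2e} {drag:11.2e} "
          f"{re:11.4f} {stk:12.2e}")

u_crit = fluid.viscosity / (fluid.density * L)
print(f"\nRe reaches 1 only at u = {u_crit * 1e3:.2f} mm/s — far above any "
      "observed particle speed, so the creeping-flow (laminar) assumption "
      "holds, and drag at the terminal velocity balances the net weight "
      "exactly (the two force columns match).")
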