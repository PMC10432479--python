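"""Magnetic trap and pore flow field of a single magnetic nanopore.

Evaluates the stray field of the magnetized NiFe film around a 3 µm pore
(Babinet superposition: uniform 0.4 T drive minus a magnetized disk) and
the unit-cell flow field, and prints the diagnostics that characterize
the device physics: where the magnetophoretic trap sits, how strong the
field gradient is near the pore edge, and that the flow field conserves
mass and matches the orifice-plus-channel resistance model.
"""

import numpy as np

from tenposim import (DeviceGeometry, FlowCondition, MagneticEnvironment,
                      PoreField, SemiAnalyticPoreFlow,
                      pore_hydraulic_resistance, solve_axisymmetric_stokes)

ML_PER_H = 1e-6 / 3600.0

geometry = DeviceGeometry(pore_diameter=3e-6)
flow = FlowCondition(2.5 * ML_PER_H)
env = MagneticEnvironment()
c = geometry.pore_radius

print(f"film: µ0·M = {env.film_saturation*4e-7*np.pi:.3f} T "
      f"(demagnetization-limited) in a {env.b_external:.1f} T drive")

# --- where is the trap? scan |B| along the membrane surface
pf = PoreField(env, geometry)
rho = np.linspace(0.2 * c, geometry.unit_cell_radius, 2000)
b2 = pf.b_squared(rho, np.full_like(rho, 5e-9), check=False)
peak = rho[np.argmax(b2)]
print(f"|B| along the membrane surface peaks at ρ = {peak*1e6:.3f} µm "
      f"(pore edge at {c*1e6:.3f} µm): the trap sits on the rim")

gr, gz = pf.grad_b_squared_cyl(c, 100e-9)
print(f"∇|B|² 100 nm above the rim: ({float(gr):.3g}, {float(gz):.3g}) T²/m")

# --- flow field: mass conservation and hydraulic resistance
sa = SemiAnalyticPoreFlow(geometry, flow)
fluxes = [sa.flux_through_plane(z) / sa.per_pore_flux
          for z in (2e-6, 0.0, -3e-6)]
print("flux through planes above/at/below the pore (fraction of ɸ/N): "
      + ", ".join(f"{f:.4f}" for f in fluxes))

sol = solve_axisymmetric_stokes(geometry, flow, nr=96, nz=192)
r_num = sol.pressure_drop() / flow.per_pore_flux(geometry)
r_formula = pore_hydraulic_resistance(geometry)
print(f"pore hydraulic resistance: numerical {r_num:.3g} Pa·s/m³ vs "
      f"orifice+channel formula {r_formula:.3g} Pa·s/m³ "
      f"({100*abs(r_num/r_formula-1):.1f}% apart)")
print("-> the trap is a rim-edge field maximum; the flow solvers agree with")
print("   exact mass conservation and the classical resistance model.")
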