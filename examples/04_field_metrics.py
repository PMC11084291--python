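"""Compute near-wall and field metrics on analytic flow fixtures.

Each fixture carries its closed-form expectations, so every printed
metric can be compared against theory on the spot.
"""

import graftflow as gf
from graftflow.constants import PhysicalConstants
from graftflow.synthetic_fields import (
    make_oscillating_wss,
    make_poiseuille,
    make_solid_rotation,
)

constants = PhysicalConstants()  # mu = 0.004 Pa s, rho = 1060 kg/m^3

# Poiseuille tube: flow rate and viscous dissipation
field, analytic = make_poiseuille(n=64, nz=8)
q = gf.section_flow_rate(field, (0, 0, 0.05), (0, 0, 1))[0]
loss = gf.viscous_energy_loss(field, constants, 0.0, 1.0)
print(f"Poiseuille flow rate   : {q:.4e} m^3/s "
      f"(Hagen-Poiseuille {analytic['flow_rate']:.4e})")
print(f"dissipation over 1 s   : {loss:.4e} J (dP*Q = "
      f"{analytic['dissipation_rate']:.4e} W x 1 s)")

# Solid-body rotation: uniform curl, zero dissipation
rot, rot_analytic = make_solid_rotation(omega=(0, 0, 5.0))
vort = gf.vorticity(rot)
print(f"solid-rotation |curl|  : {vort.values.mean():.2f} 1/s "
      f"(2*Omega = {rot_analytic['curl_magnitude']:.2f})")
print(f"solid-rotation loss    : "
      f"{gf.viscous_energy_loss(rot, constants, 0, 1):.1e} J (rigid motion)")

# Oscillating wall shear: OSI from fully reversing to unidirectional
for frac in (0.0, 0.25, 0.5):
    wss, wss_analytic = make_oscillating_wss(reversal_fraction=frac)
    print(f"OSI at reversal fraction {frac:4.2f}: "
          f"{gf.osi(wss).values[0]:.3f} (closed form {wss_analytic['osi']:.3f})")

# Reynolds number at the artificial peak systolic through the 14 mm graft
re = gf.reynolds_number(constants, mean_speed=1.35, diameter=0.014)
print(f"peak-systolic Re       : {re:.0f} (transitional: above 5000)")
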