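"""Sample the bee forward-flight kinematics over one flap cycle.

The 3D wing path (yaw/roll/pitch about the wing base) is rendered in 2D as
x/y translations of the mid-span section at pivot radius r0 = 6.61 mm plus
the pitch angle theta3.  At 150 Hz with a 110 degree stroke the section's
peak speed is ~12 m/s, which dominates the 1-5 m/s flight speeds (low
advance ratio).
"""

import numpy as np

import wingflow as wf
from wingflow import kinematics as k

spec = k.forward_flight_spec(V_inf=3.0)
print(f"flap frequency      : {spec.f} Hz")
print(f"stroke amplitude    : {spec.theta1A} deg -> x excursion "
      f"{2 * 6.61 * np.radians(110):.2f} mm peak-to-peak")
print(f"deviation amplitude : {spec.theta2A} deg (table lookup at 3 m/s)")
print(f"peak section speed  : {k.v_kin_max(spec):.2f} m/s")
print(f"Reynolds number     : "
      f"{k.reynolds(spec, 3.0, 1.204, 1.82e-5, 0.004):.0f} (air, c = 4 mm)")

print("\n tau     x/mm     y/mm   theta3/deg   |v|/(m/s)")
for tau in np.arange(0.0, 1.01, 0.125):
    s = k.motion_sample(tau / spec.f, spec)
    print(f"{tau:4.3f} {s.x:8.2f} {s.y:8.2f} {s.theta3:10.1f} "
          f"{np.hypot(s.vx, s.vy):10.2f}")
# the section is fastest and most pitched at tau = 0.25 and 0.75 (the two
# half-stroke midpoints) and momentarily still at the reversals.
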