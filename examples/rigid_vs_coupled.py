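"""Quantify the fluid-structure interaction effect on the surface load.

Runs the same jet twice -- once on a rigid, non-deforming cornea and once
fully coupled -- and reports the attenuation of the peak apex pressure
plus the location of the peripheral negative-pressure (suction) annulus.
"""

import numpy as np

from tonosim import JetConfig, build_eye, run_pair
from tonosim.jet import central_concavity, surface_pressure_field

eye = build_eye(iop=15.0)
rigid, coupled, decrease = run_pair(eye)

print(f"peak apex pressure, rigid  : {np.max(rigid.apex_p):.1f} mmHg")
print(f"peak apex pressure, coupled: {np.max(coupled.apex_p):.1f} mmHg")
print(f"FSI attenuation            : {decrease:.2f} %")

# surface pressure distribution at the instant of highest concavity
i = int(np.argmax(coupled.apex_disp))
r, z = coupled.prof_r[i], coupled.prof_z[i]
s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(r), np.diff(z)))])
fld = surface_pressure_field(
    JetConfig(), s, coupled.t[i], mode="coupled",
    apex_displacement=float(coupled.apex_disp[i]),
    concavity=central_concavity(s, coupled.prof_z[0] - z, 2.4))
j = int(np.argmin(fld.pressure))
print(f"suction annulus minimum    : {fld.pressure[j]:.0f} Pa at "
      f"{s[j]:.2f} mm from the apex")

# The deforming cornea retreats from the nozzle and shelters its own
# stagnation point, so the coupled run always sees a lower peak pressure;
# the radial wall jet produces the negative-pressure ring on the 2-4 mm
# peripheral cornea.
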