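"""Simulate one air-puff test and extract the dynamic corneal response.

Builds a default eye (IOP 15 mmHg, CCT 545 um, mu 0.0712 MPa, R 7.8 mm),
inverts it to its stress-free configuration, re-inflates it, runs the
coupled 30 ms jet simulation and reports the nine DCR parameters.
"""

from tonosim import build_eye, extract_dcr, run_simulation

eye = build_eye(iop=15.0)
trace = run_simulation(eye)
rec = extract_dcr(trace, iop=15.0)

print(f"stress-free inversion converged in {eye.stress_free_iters} iterations")
print(f"peak apex displacement : {trace.apex_disp.max():.3f} mm")
print(f"cavity pressure rise   : {trace.cavity_p.max() - 15.0:.2f} mmHg")
for name, value in rec.as_dict().items():
    print(f"{name:22s}: {value:.3f}")

# A1 marks the first instant the central cornea flattens (the chord length
# and the air pressure AP1 at that instant are the tonometer's raw IOP
# signal); HC is the deepest indentation, and SP-HC = (AP1 - IOP) /
# (HC deformation - A1 deformation) is the corneal stiffness index.
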