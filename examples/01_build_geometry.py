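"""Build one implant-in-bone scenario and interrogate its geometry.

Constructs implant 8 (D3.6-L9, trapezoid thread, mixed truncation, small
milling) placed 1 mm subcrestally with the 0.25 mm apposition collar, and
prints the quantities a clinician or engineer would first check.
"""

import numpy as np

import perifem as pf

catalogue = pf.implant_catalogue()
spec = catalogue["8"]
scenario = pf.build_scenario(spec, "P1")

solid = scenario.implant
print(f"implant {spec.label}: D = {spec.D_mm} mm, L = {spec.L_mm} mm, "
      f"thread {spec.thread.profile_kind.value}-{spec.thread.truncation.value}")
print(f"  body volume          : {solid.body_volume():6.1f} mm^3")
print(f"  platform depth       : {-scenario.platform_z:6.2f} mm below crest")
print(f"  apex depth           : {-scenario.apex_z:6.2f} mm below crest")

# the apposition collar: bone top right at the implant wall vs far away
wall, far = scenario.top_surface(np.array([spec.D_mm / 2, 6.0]))
print(f"  bone top at the wall : {wall:6.2f} mm (collar over the platform)")
print(f"  bone top far away    : {far:6.2f} mm (pristine crest)")

# region classification of a few probe points
probes = np.array([[0.0, 0.0, 3.0],    # abutment axis
                   [1.6, 0.0, -0.85],  # apposition collar
                   [2.4, 0.0, -1.5],   # crestal cortical
                   [2.2, 0.0, -6.0]])  # mid trabecular
names = {0: "outside", 1: "implant", 2: "abutment",
         3: "cortical", 4: "trabecular"}
for p, r in zip(probes, scenario.region_of(probes)):
    print(f"  point {p} -> {names[int(r)]}")
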