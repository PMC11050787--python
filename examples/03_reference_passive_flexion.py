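"""Passive flexion of the synthetic knee in the rigid reference model.

Generates the synthetic implant surfaces and 16-bundle ligament set,
finds the 0-degree reference configuration (ligament-contact equilibrium)
and sweeps flexion to 80 degrees with the five unconstrained DOFs settling
into quasi-static equilibrium at every angle.  Takes ~20 s.
"""

from vivolig import (
    ReferenceRunSpec,
    make_implant_surfaces,
    make_ligament_set,
    nominal_reference_pose,
    run_reference_flexion,
)

femoral, tibial = make_implant_surfaces()
apparatus = make_ligament_set()
spec = ReferenceRunSpec(
    schedule=[float(a) for a in range(0, 81, 4)],
    apparatus=apparatus,
    tibial_surface=tibial,
    femoral_surface=femoral,
)
result = run_reference_flexion(spec, nominal_pose=nominal_reference_pose())

cols = ["flexion_deg", "axial_force_N", "tibial_ie_deg", "femoral_ap_mm"]
print(result.table[cols].to_string(index=False, float_format=lambda x: f"{x:9.2f}"))
print(
    "\naxial force is highest at extension (taut posterior capsule), drops as it\n"
    "slackens, then rises again as collaterals and PCL tighten; the tibia rotates\n"
    "internally near extension (screw-home) and the femur rolls back posteriorly\n"
    "(femoral AP decreasing) in deep flexion."
)
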