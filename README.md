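# vivolig

Virtual-ligament joint-simulator emulation for total knee replacement (TKR)
testing: quantifying how unsensed structural compliance of a six-DOF
simulator's upper actuator corrupts virtual ligament force calculation, and
how preloading the reference configuration compensates for it.

## The problem

Six-DOF joint simulators test knee endoprostheses under physiological load:
the femoral component hangs on a two-DOF gimbal arm, the tibial component
rides a four-DOF cross table, and a built-in *virtual ligament model*
applies the restoring forces of a software-defined ligament apparatus
through the actuators. Each virtual ligament is a tension-only nonlinear
spring between points fixed to the two implants; its force follows the
Wismans/Blankevoort law

```
f(ε) = 0                  ε ≤ 0
f(ε) = k·ε²/(4εₗ)         0 < ε ≤ 2εₗ        (quadratic toe)
f(ε) = k·(ε − εₗ)         ε > 2εₗ            (linear)
```

with engineering strain ε = (L − L₀)/L₀, stiffness k (N per unit strain)
and a transition to linear behaviour at 2εₗ = 6 % strain.

The machine computes ligament lengths from its *sensed* joint coordinates.
Under the high contact forces of an artificial knee the gimbal arms deflect
elastically by `s(F)` — 0.7 mm at 500 N, then ≈0.6 mm per 1000 N — and the
angle sensors do not register it. The sensed insertion-point distances are
therefore too short by up to 2.2 mm at 3000 N, which silently slashes the
applied ligament forces. Setting the reference configuration under an
elevated contact force (the mean of the expected cycle loads) cancels the
error at that load and shrinks it elsewhere.

`vivolig` reproduces this whole situation in software: a rigid quasi-static
knee model (ligaments + elastic-foundation implant contact, flexion
prescribed, five DOFs in equilibrium) plays the role of ground truth, and
an emulator runs the same protocol with the ligament wrench computed at the
compliance-corrupted sensed pose while contact acts at the true pose.
It is aimed at implant-testing and musculoskeletal-modelling groups who
want to predict, size or compensate this artifact before machine time.

## Package layout

| module | contents |
| --- | --- |
| `vivolig.ligaments` | force law, bundle calibration, apparatus wrench, virtual resection |
| `vivolig.compliance` | degressive-then-linear actuator deflection curve, forward/inverse |
| `vivolig.kinematics` | six-coordinate joint pose (Grood–Suntay convention), rigid transforms |
| `vivolig.contact` | elastic-foundation contact with regularized Coulomb friction on triangle meshes |
| `vivolig.reference_model` | ground-truth quasi-static equilibrium sweeps, PCL-resection sweep |
| `vivolig.emulator` | reference configuration under preload, sensed-pose corruption, passive-flexion protocol |
| `vivolig.synthdata` | synthetic implant surfaces, 16-bundle ligament set, bench fixtures |
| `vivolig.experiments` / `vivolig.cli` | end-to-end experiment drivers and the thin `vivolig` CLI |

## Worked example

```python
import numpy as np
from vivolig import (default_compliance_curve, make_exemplary_lcl_fixture,
                     worked_example_force_vs_load)

curve = default_compliance_curve()          # 0.7 mm @ 500 N, 0.6 mm/kN
bundle = make_exemplary_lcl_fixture()       # k=3300 N/strain, ε_r=11 %, L0=46.5 mm
table = worked_example_force_vs_load(bundle, curve, np.linspace(30, 3000, 7))
print(table)
```

```
    load_N     s1_mm  sensed_force_N
     30.00      0.21          249.12
    525.00      0.71          213.26
   1020.00      1.01          192.18
   1515.00      1.31          171.10
   2010.00      1.61          150.03
   2505.00      1.90          128.95
   3000.00      2.20          107.87
```

The bundle is pretensioned to 264 N at its 11 % reference strain. As the
vertical load grows, the unsensed deflection `s1` shortens the sensed
fiber, and the force the machine would apply falls to ≈108 N (−60 %) at
3000 N — although the physical insertion points never moved relative to
each other. `examples/` contains five such narrated scripts, from the bare
force law up to the full preload-compensation comparison and the virtual
PCL resection (`python examples/04_compliance_artifact.py`).

A thin CLI wraps the same machinery:

```
vivolig check                      # desk-scale bench numbers
vivolig fixtures generate --out fx # synthetic meshes + ligament set
vivolig run config.yaml            # worked_example | flexion_compare | pcl_sweep
```

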