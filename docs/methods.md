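# Methods

## Scope and idea

`vivolig` models a six-DOF knee joint simulator whose built-in virtual
ligament model is corrupted by unsensed elastic deflection of the upper
(gimbal) actuator. Two models share every ingredient except that
corruption:

* the **reference model** — a quasi-static, rigid ground truth in which
  ligament and contact wrenches both act at the true relative pose of the
  implant components (the software analogue of a multibody simulation);
* the **emulator** — the same equilibrium problem, but the ligament wrench
  is evaluated at the *sensed* pose, which sits proximally of the true pose
  by `s(F) − s_ref`, where `s(F)` is the load-dependent actuator deflection
  and `s_ref` the deflection frozen in when the reference configuration was
  set under a chosen preload.

Comparing the two isolates the compliance artifact exactly; everything
else (geometry, ligament parameters, contact law, solver) is bit-identical.

## Ligament model

Bundles are tension-only fibers on the straight line between an origin
fixed in the femoral-component frame and an insertion fixed in the
tibial-component frame (no wrapping). The force law is the piecewise
Wismans/Blankevoort form, C1-continuous, with the quadratic-to-linear
transition at 6 % strain (`2εₗ = 0.06`). Strain is engineering strain.
Rest lengths are never entered directly: each bundle stores its strain at
the reference configuration and `L0 = L_ref/(1+ε_r)` is computed there, so
the stored reference strain is reproduced exactly (round-trip tested to
1e−9). Virtual resection multiplies a bundle's force by a scale in [0, 1]
without touching its rest length.

The physical simulator prints 268 N for the exemplary bundle
(k = 3300 N/strain, ε = 0.11); the standard formulation above gives 264 N.
The machine's internal formulation is proprietary, so 264 N is taken as
correct and agreement within 2 % is treated as a match; the printed value
is never hard-coded.

## Actuator compliance

The measured deflection of the upper actuator is degressive up to a break
load and linear beyond. It is modelled as `s(F) = s_b (F/F_b)^p` below the
break and `s_b + m (F − F_b)` above, with `p = m F_b / s_b` fixed by C1
continuity — the sub-break shape is only known qualitatively, so a power
law with the exponent pinned by slope matching is the minimal smooth
choice. Anchors: `F_b = 500 N`, `s_b = 0.7 mm`, `m = 0.0006 mm/N` (the
0° flexion-arm orientation, the most compliant one measured). Other arm
angles multiply the curve by configurable factors (defaults 0.9/0.8/0.7 at
30°/60°/90°); only the 0° anchors are backed by published numbers, and
nothing downstream uses the placeholders. The deflection acts purely along
the distal–proximal axis; bending and torsion of the arm segments are
lumped into this scalar.

## Kinematics

Joint coordinates follow the Grood–Suntay convention for a right knee:
flexion about the femoral gimbal (medial–lateral) axis, adduction about
the floating anterior axis, internal rotation about the tibial mechanical
axis; translations (anterior/medial/proximal positive) along the rotated
tibial axes. The rotation sequence is not dictated by the hardware
description, so the convention matching the physical gimbal/cross-table
layout was chosen; at ≤ 90° flexion the decomposition is far from gimbal
lock and round-trips to 1e−9. Femoral AP displacement is reported as the
negated tibial AP coordinate, relative to the 0° reference configuration.

## Contact

Elastic-foundation (bed-of-springs) contact stands in for polygonal
contact algorithms: pressure = `E_f ×` penetration depth, sampled at the
tibial face centroids with face areas as quadrature weights, acting along
the femoral outward normal at the closest femoral point. Closest points
are found with a cKDTree over femoral triangle centroids followed by exact
point–triangle projection on the candidates; ties break on the smallest
face index, so the field is deterministic. Flat-on-flat configurations
reproduce the closed form `E_f · d · A` to well under 1 % at the default
sampling density.

Friction is regularized Coulomb: tangential traction opposes the relative
slip of the tibial material accumulated over the previous quasi-static
step and saturates at `μ ×` normal pressure through a `tanh` ramp over a
0.05 mm regularization slip. Defaults `E_f = 30 N/mm³` (order of a UHMWPE
foundation) and `μ = 0.04` (lubricated metal-on-polyethylene); both are
config parameters because no published values exist for the machine setup
— the friction coefficient in particular is known only to have been tuned
upward to reconcile experiment and simulation, and the package reproduces
that mechanism (raising μ shifts the femur posteriorly at mid flexion).

## Equilibrium and protocols

Flexion is position-controlled; the remaining five DOFs are
force-controlled and settle where the generalized forces (virtual work of
the total wrench against the numerically differentiated pose Jacobian)
vanish: below 0.5 N on translations and 50 N·mm on rotations. The solve is
a damped Newton iteration on the scaled 5-vector residual with a central
difference Jacobian (step 1e−3 mm / 1e−3 deg), step capping and
backtracking. Sweeps warm-start each angle from the previous solution and
bisect the flexion step (down to 0.25°) on non-convergence; repeated
failures abort with a partial, flagged result.

The servo/iterative-learning control of the physical machine is idealized
as exact equilibrium per step: the hardware's converged averaged cycles
are what this computes directly, and the control internals are
manufacturer-proprietary.

In the emulator each step couples the equilibrium to the deflection by
successive substitution (under-relaxation 0.5): solve with the sensed-pose
shift frozen, update `s` from the resulting axial contact force, repeat
until the deflection changes by < 1e−4 mm. The axial force driving the
deflection is the contact force along the tibial mechanical axis — the
dominant, vertically aligned load in this rig. The machine's ligament
resultant is computed from sensed insertion positions and transferred as a
wrench about the true tibial origin.

**Reference configuration.** Ligament reference strains are defined at the
0° equilibrium, which itself depends on the ligament forces; the package
iterates calibrate → solve (3 passes, sub-micron pose changes) to obtain a
self-consistent reference state shared by both models. The preload enters
the emulator only through `s_ref = s(preload)`: the additional contact
penetration under the preload (~0.1 mm at 800 N, second order against the
0.7–1.2 mm actuator deflection) is folded into `s_ref` rather than
re-solving the preloaded pose. With the preload equal to the running
contact force the sensed-pose shift vanishes identically, which is the
compensation property the procedure relies on.

## Synthetic fixtures

No implant geometry or ligament coordinate set is publicly available, so
the generator builds a deliberately simple synthetic knee, documented as a
stand-in and never claimed to match any commercial implant:

* **Surfaces** — two toroidal femoral condyle patches (sagittal radius
  25 mm, frontal 20 mm, spacing 44 mm; a single sagittal radius, no
  J-curve) against two paraboloid tibial dishes (radii 40/24 mm),
  sagittally symmetric to 1e−6 mm, ~14k/3k faces at default resolution
  (~1 mm contact sampling; fewer than 500 faces is rejected).
* **Ligaments** — 16 bundles with the census 2 PCL, 3 MCL, 3 LCL,
  1 opMCL, 2 dMCL, 2 OPL, 1 APL, 1 mpCAP, 1 lpCAP. Coordinates and
  stiffnesses are fixture constants chosen for anatomical plausibility
  and for the qualitative passive-flexion physiology: posterior capsule
  structures attach posterior-proximally on the femur and are taut only
  near extension; collaterals attach near the flexion axis and stay
  near-isometric; the PCL runs from the posterior-distal notch to the
  posterior tibia, slack at extension and monotonically tightening from
  ~45° onward. Optional seeded jitter (default 0 mm) supports robustness
  studies without breaking exactness of the defaults.
* **Bench fixture** — the exemplary vertical LCL bundle. Its rest length
  (46.5 mm) is not a published number: it is the unique value for which
  shortening the fiber by the 2.2 mm peak deflection drives the force from
  its 11 %-strain pretension to the reported ≈108 N (a 1-D solve of the
  force law fixes it).

With these defaults the reference model produces ≈1060 N axial force at
extension decaying to ≈280 N by 15° (capsule slackening), rising again to
≈560 N at 80° (collaterals + PCL); ≈2.9° of internal tibial rotation; an
anterior femoral drift of ≈1.7 mm followed by posterior rollback. These
magnitudes sit in the physiological range for passive flexion of a TKR but
are fixture properties, not predictions for any specific implant.

**What the synthetic data does not emulate:** real condylar J-curves and
asymmetric condyles, measured ligament footprints, embedding or alignment
errors, lubricant rheology, force-sensor noise, and control-loop tracking
error. Passing tests therefore demonstrate the mechanics of the
compliance artifact and its compensation, not quantitative agreement with
any physical test bench.

## Problem sizes and numerical choices

Flexion sweeps in the tests and experiment drivers use a 2° grid over
0–80° (41 equilibria per run; the protocol default is the 1° grid);
contact uses the default mesh resolution above. The deflection fixed
point typically converges in 3–6 inner solves after the first step since
each inner solve warm-starts at the previous solution. All computations
are deterministic: identical configurations reproduce byte-identical CSV
output, and the only randomness in the package (fixture jitter) is seeded
and off by default.

## Known limitations

* The compliance corruption is a pure distal–proximal shift; arm bending
  that would also tilt the sensed frame is not represented.
* Elastic-foundation contact has no tangential coupling between samples
  and no conformal pressure redistribution; absolute contact pressures are
  not meaningful, only resultants.
* The fixed flexion axis of the synthetic femur ignores the moving
  flexion axis of real condyles, which changes how sharply posterior
  structures slacken.
* Quasi-static only: inertia, impact and cyclic (wear, creep) effects are
  out of scope.
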