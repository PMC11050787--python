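"""The nonlinear virtual-ligament force law.

Evaluates the quadratic-to-linear (Wismans-type) ligament law for the
exemplary lateral-collateral bundle: stiffness 3300 N per unit strain,
11 % reference strain, transition to linear behaviour at 6 % strain.
"""

import numpy as np

from vivolig import force_from_strain, make_exemplary_lcl_fixture

bundle = make_exemplary_lcl_fixture()
print(f"exemplary LCL bundle: k = {bundle.stiffness_k:.0f} N/strain, "
      f"eps_r = {bundle.reference_strain}, L0 = {bundle.rest_length} mm")

for eps in (0.0, 0.03, 0.06, 0.11):
    f = force_from_strain(eps, bundle.stiffness_k, bundle.linear_limit)
    print(f"  strain {eps:5.2f} -> force {f:7.2f} N")

# The force at the 11 % reference strain is the bundle's pretension at the
# start of a test (264 N here; the physical simulator reports ~268 N with
# its proprietary internal formulation, a 1.5 % difference).
ref = force_from_strain(bundle.reference_strain, bundle.stiffness_k, bundle.linear_limit)
print(f"pretension at reference configuration: {ref:.1f} N")

# Tension only: slack configurations carry no load.
assert force_from_strain(-0.05, bundle.stiffness_k, bundle.linear_limit) == 0.0
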