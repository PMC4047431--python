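"""Forward model: iris deformation under a pressure differential.

Builds the default axisymmetric iris model, assigns the reference
cohort-mean Ogden material, applies the anterior pressure program up to
25 mmHg with the lens receding along the fitted anterior-chamber-depth
line, and prints the axial displacement of three mid-segment surface
points per pressure level.
"""

import numpy as np

from irisid import (BoundaryConditions, GeometryConfig, LoadProgram,
                    build_reference_geometry, extract_point_displacements,
                    fit_acd_vs_pressure, run_forward)
from irisid.datasets import reference_acd_series, reference_mean_parameters

params = reference_mean_parameters()
mesh = build_reference_geometry(GeometryConfig())
acd_fit = fit_acd_vs_pressure(reference_acd_series())
bc = BoundaryConditions(lens_translation=acd_fit.slope)

solution = run_forward(params, mesh, bc, LoadProgram(n_increments=5))

points = [(3.5, -0.2), (4.0, -0.2), (4.5, -0.2)]   # anterior mid-segment
tracks = extract_point_displacements(solution, mesh, points)

print(f"material: mu = {params.mu} MPa, alpha = {params.alpha}")
print(f"lens recession: {acd_fit.slope:.5f} mm/mmHg")
print()
print("dp (mmHg)  " + "  ".join(f"u_y {t.point_id} (mm)" for t in tracks))
for i, dp in enumerate(solution.levels):
    row = "  ".join(f"{t.uy[i]:11.4f}" for t in tracks)
    print(f"{dp:8.1f}  {row}")
print()
print("Positive u_y is posterior motion: the iris bows toward the lens,")
print("fastest at low pressure and saturating once it drapes onto the")
print(f"lens ({len(solution.contact_nodes[-1])} surface nodes in contact "
      "at 25 mmHg).")
print(f"max |J - 1| = {solution.max_volume_error.max():.2e} "
      "(near-incompressibility)")
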