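"""Anterior chamber depth vs pressure: the lens boundary condition.

Fits the linear ACD-pressure relation to the reference perfusion series
and prints the axial lens translation it prescribes in the forward model.
"""

from irisid import fit_acd_vs_pressure, lens_displacement
from irisid.datasets import reference_acd_series

series = reference_acd_series()
fit = fit_acd_vs_pressure(series)

print("dp (mmHg)   ACD (mm)")
for dp, acd in zip(series.dp, series.acd):
    print(f"{dp:8.2f}   {acd:.3f}")
print()
print(f"OLS fit: ACD = {fit.intercept:.4f} + {fit.slope:.6f} * dp "
      f"(residual SE {fit.residual_se:.4f} mm)")
for dp in (10.0, 25.0):
    print(f"lens translation at {dp:.0f} mmHg: "
          f"{lens_displacement(fit, dp):.4f} mm posteriorly")
print()
print("The anterior chamber deepens almost linearly with the pressure")
print("differential; the rigid lens in the model recedes by exactly this")
print("depth change at each load level.")
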