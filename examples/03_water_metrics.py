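"""Water-availability predictors from monthly precipitation.

Computes the Walsh-Lawler seasonality index (0 = uniform rain, 11/6 =
all rain in one month), the normalized inter-annual variability (std of
annual sums / MAP), and the aridity index PET/MAP (> 1 = water deficit).
"""

import numpy as np

from vegres import PrecipGenParams, aridity_index, gen_precip_monthly
from vegres import interannual_variability, walsh_lawler_si

# concentrated monsoon-like regime: 60% of rain in 3 months
weights = np.array([1, 1, 2, 5, 10, 25, 25, 15, 8, 4, 2, 2], dtype=float)
weights /= weights.sum()
params = PrecipGenParams(
    map_mm=650.0, month_weights=tuple(weights), interannual_cv=0.25, n_years=40, seed=3
)
precip = gen_precip_monthly(params)

si = walsh_lawler_si(precip)
iav = interannual_variability(precip)
aridity = aridity_index(pet_mm=1400.0, map_mm=float(precip.annual_sums().mean()))

print(f"mean annual precipitation  MAP     = {precip.annual_sums().mean():7.1f} mm/yr")
print(f"Walsh-Lawler seasonality   SI      = {si:7.3f}  (target from weights: "
      f"{np.abs(weights - 1 / 12).sum():.3f})")
print(f"inter-annual variability   std/MAP = {iav:7.3f}  (generator target 0.250)")
print(f"aridity (PET/MAP)                  = {aridity:7.3f}  (> 1: water deficit)")
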