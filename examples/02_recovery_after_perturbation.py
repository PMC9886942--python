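"""Empirical recovery rate from an abrupt perturbation.

Injects an instantaneous 8-standard-deviation drop with exponential
relaxation at r = -2/yr into an OU anomaly series, then runs the full
detection chain: moving-window slopes, 99th-percentile thresholding,
drop + Kolmogorov-Smirnov validation, and exponential recovery fitting.
"""

import numpy as np

from vegres import OUParams, ResidualSeries, find_recovery_events, gen_ou_residual
from vegres.synthetic import PerturbationTruth, perturbation_component

r_true, std = -2.0, 0.04
ou = OUParams(r_true, sigma=std * 2.0, dt=1 / 24, n_steps=720, seed=7)
truth = PerturbationTruth(time_index=300, amplitude=-8 * std, recovery_rate_true=r_true)
residual = ResidualSeries(
    gen_ou_residual(ou).values + perturbation_component(720, 1 / 24, [truth]), dt=1 / 24
)

fits, counts = find_recovery_events(residual)
print(f"injected drop at sample {truth.time_index} (year {truth.time_index / 24:.1f}), "
      f"amplitude {truth.amplitude:+.2f}, true r = {r_true:+.1f}/yr")
print(f"filter chain: {counts['candidates']} candidates -> "
      f"{counts['validated']} KS-validated -> {counts['accepted']} accepted fits")
for f in fits:
    if f.accepted:
        p = f.perturbation
        print(f"  event at sample {p.peak_sample}: fitted r = {f.r:+.2f}/yr, "
              f"x0 = {f.x0:+.3f}, R^2 = {f.r2:.2f}")
print()
print("A negative fitted r means the system relaxes back at rate |r|; it should")
print("match the injected recovery rate within sampling noise.")
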