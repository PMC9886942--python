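"""Restoring rate of a linearized vegetation system, two ways.

Simulates stationary Ornstein-Uhlenbeck anomaly series with a known
restoring rate lambda and recovers lambda by inverting (a) the lag-1
autocorrelation, AC1 = exp(lambda*dt), and (b) the stationary variance,
Var = -sigma^2/(2*lambda). A single 30-year pixel carries substantial
sampling noise; the ensemble median converges on the truth.
"""

import numpy as np

from vegres import OUParams, estimate_resilience, gen_ou_residual

lambda_true = -2.0  # 1/year; negative = stable, closer to 0 = less resilient

single = estimate_resilience(
    gen_ou_residual(OUParams(lambda_true, sigma=0.1, dt=1 / 24, n_steps=720, seed=42))
)
ensemble = [
    estimate_resilience(
        gen_ou_residual(OUParams(lambda_true, sigma=0.1, dt=1 / 24, n_steps=720, seed=s))
    )
    for s in range(100)
]
med_ac1 = np.median([e.lambda_ac1 for e in ensemble])
med_var = np.median([e.lambda_var for e in ensemble])

print(f"true restoring rate       lambda = {lambda_true:+.3f} /yr")
print(f"single pixel (30 yr):     AC1 = {single.ac1:.3f}  ->  "
      f"lambda_ac1 = {single.lambda_ac1:+.2f}, lambda_var = {single.lambda_var:+.2f}")
print(f"100-pixel ensemble median:         "
      f"lambda_ac1 = {med_ac1:+.2f}, lambda_var = {med_var:+.2f}")
print()
print("One pixel's estimate scatters around the truth (here by tenths of 1/yr);")
print("the ensemble median recovers the prescribed rate. The variance route is")
print("biased slightly toward zero at finite sampling steps (docs/methods.md).")
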