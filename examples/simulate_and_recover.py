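"""Generate synthetic NDGM series and check the fitter recovers the truth.

A noise-free draw lies exactly on the model manifold, so refitting must
return the generating coefficients to numerical precision; with mild
multiplicative noise the estimates scatter around the truth.
"""

import numpy as np

import greycast as gc

truth = dict(beta1=1.05, beta2=300.0, beta3=1500.0, x0=30000.0)

exact = gc.generate(gc.GeneratorSpec(**truth, sigma=0.0))
f = gc.fit(exact)
print("noise-free draw:")
print(f"  true beta1=1.05, recovered {f.params.beta1:.12f}  (MAPE {f.mape_percent:.2e}%)")

estimates = []
for seed in range(50):
    noisy = gc.generate(gc.GeneratorSpec(**truth, sigma=0.01, seed=seed))
    estimates.append(gc.fit(noisy).params.beta1)
print("sigma=0.01, 50 seeds:")
print(f"  median recovered beta1 {np.median(estimates):.4f}, "
      f"spread {np.std(estimates):.4f}")

# The noise-free recovery demonstrates the estimation chain is exact on the
# model's own output; the noisy median near 1.05 shows the estimator is not
# systematically biased by proportional count noise of realistic size.
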