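"""Fit the oscillatory kernel to a noisy rhythm and inspect the posterior.

The GP posterior mean reconstructs the underlying waveform between (and at)
the observed time points; its standard deviation quantifies uncertainty,
reverting to the prior far from any data.
"""

import numpy as np

from odegp import WaveSpec, collapse_replicates, gen_wave, normalize
from odegp.gp_regression import OptimizerConfig, optimize_hyperparameters, posterior

spec = WaveSpec(family="nonstat_decreasing", A=5.0, tau=72.0, sigma=0.3, seed=7)
ds = collapse_replicates(normalize(gen_wave(spec), "zscore"), "stack")

fit = optimize_hyperparameters(ds, "nonstationary", OptimizerConfig(seed=0))
curve = posterior(ds, fit, np.arange(0.0, 48.1, 6.0))

print(f"maximized marginal log-likelihood: {fit.mll:.2f}\n")
print("time[h]   posterior mean   posterior sd")
for t, m, s in zip(curve.query_times, curve.mean, curve.sd):
    print(f"{t:6.1f}   {m:12.3f}   {s:10.3f}")

print("\nThe mean tracks the z-scored decreasing-period waveform; the sd is")
print("smallest at the sampled times and grows between them.")
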