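"""How intercellular coupling creates a population-level rhythm.

Simulates 50 noisy, low-amplitude Poincare oscillators with heterogeneous
free-running periods (24 +- 1.5 h).  Uncoupled, their phases stay spread out
and the population-average rhythm is weak (a finite dish never averages to
exactly flat); with mean-field coupling they synchronize and the bulk rhythm
sharpens dramatically.  The Bayes-factor detector run on the sampled
population average quantifies exactly this transition.
"""

import numpy as np

from odegp import PoincarePopulation, bayes_factor, simulate
from odegp.detection import DetectionConfig
from odegp.gp_regression import OptimizerConfig

config = DetectionConfig(optimizer=OptimizerConfig(n_restarts=4, seed=0))

for K in (0.0, 0.3):
    pop = PoincarePopulation(N=50, A=0.5, gamma=0.1, K=K, noise=0.3, seed=4)
    traj, ds = simulate(pop, t_end=96.0, dt=0.02, sample_every=3.0,
                        sample_start=60.0, n_replicates=3, obs_noise=0.05)
    phases = np.arctan2(traj.y[-1], traj.x[-1])
    order = np.abs(np.exp(1j * phases).mean())
    call = bayes_factor(ds, config)
    print(f"K = {K:4.2f}: phase coherence R = {order:.2f}   "
          f"log10 BF = {call.log10_bf:6.2f}   label = {call.label}")

print("\nR near 0 means dephased single-cell clocks; coupling raises R toward 1")
print("and with it the evidence (log10 BF) for a population-level oscillation.")
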