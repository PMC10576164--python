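"""Call a single dataset oscillatory or not.

Generates one strongly rhythmic wave (24 h sine, amplitude 3, noise sd 0.1,
three replicates over 48 h) and one pure-noise wave, and runs the two-kernel
Bayes-factor test on each.  A Bayes factor far above the default cutoff of 14
is strong evidence for oscillation; values near 1 favour the flat null.
"""

from odegp import WaveSpec, bayes_factor, gen_wave

for spec in (
    WaveSpec(family="stationary_symmetric", A1=3.0, A2=0.0,
             tau1=24.0, tau2=24.0, sigma=0.1, seed=1),
    WaveSpec(family="noise", sigma=1.0, seed=1),
):
    call = bayes_factor(gen_wave(spec))
    print(f"{spec.family:22s} log10 BF = {call.log10_bf:7.2f}   label = {call.label}")

print("\nlog10 BF > log10(14) ~ 1.15 means the oscillatory kernel explains the")
print("data better than white noise even after the Occam penalty.")
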