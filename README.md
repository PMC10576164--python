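# odegp

Oscillation detection in noisy, unevenly sampled, replicated biological time
series — circadian qPCR time courses being the motivating case — by Bayesian
model selection between two Gaussian-process priors.

Most rhythm-detection tools report a P-value against a null of no rhythm and
struggle with one or more of: uneven sampling, missing points, replicate
error bars, and non-stationary rhythms whose period drifts over the record.
`odegp` instead models both hypotheses explicitly and reports the Bayes
factor between them:

* **null**: observations are uncorrelated noise, covariance
  `K_D(x,x') = ε² δ_{xx'}`;
* **alternative**: the signal is an oscillation drawn from a GP with the
  non-stationary kernel
  `K_NS(x,x') = w(x) w(x') k_gibbs(x,x') cos(2π(x μ(x) − x' μ(x'))) + ε² δ_{xx'}`,
  where the amplitude `w(x)`, lengthscale `ℓ(x)` (inside the Gibbs kernel)
  and frequency `μ(x)` are positive functions of time.

Hyperparameters for each kernel are learned by maximizing the Gaussian
marginal log-likelihood (MLL), and

```
BF = exp(MLL_NS − MLL_D)
```

is the evidence for oscillation; the log-determinant term in the MLL
penalizes the richer kernel, so flexibility is not free. A Bonferroni-type
prior odds `1/M` corrects for screening `M` datasets, and the default cutoff
of 14 (the Bayes-factor bound of a 0.005 P-value) classifies calls as
oscillatory / weak / non-oscillatory. For head-to-head comparisons with
P-value methods, `pvalue_to_bf_bound` converts a P-value into the bound
`−1/(e p ln p)`.

The package also ships the synthetic wave families used to benchmark such
detectors (stationary and non-stationary, symmetric and sawtooth, with
replicate/missingness structure), internal Cosinor and Lomb–Scargle
baselines with ROC/AUC evaluation, and a mean-field-coupled Poincaré
oscillator simulator for studying how single-cell amplitude and
intercellular coupling shape population-level evidence for rhythmicity.
Details and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

```python
from odegp import WaveSpec, bayes_factor, gen_wave

# a strong 24 h rhythm: amplitude 3, noise sd 0.1, 3 replicates, 48 h / 3 h
rhythmic = gen_wave(WaveSpec(family="stationary_symmetric",
                             A1=3.0, A2=0.0, tau1=24.0, tau2=24.0,
                             sigma=0.1, seed=1))
flat = gen_wave(WaveSpec(family="noise", sigma=1.0, seed=3))

for ds in (rhythmic, flat):
    call = bayes_factor(ds)
    print(f"{ds.label:30s} log10 BF = {call.log10_bf:7.2f}  label = {call.label}")
```

prints

```
stationary_symmetric(seed=1)   log10 BF =   66.06  label = oscillatory
noise(seed=3)                  log10 BF =    0.30  label = non-oscillatory
```

The rhythmic wave's evidence is astronomically above the cutoff
(log10 14 ≈ 1.15): the oscillatory kernel explains the data that much
better than white noise even after the complexity penalty. This pure-noise
wave lands near BF ≈ 2 — no real evidence either way, labelled
non-oscillatory. Single noise draws can land higher (the median pure-noise
BF at this design is ≈ 8, and occasional draws exceed the cutoff), which is
why borderline calls carry the "weak" label and multi-dataset screens
should pass `n_tests` for the prior-odds correction.

The same call works on your own data:

```python
from odegp import read_timeseries
ds = read_timeseries("expression.csv")   # time column + replicate columns
call = bayes_factor(ds)
```

or from the shell:

```bash
odegp detect expression.csv --seed 1
odegp simulate --preset fig2b --seed 1 -o wave.csv
odegp benchmark --preset fig3e --detectors odegp,cosinor -n 100 --seed 1 -o out/
odegp poincare --n 100 --coupling 0.3 --amplitude 0.5 --seed 1 -o dish.csv
```

Short narrative scripts for each capability live in `examples/`.

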