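"""Simulated benchmark waves with qPCR-like replicate and missingness structure.

Six wave families cover the space of non-oscillatory, stationary and
non-stationary signals:

* ``noise`` — pure Gaussian noise N(0, sigma) at each time point;
* ``stationary_symmetric`` — a sum of two sines,
  ``A1 sin(2 pi t / tau1) + A2 sin(2 pi t / tau2)``;
* ``stationary_sawtooth`` — ``A * frac(t / tau)`` (asymmetric ramp);
* ``nonstat_decreasing`` — ``A sin(2 pi t / (1 + |t - tau|))`` with
  ``tau >= 48`` so the instantaneous period shrinks over the record;
* ``nonstat_random_period`` — a sine whose period is redrawn from
  ``N(mu_period, sd_period)`` at the start of every cycle, phase resetting
  to zero at each cycle boundary;
* ``nonstat_random_sawtooth`` — the sawtooth analogue with per-cycle period
  drawn from ``U(tau1, tau2)``.

Every dataset consists of one underlying waveform shared by all replicates
(the random period sequence, if any, is drawn once per wave) plus independent
Gaussian noise per replicate per time point.  Defaults mirror a typical
circadian qPCR design: 3 replicates, 48 h record sampled every 3 h (17 time
points, both endpoints included), with optional random removal of half the
time points applied identically across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .timeseries_io import RhythmDataset

__all__ = [
    "WaveSpec",
    "FAMILIES",
    "gen_wave",
    "waveform",
    "apply_missingness",
    "make_benchmark_pair",
    "PRESETS",
    "preset_pair",
]

FAMILIES = (
    "noise",
    "stationary_symmetric",
    "stationary_sawtooth",
    "nonstat_decreasing",
    "nonstat_random_period",
    "nonstat_random_sawtooth",
)


@dataclass(frozen=True)
class WaveSpec:
    """Recipe for one simulated replicated dataset.

    Only the parameters relevant to ``family`` are used: ``A`` for
    single-amplitude families, ``A1/A2`` with ``tau1/tau2`` for the two-sine
    family, ``tau1/tau2`` as the uniform period range for the random sawtooth,
    ``mu_period/sd_period`` for the random-period sine.  ``sigma`` is the
    observation noise sd, shared by all families.
    """

    family: str
    A: float = 1.0
    A1: float = 1.0
    A2: float = 1.0
    tau: float = 24.0
    tau1: float = 18.0
    tau2: float = 26.0
    mu_period: float = 24.0
    sd_period: float = 1.33
    sigma: float = 0.1
    duration: float = 48.0
    spacing: float = 3.0
    n_replicates: int = 3
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown wave family {self.family!r}")
        if self.sigma < 0:
            raise ValueError("noise sd must be nonnegative")
        if min(self.tau, self.tau1, self.tau2, self.mu_period) <= 0:
            raise ValueError("periods must be positive")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must lie in [0, 1)")
        n_points = int(np.floor(self.duration / self.spacing)) + 1
        if n_points < 4:
            raise ValueError("duration/spacing yield fewer than 4 time points")

    @property
    def times(self) -> np.ndarray:
        """Time grid t = 0, spacing, ..., duration (both endpoints included)."""
        n = int(np.floor(self.duration / self.spacing + 1e-9)) + 1
        return np.arange(n) * self.spacing


def _random_cycle_waveform(
    t: np.ndarray, draw_period, shape, rng: np.random.Generator
) -> np.ndarray:
    """Piecewise waveform with per-cycle period: cycle boundaries phi are
    cumulative sums of drawn periods; within a cycle starting at phi,
    f(t) = shape((t - phi)/tau)."""
    t_end = t.max()
    boundaries = [0.0]
    periods = []
    while boundaries[-1] <= t_end:
        tau = draw_period(rng)
        tau = max(tau, 1e-6)
        periods.append(tau)
        boundaries.append(boundaries[-1] + tau)
    out = np.empty_like(t, dtype=float)
    for i, ti in enumerate(t):
        k = np.searchsorted(boundaries, ti, side="right") - 1
        out[i] = shape((ti - boundaries[k]) / periods[k])
    return out


def waveform(spec: WaveSpec, t: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Deterministic (noise-free) waveform of the spec's family at times t.

    For the random-period families the cycle-period sequence is drawn from
    ``rng``; pass the same generator state to share one realization across
    replicates.
    """
    t = np.asarray(t, dtype=float)
    f = spec.family
    if f == "noise":
        return np.zeros_like(t)
    if f == "stationary_symmetric":
        return spec.A1 * np.sin(2 * np.pi * t / spec.tau1) + spec.A2 * np.sin(
            2 * np.pi * t / spec.tau2
        )
    if f == "stationary_sawtooth":
        return spec.A * np.mod(t / spec.tau, 1.0)
    if f == "nonstat_decreasing":
        if spec.tau < spec.duration:
            raise ValueError("decreasing-period family requires tau >= duration")
        return spec.A * np.sin(2 * np.pi * t / (1.0 + np.abs(t - spec.tau)))
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if f == "nonstat_random_period":
        return _random_cycle_waveform(
            t,
            lambda g: g.normal(spec.mu_period, spec.sd_period),
            lambda u: spec.A * np.sin(2 * np.pi * u),
            rng,
        )
    if f == "nonstat_random_sawtooth":
        return _random_cycle_waveform(
            t,
            lambda g: g.uniform(spec.tau1, spec.tau2),
            lambda u: spec.A * np.mod(u, 1.0),
            rng,
        )
    raise ValueError(f"unknown wave family {f!r}")


def gen_wave(spec: WaveSpec) -> RhythmDataset:
    """Generate one replicated dataset from a wave recipe.

    The waveform is shared across replicates; Gaussian noise N(0, sigma) is
    drawn independently per replicate per time point; missingness (if any)
    removes the same randomly chosen time points from every replicate.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.times
    base = waveform(spec, t, rng)
    noise = rng.normal(0.0, spec.sigma, size=(t.size, spec.n_replicates)) if spec.sigma > 0 else 0.0
    values = base[:, None] + noise
    if spec.sigma == 0:
        values = np.broadcast_to(base[:, None], (t.size, spec.n_replicates)).copy()
    ds = RhythmDataset(
        times=t, values=values, label=f"{spec.family}(seed={spec.seed})"
    )
    if spec.missing_fraction > 0:
        ds = apply_missingness(ds, spec.missing_fraction, rng)
    return ds


def apply_missingness(ds: RhythmDataset, fraction: float, seed) -> RhythmDataset:
    """Drop ``round(fraction * n_times)`` time points, chosen uniformly
    without replacement, from all replicates at once.

    Rounding is half-away-from-zero (``floor(f*n + 0.5)``), so half of 17
    points means 9 dropped and 8 retained.  ``seed`` may be an integer or a
    ``numpy.random.Generator``.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0:
        return ds
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = ds.n_times
    n_drop = int(np.floor(fraction * n + 0.5))
    if n - n_drop < 4:
        raise ValueError(
            f"dropping {n_drop} of {n} points leaves fewer than 4 time points"
        )
    drop = rng.choice(n, size=n_drop, replace=False)
    keep = np.setdiff1d(np.arange(n), drop)
    return RhythmDataset(
        times=ds.times[keep],
        values=ds.values[keep],
        noise_var=None if ds.noise_var is None else ds.noise_var[keep],
        label=ds.label,
    )


def make_benchmark_pair(
    osc_spec: WaveSpec, null_spec: WaveSpec, n_per_class: int, seed: int
) -> tuple[list[RhythmDataset], np.ndarray]:
    """Labeled collection of oscillatory (label 1) and non-oscillatory
    (label 0) waves; per-wave seeds derive deterministically from ``seed``."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_per_class)]
    datasets, labels = [], []
    for i in range(n_per_class):
        datasets.append(gen_wave(replace(osc_spec, seed=child_seeds[i])))
        labels.append(1)
    for i in range(n_per_class):
        datasets.append(gen_wave(replace(null_spec, seed=child_seeds[n_per_class + i])))
        labels.append(0)
    return datasets, np.asarray(labels)


def _preset(osc: WaveSpec, null: WaveSpec) -> dict:
    return {"oscillatory": osc, "null": null}


#: figure-caption parameter sets for the published benchmark pairings
PRESETS: dict[str, dict] = {
    # two-sine vs noise, sigma=0.1, half the points missing
    "fig2b": _preset(
        WaveSpec(
            family="stationary_symmetric",
            A1=3.0, A2=3.0, tau1=18.0, tau2=26.0, sigma=0.1, missing_fraction=0.5,
        ),
        WaveSpec(family="noise", sigma=0.1, missing_fraction=0.5),
    ),
    # sawtooth vs noise, sigma=1, no missing points
    "fig2e": _preset(
        WaveSpec(family="stationary_sawtooth", A=5.0, tau=18.0, sigma=1.0),
        WaveSpec(family="noise", sigma=1.0),
    ),
    # decreasing-period sine vs noise, sigma=0.1, half missing
    "fig3b": _preset(
        WaveSpec(
            family="nonstat_decreasing", A=5.0, tau=72.0, sigma=0.1,
            missing_fraction=0.5,
        ),
        WaveSpec(family="noise", sigma=0.1, missing_fraction=0.5),
    ),
    # random-period sine vs noise, sigma=0.5, half missing
    "fig3e": _preset(
        WaveSpec(
            family="nonstat_random_period",
            A=1.5, mu_period=24.0, sd_period=1.33, sigma=0.5, missing_fraction=0.5,
        ),
        WaveSpec(family="noise", sigma=0.5, missing_fraction=0.5),
    ),
    # random-period sawtooth vs noise, sigma=0.1, no missing
    "fig3h": _preset(
        WaveSpec(
            family="nonstat_random_sawtooth", A=5.0, tau1=12.0, tau2=30.0, sigma=0.1,
        ),
        WaveSpec(family="noise", sigma=0.1),
    ),
}


def preset_pair(name: str) -> tuple[WaveSpec, WaveSpec]:
    """Return (oscillatory, null) specs for a named figure preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[name]
    return p["oscillatory"], p["null"]
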