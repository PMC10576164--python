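"""Bayes-factor oscillation calls and P-value calibration.

The detector fits the diagonal (non-oscillatory) and non-stationary
(oscillatory) kernels to the same dataset and forms the Bayes factor

    BF = exp(MLL_NS - MLL_D),

the ratio of the two maximized marginal likelihoods.  A Bonferroni-type prior
odds ``1/n_tests`` multiplies the BF when several datasets are screened.  The
default classification cutoff is 14, the Bayes-factor bound corresponding to
a P-value of 0.005; values within a factor of two of the cutoff are labelled
weak oscillations.

For comparing against P-value methods, :func:`pvalue_to_bf_bound` converts a
P-value into the Bayes-factor upper bound ``-1/(e p ln p)`` (valid for
p <= 1/e; clamped to 1 above by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gp_regression import GPFit, OptimizerConfig, optimize_hyperparameters
from .timeseries_io import RhythmDataset, collapse_replicates, normalize

__all__ = [
    "DetectionConfig",
    "OscillationCall",
    "bayes_factor",
    "prior_odds_correction",
    "pvalue_to_bf_bound",
    "classify",
    "DEFAULT_CUTOFF",
]

#: default Bayes-factor cutoff for calling a dataset oscillatory
DEFAULT_CUTOFF = 14.0

#: multiplicative half-width of the "weak oscillation" band around the cutoff
WEAK_BAND_FACTOR = 2.0


@dataclass(frozen=True)
class DetectionConfig:
    """End-to-end settings for an oscillation call.

    ``replicate_mode`` controls how replicates reach the GP: ``stack``
    (default) feeds every replicate observation as its own row, so the learned
    noise scale must account for the visible replicate scatter; ``mean_sem``
    averages replicates and uses the squared SEM as a per-point noise floor
    (appropriate when a trusted error model exists); ``mean`` averages without
    an error estimate; ``none`` passes the dataset through untouched.
    """

    normalize_method: str = "zscore"
    replicate_mode: str = "stack"
    cutoff: float = DEFAULT_CUTOFF
    n_tests: int = 1
    optimizer: OptimizerConfig = OptimizerConfig()


@dataclass(frozen=True)
class OscillationCall:
    """Outcome of the two-kernel model comparison on one dataset."""

    bayes_factor: float
    log10_bf: float
    posterior_odds: float
    n_tests: int
    label: str
    null_fit: GPFit
    alt_fit: GPFit
    dataset_label: str = ""


def prior_odds_correction(bf: float, n_tests: int) -> float:
    """Multiply a Bayes factor by the Bonferroni-type prior odds 1/n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be a positive integer")
    return bf / n_tests


def pvalue_to_bf_bound(p: float, clamp: bool = True) -> float:
    """Upper bound ``-1/(e p ln p)`` on the Bayes factor implied by P-value p.

    The bound holds for p <= 1/e; for larger p it is taken as 1 when
    ``clamp=True`` (the default), or the raw formula is applied when
    ``clamp=False``.  Strictly decreasing on (0, 1/e] and continuous at 1/e.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"P-value must lie in (0, 1], got {p}")
    if clamp and p > 1.0 / np.e:
        return 1.0
    if p == 1.0:
        raise ValueError("P-value of exactly 1 has no finite unclamped bound")
    return float(-1.0 / (np.e * p * np.log(p)))


def classify(
    posterior_odds: float,
    cutoff: float = DEFAULT_CUTOFF,
    weak_band: tuple[float, float] | None = None,
) -> str:
    """Label corrected odds as oscillatory / weak / non-oscillatory.

    The default weak band is ``[cutoff/2, cutoff*2)``: odds inside it are
    called weak regardless of the side of the cutoff they fall on.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if weak_band is None:
        weak_band = (cutoff / WEAK_BAND_FACTOR, cutoff * WEAK_BAND_FACTOR)
    lo, hi = weak_band
    if not (lo <= hi):
        raise ValueError(f"malformed weak band {weak_band}")
    if lo <= posterior_odds < hi:
        return "weak"
    if posterior_odds >= cutoff:
        return "oscillatory"
    return "non-oscillatory"


def bayes_factor(
    ds: RhythmDataset, config: DetectionConfig | None = None
) -> OscillationCall:
    """Run the full oscillation-detection pipeline on one dataset.

    Normalizes, arranges replicates for the GP (stacked rows by default), fits
    the diagonal and non-stationary kernels, and reports
    ``BF = exp(MLL_NS - MLL_D)`` with the prior-odds-corrected odds and label.
    ``log10_bf`` is always finite even when BF itself overflows.
    """
    if config is None:
        config = DetectionConfig()
    prepped = normalize(ds, config.normalize_method)
    if config.replicate_mode != "none":
        prepped = collapse_replicates(prepped, config.replicate_mode)
    null_fit = optimize_hyperparameters(prepped, "diagonal", config.optimizer)
    alt_fit = optimize_hyperparameters(prepped, "nonstationary", config.optimizer)
    log_bf = alt_fit.mll - null_fit.mll
    bf = float(np.exp(log_bf)) if log_bf < 700 else np.inf
    odds = prior_odds_correction(bf, config.n_tests)
    log10_odds = log_bf / np.log(10.0) - np.log10(config.n_tests)
    label = classify(
        odds if np.isfinite(odds) else 10.0**log10_odds, cutoff=config.cutoff
    )
    return OscillationCall(
        bayes_factor=bf,
        log10_bf=float(log_bf / np.log(10.0)),
        posterior_odds=odds,
        n_tests=config.n_tests,
        label=label,
        null_fit=null_fit,
        alt_fit=alt_fit,
        dataset_label=ds.label,
    )


def log10_bayes_factor(ds: RhythmDataset, config: DetectionConfig | None = None) -> float:
    """Convenience scalar score used by the benchmark module."""
    return bayes_factor(ds, config).log10_bf
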