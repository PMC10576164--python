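"""Gaussian-process regression: marginal likelihood, fitting, prediction.

All inference is empirical Bayes (type-II maximum likelihood): kernel
hyperparameters are chosen to maximize the Gaussian marginal log-likelihood

    MLL = -1/2 y^T C^-1 y - 1/2 log|C| - n/2 log(2 pi),

where ``C = K(theta) + diag(noise_var)`` combines the kernel evaluated on the
observation times with any per-point measurement-error variance carried by the
dataset.  The log-determinant term is the Occam factor that penalizes the
richer oscillatory kernel on structureless data, so Bayes factors formed from
two maximized MLLs do not systematically favour the bigger model.

The GP prior mean is zero; callers are expected to normalize data first
(see :func:`odegp.timeseries_io.normalize`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from .kernels import (
    DiagonalHyperparams,
    NonStationaryHyperparams,
    SpectralMixtureHyperparams,
    cross_covariance,
    kernel_matrix,
    prior_variance,
)
from .timeseries_io import RhythmDataset

__all__ = [
    "OptimizerConfig",
    "GPFit",
    "PosteriorCurve",
    "marginal_log_likelihood",
    "optimize_hyperparameters",
    "posterior",
]

#: relative jitter added to the covariance diagonal before factorization
JITTER = 1e-8

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings for multi-restart hyperparameter optimization.

    Restart initializations are drawn from broad log-uniform priors over
    circadian-plausible ranges.  The frequency function is bounded to periods
    of [12, 96] h: the ceiling is twice a 48 h record; the floor asks for at
    least four samples per cycle at the typical 3 h spacing — the 6 h Nyquist
    period is formally identifiable but, for noisy data, candidate rhythms
    faster than half a day are dominated by alias- and noise-chasing fits
    that inflate the evidence on structureless data.  All randomness flows
    from ``seed``.
    """

    n_restarts: int = 8
    seed: int = 0
    n_anchors: int = 3
    n_components: int = 2           # spectral-mixture Q
    maxiter: int = 200
    # [low, high] bounds on log-scale parameters
    log_w_bounds: tuple = (np.log(1e-3), np.log(10.0))
    log_l_bounds: tuple = (np.log(0.5), np.log(200.0))
    log_mu_bounds: tuple = (np.log(1.0 / 96.0), np.log(1.0 / 12.0))
    log_eps_bounds: tuple = (np.log(1e-4), np.log(10.0))
    # restart-initialization priors (log-uniform)
    init_w: tuple = (0.1, 3.0)
    init_period: tuple = (12.0, 48.0)
    init_l: tuple = (3.0, 48.0)
    init_eps: tuple = (0.01, 2.0)


@dataclass(frozen=True)
class GPFit:
    """Result of hyperparameter optimization for one kernel family."""

    kernel_family: str
    hyperparams: object
    mll: float
    optimizer_trace: tuple = ()

    def to_dict(self) -> dict:
        return {
            "kernel_family": self.kernel_family,
            "hyperparams": self.hyperparams.to_dict(),
            "mll": float(self.mll),
        }


@dataclass(frozen=True)
class PosteriorCurve:
    """GP predictive mean and marginal standard deviation on a query grid."""

    query_times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray


def _observations(ds: RhythmDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t, y, nv = ds.observed()
    if t.size == 0:
        raise ValueError("dataset has no observations")
    return t, y, nv


def _chol_mll(y: np.ndarray, c: np.ndarray) -> float:
    """Cholesky-based Gaussian MLL; -inf when C is not PD after jitter."""
    n = y.size
    c = c + JITTER * np.mean(np.diag(c)) * np.eye(n)
    try:
        chol = linalg.cholesky(c, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    alpha = linalg.solve_triangular(chol, y, lower=True, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return float(-0.5 * alpha @ alpha - 0.5 * logdet - 0.5 * n * _LOG_2PI)


def marginal_log_likelihood(ds: RhythmDataset, hp) -> float:
    """Exact Gaussian MLL of the dataset's observations under kernel ``hp``.

    Replicates are flattened to per-observation rows; any per-point
    measurement variance in the dataset is added to the kernel diagonal.
    Returns ``-inf`` when the covariance cannot be factorized after jitter.
    """
    t, y, nv = _observations(ds)
    c = kernel_matrix(t, hp)
    if nv.any():
        c = c + np.diag(nv)
    return _chol_mll(y, c)


def _anchor_times(t: np.ndarray, m: int) -> np.ndarray:
    if m == 1:
        return np.array([0.5 * (t.min() + t.max())])
    return np.linspace(t.min(), t.max(), m)


def _ns_pack(hp: NonStationaryHyperparams) -> np.ndarray:
    return np.concatenate(
        [hp.w_anchors, hp.l_anchors, hp.mu_anchors, [np.log(hp.epsilon)]]
    )


def _ns_unpack(theta: np.ndarray, anchor_times: np.ndarray) -> NonStationaryHyperparams:
    m = anchor_times.size
    return NonStationaryHyperparams(
        w_anchors=theta[:m],
        l_anchors=theta[m : 2 * m],
        mu_anchors=theta[2 * m : 3 * m],
        anchor_times=anchor_times,
        epsilon=float(np.exp(theta[-1])),
    )


def _sm_unpack(theta: np.ndarray, q: int) -> SpectralMixtureHyperparams:
    return SpectralMixtureHyperparams(
        weights=np.exp(theta[:q]),
        means=np.exp(theta[q : 2 * q]),
        variances=np.exp(theta[2 * q : 3 * q]),
        epsilon=float(np.exp(theta[-1])),
    )


def _fit_diagonal(t, y, nv, config) -> GPFit:
    def neg_mll(log_eps):
        c = np.diag(np.exp(2.0 * log_eps) + nv)
        return -_chol_mll(y, c)

    res = optimize.minimize_scalar(
        neg_mll,
        bounds=(config.log_eps_bounds[0], config.log_eps_bounds[1]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    hp = DiagonalHyperparams(epsilon=float(np.exp(res.x)))
    return GPFit(
        kernel_family="diagonal",
        hyperparams=hp,
        mll=float(-res.fun),
        optimizer_trace=((0, bool(res.success), float(-res.fun)),),
    )


def _multi_restart(t, y, nv, config, unpack, draw_init, bounds) -> tuple:
    """Bounded L-BFGS-B maximization of the MLL over log-parameters,
    restarted from prior draws; non-factorizable candidates are rejected by
    assigning a large penalty."""
    penalty = 1e10

    def neg_mll(theta):
        try:
            hp = unpack(theta)
            c = kernel_matrix(t, hp)
        except (FloatingPointError, ValueError):
            return penalty
        if nv.any():
            c = c + np.diag(nv)
        mll = _chol_mll(y, c)
        return penalty if not np.isfinite(mll) else -mll

    rng = np.random.default_rng(config.seed)
    trace = []
    best_theta, best_mll = None, -np.inf
    for r in range(config.n_restarts):
        theta0 = draw_init(rng)
        res = optimize.minimize(
            neg_mll,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.maxiter},
        )
        mll = -res.fun if res.fun < penalty else -np.inf
        trace.append((r, bool(res.success), float(mll)))
        if mll > best_mll:  # strict: ties keep the lowest restart index
            best_mll, best_theta = mll, res.x
    if best_theta is None or not np.isfinite(best_mll):
        raise RuntimeError(
            f"all {config.n_restarts} restarts failed to produce a finite "
            f"marginal log-likelihood; trace: {trace}"
        )
    return best_theta, float(best_mll), tuple(trace)


def _fit_nonstationary(t, y, nv, config) -> GPFit:
    m = config.n_anchors
    anchor_times = _anchor_times(t, m)

    def draw_init(rng):
        w = rng.uniform(np.log(config.init_w[0]), np.log(config.init_w[1]), m)
        l = rng.uniform(np.log(config.init_l[0]), np.log(config.init_l[1]), m)
        mu = -rng.uniform(
            np.log(config.init_period[0]), np.log(config.init_period[1]), m
        )
        eps = rng.uniform(np.log(config.init_eps[0]), np.log(config.init_eps[1]))
        return np.concatenate([w, l, mu, [eps]])

    bounds = (
        [config.log_w_bounds] * m
        + [config.log_l_bounds] * m
        + [config.log_mu_bounds] * m
        + [config.log_eps_bounds]
    )
    theta, mll, trace = _multi_restart(
        t, y, nv, config, lambda th: _ns_unpack(th, anchor_times), draw_init, bounds
    )
    return GPFit(
        kernel_family="nonstationary",
        hyperparams=_ns_unpack(theta, anchor_times),
        mll=mll,
        optimizer_trace=trace,
    )


def _fit_spectral_mixture(t, y, nv, config) -> GPFit:
    q = config.n_components

    def draw_init(rng):
        w = rng.uniform(np.log(config.init_w[0]), np.log(config.init_w[1]), q)
        mean = -rng.uniform(
            np.log(config.init_period[0]), np.log(config.init_period[1]), q
        )
        # spectral bandwidth ~ (1 / lengthscale)^2 scale
        var = 2.0 * rng.uniform(-np.log(config.init_l[1]), -np.log(config.init_l[0]), q)
        eps = rng.uniform(np.log(config.init_eps[0]), np.log(config.init_eps[1]))
        return np.concatenate([w, mean, var, [eps]])

    bounds = (
        [(np.log(1e-4), np.log(100.0))] * q
        + [config.log_mu_bounds] * q
        + [(2 * np.log(1.0 / 200.0), 2 * np.log(2.0))] * q
        + [config.log_eps_bounds]
    )
    theta, mll, trace = _multi_restart(
        t, y, nv, config, lambda th: _sm_unpack(th, q), draw_init, bounds
    )
    return GPFit(
        kernel_family="spectral_mixture",
        hyperparams=_sm_unpack(theta, q),
        mll=mll,
        optimizer_trace=trace,
    )


def optimize_hyperparameters(
    ds: RhythmDataset, family: str, config: OptimizerConfig | None = None
) -> GPFit:
    """Fit one kernel family to a dataset by multi-restart MLL maximization.

    Deterministic given ``config.seed``.  The single-parameter diagonal family
    is solved by bounded scalar minimization to tight tolerance; the
    non-stationary and spectral-mixture families use bounded quasi-Newton
    restarts initialized from broad circadian-range priors.
    """
    if config is None:
        config = OptimizerConfig()
    t, y, nv = _observations(ds)
    if np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct time points to fit")
    if family == "diagonal":
        return _fit_diagonal(t, y, nv, config)
    if family == "nonstationary":
        return _fit_nonstationary(t, y, nv, config)
    if family == "spectral_mixture":
        return _fit_spectral_mixture(t, y, nv, config)
    raise ValueError(f"unknown kernel family {family!r}")


def posterior(ds: RhythmDataset, fit: GPFit, query_times) -> PosteriorCurve:
    """Predictive mean and marginal sd at ``query_times`` under a fit.

    The predictive variance includes the noise floor, so far from the data the
    sd reverts to the prior marginal sd ``sqrt(w(t)^2 + eps^2)``.
    """
    q = np.asarray(query_times, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("query times must be finite")
    t, y, nv = _observations(ds)
    hp = fit.hyperparams
    c = kernel_matrix(t, hp)
    if nv.any():
        c = c + np.diag(nv)
    c = c + JITTER * np.mean(np.diag(c)) * np.eye(t.size)
    chol = linalg.cholesky(c, lower=True, check_finite=False)
    kqt = cross_covariance(q, t, hp)
    alpha = linalg.cho_solve((chol, True), y, check_finite=False)
    mean = kqt @ alpha
    v = linalg.solve_triangular(chol, kqt.T, lower=True, check_finite=False)
    var = prior_variance(q, hp) - np.sum(v**2, axis=0)
    return PosteriorCurve(query_times=q, mean=mean, sd=np.sqrt(np.clip(var, 0.0, None)))
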