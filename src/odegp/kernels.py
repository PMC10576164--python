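"""Covariance kernels for the oscillation-detection GP models.

Three kernel families are provided:

* the **diagonal** null kernel ``K_D(x, x') = eps^2 * delta_{xx'}`` encoding
  "no correlation between time points" (non-oscillatory data);
* the **non-stationary** alternative kernel
  ``K_NS(x, x') = w(x) w(x') k_gibbs(x, x') cos(2*pi*(x mu(x) - x' mu(x')))
  + eps^2 * delta_{xx'}`` whose amplitude ``w``, lengthscale ``l`` (inside the
  Gibbs kernel) and frequency ``mu`` are positive functions of time, letting
  the prior represent oscillations whose period and amplitude drift;
* a stationary **spectral-mixture** kernel (weighted Gaussian-envelope
  cosines) used as a comparison baseline.

The latent functions ``w(x)``, ``l(x)``, ``mu(x)`` are parametrized as
exponentiated piecewise-linear interpolants over M anchor times spanning the
observed record, held constant beyond the outermost anchors.  M=1 recovers the
stationary quasi-periodic kernel exactly; M>=2 yields genuine non-stationarity
with only 3M+1 hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiagonalHyperparams",
    "NonStationaryHyperparams",
    "SpectralMixtureHyperparams",
    "latent_eval",
    "gibbs_kernel",
    "diagonal_matrix",
    "nonstationary_matrix",
    "spectral_mixture_matrix",
    "kernel_matrix",
]


@dataclass(frozen=True)
class DiagonalHyperparams:
    """White-noise kernel: a single positive noise scale ``epsilon``."""

    epsilon: float

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")

    def to_dict(self) -> dict:
        return {"family": "diagonal", "epsilon": float(self.epsilon)}

    @classmethod
    def from_dict(cls, d: dict) -> "DiagonalHyperparams":
        return cls(epsilon=float(d["epsilon"]))


@dataclass(frozen=True)
class NonStationaryHyperparams:
    """Anchor-point parametrization of the non-stationary oscillatory kernel.

    ``w_anchors``, ``l_anchors`` and ``mu_anchors`` hold *log* values of the
    amplitude (signal units), lengthscale (hours) and frequency (cycles/hour)
    at ``anchor_times``; the latent functions are exponentiated piecewise-linear
    interpolants, hence strictly positive everywhere.
    """

    w_anchors: np.ndarray
    l_anchors: np.ndarray
    mu_anchors: np.ndarray
    anchor_times: np.ndarray
    epsilon: float

    def __post_init__(self):
        for name in ("w_anchors", "l_anchors", "mu_anchors", "anchor_times"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        m = self.anchor_times.size
        if m < 1:
            raise ValueError("need at least one anchor point")
        for name in ("w_anchors", "l_anchors", "mu_anchors"):
            if getattr(self, name).size != m:
                raise ValueError(f"{name} must match anchor_times length {m}")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")

    @property
    def n_anchors(self) -> int:
        return self.anchor_times.size

    def w(self, x) -> np.ndarray:
        return latent_eval(self.w_anchors, self.anchor_times, x)

    def lengthscale(self, x) -> np.ndarray:
        return latent_eval(self.l_anchors, self.anchor_times, x)

    def mu(self, x) -> np.ndarray:
        return latent_eval(self.mu_anchors, self.anchor_times, x)

    def to_dict(self) -> dict:
        return {
            "family": "nonstationary",
            "w_anchors": self.w_anchors.tolist(),
            "l_anchors": self.l_anchors.tolist(),
            "mu_anchors": self.mu_anchors.tolist(),
            "anchor_times": self.anchor_times.tolist(),
            "epsilon": float(self.epsilon),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NonStationaryHyperparams":
        return cls(
            w_anchors=np.asarray(d["w_anchors"], float),
            l_anchors=np.asarray(d["l_anchors"], float),
            mu_anchors=np.asarray(d["mu_anchors"], float),
            anchor_times=np.asarray(d["anchor_times"], float),
            epsilon=float(d["epsilon"]),
        )


@dataclass(frozen=True)
class SpectralMixtureHyperparams:
    """Stationary spectral-mixture kernel with Q Gaussian spectral components.

    ``weights`` are component variances, ``means`` spectral means in
    cycles/hour, ``variances`` spectral bandwidths (cycles/hour squared).
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    epsilon: float

    def __post_init__(self):
        for name in ("weights", "means", "variances"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        q = self.weights.size
        if q < 1 or self.means.size != q or self.variances.size != q:
            raise ValueError("weights, means, variances must share length Q >= 1")
        if np.any(self.weights <= 0) or np.any(self.variances < 0):
            raise ValueError("weights must be positive, variances nonnegative")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")

    @property
    def n_components(self) -> int:
        return self.weights.size

    def to_dict(self) -> dict:
        return {
            "family": "spectral_mixture",
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "epsilon": float(self.epsilon),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralMixtureHyperparams":
        return cls(
            weights=np.asarray(d["weights"], float),
            means=np.asarray(d["means"], float),
            variances=np.asarray(d["variances"], float),
            epsilon=float(d["epsilon"]),
        )


def latent_eval(anchors, anchor_times, x):
    """Evaluate ``exp(s(x))`` where s linearly interpolates log-anchor values.

    Outside the anchor span the nearest anchor value is held constant (the
    default behaviour of :func:`numpy.interp`), so the function is defined and
    positive on the whole real line.  With a single anchor it is constant.
    """
    anchors = np.atleast_1d(np.asarray(anchors, dtype=float))
    anchor_times = np.atleast_1d(np.asarray(anchor_times, dtype=float))
    if anchors.size == 0:
        raise ValueError("empty anchor vector")
    if anchors.size == 1:
        out = np.full_like(np.asarray(x, dtype=float), np.exp(anchors[0]))
        return out if out.ndim else float(out)
    out = np.exp(np.interp(x, anchor_times, anchors))
    return out if np.ndim(x) else float(out)


def gibbs_kernel(x, x2, l_fn):
    """Gibbs kernel with input-dependent lengthscale ``l_fn``.

    ``k(x, x') = sqrt(2 l(x) l(x') / (l(x)^2 + l(x')^2))
    * exp(-(x - x')^2 / (l(x)^2 + l(x')^2))``; symmetric, in (0, 1], equal to
    1 iff x = x'.  Reduces to the squared-exponential kernel when l is constant.
    """
    lx = np.asarray(l_fn(x), dtype=float)
    lx2 = np.asarray(l_fn(x2), dtype=float)
    s = lx**2 + lx2**2
    return np.sqrt(2.0 * lx * lx2 / s) * np.exp(-((np.asarray(x) - np.asarray(x2)) ** 2) / s)


def diagonal_matrix(times, hp: DiagonalHyperparams) -> np.ndarray:
    """``eps^2 * I`` over the given time grid."""
    times = np.asarray(times, dtype=float)
    return hp.epsilon**2 * np.eye(times.size)


def nonstationary_matrix(times, hp: NonStationaryHyperparams) -> np.ndarray:
    """Dense non-stationary covariance over ``times``.

    Entry (i, j) is ``w(t_i) w(t_j) k_gibbs(t_i, t_j)
    cos(2*pi*(t_i mu(t_i) - t_j mu(t_j)))`` plus ``eps^2`` on the diagonal.
    """
    t = np.asarray(times, dtype=float)
    w = hp.w(t)
    l = hp.lengthscale(t)
    mu = hp.mu(t)
    l2 = l**2
    s = l2[:, None] + l2[None, :]
    gibbs = np.sqrt(2.0 * np.outer(l, l) / s) * np.exp(
        -((t[:, None] - t[None, :]) ** 2) / s
    )
    phase = 2.0 * np.pi * t * mu
    cos_part = np.cos(phase[:, None] - phase[None, :])
    k = np.outer(w, w) * gibbs * cos_part
    k[np.diag_indices_from(k)] += hp.epsilon**2
    if not np.all(np.isfinite(k)):
        raise FloatingPointError(
            "non-finite covariance entry; check w/l/mu anchor values"
        )
    return k


def spectral_mixture_matrix(times, hp: SpectralMixtureHyperparams) -> np.ndarray:
    """Stationary spectral-mixture covariance plus ``eps^2`` diagonal.

    ``k(tau) = sum_q w_q exp(-2 pi^2 tau^2 v_q) cos(2 pi tau m_q)`` with
    ``tau = t_i - t_j``: the inverse Fourier transform of a symmetrized
    mixture of Gaussians on the spectral axis, hence positive semidefinite.
    """
    t = np.asarray(times, dtype=float)
    tau = t[:, None] - t[None, :]
    k = np.zeros_like(tau)
    for wq, mq, vq in zip(hp.weights, hp.means, hp.variances):
        k += wq * np.exp(-2.0 * np.pi**2 * tau**2 * vq) * np.cos(2.0 * np.pi * tau * mq)
    k[np.diag_indices_from(k)] += hp.epsilon**2
    return k


def kernel_matrix(times, hp) -> np.ndarray:
    """Dispatch on hyperparameter type."""
    if isinstance(hp, DiagonalHyperparams):
        return diagonal_matrix(times, hp)
    if isinstance(hp, NonStationaryHyperparams):
        return nonstationary_matrix(times, hp)
    if isinstance(hp, SpectralMixtureHyperparams):
        return spectral_mixture_matrix(times, hp)
    raise TypeError(f"unknown hyperparameter type {type(hp).__name__}")


def cross_covariance(query_times, obs_times, hp) -> np.ndarray:
    """Covariance between query and observation times, *without* the noise
    diagonal (used for posterior prediction)."""
    q = np.asarray(query_times, dtype=float)
    t = np.asarray(obs_times, dtype=float)
    if isinstance(hp, DiagonalHyperparams):
        return np.zeros((q.size, t.size))
    if isinstance(hp, NonStationaryHyperparams):
        wq, wt = hp.w(q), hp.w(t)
        lq, lt = hp.lengthscale(q), hp.lengthscale(t)
        s = lq[:, None] ** 2 + lt[None, :] ** 2
        gibbs = np.sqrt(2.0 * np.outer(lq, lt) / s) * np.exp(
            -((q[:, None] - t[None, :]) ** 2) / s
        )
        phase_q = 2.0 * np.pi * q * hp.mu(q)
        phase_t = 2.0 * np.pi * t * hp.mu(t)
        return np.outer(wq, wt) * gibbs * np.cos(phase_q[:, None] - phase_t[None, :])
    if isinstance(hp, SpectralMixtureHyperparams):
        tau = q[:, None] - t[None, :]
        k = np.zeros_like(tau)
        for w, m, v in zip(hp.weights, hp.means, hp.variances):
            k += w * np.exp(-2.0 * np.pi**2 * tau**2 * v) * np.cos(2.0 * np.pi * tau * m)
        return k
    raise TypeError(f"unknown hyperparameter type {type(hp).__name__}")


def prior_variance(query_times, hp) -> np.ndarray:
    """Marginal prior variance at query times (including the noise term)."""
    q = np.asarray(query_times, dtype=float)
    if isinstance(hp, DiagonalHyperparams):
        return np.full(q.size, hp.epsilon**2)
    if isinstance(hp, NonStationaryHyperparams):
        return hp.w(q) ** 2 + hp.epsilon**2
    if isinstance(hp, SpectralMixtureHyperparams):
        return np.full(q.size, hp.weights.sum() + hp.epsilon**2)
    raise TypeError(f"unknown hyperparameter type {type(hp).__name__}")
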