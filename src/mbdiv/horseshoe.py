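"""Multivariate birth-death rate transformations and the horseshoe prior.

The multivariate birth-death (MBD) model lets origination and extinction
rates vary through time as functions of N rescaled covariate
trajectories C_i(t), shared equally across lineages.  Two link forms are
supported:

* linear:       λ(t) = max{0, λ0 + λ0 Σ_i G_i C_i(t)}
                μ(t) = max{0, μ0 + μ0 Σ_i H_i C_i(t)}
* exponential:  λ(t) = λ0 exp(Σ_i G_i C_i(t))
                μ(t) = μ0 exp(Σ_i H_i C_i(t))

G_i and H_i are per-covariate correlation parameters (sign gives the
direction of the correlation).  With N covariates the model has exactly
2N + 2 free core parameters.

Overparameterization is controlled by a horseshoe prior:

    G_i ~ N(0, ε_i² τ²),  H_i ~ N(0, ζ_i² τ²)
    ε_i, ζ_i ~ C+(0, 1),  τ ~ C+(0, 1)

with local scales ε_i, ζ_i and one global scale τ.  The posterior
shrinkage weight

    w = 1 - 1 / (1 + τ² ε²)

separates signal from noise: a mean weight strictly above 0.5 classifies
the correlation as significant, with the sign taken from the posterior
mean of the correlation parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import CovariateTrajectory, LineageRecord
from .errors import ValidationError
from .likelihood import bd_loglik

__all__ = [
    "MBDParameters",
    "HorseshoeState",
    "mbd_rates",
    "mbd_rate_functions",
    "mbd_loglik",
    "horseshoe_log_prior",
    "shrinkage_weight",
    "classify_significance",
]

MODES = ("linear", "exponential")


@dataclass
class MBDParameters:
    """Baseline rates and per-covariate correlation parameters."""

    lambda0: float
    mu0: float
    G: np.ndarray
    H: np.ndarray
    mode: str = "exponential"

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if self.G.shape != self.H.shape or self.G.ndim != 1:
            raise ValidationError("G and H must be equal-length vectors")
        if self.lambda0 < 0 or self.mu0 < 0:
            raise ValidationError("baseline rates must be >= 0")
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}")

    @property
    def n_covariates(self) -> int:
        return self.G.size

    @property
    def n_free_parameters(self) -> int:
        """Free core parameters: λ0, μ0 and one G and one H per covariate."""
        return 2 * self.n_covariates + 2


@dataclass
class HorseshoeState:
    """Local (ε, ζ) and global (τ) shrinkage scales; all strictly positive."""

    eps: np.ndarray
    zeta: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        self.eps = np.asarray(self.eps, dtype=float)
        self.zeta = np.asarray(self.zeta, dtype=float)
        if self.eps.shape != self.zeta.shape or self.eps.ndim != 1:
            raise ValidationError("eps and zeta must be equal-length vectors")
        if np.any(self.eps <= 0) or np.any(self.zeta <= 0) or self.tau <= 0:
            raise ValidationError("horseshoe scales must be strictly positive")


def _covariate_matrix(
    covset: Sequence[CovariateTrajectory], t: np.ndarray
) -> np.ndarray:
    for c in covset:
        if not c.rescaled:
            raise ValidationError(
                f"covariate {c.name!r} must be rescaled to [0, 1] before use"
            )
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return np.column_stack([c.at(t) for c in covset])


def mbd_rates(params: MBDParameters, covset: Sequence[CovariateTrajectory], t):
    """Evaluate (λ(t), μ(t)) at time(s) t under the MBD transformation."""
    if len(covset) != params.n_covariates:
        raise ValidationError("covariate set does not match parameter vectors")
    scalar = np.ndim(t) == 0
    C = _covariate_matrix(covset, t)  # (n_t, N)
    s_lam = C @ params.G
    s_mu = C @ params.H
    if params.mode == "linear":
        lam = np.maximum(0.0, params.lambda0 * (1.0 + s_lam))
        mu = np.maximum(0.0, params.mu0 * (1.0 + s_mu))
    else:
        lam = params.lambda0 * np.exp(s_lam)
        mu = params.mu0 * np.exp(s_mu)
    if scalar:
        return float(lam[0]), float(mu[0])
    return lam, mu


def mbd_rate_functions(params: MBDParameters, covset: Sequence[CovariateTrajectory]):
    """Vectorized λ(t) and μ(t) callables for use with the BD likelihood."""

    def lam(t):
        return mbd_rates(params, covset, np.asarray(t, dtype=float))[0]

    def mu(t):
        return mbd_rates(params, covset, np.asarray(t, dtype=float))[1]

    return lam, mu


def mbd_loglik(
    lineages: Sequence[LineageRecord],
    params: MBDParameters,
    covset: Sequence[CovariateTrajectory],
    step: float = 1.0,
) -> float:
    """BD log-likelihood with the MBD covariate-driven rate functions."""
    lam, mu = mbd_rate_functions(params, covset)
    return bd_loglik(lineages, lam, mu, step=step)


_LOG_HALF_CAUCHY_UNIT = math.log(2.0 / math.pi)


def horseshoe_log_prior(G, H, hs: HorseshoeState) -> float:
    """Joint log density of (G, H, ε, ζ, τ) under the horseshoe prior.

    Normal densities are parameterized by *variance* ε_i²τ² (resp.
    ζ_i²τ²); all scale hyper-priors are standard half-Cauchy C+(0, 1).
    Non-positive scales give -inf.
    """
    G = np.asarray(G, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(hs.eps <= 0) or np.any(hs.zeta <= 0) or hs.tau <= 0:
        return -np.inf

    def normal_term(x, local):
        var = (local * hs.tau) ** 2
        return -0.5 * np.log(2.0 * np.pi * var) - 0.5 * x**2 / var

    def hc_unit(x):
        return _LOG_HALF_CAUCHY_UNIT - np.log1p(np.asarray(x, dtype=float) ** 2)

    lp = float(normal_term(G, hs.eps).sum())
    lp += float(normal_term(H, hs.zeta).sum())
    lp += float(hc_unit(hs.eps).sum()) + float(hc_unit(hs.zeta).sum())
    lp += float(hc_unit(hs.tau))
    return lp


def shrinkage_weight(local_scale, tau):
    """Shrinkage weight w = 1 - 1/(1 + τ² ε²), in [0, 1).

    Strictly increasing in both scales; w above 0.5 marks the
    corresponding correlation parameter as signal rather than noise.
    """
    local_scale = np.asarray(local_scale, dtype=float)
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(local_scale <= 0) or np.any(tau_arr <= 0):
        raise ValidationError("shrinkage weight requires strictly positive scales")
    w = 1.0 - 1.0 / (1.0 + tau_arr**2 * local_scale**2)
    if w.ndim == 0:
        return float(w)
    return w


def classify_significance(
    mean_w: float, mean_corr: float, threshold: float = 0.5
) -> str:
    """Classify a correlation parameter from its mean shrinkage weight.

    Significant only when the mean weight strictly exceeds the
    threshold (0.5 by default); the direction comes from the sign of the
    posterior-mean correlation parameter.
    """
    if not (0.0 <= mean_w < 1.0):
        raise ValidationError("mean shrinkage weight must lie in [0, 1)")
    if mean_w > threshold:
        return "significant_positive" if mean_corr >= 0 else "significant_negative"
    return "noise"
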