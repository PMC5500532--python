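"""Model comparison and posterior summarization.

Marginal likelihoods are approximated by the harmonic mean of the
likelihoods sampled through MCMC (computed stably in log space).  Log
Bayes factors are reported as 2·(log ML_a − log ML_b) and interpreted on
the Kass-Raftery scale.  Replicate traces (e.g. from dating-uncertainty
resampling) are pooled by concatenating their post-burn-in samples
before summarizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import pearsonr

from .data import CovariateTrajectory, EpochGrid
from .diagnostics import hpd_interval
from .errors import ValidationError
from .horseshoe import classify_significance
from .mcmc import TraceLog

__all__ = [
    "PosteriorSummary",
    "RatesThroughTime",
    "harmonic_mean_logml",
    "log_bayes_factor",
    "kass_raftery_category",
    "pool_traces",
    "summarize_posterior",
    "rates_through_time",
    "rate_r2",
    "interval_overlap",
]


def harmonic_mean_logml(loglik_samples) -> float:
    """Log marginal likelihood via the harmonic mean of sampled likelihoods.

    log( n / Σ exp(-ℓ_i) ) computed with log-sum-exp; never exceeds the
    maximum sampled log-likelihood and equals ℓ for a constant chain.
    """
    ll = np.asarray(loglik_samples, dtype=float)
    if ll.size < 10:
        raise ValidationError("need >= 10 likelihood samples")
    if not np.all(np.isfinite(ll)):
        raise ValidationError("harmonic mean undefined for non-finite likelihoods")
    return float(math.log(ll.size) - logsumexp(-ll))


def log_bayes_factor(logml_a: float, logml_b: float) -> float:
    """2·(log ML_a − log ML_b); positive values favour model a."""
    if not (np.isfinite(logml_a) and np.isfinite(logml_b)):
        raise ValidationError("log marginal likelihoods must be finite")
    return 2.0 * (logml_a - logml_b)


def kass_raftery_category(log_bf: float) -> str:
    """Verbal strength-of-evidence category for 2·log BF (Kass & Raftery)."""
    v = abs(log_bf)
    if v < 2.0:
        return "not worth more than a bare mention"
    if v < 6.0:
        return "positive"
    if v < 10.0:
        return "strong"
    return "very strong"


def pool_traces(
    traces: Sequence[TraceLog], burnin_fraction: float = 0.10
) -> pd.DataFrame:
    """Concatenate post-burn-in samples from replicate traces."""
    if not traces:
        raise ValidationError("no traces to pool")
    frames = [t.post_burnin(burnin_fraction) for t in traces]
    cols = list(frames[0].columns)
    for f in frames[1:]:
        if list(f.columns) != cols:
            raise ValidationError("replicate traces have differing columns")
    pooled = pd.concat(frames, ignore_index=True)
    if pooled.empty:
        raise ValidationError("all samples removed as burn-in")
    return pooled


@dataclass
class PosteriorSummary:
    """Per-parameter posterior means, 95% HPD bounds and, for correlation
    parameters, mean shrinkage weights with a significance class."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def __str__(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}")


def summarize_posterior(
    traces: Sequence[TraceLog] | TraceLog,
    burnin_fraction: float = 0.10,
    prob: float = 0.95,
) -> PosteriorSummary:
    """Pool replicate traces and summarize every model parameter.

    For each correlation parameter G_x / H_x the matching trace column
    w_G_x / w_H_x provides the shrinkage weight whose mean, compared
    against the 0.5 threshold, yields the significance class.
    """
    if isinstance(traces, TraceLog):
        traces = [traces]
    pooled = pool_traces(traces, burnin_fraction)
    skip = {"state", "posterior", "likelihood", "prior"}
    rows = []
    for col in pooled.columns:
        if col in skip or col.startswith("w_"):
            continue
        x = pooled[col].to_numpy(float)
        mean = float(x.mean())
        if np.ptp(x) == 0:
            lo = hi = float(x[0])
        elif x.size >= 20:
            lo, hi = hpd_interval(x, prob)
        else:  # too few samples for an HPD; fall back to the range
            lo, hi = float(x.min()), float(x.max())
        row = {"parameter": col, "mean": mean, "hpd_low": lo, "hpd_high": hi,
               "mean_w": np.nan, "class": ""}
        if col.startswith(("G_", "H_")):
            wcol = "w_" + col
            if wcol in pooled.columns:
                mean_w = float(pooled[wcol].mean())
                row["mean_w"] = mean_w
                row["class"] = classify_significance(mean_w, mean)
        rows.append(row)
    return PosteriorSummary(pd.DataFrame(rows))


@dataclass
class RatesThroughTime:
    """Pointwise posterior mean and 95% HPD band for λ(t) and μ(t)."""

    times: np.ndarray
    lambda_mean: np.ndarray
    lambda_low: np.ndarray
    lambda_high: np.ndarray
    mu_mean: np.ndarray
    mu_low: np.ndarray
    mu_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "lambda_mean": self.lambda_mean,
                "lambda_low": self.lambda_low,
                "lambda_high": self.lambda_high,
                "mu_mean": self.mu_mean,
                "mu_low": self.mu_low,
                "mu_high": self.mu_high,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, ax=None):
        """Rates-through-time figure (time axis reversed, past on the left)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.lambda_mean, label="origination", color="C0")
        ax.fill_between(
            self.times, self.lambda_low, self.lambda_high, alpha=0.25, color="C0"
        )
        ax.plot(self.times, self.mu_mean, label="extinction", color="C3")
        ax.fill_between(self.times, self.mu_low, self.mu_high, alpha=0.25, color="C3")
        ax.set_xlabel("time (Ma)")
        ax.set_ylabel("rate (events / lineage / Ma)")
        ax.invert_xaxis()
        ax.legend()
        return ax


def _band(samples: np.ndarray, prob: float) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise HPD band over a (n_samples, n_times) matrix."""
    n, m = samples.shape
    lo = np.empty(m)
    hi = np.empty(m)
    for j in range(m):
        col = samples[:, j]
        if n < 20 or np.ptp(col) == 0:
            lo[j] = col.min()
            hi[j] = col.max()
        else:
            lo[j], hi[j] = hpd_interval(col, prob)
    return lo, hi


def rates_through_time(
    traces: Sequence[TraceLog] | TraceLog,
    model: str,
    grid,
    covset: Sequence[CovariateTrajectory] | None = None,
    epochs: EpochGrid | None = None,
    mode: str = "exponential",
    burnin_fraction: float = 0.10,
    prob: float = 0.95,
) -> RatesThroughTime:
    """Evaluate λ(t), μ(t) on a time grid for every pooled posterior sample.

    ``model`` is 'mbd' (needs covset and mode) or 'bds' (needs epochs).
    The grid must be strictly decreasing (oldest first).
    """
    if isinstance(traces, TraceLog):
        traces = [traces]
    pooled = pool_traces(traces, burnin_fraction)
    t = np.asarray(grid, dtype=float)
    if t.ndim != 1 or t.size < 1 or (t.size > 1 and np.any(np.diff(t) >= 0)):
        raise ValidationError("grid must be strictly decreasing, oldest first")

    if model == "mbd":
        if not covset:
            raise ValidationError("MBD rates-through-time needs the covariate set")
        C = np.column_stack([c.at(t) for c in covset])  # (n_t, N)
        names = [c.name for c in covset]
        G = pooled[[f"G_{n}" for n in names]].to_numpy(float)
        H = pooled[[f"H_{n}" for n in names]].to_numpy(float)
        lam0 = pooled["lambda0"].to_numpy(float)[:, None]
        mu0 = pooled["mu0"].to_numpy(float)[:, None]
        if mode == "exponential":
            lam = lam0 * np.exp(G @ C.T)
            mu = mu0 * np.exp(H @ C.T)
        else:
            lam = np.maximum(0.0, lam0 * (1.0 + G @ C.T))
            mu = np.maximum(0.0, mu0 * (1.0 + H @ C.T))
    elif model == "bds":
        if epochs is None:
            raise ValidationError("BDS rates-through-time needs the epoch grid")
        idx = epochs.index_of(t)
        lam = pooled[[f"lambda_{i}" for i in range(epochs.k)]].to_numpy(float)[:, idx]
        mu = pooled[[f"mu_{i}" for i in range(epochs.k)]].to_numpy(float)[:, idx]
    else:
        raise ValidationError(f"unknown model {model!r}")

    lam_lo, lam_hi = _band(lam, prob)
    mu_lo, mu_hi = _band(mu, prob)
    return RatesThroughTime(
        t, lam.mean(axis=0), lam_lo, lam_hi, mu.mean(axis=0), mu_lo, mu_hi
    )


def rate_r2(rates_a, rates_b) -> float:
    """Squared Pearson correlation between two mean-rate vectors on a
    common grid (affine-invariant; symmetric)."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValidationError("need two equal-length rate vectors (>= 3 points)")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("correlation undefined for a zero-variance input")
    r = pearsonr(a, b).statistic
    return float(r * r)


def interval_overlap(
    a_low: float, a_high: float, b_low: float, b_high: float
) -> tuple[str, float]:
    """Classify two credible intervals as congruent/incongruent.

    Congruent when max(lows) <= min(highs) (a single shared endpoint
    counts).  Returns the class and, when incongruent, the positive gap
    max(lows) − min(highs); the gap is 0.0 for congruent pairs.
    """
    if a_low > a_high or b_low > b_high:
        raise ValidationError("interval bounds must satisfy low <= high")
    gap = max(a_low, b_low) - min(a_high, b_high)
    if gap <= 0:
        return "congruent", 0.0
    return "incongruent", float(gap)
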