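"""MCMC chain diagnostics: effective sample size and HPD intervals."""

from __future__ import annotations

import math
import warnings

import numpy as np

from .errors import DegenerateChainWarning, ValidationError

__all__ = ["effective_sample_size", "hpd_interval"]


def effective_sample_size(samples) -> float:
    """ESS = n / (1 + 2 Σ_k ρ_k), autocorrelations summed up to the first
    non-positive lag.

    A zero-variance chain returns 0 and emits
    :class:`~mbdiv.errors.DegenerateChainWarning`.  Requires >= 10
    samples.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise ValidationError("need at least 10 samples for an ESS estimate")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0.0:
        warnings.warn("zero-variance chain; ESS undefined", DegenerateChainWarning)
        return 0.0
    # FFT-based autocovariance, normalized to autocorrelation
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0.0:
            break
        s += rho[k]
    return float(n / (1.0 + 2.0 * s))


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted samples holding ceil(prob*n)
    of them; ties broken by the lowest starting index.

    Requires >= 20 samples and 0 < prob < 1.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValidationError("need at least 20 samples for an HPD interval")
    if not (0.0 < prob < 1.0):
        raise ValidationError("prob must lie strictly between 0 and 1")
    m = int(math.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest start
    return float(x[i]), float(x[i + m - 1])
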