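"""Metropolis-Hastings / Gibbs samplers for the BDS and MBD models.

Update policy (per iteration, one block chosen at random):

* baseline / epoch rates: multiplier proposals on the log scale,
  ``rate' = rate * exp(U(-w, w))`` with the log-multiplier Hastings
  correction;
* correlation parameters G, H: Gaussian random-walk proposals;
* horseshoe scales ε, ζ, τ: exact conjugate Gibbs draws via the
  inverse-gamma auxiliary-variable representation of the half-Cauchy;
* BDS prior scales s1, s2: sliding-window proposals bounded by the
  U[0, 20] hyper-prior.

The sampler is fully driven by one seeded generator: identical
configuration and seed give bit-identical traces.  When the likelihood
is disabled (``prior_only``) every conditional is conjugate and a
systematic-scan Gibbs sweep is used instead, which samples the
horseshoe prior exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CovariateTrajectory, EpochGrid, LineageRecord
from .errors import InitializationError, ValidationError
from .horseshoe import HorseshoeState, horseshoe_log_prior
from .likelihood import BDSParameters, bds_log_prior

__all__ = [
    "MCMCConfig",
    "TraceLog",
    "run_mcmc",
    "gibbs_update_horseshoe",
    "sample_horseshoe_prior",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``mult_window`` is the half-width of the uniform log-multiplier
    window for positive parameters, ``gh_sigma`` the random-walk sd for
    the correlation parameters, ``s_window`` the sd of the sliding
    window used for the BDS prior scales.  ``block_weights`` orders the
    blocks (rates, G, H, hyper); for the BDS model the G/H weights are
    folded into the rate blocks.
    """

    n_iter: int = 100_000
    sample_freq: int = 100
    seed: int = 0
    burnin_fraction: float = 0.10
    mult_window: float = 0.2
    gh_sigma: float = 0.1
    s_window: float = 1.0
    block_weights: tuple = (0.3, 0.25, 0.25, 0.2)
    prior_only: bool = False
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.n_iter < 0:
            raise ValidationError("n_iter must be >= 0")
        if self.sample_freq < 1:
            raise ValidationError("sample_freq must be >= 1")
        if not (0.0 <= self.burnin_fraction < 1.0):
            raise ValidationError("burnin_fraction must lie in [0, 1)")


class TraceLog:
    """An ordered table of MCMC samples plus per-block acceptance counts."""

    def __init__(self, df: pd.DataFrame, acceptance: dict | None = None):
        if "state" not in df.columns:
            raise ValidationError("trace must have a 'state' column")
        if np.any(np.diff(df["state"].to_numpy()) <= 0) and len(df) > 1:
            raise ValidationError("trace iterations must be strictly increasing")
        self.df = df.reset_index(drop=True)
        self.acceptance = acceptance or {}

    def __len__(self) -> int:
        return len(self.df)

    def post_burnin(self, burnin_fraction: float = 0.10) -> pd.DataFrame:
        n_drop = int(math.floor(burnin_fraction * len(self.df)))
        return self.df.iloc[n_drop:].reset_index(drop=True)

    def acceptance_rates(self) -> dict:
        return {
            k: (a / p if p else float("nan"))
            for k, (a, p) in self.acceptance.items()
        }

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TraceLog":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# horseshoe Gibbs


# squared-scale draws are clipped to this range.  The floor matters: when a
# correlation parameter sits exactly at 0 its scale's full conditional is
# improper at 0, so an unbounded Gibbs chain can spiral into the funnel and
# numerically freeze there.  Truncating the half-Cauchy at 1e-6 (prior mass
# ~6e-7) keeps the chain recoverable without visibly distorting the prior.
_SCALE2_FLOOR = 1e-12
_SCALE2_CEIL = 1e12


def _inv_gamma(rng: np.random.Generator, shape: float, scale) -> np.ndarray:
    """Draw from InvGamma(shape, scale) as scale / Gamma(shape, 1)."""
    scale = np.clip(scale, _SCALE2_FLOOR, _SCALE2_CEIL)
    draw = scale / rng.gamma(shape, 1.0, size=np.shape(scale))
    return np.clip(draw, _SCALE2_FLOOR, _SCALE2_CEIL)


def gibbs_update_horseshoe(
    G, H, hs: HorseshoeState, rng: np.random.Generator
) -> HorseshoeState:
    """One conjugate Gibbs refresh of (ε, ζ, τ) given the correlations.

    Uses the inverse-gamma auxiliary representation of the half-Cauchy:
    x ~ C+(0,1) iff x²|ν ~ IG(1/2·..), marginalized here as the standard
    two-stage IG(1, ·) draws.  The kernel leaves the joint horseshoe
    prior (and any posterior that keeps G, H fixed) invariant.
    """
    G = np.asarray(G, dtype=float)
    H = np.asarray(H, dtype=float)
    tau2 = hs.tau**2

    nu = _inv_gamma(rng, 1.0, 1.0 + 1.0 / hs.eps**2)
    eps2 = _inv_gamma(rng, 1.0, 1.0 / nu + G**2 / (2.0 * tau2))
    omega = _inv_gamma(rng, 1.0, 1.0 + 1.0 / hs.zeta**2)
    zeta2 = _inv_gamma(rng, 1.0, 1.0 / omega + H**2 / (2.0 * tau2))

    p = G.size + H.size
    xi = float(_inv_gamma(rng, 1.0, 1.0 + 1.0 / tau2))
    rate = 1.0 / xi + 0.5 * (np.sum(G**2 / eps2) + np.sum(H**2 / zeta2))
    tau2_new = float(_inv_gamma(rng, (p + 1.0) / 2.0, rate))

    return HorseshoeState(np.sqrt(eps2), np.sqrt(zeta2), math.sqrt(tau2_new))


def sample_horseshoe_prior(
    n_covariates: int, n_samples: int, seed: int = 0
) -> pd.DataFrame:
    """Systematic-scan Gibbs draws from the horseshoe prior itself.

    Alternates exact conditional draws G, H ~ N(0, local²τ²) with the
    scale refresh of :func:`gibbs_update_horseshoe`; the stationary
    marginals are the prior (e.g. τ ~ C+(0, 1)).
    """
    rng = np.random.default_rng(seed)
    hs = HorseshoeState(
        np.ones(n_covariates), np.ones(n_covariates), 1.0
    )
    G = np.zeros(n_covariates)
    H = np.zeros(n_covariates)
    rows = np.empty((n_samples, 2 * n_covariates + 1))
    for i in range(n_samples):
        G = rng.normal(0.0, hs.eps * hs.tau)
        H = rng.normal(0.0, hs.zeta * hs.tau)
        hs = gibbs_update_horseshoe(G, H, hs, rng)
        rows[i, :n_covariates] = G
        rows[i, n_covariates : 2 * n_covariates] = H
        rows[i, -1] = hs.tau
    cols = (
        [f"G_{i}" for i in range(n_covariates)]
        + [f"H_{i}" for i in range(n_covariates)]
        + ["tau"]
    )
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# cached likelihood evaluators


class _BDSCache:
    """Sufficient statistics for the epoch-shift likelihood: per-epoch
    alive lengths and event counts (exact, no quadrature)."""

    def __init__(self, lineages: Sequence[LineageRecord], grid: EpochGrid):
        if not lineages:
            raise ValidationError("empty lineage set")
        if max(l.ts for l in lineages) > grid.span:
            raise ValidationError("lineage times extend beyond the epoch grid")
        self.grid = grid
        k = grid.k
        self.exposure = np.zeros(k)
        self.n_orig = np.zeros(k)
        self.n_ext = np.zeros(k)
        oldest = int(np.argmax([l.ts for l in lineages]))
        for i, l in enumerate(lineages):
            self.exposure += grid.overlap_lengths(l.te, l.ts)
            if i != oldest:
                self.n_orig[int(grid.index_of(l.ts))] += 1
            if not l.extant:
                self.n_ext[int(grid.index_of(l.te))] += 1
        self.n_lineages = len(lineages)

    def loglik(self, lam_k: np.ndarray, mu_k: np.ndarray) -> float:
        if np.any(lam_k[self.n_orig > 0] <= 0) or np.any(mu_k[self.n_ext > 0] <= 0):
            return -np.inf
        with np.errstate(divide="ignore"):
            ll = float(
                np.sum(self.n_orig * np.where(self.n_orig > 0, np.log(lam_k), 0.0))
                + np.sum(self.n_ext * np.where(self.n_ext > 0, np.log(mu_k), 0.0))
            )
        return ll - float(np.dot(lam_k + mu_k, self.exposure))


class _MBDCache:
    """Covariate sums cached on the exposure grid and at event times.

    The exposure integral is a midpoint rule on one global grid over
    [0, max ts] with exact per-cell alive lengths; event-time rates are
    interpolated exactly at each ts/te.
    """

    def __init__(
        self,
        lineages: Sequence[LineageRecord],
        covset: Sequence[CovariateTrajectory],
        step: float = 1.0,
    ):
        if not lineages:
            raise ValidationError("empty lineage set")
        if not covset:
            raise ValidationError("MBD requires at least one covariate")
        for c in covset:
            if not c.rescaled:
                raise ValidationError(
                    f"covariate {c.name!r} must be rescaled before fitting"
                )
        t_max = max(l.ts for l in lineages)
        n_cells = max(1, int(math.ceil(t_max / step)))
        h = t_max / n_cells
        edges = np.arange(n_cells + 1) * h
        mids = 0.5 * (edges[:-1] + edges[1:])
        self.cov_names = [c.name for c in covset]
        self.C_grid = np.column_stack([c.at(mids) for c in covset])
        self.alive_len = np.zeros(n_cells)
        for l in lineages:
            self.alive_len += np.maximum(
                0.0, np.minimum(l.ts, edges[1:]) - np.maximum(l.te, edges[:-1])
            )
        oldest = int(np.argmax([l.ts for l in lineages]))
        ts_events = np.array(
            [l.ts for i, l in enumerate(lineages) if i != oldest], dtype=float
        )
        te_events = np.array([l.te for l in lineages if not l.extant], dtype=float)
        self.C_ts = np.column_stack([c.at(ts_events) for c in covset])
        self.C_te = np.column_stack([c.at(te_events) for c in covset])
        self.n_orig = ts_events.size
        self.n_ext = te_events.size
        self.n_lineages = len(lineages)
        self.total_duration = float(sum(l.duration for l in lineages))

    def loglik(self, lam0, mu0, G, H, mode) -> float:
        s_lam_grid = self.C_grid @ G
        s_mu_grid = self.C_grid @ H
        s_lam_ts = self.C_ts @ G if self.n_orig else np.empty(0)
        s_mu_te = self.C_te @ H if self.n_ext else np.empty(0)
        if mode == "exponential":
            if lam0 <= 0 and self.n_orig:
                return -np.inf
            if mu0 <= 0 and self.n_ext:
                return -np.inf
            exposure = float(
                self.alive_len @ (lam0 * np.exp(s_lam_grid) + mu0 * np.exp(s_mu_grid))
            )
            ev = self.n_orig * math.log(lam0) + float(s_lam_ts.sum()) if self.n_orig else 0.0
            ev += self.n_ext * math.log(mu0) + float(s_mu_te.sum()) if self.n_ext else 0.0
            return ev - exposure
        # linear mode with truncation at zero
        lam_grid = np.maximum(0.0, lam0 * (1.0 + s_lam_grid))
        mu_grid = np.maximum(0.0, mu0 * (1.0 + s_mu_grid))
        exposure = float(self.alive_len @ (lam_grid + mu_grid))
        lam_ts = lam0 * (1.0 + s_lam_ts)
        mu_te = mu0 * (1.0 + s_mu_te)
        if np.any(lam_ts <= 0.0) or np.any(mu_te <= 0.0):
            return -np.inf
        ev = float(np.log(lam_ts).sum()) + float(np.log(mu_te).sum())
        return ev - exposure


def _half_cauchy_unit_logpdf(x: float) -> float:
    if x <= 0:
        return -np.inf
    return math.log(2.0 / math.pi) - math.log1p(x * x)


# ---------------------------------------------------------------------------
# samplers


def _trace_frame(rows: list, columns: list) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=columns)


def _run_mbd(
    lineages: Sequence[LineageRecord],
    covset: Sequence[CovariateTrajectory],
    config: MCMCConfig,
    mode: str,
) -> TraceLog:
    cache = _MBDCache(lineages, covset, step=config.step)
    n_cov = len(covset)
    rng = np.random.default_rng(config.seed)

    # method-of-moments start; correlations get a small jitter because a
    # start at exactly 0 makes the horseshoe scale conditionals improper
    # (the chain can collapse into the funnel before any G/H move accepts)
    lam0 = max((cache.n_lineages - 1) / cache.total_duration, 1e-2)
    mu0 = max(cache.n_ext / cache.total_duration, 1e-2)
    G = 0.05 * rng.standard_normal(n_cov)
    H = 0.05 * rng.standard_normal(n_cov)
    hs = HorseshoeState(np.ones(n_cov), np.ones(n_cov), 1.0)

    def loglik(lam0_, mu0_, G_, H_):
        if config.prior_only:
            return 0.0
        return cache.loglik(lam0_, mu0_, G_, H_, mode)

    def logprior(lam0_, mu0_, G_, H_, hs_):
        lp = horseshoe_log_prior(G_, H_, hs_)
        lp += _half_cauchy_unit_logpdf(lam0_) + _half_cauchy_unit_logpdf(mu0_)
        return lp

    ll = loglik(lam0, mu0, G, H)
    lp = logprior(lam0, mu0, G, H, hs)
    if not np.isfinite(ll + lp):
        raise InitializationError(
            "initial MCMC state has zero posterior probability"
        )

    names = cache.cov_names
    columns = (
        ["state", "posterior", "likelihood", "prior", "lambda0", "mu0"]
        + [f"G_{n}" for n in names]
        + [f"H_{n}" for n in names]
        + [f"eps_{n}" for n in names]
        + [f"zeta_{n}" for n in names]
        + ["tau"]
        + [f"w_G_{n}" for n in names]
        + [f"w_H_{n}" for n in names]
    )
    rows: list = []

    def record(it):
        w_g = 1.0 - 1.0 / (1.0 + hs.tau**2 * hs.eps**2)
        w_h = 1.0 - 1.0 / (1.0 + hs.tau**2 * hs.zeta**2)
        rows.append(
            [it, ll + lp, ll, lp, lam0, mu0]
            + list(G)
            + list(H)
            + list(hs.eps)
            + list(hs.zeta)
            + [hs.tau]
            + list(w_g)
            + list(w_h)
        )

    record(0)
    acc = {k: [0, 0] for k in ("rates", "G", "H", "hyper")}
    weights = np.asarray(config.block_weights, dtype=float)
    weights = weights / weights.sum()

    for it in range(1, config.n_iter + 1):
        if config.prior_only:
            # all conditionals are conjugate: systematic Gibbs scans.  The
            # global scale mixes slowest (it is tied to all 2N correlations),
            # so several inner scans are run per iteration to decorrelate it.
            for _ in range(10):
                G = rng.normal(0.0, hs.eps * hs.tau)
                H = rng.normal(0.0, hs.zeta * hs.tau)
                hs = gibbs_update_horseshoe(G, H, hs, rng)
            lam0 = abs(rng.standard_cauchy())
            mu0 = abs(rng.standard_cauchy())
            lp = logprior(lam0, mu0, G, H, hs)
            ll = 0.0
            if it % config.sample_freq == 0:
                record(it)
            continue

        block = rng.choice(4, p=weights)
        if block == 0:  # baseline rates: log-scale multipliers
            u = rng.uniform(-config.mult_window, config.mult_window, size=2)
            lam0_n, mu0_n = lam0 * math.exp(u[0]), mu0 * math.exp(u[1])
            ll_n = loglik(lam0_n, mu0_n, G, H)
            lp_n = logprior(lam0_n, mu0_n, G, H, hs)
            acc["rates"][1] += 1
            if math.log(rng.random()) < (ll_n + lp_n) - (ll + lp) + u.sum():
                lam0, mu0, ll, lp = lam0_n, mu0_n, ll_n, lp_n
                acc["rates"][0] += 1
        elif block == 1:  # G: Gaussian random walk
            G_n = G + config.gh_sigma * rng.standard_normal(n_cov)
            ll_n = loglik(lam0, mu0, G_n, H)
            lp_n = logprior(lam0, mu0, G_n, H, hs)
            acc["G"][1] += 1
            if math.log(rng.random()) < (ll_n + lp_n) - (ll + lp):
                G, ll, lp = G_n, ll_n, lp_n
                acc["G"][0] += 1
        elif block == 2:  # H: Gaussian random walk
            H_n = H + config.gh_sigma * rng.standard_normal(n_cov)
            ll_n = loglik(lam0, mu0, G, H_n)
            lp_n = logprior(lam0, mu0, G, H_n, hs)
            acc["H"][1] += 1
            if math.log(rng.random()) < (ll_n + lp_n) - (ll + lp):
                H, ll, lp = H_n, ll_n, lp_n
                acc["H"][0] += 1
        else:  # horseshoe scales: exact Gibbs
            hs = gibbs_update_horseshoe(G, H, hs, rng)
            lp = logprior(lam0, mu0, G, H, hs)
            acc["hyper"][1] += 1
            acc["hyper"][0] += 1
        if it % config.sample_freq == 0:
            record(it)

    return TraceLog(
        _trace_frame(rows, columns),
        {k: (a, p) for k, (a, p) in acc.items()},
    )


def _run_bds(
    lineages: Sequence[LineageRecord],
    grid: EpochGrid,
    config: MCMCConfig,
) -> TraceLog:
    cache = _BDSCache(lineages, grid)
    k = grid.k
    rng = np.random.default_rng(config.seed)

    total_duration = float(sum(l.duration for l in lineages))
    lam_k = np.full(k, max((cache.n_lineages - 1) / total_duration, 1e-2))
    mu_k = np.full(k, max(cache.n_ext.sum() / total_duration, 1e-2))
    s1 = s2 = 1.0

    def loglik(lam, mu):
        if config.prior_only:
            return 0.0
        return cache.loglik(lam, mu)

    def logprior(lam, mu, s1_, s2_):
        return bds_log_prior(BDSParameters(lam, mu, s1_, s2_))

    ll = loglik(lam_k, mu_k)
    lp = logprior(lam_k, mu_k, s1, s2)
    if not np.isfinite(ll + lp):
        raise InitializationError(
            "initial MCMC state has zero posterior probability"
        )

    columns = (
        ["state", "posterior", "likelihood", "prior"]
        + [f"lambda_{i}" for i in range(k)]
        + [f"mu_{i}" for i in range(k)]
        + ["s1", "s2"]
    )
    rows: list = []

    def record(it):
        rows.append([it, ll + lp, ll, lp] + list(lam_k) + list(mu_k) + [s1, s2])

    record(0)
    acc = {key: [0, 0] for key in ("lambda", "mu", "hyper")}

    for it in range(1, config.n_iter + 1):
        block = rng.choice(3, p=(0.4, 0.4, 0.2))
        if block == 0:
            u = rng.uniform(-config.mult_window, config.mult_window, size=k)
            lam_n = lam_k * np.exp(u)
            ll_n = loglik(lam_n, mu_k)
            lp_n = logprior(lam_n, mu_k, s1, s2)
            acc["lambda"][1] += 1
            if math.log(rng.random()) < (ll_n + lp_n) - (ll + lp) + u.sum():
                lam_k, ll, lp = lam_n, ll_n, lp_n
                acc["lambda"][0] += 1
        elif block == 1:
            u = rng.uniform(-config.mult_window, config.mult_window, size=k)
            mu_n = mu_k * np.exp(u)
            ll_n = loglik(lam_k, mu_n)
            lp_n = logprior(lam_k, mu_n, s1, s2)
            acc["mu"][1] += 1
            if math.log(rng.random()) < (ll_n + lp_n) - (ll + lp) + u.sum():
                mu_k, ll, lp = mu_n, ll_n, lp_n
                acc["mu"][0] += 1
        else:  # prior scales: sliding window inside U[0, 20]
            s1_n = s1 + config.s_window * rng.standard_normal()
            s2_n = s2 + config.s_window * rng.standard_normal()
            lp_n = logprior(lam_k, mu_k, s1_n, s2_n)
            acc["hyper"][1] += 1
            if math.log(rng.random()) < lp_n - lp:
                s1, s2, lp = s1_n, s2_n, lp_n
                acc["hyper"][0] += 1
        if it % config.sample_freq == 0:
            record(it)

    return TraceLog(
        _trace_frame(rows, columns),
        {key: (a, p) for key, (a, p) in acc.items()},
    )


def run_mcmc(
    model: str,
    lineages: Sequence[LineageRecord],
    covset: Sequence[CovariateTrajectory] | None = None,
    config: MCMCConfig | None = None,
    *,
    epochs: EpochGrid | None = None,
    mode: str = "exponential",
) -> TraceLog:
    """Run the posterior sampler for ``model`` ('bds' or 'mbd').

    The BDS model needs ``epochs``; the MBD model needs a rescaled
    ``covset`` and a link ``mode`` ('linear' or 'exponential').
    """
    config = config or MCMCConfig()
    if model == "bds":
        if epochs is None:
            raise ValidationError("BDS model requires an epoch grid")
        return _run_bds(lineages, epochs, config)
    if model == "mbd":
        if not covset:
            raise ValidationError("MBD model requires at least one covariate")
        if mode not in ("linear", "exponential"):
            raise ValidationError("mode must be 'linear' or 'exponential'")
        return _run_mbd(lineages, covset, config, mode)
    raise ValidationError(f"unknown model {model!r}")
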