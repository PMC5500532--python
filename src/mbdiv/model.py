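"""Model classes tying data, likelihood, sampler and summaries together.

The API follows the fit/results idiom of statistical modelling packages:
a model object is built from data, ``fit()`` runs the MCMC and returns a
results object carrying the trace, posterior summaries, diagnostics and
derived products (rates through time, marginal-likelihood estimates).

>>> model = MBDModel(lineages, covariates, mode="exponential")
>>> res = model.fit(n_iter=200_000, seed=1)
>>> print(res.summary())
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .data import CovariateTrajectory, EpochGrid, LineageRecord
from .diagnostics import effective_sample_size, hpd_interval
from .errors import ValidationError
from .horseshoe import MBDParameters, mbd_loglik
from .likelihood import BDSParameters, bds_loglik
from .mcmc import MCMCConfig, TraceLog, run_mcmc
from .summary import (
    PosteriorSummary,
    RatesThroughTime,
    harmonic_mean_logml,
    pool_traces,
    rates_through_time,
    summarize_posterior,
)

__all__ = ["BDSModel", "MBDModel", "BDSResults", "MBDResults"]


class _BaseResults:
    """Shared machinery for posterior results built from one or more traces."""

    def __init__(self, model, traces: Sequence[TraceLog], config: MCMCConfig):
        if isinstance(traces, TraceLog):
            traces = [traces]
        if not traces:
            raise ValidationError("results need at least one trace")
        self.model = model
        self.traces = list(traces)
        self.config = config

    @property
    def trace(self) -> TraceLog:
        """The first (or only) replicate trace."""
        return self.traces[0]

    def pooled(self) -> pd.DataFrame:
        return pool_traces(self.traces, self.config.burnin_fraction)

    def posterior_mean(self) -> pd.Series:
        pooled = self.pooled()
        cols = [c for c in pooled.columns if c not in ("state",)]
        return pooled[cols].mean()

    def hpd(self, parameter: str, prob: float = 0.95) -> tuple[float, float]:
        return hpd_interval(self.pooled()[parameter].to_numpy(float), prob)

    def ess(self, parameter: str) -> float:
        return effective_sample_size(self.pooled()[parameter].to_numpy(float))

    def log_marginal_likelihood(self) -> float:
        """Harmonic-mean estimate from the pooled sampled log-likelihoods."""
        return harmonic_mean_logml(self.pooled()["likelihood"].to_numpy(float))

    def summary(self) -> PosteriorSummary:
        return summarize_posterior(self.traces, self.config.burnin_fraction)

    @property
    def acceptance_rates(self) -> dict:
        return self.trace.acceptance_rates()


class BDSResults(_BaseResults):
    """Posterior sample of the epoch-shift birth-death model."""

    def rates_through_time(self, grid=None, prob: float = 0.95) -> RatesThroughTime:
        if grid is None:
            grid = self.model.epochs.midpoints()
        return rates_through_time(
            self.traces,
            "bds",
            grid,
            epochs=self.model.epochs,
            burnin_fraction=self.config.burnin_fraction,
            prob=prob,
        )


class MBDResults(_BaseResults):
    """Posterior sample of the multivariate birth-death model."""

    def shrinkage_weights(self) -> pd.DataFrame:
        """Mean shrinkage weight per covariate for origination (G) and
        extinction (H) correlations."""
        pooled = self.pooled()
        names = [c.name for c in self.model.covariates]
        return pd.DataFrame(
            {
                "covariate": names,
                "w_G": [pooled[f"w_G_{n}"].mean() for n in names],
                "w_H": [pooled[f"w_H_{n}"].mean() for n in names],
            }
        )

    def rates_through_time(self, grid=None, prob: float = 0.95) -> RatesThroughTime:
        if grid is None:
            t_max = max(l.ts for l in self.model.lineages)
            grid = np.linspace(t_max, 0.0, 101)
        return rates_through_time(
            self.traces,
            "mbd",
            grid,
            covset=self.model.covariates,
            mode=self.model.mode,
            burnin_fraction=self.config.burnin_fraction,
            prob=prob,
        )


class BDSModel:
    """Birth-death model with rate shifts at fixed epoch boundaries.

    Rates are constant within each stratigraphic epoch; all origination
    rates share one half-Cauchy prior C+(0, s1) and all extinction rates
    one C+(0, s2), with s1, s2 ~ U[0, 20] estimated from the data.
    """

    def __init__(self, lineages: Sequence[LineageRecord], epochs: EpochGrid):
        if not lineages:
            raise ValidationError("empty lineage set")
        self.lineages = list(lineages)
        self.epochs = epochs

    def loglike(self, params: BDSParameters) -> float:
        return bds_loglik(self.lineages, params, self.epochs)

    def fit(
        self,
        n_iter: int = 100_000,
        sample_freq: int = 100,
        seed: int = 0,
        config: MCMCConfig | None = None,
        **kwargs,
    ) -> BDSResults:
        config = config or MCMCConfig(
            n_iter=n_iter, sample_freq=sample_freq, seed=seed, **kwargs
        )
        trace = run_mcmc("bds", self.lineages, config=config, epochs=self.epochs)
        return BDSResults(self, [trace], config)

    def fit_replicates(
        self, lineage_sets: Sequence[Sequence[LineageRecord]], **fit_kwargs
    ) -> BDSResults:
        """Fit each resampled-age lineage set (replicate r uses seed + r)
        and pool the traces."""
        base_seed = fit_kwargs.pop("seed", 0)
        traces = []
        config = None
        for r, lins in enumerate(lineage_sets):
            m = BDSModel(lins, self.epochs)
            res = m.fit(seed=base_seed + r, **fit_kwargs)
            traces.append(res.trace)
            config = res.config
        return BDSResults(self, traces, config)


class MBDModel:
    """Multivariate birth-death model over rescaled covariate trajectories.

    Origination and extinction rates are linear or exponential functions
    of the covariates (shared across lineages); the per-covariate
    correlation parameters G, H carry a horseshoe shrinkage prior with
    local scales ε, ζ and global scale τ.
    """

    def __init__(
        self,
        lineages: Sequence[LineageRecord],
        covariates: Sequence[CovariateTrajectory],
        mode: str = "exponential",
        step: float = 1.0,
    ):
        if not lineages:
            raise ValidationError("empty lineage set")
        if not covariates:
            raise ValidationError("MBD model needs at least one covariate")
        for c in covariates:
            if not c.rescaled:
                raise ValidationError(
                    f"covariate {c.name!r} must be rescaled to [0, 1]"
                )
        if mode not in ("linear", "exponential"):
            raise ValidationError("mode must be 'linear' or 'exponential'")
        self.lineages = list(lineages)
        self.covariates = list(covariates)
        self.mode = mode
        self.step = step

    @property
    def n_free_parameters(self) -> int:
        """2N + 2: baselines plus one G and one H per covariate."""
        return 2 * len(self.covariates) + 2

    def loglike(self, params: MBDParameters) -> float:
        if params.mode != self.mode:
            raise ValidationError("parameter mode does not match the model")
        return mbd_loglik(self.lineages, params, self.covariates, step=self.step)

    def fit(
        self,
        n_iter: int = 200_000,
        sample_freq: int = 100,
        seed: int = 0,
        config: MCMCConfig | None = None,
        **kwargs,
    ) -> MBDResults:
        config = config or MCMCConfig(
            n_iter=n_iter,
            sample_freq=sample_freq,
            seed=seed,
            step=self.step,
            **kwargs,
        )
        trace = run_mcmc(
            "mbd", self.lineages, self.covariates, config, mode=self.mode
        )
        return MBDResults(self, [trace], config)

    def fit_replicates(
        self, lineage_sets: Sequence[Sequence[LineageRecord]], **fit_kwargs
    ) -> MBDResults:
        """Fit each resampled-age lineage set (replicate r uses seed + r)
        and pool the traces."""
        base_seed = fit_kwargs.pop("seed", 0)
        traces = []
        config = None
        for r, lins in enumerate(lineage_sets):
            m = MBDModel(lins, self.covariates, self.mode, self.step)
            res = m.fit(seed=base_seed + r, **fit_kwargs)
            traces.append(res.trace)
            config = res.config
        return MBDResults(self, traces, config)
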