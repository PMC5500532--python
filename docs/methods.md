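# Methods

## The models

`mbdiv` estimates genus-level origination and extinction rates from
lineage span data: one row per genus with an origination time `ts` and an
extinction time `te`, both in Ma before present (`te = 0` marks an extant
genus).  Times increase into the past; an extinct lineage occupies the
half-open interval `(te, ts]` and an extant one `[0, ts]`, so shared
boundary times are never double-counted.

Both models share the birth-death likelihood for fully observed lineage
spans under rates λ(t), μ(t) common to all lineages:

    log L = Σ_{i ≠ oldest} log λ(ts_i)
          + Σ_{extinct i}  log μ(te_i)
          − Σ_i ∫_{te_i}^{ts_i} (λ(t) + μ(t)) dt

**Conditioning on the origin.**  The single oldest lineage contributes no
λ factor: the process had to start with one lineage, and no rate
parameter can explain that first appearance.  Ties for oldest are broken
by excluding exactly one lineage (the first in input order).  This is a
modelling assumption — other conventions (conditioning on survival, on
the number of tips) exist — and it matters only through an additive
`log λ(ts_oldest)` term.

**BDS (birth-death with shifts).**  Rates are constant within the
intervals of a fixed epoch grid (e.g. the stratigraphic timescale).  A
time falling exactly on an epoch boundary belongs to the younger epoch.
All K origination rates share one half-Cauchy prior C+(0, s1), all K
extinction rates one C+(0, s2); the scales s1, s2 carry uniform
hyper-priors on [0, 20] and are estimated from the data, which shrinks
the per-epoch rates towards a common scale and controls
overparameterization on sparse intervals.  The exposure integral is
computed exactly from per-epoch overlap lengths, no quadrature.

**MBD (multivariate birth-death).**  Rates are deterministic functions of
N time-continuous covariate trajectories C_i(t), each min-max rescaled to
[0, 1] before the analysis so the correlation parameters are comparable
across covariates:

* linear:       λ(t) = max{0, λ0 + λ0 Σ G_i C_i(t)}   (and μ alike with H)
* exponential:  λ(t) = λ0 exp(Σ G_i C_i(t))

The linear form is truncated at zero; the exponential form is always
positive.  An MBD model over N covariates has exactly 2N + 2 free core
parameters (λ0, μ0, G_1..N, H_1..N); with 17 covariates that is 36.
Covariates are fixed inputs during inference — a diversity covariate is
precomputed (e.g. from a BDS fit or from the lineage table via
`diversity_trajectory`) and not updated within the MCMC.

Between tabulated points covariates are interpolated linearly; outside
their tabulated range they are constant-extrapolated from the nearest
endpoint.  Linear interpolation is the minimal smooth choice; nothing in
the likelihood depends on higher smoothness.  Rescaling can optionally be
restricted to an analysis window; the default uses each variable's full
tabulated range, and values outside the window are clipped into [0, 1].

**Horseshoe shrinkage.**  With 2N correlation parameters and one dataset,
unregularized estimates would overfit.  Each G_i gets a normal prior with
mean 0 and *variance* ε_i² τ² (H_i likewise with ζ_i² τ²); the local
scales ε_i, ζ_i and the global scale τ are all standard half-Cauchy
C+(0, 1).  The posterior of the scales yields a shrinkage weight per
parameter,

    w = 1 − 1 / (1 + τ² ε²),

which is 0.5 exactly at τ = ε = 1.  A posterior-mean weight strictly
above 0.5 classifies the correlation as signal; the direction is the sign
of the posterior-mean correlation parameter.  Weights are not posterior
probabilities, but they separate signal from noise reliably in
simulation.

## Posterior sampling

One block is updated per iteration, chosen at random with weights
(baseline rates 0.3, G 0.25, H 0.25, horseshoe scales 0.2) for MBD and
(λ vector 0.4, μ vector 0.4, scales 0.2) for BDS:

* positive parameters (λ0, μ0, per-epoch rates) use log-scale multiplier
  proposals `x' = x·e^u`, `u ~ U(−0.2, 0.2)`, with the log-multiplier
  Hastings correction;
* G and H use Gaussian random walks (σ = 0.1, all coordinates at once);
* the horseshoe scales use exact conjugate Gibbs draws via the
  inverse-gamma auxiliary representation of the half-Cauchy — no tuning
  parameters and correct heavy-tailed behaviour;
* the BDS prior scales s1, s2 use a sliding-window proposal (σ = 1.0)
  bounded by their uniform support.

All proposal windows are configurable through `MCMCConfig`.  On the
standard recovery benchmark below, every Metropolis block accepts at
rates between 0.2 and 0.4.

The MBD baselines λ0, μ0 carry a half-Cauchy C+(0, 1) prior — weakly
informative on the scale of plausible genus-level rates (10⁻²–10⁰
events/lineage/Ma) and of the same family as the rest of the model.

**Initialization.**  λ0 and μ0 start at method-of-moments values
(events/total exposure, floored at 0.01); the scale state starts at
ε = ζ = τ = 1.  The correlations start at a small N(0, 0.05²) jitter
rather than exactly 0: when a correlation parameter is exactly zero its
local scale's full conditional is improper at the origin, and the Gibbs
chain can spiral into the shrinkage funnel and numerically freeze there
before any correlation move is accepted.  A nonzero start keeps every
conditional proper; one sweep of the scale updates then self-corrects
the scales to match the correlations.  For the same reason the squared
scales are clipped to [1e-12, 1e12] (half-Cauchy mass beyond either
bound ≈ 6e-7, statistically invisible).

**Likelihood evaluation.**  The exposure integral uses a midpoint rule
(default step 1 Ma, configurable) — second-order, exact for rates
constant or linear in t.  Inside the sampler the covariate sums are
cached on one global grid over [0, max ts] together with per-cell total
alive-lengths, making an iteration O(grid + events) regardless of the
number of lineages; event-time rates are interpolated exactly at each
ts/te.  The public `bd_loglik` integrates per lineage instead; both are
midpoint rules and agree to grid error.  BDS needs no quadrature at all.

**Prior-only mode.**  With the likelihood disabled every conditional is
conjugate, so the sampler switches to systematic-scan Gibbs: G, H drawn
from N(0, local²τ²), scales refreshed by the auxiliary-variable updates,
baselines from their priors.  Ten inner scans per recorded iteration
decorrelate the global scale, whose conditional is tied to all 2N
correlations.  This mode is used to validate that the sampler's
stationary marginals reproduce the horseshoe prior (e.g. τ ~ C+(0, 1) by
Kolmogorov-Smirnov distance).

**Determinism.**  A single seeded generator drives each chain; identical
configuration and seed give bit-identical traces.  Replicate r (for
dating-uncertainty resampling) derives its stream as `seed + r`.

## Dating uncertainty

Fossil occurrence ages are typically known only to a stratigraphic
interval [age_min, age_max].  Ages are resampled uniformly and
independently within their intervals to build replicate datasets
(100 by convention); each replicate is analysed separately and the
post-burn-in samples are pooled before summarizing, so dating
uncertainty propagates into the posterior.  When the fitting command is
given occurrences rather than lineage spans, each replicate's lineage
table uses the observed resampled range of each genus (oldest sampled
age as ts, youngest as te, 0 if extant).  This is a deliberate,
documented proxy: joint inference of true origination/extinction times
under a preservation model is outside this package's scope, and observed
ranges systematically underestimate true spans at low preservation
rates.

## Model comparison and adequacy

Marginal likelihoods are approximated by the harmonic mean of the
sampled likelihoods, computed with log-sum-exp.  The estimator is
biased-high and high-variance — it is dominated by the lowest sampled
likelihood, so generous burn-in matters — but it suffices for
directional comparisons; the package reports log Bayes factors as
2·(log ML_a − log ML_b) in both orientations with the Kass-Raftery
verbal category.  Path-sampling estimators are deliberately out of
scope.

As an adequacy check, rates-through-time curves from an MBD fit are
compared against a BDS fit of the same data (the BDS makes no assumption
about what drives rate variation).  The squared Pearson correlation R²
between the two posterior-mean rate vectors — evaluated at the BDS epoch
midpoints, where the BDS estimate is piecewise-constant — measures how
much of the nonparametric rate variation the covariates capture.  When a
simulated dataset starts from a standing cohort of founder lineages, all
founders register their first appearance at the window edge; that
boundary artifact inflates the nonparametric origination estimate in the
edge interval under any windowed analysis, so the validation design
assigns a short sacrificial edge epoch and compares rates on the
interior midpoints.

Congruence of two credible intervals (e.g. fossil vs molecular ages)
uses the overlap rule max(lows) ≤ min(highs); a single shared endpoint
counts as congruent, and the signed gap max(lows) − min(highs) is
reported when they are disjoint.

## The synthetic-data generator

The simulator produces the package's validation inputs:

* **Covariates**: independent Gaussian random walks on a 1-Ma grid,
  min-max rescaled to [0, 1].  Real palaeoenvironmental series are
  smoother and mutually correlated; random walks are a conservative
  stand-in with realistic low-frequency structure.
* **Lineages**: a forward birth-death simulation from one seed lineage at
  `t_start`, with event times drawn by thinning against a per-1-Ma-window
  bound (1.5x the maximum of the total rate at the window endpoints and
  midpoint).  Histories outside a lineage-count band are
  rejection-resampled (cap 1000 attempts) to avoid degenerate datasets.
* **Preservation**: Poisson fossil sampling at rate q per lineage per Ma,
  with across-lineage Gamma(α, α) rate heterogeneity discretized into
  n_cat equal-probability categories (category means renormalized to
  average exactly 1).  Exact simulated ages can then be blurred to epoch
  bounds to emulate stratigraphic dating uncertainty.

The default generator condition — the recovery benchmark — is an
exponential model over 5 covariates with one true extinction effect
H_1 = 2.5 (all other effects 0), λ0 = 0.30, μ0 = 0.03 over 30 Ma,
conditioned on 300–600 total lineages.  These sizes give a few hundred
origination events and ~100 extinction events: enough signal that the
true effect should be detected, small enough that one fit takes seconds.
The "forced" variant puts effects on both rates (G_1 = 2.5, H_1 = 2.5,
λ0 = 0.12) so that origination and extinction both vary through time;
it is used for the model-comparison and adequacy checks.  Preservation
defaults (q = 1 occurrence/lineage/Ma, α = 0.33, 8 categories) mirror a
strongly heterogeneous plant-type fossil record.

What passing these simulations does *not* show: robustness to
misspecified preservation, to correlated or measurement-noisy
covariates, to rate heterogeneity across lineages (the model assumes
none), or to the observed-range bias in ts/te.  Real-data inferences
inherit all of those caveats.

## Problem sizes used in validation

Validation fits use 300–2000 lineages with 50k–200k MCMC iterations and
10% (recovery) to 50% (harmonic-mean comparisons) burn-in.  These sizes
were chosen so that each check isolates one property with comfortable
Monte-Carlo margins; the empirical-scale analyses this package is
patterned on run two to three orders of magnitude longer on much larger
occurrence datasets.

## Known limitations

* The harmonic-mean marginal likelihood is a rough instrument; only the
  sign of large Bayes factors should be trusted.
* Observed-range lineage spans understate true durations; a joint
  preservation model (not included) removes that bias.
* Shrinkage weights depend on the covariate rescaling; a covariate with
  one extreme excursion compresses the rest of its range.
* The linear rate model can place exactly zero rate on an observed event
  (likelihood −inf); the sampler simply rejects such states, but a
  posterior concentrated near the truncation boundary mixes slowly.
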