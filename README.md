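# mbdiv

Bayesian birth-death models of origination and extinction for
genus-level fossil data, with multivariate environmental correlates
under horseshoe shrinkage.

## The problem

Macroevolutionary questions — does a clade's own diversity throttle its
origination rate? do temperature, sea level, or competitor diversity
drive its extinctions? — require estimating time-varying origination
and extinction rates from the fossil record and relating them to many
candidate drivers *jointly*, not one at a time.  `mbdiv` implements two
complementary models for lineage span data (per-genus origination time
`ts` and extinction time `te`, in Ma before present, `te = 0` for
extant genera):

* **BDS** — a birth-death model with rate shifts at fixed stratigraphic
  epoch boundaries: rates λ_k, μ_k are constant within epochs, with
  shared half-Cauchy priors C+(0, s1), C+(0, s2) whose scales get
  uniform [0, 20] hyper-priors.  It estimates rate trajectories without
  assuming anything about their causes.
* **MBD** — a multivariate birth-death model in which rates are linear
  or exponential functions of N time-continuous covariates C_i(t)
  (each rescaled to [0, 1]):

      λ(t) = λ0 exp(Σᵢ Gᵢ Cᵢ(t)),   μ(t) = μ0 exp(Σᵢ Hᵢ Cᵢ(t))

  (or the truncated-linear analogue).  The 2N correlation parameters
  carry a horseshoe prior — Gᵢ ~ N(0, εᵢ²τ²) with half-Cauchy local
  scales εᵢ and global scale τ — so that noise correlations shrink to
  zero while true signals escape.  The per-parameter **shrinkage
  weight** w = 1 − 1/(1 + τ²ε²) classifies each covariate: a posterior
  mean weight above 0.5 is significant signal, with the sign of the
  correlation parameter giving the direction.

Both models share the lineage-span likelihood (the single oldest
lineage's origination is conditioned upon):

    log L = Σ_{i≠oldest} log λ(tsᵢ) + Σ_{extinct} log μ(teᵢ)
          − Σᵢ ∫_{teᵢ}^{tsᵢ} (λ(t)+μ(t)) dt

Posterior sampling is Metropolis-Hastings with exact conjugate Gibbs
updates for the horseshoe scales; model comparison uses harmonic-mean
marginal likelihoods and 2·log Bayes factors; dating uncertainty is
propagated by uniform resampling of occurrence ages into replicate
datasets whose posteriors are pooled.  A forward simulator (covariate
random walks, covariate-driven birth-death histories, Poisson fossil
preservation with discrete-gamma rate heterogeneity) generates all
validation data.  See `docs/methods.md` for the full model account.

## Worked example

Simulate the standard recovery condition — an exponential MBD over five
random-walk covariates with one true extinction effect H₁ = 2.5 — and
fit it:

```python
from mbdiv import MBDModel
from mbdiv.simulate import SimulationConfig, simulate_dataset

lineages, covariates, truth = simulate_dataset(SimulationConfig(seed=0))
model = MBDModel(lineages, covariates, mode="exponential")
res = model.fit(n_iter=200_000, sample_freq=100, seed=1)
print(res.shrinkage_weights())
```

This prints (315 simulated lineages, 92 extinct):

```
covariate      w_G      w_H
    cov_0 0.176667 0.782792
    cov_1 0.136466 0.160776
    cov_2 0.115890 0.196272
    cov_3 0.115445 0.138937
    cov_4 0.132881 0.176905
```

The true extinction driver `cov_0` is the only parameter whose mean
shrinkage weight exceeds 0.5 (w_H = 0.78 > 0.5 — significant); all
eight null effects stay shrunk well below it.  The posterior summary
recovers the generating values:

```
lambda0: mean 0.271  95% HPD [0.175, 0.357]   (truth 0.30)
mu0:     mean 0.038  95% HPD [0.015, 0.067]   (truth 0.03)
H_cov_0: mean 2.391  95% HPD [1.630, 3.135]   (truth 2.5)  -> significant_positive
```

The same workflow is available from the shell:

```sh
mbdiv simulate --seed 0 --out data/
mbdiv fit --model mbd --lineages data/lineages.tsv \
          --covariates data/covariates --mode exponential \
          --iterations 200000 --seed 1 --out fit/
mbdiv compare --trace-a fit_linear/ --trace-b fit/     # 2 log BF, both ways
mbdiv rtt --traces fit/ --model mbd --covariates data/covariates --out rtt/
```

`fit` accepts an occurrence table with stratigraphic age ranges instead
of lineage spans (`--occurrences ... --replicates 100`), in which case
ages are resampled uniformly per replicate and the replicate posteriors
are pooled.

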