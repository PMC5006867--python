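# Methods

`cesmark` estimates sex-specific adult survival and adult sex ratios for
a migratory passerine monitored by a constant-effort ringing scheme, and
propagates those estimates into the downstream ecological regressions
(spatio-temporal sex-ratio trends, the abundance–sex-ratio relationship,
and juvenile productivity).  Because no individual-level ringing data
are publicly deposited for this system, the package is organised around
a synthetic-data generator with known ground truth: every stage is
validated by recovery of the quantities the generator used.

## 1. The transient-corrected CJS survival model

### Model

Capture histories are annual: one detection indicator per breeding
season per marked adult, conditional on first capture.  Apparent
survival confounds mortality and permanent emigration; more seriously
for mist-netting data, many first captures are *transients* — birds
passing through that are never again available for capture — which
biases apparent survival downward.  The correction inserts a
pseudo-occasion directly after the first capture:

* survival over the zero-length first interval is the residency
  probability `r[sex]`;
* detection at the pseudo-occasion is the probability `p_within[sex]`
  of at least one further capture within the first season;
* a bird that "dies" at the pseudo-interval (a transient) is absorbed
  and contributes nothing afterwards.

After the pseudo-occasion the model is standard CJS with

```
logit(phi[site, sex, t]) = logit(phi[site, sex]) + eps[t]
logit(p[site, sex])      = logit(mu_p[sex]) + eta[site, sex]
```

`eps[t] ~ N(0, sigma_year^2)` is a single annual random effect shared
across sites and sexes (survival varies in parallel between years);
`eta ~ N(0, sigma_p[sex]^2)` is a site random effect on recapture with
a sex-specific standard deviation (the sexes are caught by different
processes — singing males vs. brooding females — so their site spreads
need not match; a shared-SD variant would be a one-line change).
Residency and within-season recapture are constant over sites and
years, varying only by sex.  Recapture has no year variation, matching
constant-effort protocol.  Random effects act on the logit scale — the
only scale on which zero-mean normal deviations keep probabilities in
(0,1).

Priors: `U(0,1)` on every `phi[site, sex]`; `Beta(1,1)` on `mu_p`, `r`
and `p_within`; `U(0,10)` on both random-effect standard deviations
(the SD, not the variance, carries the flat prior, following common
ringing-model practice; configurable via `ModelSpec`).

### Likelihood

The per-individual likelihood is the product of the residency mixture
at first capture and the conditional CJS chain, with the standard
"never seen again" recursion

```
chi[T-1] = 1
chi[i]   = (1 - phi_i) + phi_i (1 - p * op[i+1]) chi[i+1]
```

extended with an operation mask `op` so that seasons in which a site
did not run contribute no detection term (a gap year blocks detection
but not survival).  A bird caught once and never recaught within its
first season contributes the mixture term
`(1 - r) + r (1 - p_within) chi[f]`.

For speed the fitted likelihood is evaluated over sufficient statistics
— an m-array of observed transition cells extended with residency
counts (`n` recaught within season, `n` confirmed residents without a
within-season recapture, never-seen-again first captures by occasion) —
which is algebraically identical to the per-individual form.  The test
suite verifies that identity to 1e-10 and checks both against
brute-force enumeration over all latent resident/alive sequences, and
that the modelled probabilities of all possible augmented histories sum
to one.

### Sampling

No probabilistic-programming backend is used; the sampler is an
adaptive Metropolis-within-Gibbs scheme written for this model:

1. joint random-walk updates of `(logit phi, eta)` for every site–sex
   cell — the cell likelihoods factorize given the shared parameters,
   so all cells are proposed in one vectorized pass and accepted
   independently;
2. a joint update of the year-effect vector `eps`;
3. a likelihood-invariant "shift" move trading a constant between
   `eps` and all survival intercepts (the two are only softly
   identified through the zero-mean prior on `eps`; this move mixes
   that direction);
4. per-sex joint updates of `(mu_p, r, p_within)`;
5. prior-conditional updates of `sigma_year` and `sigma_p` (their
   conditionals involve no data).

Proposal scales adapt by Robbins–Monro during burn-in only, targeting
acceptance 0.25–0.4, which keeps the post-burn-in chain a fixed
Markov kernel.  Probabilities are sampled on the logit scale with the
Jacobian folded into the prior density.

The default configuration is two chains of 60 000 iterations, 20 000
burn-in, thinning 10.  That arithmetic yields 2 × 4 000 = 8 000 retained
draws; descriptions of this design elsewhere quote 6 000 samples, which
is inconsistent with the stated chain arithmetic — the package follows
the arithmetic.  Split-chain R-hat and bulk ESS (via `arviz`) are
reported for every parameter; R-hat > 1.1 triggers a warning, never a
silent pass.  Test-scale runs (2 × 3 000–6 000) are used throughout the
suite; at the 10-site × 10-year recovery design they reproduce truth
well within the posterior spread (see `tests/test_acceptance.py`).

## 2. Detection-weighted sex ratios

The count of distinct adults of sex `j` caught at site `s` in year `t`
under-represents the harder-to-catch sex.  Per MCMC draw the package
forms `weighted_count = count / p[j, s]` and

```
SR[t, s] = (C_m / p_m) / (C_m / p_m + C_f / p_f)
```

so recapture-probability uncertainty propagates into the sex-ratio
posterior.  Site means average the annual ratios within each draw;
means, variances and central 95% intervals are reported over draws.
Site-years with no sexed adults yield no estimate.  Counts include
transient individuals (they are adults present in the season); a
resident-weighted variant would additionally divide by `r[sex]` and is
deliberately not implemented — it changes the estimand, not the
correction.

Survival-implied expected sex ratios use the stationarity identity
`males per female = phi_m (1 - phi_f) / (phi_f (1 - phi_m))`, converted
to a proportion of males.  This presumes equal-by-sex recruitment at
stationarity; the package applies it as a static conversion only.
Posterior correlations (male vs. female survival across sites;
expected vs. estimated sex ratio) are computed per draw, summarized by
mean, 95% interval and P(r > 0), with leave-one-site-out re-runs
supported; draws in which either vector is constant across sites have
no defined correlation and are dropped with a count.

## 3. Downstream regressions

* **Sex-ratio trend** — Gaussian mixed model of the site-year sex ratio
  on year (calendar year minus first year), latitude, longitude and
  their interaction, with crossed site and year random intercepts and
  precision weights.  statsmodels' MixedLM supports neither
  per-observation precision weights nor crossed intercepts cleanly, so
  the stage uses an in-package maximum-likelihood fitter: the two
  variance ratios are optimized by Nelder–Mead with the fixed effects
  and residual variance profiled out analytically; the tables involved
  are small (hundreds of rows), so dense Cholesky factorizations are
  fine.  The fitter is cross-checked against `lme4::lmer(…, weights=…)`
  through `Rscript` in the test suite.
* **Weights.**  The posterior variance of a weighted-count sex ratio
  conditions on the observed counts: a site-year in which only one sex
  was caught has variance exactly zero and would receive unbounded
  weight.  Weights are therefore `1 / (posterior variance + p̃(1-p̃)/n)`
  with `p̃` the Agresti–Coull smoothed proportion and `n` the adults
  counted — the binomial component is precisely the count-sampling
  variance the posterior omits.
* **Abundance surface** — Poisson regression of census counts with a
  log link, additive B-spline smooths in longitude and latitude
  (statsmodels `GLMGam`, 8 basis functions per axis, penalty weight 1)
  and year fixed effects.  This simplifies the original thin-plate
  `s(lon, lat)` interaction smooth with site/year random intercepts;
  for the smooth monotone gradients simulated here an additive basis
  recovers the surface (predicted vs. true log abundance correlate
  > 0.99 in tests), and unmodelled site effects surface as
  overdispersion rather than bias.  Predictions are clamped to the
  spline support; queries outside the surveyed convex hull are flagged.
* **Abundance vs. sex ratio** — weighted least squares of site mean sex
  ratio on log predicted relative abundance (weights as above, using
  the site-mean posterior variance).
* **Productivity** — Poisson mixed model of juvenile catches on the
  centred sex ratio, its square, and log relative abundance, with
  crossed site and year random intercepts, fitted by statsmodels'
  variational `PoissonBayesMixedGLM` (fixed-effect prior SD widened to
  25 so the prior does not shrink genuinely large curvature).  The sex
  ratio is centred at 0.5 so the quadratic peaks at parity
  (configurable).  A documented fallback (`method="glm"`) fits year
  fixed effects with site-cluster-robust errors — site dummies would
  absorb the site-constant abundance term, so site dependence moves to
  the covariance — and the two routes are compared on synthetic data in
  the tests.  A Pearson overdispersion ratio is always reported.
  Inference everywhere is large-sample Wald; no Satterthwaite
  small-sample correction is attempted, since sign and magnitude
  recovery, not p-value reproduction, is the contract.

All stages are deterministic given their inputs; the variational
optimizer's random start is pinned internally.

## 4. The synthetic-data generator

The generator emulates the study conditions: 34 sites over 19 seasons
on Britain-like coordinates; log relative abundance
`0.15 (lat − 54.5) − 0.15 (lon + 2)` (a smooth SE→NW doubling-plus
gradient); site sex ratios `0.55 − 0.07 × (centred log abundance)`
plus a `+0.005 / yr` drift (males rarer where abundance is high, skew
growing over time); sex-specific annual survival 0.48 (M) / 0.42 (F)
with a shared logit-scale year effect (SD 0.15); catch probabilities
0.5 (M) / 0.4 (F); 18% of adults unsexed.  Residency (0.7 both sexes)
and within-season recapture (0.5 M / 0.4 F) have no published
magnitudes, so defaults were chosen at plausible mid-range values and
are varied in tests.

Structure choices that matter:

* **Capture is a thinning of the standing population.**  Adults arrive
  per site-year as Poisson (default mean 30 per unit relative
  abundance); residents survive onward, transients stay one season.
  Every adult present in an operated season — ringed or not — is caught
  with its sex/site catch probability; the first success is the first
  capture.  This makes the season's count of distinct caught adults a
  single Bernoulli(p) thinning of the present pool, which is exactly
  the premise of the weighted-count estimator; with it, the naive count
  ratio converges to `0.5 p_m / (0.5 p_m + 0.5 p_f)` and the weighted
  estimator back to the true proportion, as the tests verify.  One
  consequence: residents have several seasons of first-capture
  exposure, so the residency parameter estimated from the inserted
  occasion converges to P(resident | first capture), slightly above the
  arrival residency.  Recovery tests therefore compare the posterior
  against the realized resident fraction among caught birds, which the
  truth sidecar records.
* **Productivity responds to the realized composition.**  Juvenile
  counts are Poisson with
  `log mean = 2.75 + 0·SRc − 15·SRc² + 0.7·log(rel. abundance)`,
  where SRc is the *realized* proportion of males among adults actually
  present that season, centred at 0.5.  Using the smooth latent
  sex-ratio parameter instead would leave essentially no recoverable
  quadratic signal: demographic stochasticity in the standing
  population is real between-year sex-ratio variation, and it is what
  juvenile production can respond to.  The curvature −15 is anchored to
  the observed decline of juvenile catches from roughly 20 near parity
  to roughly 5 at a proportion of males near 0.8
  (`ln(5/20) / 0.3² ≈ −15`); the intercept 2.75 and abundance
  coefficient 0.7 match the reported productivity model.
* Census counts for the abundance surface are Poisson over the same
  surface with independent square and year log-normal increments
  (SDs 0.2 / 0.1).
* Ground truth (site parameters, year effects, realized compositions,
  per-individual latent fates) is written to sidecar files, never mixed
  into analysis inputs.

What the generator does **not** emulate: within-season multi-visit
structure (a single residency flag stands in for it), between-site
movement, observation heterogeneity among individuals, sexing errors,
and any non-stationarity in survival.  Passing tests therefore show the
estimators are correct for data that satisfy the model's assumptions —
they cannot show robustness to the violations real ringing data
contain.

## 5. Numerical notes and limitations

* Likelihood evaluations reject parameters outside (0,1) with −inf
  rather than clipping.  `chi` recursions are carried in probability
  space (all factors bounded away from overflow); transition-cell logs
  are only formed where the corresponding count is nonzero.
* The SD hyper-updates are Metropolis on the log scale with a floor at
  1e-8 to avoid underflow of the proposal; the funnel at sigma→0 is
  reachable but data with real year variation keep chains away from it.
* The weighted LMM profiles out scale, so rescaling all weights leaves
  point estimates invariant up to optimizer termination noise
  (≲ 1e-3 relative; asserted in tests).
* Split-chain diagnostics at test-scale chain lengths can flag
  marginal R-hat on the hyperparameters (`sigma_year` especially);
  headline survival and recapture parameters converge quickly because
  the sufficient-statistic likelihood is cheap and the blocked updates
  mix well.  Production-scale runs should use the default 60 000 / 20
  000 / 10 configuration.
* Problem sizes in the shipped tests (10–34 sites, 6–19 years, 2 000–
  6 000 iterations, 20 replicates) were chosen so the full suite
  completes on a single CPU in well under half an hour while leaving
  recovery margins that are not seed-dependent.
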