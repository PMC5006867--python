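# cesmark

Transient-corrected Bayesian survival estimation and detection-corrected
adult sex ratios for constant-effort ringing data, with the downstream
demographic regressions that link sex-ratio skew to local abundance and
productivity.

## The problem

Constant-effort mist-netting schemes catch and ring adult birds at fixed
sites with standardized effort, season after season. Two things make the
raw data treacherous for demography:

1. **Transients.** Many first captures are birds merely passing through.
   They are never available for recapture, so a standard
   Cormack–Jolly–Seber (CJS) model mistakes their departure for death
   and biases apparent survival downward.
2. **Sex-biased catchability.** Males and females are caught at
   different rates, so raw counts of caught adults misstate the adult
   sex ratio — exactly the quantity needed to study male-biased skews in
   small populations.

`cesmark` implements the joint fix. The CJS model is augmented with a
pseudo-occasion after each bird's first capture: "survival" over that
zero-length interval is the residency probability r (per sex), and
"detection" at it is the probability of a within-first-season recapture.
After the pseudo-occasion, survival is site- and sex-specific with a
shared annual random effect on the logit scale, and recapture is sex-
specific with a site random effect:

    logit(phi[site,sex,t]) = logit(phi[site,sex]) + eps[t],  eps[t] ~ N(0, sigma^2)
    logit(p[site,sex])     = logit(mu_p[sex]) + eta[site,sex]

The model is fitted by MCMC (adaptive Metropolis-within-Gibbs over an
extended m-array likelihood; uniform and Beta(1,1) priors, U(0,10) on
random-effect SDs). Per posterior draw, counts of caught adults are
detection-corrected as `count / p[sex,site]`, giving the adult sex
ratio (proportion of males)

    SR = (C_m/p_m) / (C_m/p_m + C_f/p_f)

with full uncertainty propagation. A sex difference in survival alone
implies a stationary sex ratio via
`males per female = phi_m(1-phi_f) / (phi_f(1-phi_m))`, which the
package converts to a proportion of males and correlates with the
count-based estimates across sites, draw by draw.

Downstream stages regress the sex-ratio estimates on year and
geography (weighted crossed-random-intercept LMM), fit a Poisson
spatial smooth to census counts to predict relative abundance, relate
site mean sex ratio to log abundance (WLS), and model juvenile catches
as a Poisson GLMM with a quadratic in the sex ratio that peaks at
parity. Because the original individual-level ringing records are not
publicly deposited, the package ships a synthetic-data generator that
emulates the study system (34 sites × 19 years, survival 0.48/0.42,
male-biased low-abundance sites, a +0.005/yr skew trend, ~18% unsexed
adults) with full ground truth, so every stage is tested by parameter
recovery. See `docs/methods.md` for the model details and design
decisions.

## Worked example

Run the whole chain — simulate, filter by the inclusion rules (≥5
years, ≥8 visits, ≥50 captures per sex), fit survival, derive sex
ratios, regress — on a 12-site × 10-year synthetic dataset:

```python
from cesmark.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="demo",
    simulation={"n_sites": 12, "n_years": 10},
    mcmc={"chains": 2, "iterations": 3000, "burnin": 1000, "thin": 5},
    n_census_squares=200,
    seeds={"simulate": 11, "fit": 12},
)
run_pipeline(cfg)
```

This takes ~10 s and writes CSVs under `demo/`. The posterior summary
(`demo/posterior/posterior_summary.csv`) contains, among others:

```
     parameter  mean    sd  q2.5  q97.5  rhat
    mu_p[male] 0.505 0.040 0.428  0.585 1.031
  mu_p[female] 0.390 0.061 0.279  0.520 1.054
       r[male] 0.702 0.034 0.638  0.766 1.010
p_within[male] 0.514 0.030 0.455  0.574 1.014
```

The generator's truth was p = 0.5/0.4 by sex and residency 0.7: the
sex-specific recapture means and the residency parameter are recovered
inside tight credible intervals. `demo/derived/sexratio_site_mean.csv`
holds the detection-corrected proportion of males per site with 95%
intervals, and `demo/regress/coefficients.csv` the stacked regression
table:

```
             stage          term  estimate     se
    sexratio_trend          year    0.0057 0.0037
abundance_sexratio log_abundance   -0.0213 0.0413
      productivity   sex_ratio^2   -1.3266 1.1734
      productivity log_abundance    0.8277 0.0852
```

The year trend (+0.0057/yr, truth +0.005) and the abundance effect on
productivity (+0.83, truth +0.7) are already well determined at this
small scale; the abundance–sex-ratio slope and the productivity
quadratic carry the expected signs but need the full 34-site design for
significance — at full scale the pipeline recovers the complete sign
pattern in essentially every replicate (see the acceptance tests).

The same stages are available from the shell:

```bash
cesmark simulate --out demo_data --seed 3
cesmark filter --data demo_data --out demo_filtered
cesmark fit-survival --data demo_filtered --out demo_post \
        --chains 2 --iters 3000 --burnin 1000 --thin 5 --seed 4
cesmark derive --posterior demo_post --data demo_filtered --out demo_derived
cesmark run --config pipeline.yaml   # everything, resumable, manifest.json
```

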