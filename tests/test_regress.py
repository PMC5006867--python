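"""Regression stages: recovery of generator truth, weighting contracts,
and a cross-check of the in-package mixed model against lme4."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

from cesmark.regress import (fit_abundance_sexratio, fit_abundance_surface,
                             fit_productivity, fit_sexratio_trend, report)
from cesmark.simulate import SimulationConfig, simulate_census_counts


def synth_trend_table(rng, n_sites=14, n_years=14, slope=0.006, site_sd=0.02,
                      noise=0.012):
    sites = pd.DataFrame({
        "site_id": [f"S{i:02d}" for i in range(n_sites)],
        "longitude": rng.uniform(-5, 1, n_sites),
        "latitude": rng.uniform(51, 58, n_sites),
    })
    rows = []
    for i, srow in sites.iterrows():
        a = rng.normal(0, site_sd)
        for yr in range(1994, 1994 + n_years):
            y = 0.5 + slope * (yr - 1994) + a + rng.normal(0, noise)
            rows.append((srow.site_id, yr, y, noise ** 2, 40))
    est = pd.DataFrame(rows, columns=["site_id", "year", "posterior_mean",
                                      "posterior_variance", "n_adults"])
    return est, sites


def test_trend_recovers_positive_year_slope(rng):
    est, sites = synth_trend_table(rng)
    res = fit_sexratio_trend(est, sites)
    assert res.coef("year") > 0
    assert abs(res.coef("year") - 0.006) < 3 * res.se("year")


def test_trend_null_simulation_recovers_zeros(rng):
    est, sites = synth_trend_table(rng, slope=0.0, site_sd=0.0)
    res = fit_sexratio_trend(est, sites)
    for term in ("year", "latitude", "longitude", "latitude:longitude"):
        assert abs(res.coef(term)) < 3 * res.se(term)


def test_trend_equal_weights_match_unweighted(rng):
    est, sites = synth_trend_table(rng, n_sites=8, n_years=8)
    res1 = fit_sexratio_trend(est, sites)
    est2 = est.assign(posterior_variance=est.posterior_variance * 7.0)
    res2 = fit_sexratio_trend(est2, sites)
    # uniform rescaling of all weights leaves point estimates unchanged
    # up to variance-optimizer termination noise
    np.testing.assert_allclose(res1.params["estimate"], res2.params["estimate"],
                               rtol=1e-3)


def test_trend_is_deterministic(rng):
    est, sites = synth_trend_table(rng, n_sites=6, n_years=6)
    a = fit_sexratio_trend(est, sites)
    b = fit_sexratio_trend(est, sites)
    np.testing.assert_array_equal(a.params["estimate"], b.params["estimate"])


def test_trend_needs_two_sites_and_years(rng):
    est, sites = synth_trend_table(rng, n_sites=1)
    with pytest.raises(ValueError, match="2 sites"):
        fit_sexratio_trend(est, sites)


def test_weighted_lmm_matches_lme4():
    """The in-package weighted crossed-intercept ML fit agrees with lme4."""
    rng = np.random.default_rng(42)
    est, sites = synth_trend_table(rng, n_sites=10, n_years=10, site_sd=0.03)
    res = fit_sexratio_trend(est, sites)
    df = est.merge(sites, on="site_id")
    df["year_c"] = df["year"] - df["year"].min()
    df["w"] = 1.0 / (df["posterior_variance"]
                     + (df["posterior_mean"] * df["n_adults"] + 1)
                     / (df["n_adults"] + 2)
                     * (1 - (df["posterior_mean"] * df["n_adults"] + 1)
                        / (df["n_adults"] + 2)) / df["n_adults"])
    import tempfile, os
    with tempfile.TemporaryDirectory() as d:
        csv = os.path.join(d, "d.csv")
        out = os.path.join(d, "fe.csv")
        df.to_csv(csv, index=False)
        rcode = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(posterior_mean ~ year_c + latitude + longitude +
                  latitude:longitude + (1|site_id) + (1|year),
                  data = d, weights = w, REML = FALSE,
                  control = lmerControl(check.conv.singular = "ignore"))
        write.csv(data.frame(term = names(fixef(m)), est = fixef(m)),
                  "{out}", row.names = FALSE)
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        fe = pd.read_csv(out).set_index("term")["est"]
    ours = res.params.set_index("term")["estimate"]
    assert ours["year"] == pytest.approx(fe["year_c"], abs=2e-4)
    assert ours["latitude"] == pytest.approx(fe["latitude"], abs=2e-3)
    assert ours["intercept"] == pytest.approx(fe["(Intercept)"], rel=0.02, abs=0.05)


# ---------------------------------------------------------------------
# Abundance surface
# ---------------------------------------------------------------------

@pytest.fixture(scope="module")
def census():
    cfg = SimulationConfig(seed=88)
    return simulate_census_counts(cfg, 400)


def test_surface_recovers_true_gradient(census):
    surf = fit_abundance_surface(census)
    sq = census.drop_duplicates("square_id")
    pred = surf.predict_log(sq["longitude"].to_numpy(), sq["latitude"].to_numpy(),
                            warn_extrapolation=False)
    r = np.corrcoef(pred, sq["true_log_abundance"].to_numpy())[0, 1]
    assert r > 0.9


def test_surface_constant_when_counts_flat():
    cfg = SimulationConfig(census_site_sd=0.0, census_year_sd=0.0,
                           abundance_surface=lambda lon, lat:
                               5.0 * np.ones_like(np.asarray(lon)), seed=89)
    census = simulate_census_counts(cfg, 300)
    surf = fit_abundance_surface(census)
    sq = census.drop_duplicates("square_id")
    pred = surf.predict_log(sq["longitude"].to_numpy(), sq["latitude"].to_numpy(),
                            warn_extrapolation=False)
    assert pred.std() < 0.05


def test_surface_doubling_counts_shifts_by_log2(census):
    # unpenalized so the Poisson log-link equivariance is exact
    doubled = census.assign(count=census["count"] * 2)
    s1 = fit_abundance_surface(census, alpha=0.0)
    s2 = fit_abundance_surface(doubled, alpha=0.0)
    lon = np.array([-3.0, -1.0, 0.5])
    lat = np.array([52.0, 54.5, 57.0])
    np.testing.assert_allclose(
        s2.predict_log(lon, lat, warn_extrapolation=False)
        - s1.predict_log(lon, lat, warn_extrapolation=False),
        np.log(2.0), atol=1e-6)


def test_surface_flags_extrapolation(census):
    surf = fit_abundance_surface(census)
    with pytest.warns(UserWarning, match="outside"):
        surf.predict_log(np.array([30.0]), np.array([70.0]))


def test_surface_needs_thirty_locations(census):
    small = census[census["square_id"].isin(census["square_id"].unique()[:10])]
    with pytest.raises(ValueError, match="30"):
        fit_abundance_surface(small)


# ---------------------------------------------------------------------
# Sex ratio vs abundance
# ---------------------------------------------------------------------

def synth_site_means(rng, n_sites=30, slope=-0.07, noise=0.015):
    la = rng.normal(0.0, 1.0, n_sites)
    sr = 0.55 + slope * la + rng.normal(0, noise, n_sites)
    return pd.DataFrame({
        "site_id": [f"S{i:02d}" for i in range(n_sites)],
        "posterior_mean": sr,
        "posterior_variance": np.full(n_sites, noise ** 2),
        "n_adults": np.full(n_sites, 400),
        "log_abundance": la,
    })


def test_abundance_sexratio_negative_slope_recovered(rng):
    sm_df = synth_site_means(rng)
    res = fit_abundance_sexratio(sm_df)
    assert res.coef("log_abundance") < 0
    assert abs(res.coef("log_abundance") + 0.07) < 3 * res.se("log_abundance")


def test_abundance_sexratio_null_slope(rng):
    sm_df = synth_site_means(rng, slope=0.0)
    res = fit_abundance_sexratio(sm_df)
    assert abs(res.coef("log_abundance")) < 3 * res.se("log_abundance")


def test_abundance_sexratio_outlier_with_tiny_weight_is_ignored(rng):
    sm_df = synth_site_means(rng, n_sites=20)
    outlier = pd.DataFrame({
        "site_id": ["OUT"], "posterior_mean": [0.99],
        "posterior_variance": [25.0], "n_adults": [2], "log_abundance": [0.0]})
    with_outlier = pd.concat([sm_df, outlier], ignore_index=True)
    a = fit_abundance_sexratio(sm_df)
    b = fit_abundance_sexratio(with_outlier)
    assert b.coef("log_abundance") == pytest.approx(a.coef("log_abundance"),
                                                    abs=0.2 * a.se("log_abundance"))


def test_abundance_sexratio_needs_three_sites(rng):
    with pytest.raises(ValueError, match="3 sites"):
        fit_abundance_sexratio(synth_site_means(rng, n_sites=2))


# ---------------------------------------------------------------------
# Productivity
# ---------------------------------------------------------------------

def synth_productivity(rng, n_sites=25, n_years=12, b1=0.0, b2=-15.0, b3=0.7):
    rows = []
    for i in range(n_sites):
        la = rng.normal(0, 1)
        for yr in range(n_years):
            sr = float(np.clip(rng.normal(0.55, 0.09), 0.2, 0.9))
            mu = np.exp(2.0 + b1 * (sr - 0.5) + b2 * (sr - 0.5) ** 2 + b3 * la)
            rows.append((f"S{i:02d}", yr, rng.poisson(mu), sr, la))
    return pd.DataFrame(rows, columns=["site_id", "year", "juveniles",
                                       "sex_ratio", "log_abundance"])


def test_productivity_recovers_quadratic_and_abundance(rng):
    table = synth_productivity(rng)
    res = fit_productivity(table)
    assert res.coef("sex_ratio^2") < 0
    assert abs(res.coef("sex_ratio^2") + 15.0) < 3 * res.se("sex_ratio^2")
    assert abs(res.coef("log_abundance") - 0.7) < 3 * res.se("log_abundance")


def test_productivity_null_sex_ratio_terms(rng):
    table = synth_productivity(rng, b1=0.0, b2=0.0)
    res = fit_productivity(table)
    assert abs(res.coef("sex_ratio")) < 3 * res.se("sex_ratio")
    assert abs(res.coef("sex_ratio^2")) < 3 * res.se("sex_ratio^2")


def test_productivity_mixed_and_glm_agree_on_focal_terms(rng):
    table = synth_productivity(rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixed = fit_productivity(table, method="mixed")
        glm = fit_productivity(table, method="glm")
    for term in ("sex_ratio^2", "log_abundance"):
        assert np.sign(mixed.coef(term)) == np.sign(glm.coef(term))
        assert mixed.coef(term) == pytest.approx(
            glm.coef(term), abs=3 * max(mixed.se(term), glm.se(term)))
    assert glm.extra["method"] == "glm"


def test_productivity_reports_overdispersion(rng):
    table = synth_productivity(rng)
    # inflate counts to create overdispersion
    table["juveniles"] = table["juveniles"] * rng.integers(1, 4, len(table))
    with pytest.warns(UserWarning, match="overdispersion"):
        res = fit_productivity(table)
    assert res.extra["overdispersion"] > 2.0


def test_report_stacks_stages(rng):
    est, sites = synth_trend_table(rng, n_sites=6, n_years=6)
    res = fit_sexratio_trend(est, sites)
    table = report([res])
    assert set(table["stage"]) == {"sexratio_trend"}
    assert {"term", "estimate", "se"} <= set(table.columns)
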