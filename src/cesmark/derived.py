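"""Posterior-derived quantities: detection-corrected sex ratios,
survival-implied expected sex ratios, and posterior correlations.

Raw counts of caught adults confound the true sex ratio with sex
differences in catchability.  Dividing each count by the posterior
recapture probability of that sex at that site gives a detection-
weighted count,

    weighted_count = count / p[sex, site],

and the adult sex ratio (proportion of males) follows per MCMC draw as
weighted male count / (weighted male + weighted female count), so the
uncertainty in p propagates into the sex-ratio estimate.

A sex difference in apparent survival alone implies a stationary sex
ratio: with equal recruitment of the sexes, the standing number of males
per female is phi_m (1 - phi_f) / (phi_f (1 - phi_m)), converted here to
a proportion of males.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FEMALE, MALE, CesDataset
from .survival import SurvivalPosterior


def weighted_count(count: float, p: float) -> float:
    """Detection-corrected count: ``count / p``; requires p in (0, 1]."""
    if not 0 < p <= 1:
        raise ValueError(f"recapture probability must lie in (0, 1], got {p}")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / p


def expected_sex_ratio(phi_male, phi_female):
    """Proportion of males implied by a sex difference in survival.

    Males per female = phi_m (1 - phi_f) / (phi_f (1 - phi_m)); the
    returned value is that ratio converted to males / (males + females).
    Accepts scalars or arrays; survival must lie strictly inside (0, 1).
    """
    phi_m = np.asarray(phi_male, dtype=float)
    phi_f = np.asarray(phi_female, dtype=float)
    if np.any(phi_m <= 0) or np.any(phi_m >= 1) or np.any(phi_f <= 0) or np.any(phi_f >= 1):
        raise ValueError("survival probabilities must lie strictly inside (0, 1)")
    males_per_female = (phi_m * (1.0 - phi_f)) / (phi_f * (1.0 - phi_m))
    out = males_per_female / (1.0 + males_per_female)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class SexRatioEstimate:
    site_id: str
    year: int | str          # calendar year, or "all" for the site mean
    posterior_mean: float
    posterior_variance: float
    cri_low: float
    cri_high: float

    def __post_init__(self):
        if not (0 <= self.cri_low <= self.posterior_mean <= self.cri_high <= 1):
            raise ValueError(f"inconsistent sex-ratio interval for "
                             f"{self.site_id}/{self.year}")


@dataclass
class SexRatioResult:
    """Per-draw and summarized sex ratios.

    ``site_year`` / ``site_mean`` are tidy summary tables; ``draws_site``
    holds the per-draw site means (n_draws, n_sites) for downstream
    posterior correlations.
    """

    site_year: pd.DataFrame
    site_mean: pd.DataFrame
    draws_site: np.ndarray
    sites: list[str]

    def estimates(self) -> list[SexRatioEstimate]:
        out = []
        for r in self.site_year.itertuples():
            out.append(SexRatioEstimate(r.site_id, int(r.year), r.posterior_mean,
                                        r.posterior_variance, r.cri_low, r.cri_high))
        for r in self.site_mean.itertuples():
            out.append(SexRatioEstimate(r.site_id, "all", r.posterior_mean,
                                        r.posterior_variance, r.cri_low, r.cri_high))
        return out


def _summarize(draws: np.ndarray) -> tuple[float, float, float, float]:
    return (float(np.mean(draws)), float(np.var(draws, ddof=1)) if len(draws) > 1 else 0.0,
            float(np.quantile(draws, 0.025)), float(np.quantile(draws, 0.975)))


def sex_ratio_draws(dataset: CesDataset, posterior: SurvivalPosterior) -> SexRatioResult:
    """Detection-weighted sex ratios per site-year and site, over all draws.

    For each draw the site-year sex ratio is
    ``(C_m / p_m) / (C_m / p_m + C_f / p_f)`` with C the count of
    distinct sexed adults caught; the site mean is the average of that
    site's annual ratios within the draw.  Site-years with no sexed
    adults of either sex yield no estimate.
    """
    counts = dataset.adult_counts()
    counts = counts[counts["sex"].isin([MALE, FEMALE])]
    table = counts.pivot_table(index=["site_id", "year"], columns="sex",
                               values="count", fill_value=0)
    for sex in (MALE, FEMALE):
        if sex not in table.columns:
            table[sex] = 0

    site_index = {sid: i for i, sid in enumerate(posterior.sites)}
    n = posterior.n_draws

    sy_rows = []
    per_site_draws: dict[str, list[np.ndarray]] = {sid: [] for sid in posterior.sites}
    site_totals: dict[str, int] = {sid: 0 for sid in posterior.sites}
    for (sid, year), row in table.iterrows():
        cm, cf = float(row[MALE]), float(row[FEMALE])
        if cm + cf == 0 or sid not in site_index:
            continue
        s = site_index[sid]
        wm = cm / posterior.p[:, s, 0]
        wf = cf / posterior.p[:, s, 1]
        sr = wm / (wm + wf)
        mean, var, lo, hi = _summarize(sr)
        sy_rows.append((sid, int(year), mean, var, lo, hi, int(cm + cf)))
        per_site_draws[sid].append(sr)
        site_totals[sid] += int(cm + cf)

    site_year = pd.DataFrame(sy_rows, columns=["site_id", "year", "posterior_mean",
                                               "posterior_variance", "cri_low",
                                               "cri_high", "n_adults"])

    sm_rows = []
    draws_site = np.full((n, len(posterior.sites)), np.nan)
    for sid, srs in per_site_draws.items():
        if not srs:
            continue
        site_draws = np.mean(np.column_stack(srs), axis=1)
        draws_site[:, site_index[sid]] = site_draws
        mean, var, lo, hi = _summarize(site_draws)
        sm_rows.append((sid, mean, var, lo, hi, site_totals[sid]))
    site_mean = pd.DataFrame(sm_rows, columns=["site_id", "posterior_mean",
                                               "posterior_variance", "cri_low",
                                               "cri_high", "n_adults"])
    return SexRatioResult(site_year, site_mean, draws_site, list(posterior.sites))


@dataclass(frozen=True)
class CorrelationSummary:
    mean_r: float
    cri_low: float
    cri_high: float
    prob_positive: float
    n_dropped: int = 0

    def __post_init__(self):
        if not -1 <= self.mean_r <= 1:
            raise ValueError("mean correlation outside [-1, 1]")
        if not 0 <= self.prob_positive <= 1:
            raise ValueError("prob_positive outside [0, 1]")


def posterior_correlation(x_draws: np.ndarray, y_draws: np.ndarray,
                          drop_site: int | None = None) -> CorrelationSummary:
    """Pearson correlation of two per-site quantities, draw by draw.

    ``x_draws`` and ``y_draws`` have shape (n_draws, n_sites) over a
    matched site set.  ``drop_site`` removes one site (column) before
    computing, for leave-one-site-out sensitivity.  Draws where either
    vector has zero variance are dropped and counted.
    """
    x = np.asarray(x_draws, dtype=float)
    y = np.asarray(y_draws, dtype=float)
    if x.shape != y.shape:
        raise ValueError("draw matrices must have matching shapes")
    if drop_site is not None:
        keep = np.arange(x.shape[1]) != drop_site
        x, y = x[:, keep], y[:, keep]
    if x.shape[1] < 3:
        raise ValueError("need at least 3 sites for a correlation")

    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt(np.sum(xc ** 2, axis=1))
    sy = np.sqrt(np.sum(yc ** 2, axis=1))
    valid = (sx > 0) & (sy > 0)
    n_dropped = int(np.sum(~valid))
    if not np.any(valid):
        raise ValueError("all draws have zero variance across sites")
    r = np.sum(xc[valid] * yc[valid], axis=1) / (sx[valid] * sy[valid])
    return CorrelationSummary(
        mean_r=float(np.mean(r)),
        cri_low=float(np.quantile(r, 0.025)),
        cri_high=float(np.quantile(r, 0.975)),
        prob_positive=float(np.mean(r > 0)),
        n_dropped=n_dropped,
    )


def survival_sex_ratio_correlations(posterior: SurvivalPosterior,
                                    sex_ratios: SexRatioResult,
                                    drop_site: int | None = None
                                    ) -> dict[str, CorrelationSummary]:
    """The two headline posterior correlations.

    ``male_female_survival``: correlation of male vs female apparent
    survival across sites per draw.  ``expected_vs_estimated``:
    correlation of the survival-implied expected sex ratio with the
    detection-weighted estimated site mean sex ratio.
    """
    phi_m = posterior.phi[:, :, 0]
    phi_f = posterior.phi[:, :, 1]
    out = {"male_female_survival": posterior_correlation(phi_m, phi_f, drop_site)}
    expected = expected_sex_ratio(phi_m, phi_f)
    estimated = sex_ratios.draws_site
    ok = ~np.any(np.isnan(estimated), axis=0)
    if drop_site is not None:
        ok = ok & (np.arange(estimated.shape[1]) != drop_site)
    out["expected_vs_estimated"] = posterior_correlation(
        expected[:, ok], estimated[:, ok])
    return out
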