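"""Transient-corrected Cormack–Jolly–Seber survival model.

Apparent survival of adults at constant-effort ringing sites is biased
low by transients: birds caught once while passing through, never
available for recapture.  The model corrects for this by inserting a
pseudo-occasion immediately after each bird's first capture.  "Survival"
over the zero-length first interval is the residency probability r_sex;
"detection" at the pseudo-occasion is the probability p_within_sex of a
within-first-season recapture.  A transient is absorbed at the
pseudo-interval and can never be caught again.  After the pseudo-
occasion the model is a standard CJS chain with

    logit(phi[site, sex, t]) = logit(phi[site, sex]) + eps[t]
    logit(p[site, sex])      = logit(mu_p[sex]) + eta[site, sex]

where eps is a shared annual random effect (N(0, sigma_year^2)) and eta
a sex-specific site random effect on recapture (N(0, sigma_p[sex]^2)).
Priors: U(0,1) on each phi[site, sex]; Beta(1,1) on mu_p, r, p_within;
U(0,10) on the random-effect standard deviations.

The likelihood is conditional on first capture.  It is evaluated over
sufficient statistics (an m-array extended with residency cells), which
is algebraically identical to the per-individual form
(:func:`history_loglik`); the test-suite verifies the equivalence and
checks both against brute-force enumeration over latent
resident/alive sequences.

Sampling uses an adaptive Metropolis-within-Gibbs scheme: joint
random-walk updates of (logit phi, eta) per site-sex cell, a joint
update of the year-effect vector, a likelihood-invariant shift move
exchanging mass between eps and the phi intercepts, per-sex joint
updates of (mu_p, r, p_within), and prior-conditional updates of the
hyper-SDs.  Proposal scales adapt during burn-in only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import FEMALE, MALE, SEXES, CaptureHistory, CesDataset

_SEX_INDEX = {MALE: 0, FEMALE: 1}


# ---------------------------------------------------------------------
# History augmentation
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentedHistory:
    """An annual capture history with the residency pseudo-occasion inserted.

    ``detections[0]`` is the first capture (always 1), ``detections[1]``
    the pseudo-occasion (the within-first-season recapture flag), and the
    remainder the annual occasions after first capture.
    """

    detections: tuple[int, ...]
    #: occasion labels, e.g. ('1994', 'residency', '1995', ...)
    occasions: tuple[str, ...]

    def __str__(self) -> str:  # e.g. '11|010'
        d = "".join(str(v) for v in self.detections)
        return d[:2] + "|" + d[2:]


def augment_history(h: CaptureHistory, years: Sequence[int]) -> AugmentedHistory:
    """Insert the residency pseudo-occasion after the first capture.

    ``years`` are the site's operating years; occasions before the first
    capture are dropped (the model conditions on first capture).
    """
    years = sorted(int(y) for y in years)
    if h.first_year not in years:
        raise ValueError(f"first_year {h.first_year} not among operating years")
    later = [y for y in years if y > h.first_year]
    det = [1, int(h.within_first_season_recapture)]
    det += [int(y in h.detection_years) for y in later]
    occ = [str(h.first_year), "residency"] + [str(y) for y in later]
    return AugmentedHistory(tuple(det), tuple(occ))


# ---------------------------------------------------------------------
# Parameters and sufficient statistics
# ---------------------------------------------------------------------

@dataclass
class ModelParams:
    """A point in parameter space (probability scale).

    phi, p have shape (n_sites, 2) [male, female]; eps has shape
    (n_years - 1,); r and p_within have shape (2,).
    """

    phi: np.ndarray
    eps: np.ndarray
    p: np.ndarray
    r: np.ndarray
    p_within: np.ndarray

    def phi_year(self) -> np.ndarray:
        """Year-specific survival, shape (n_sites, 2, n_years-1)."""
        return expit(logit(self.phi)[:, :, None] + self.eps[None, None, :])


@dataclass
class ModelSpec:
    """Prior and structure configuration (defaults mirror the fitted model)."""

    prior_sd_upper: float = 10.0          # U(0, upper) on random-effect SDs
    sex_specific_site_sd: bool = True     # separate sigma_p per sex


@dataclass
class McmcConfig:
    chains: int = 2
    iterations: int = 60_000
    burnin: int = 20_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.burnin >= self.iterations:
            raise ValueError("burnin must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be positive")


@dataclass
class SufficientStats:
    """Extended m-array summary of a dataset.

    Occasions are indexed on a global calendar grid ``years``.  ``op``
    marks years each site operated.  ``M[s, x, i, j]`` counts observed
    transitions (detection at occasion i, next detection at j);
    ``z[s, x, i]`` counts confirmed residents last detected at i;
    ``u0[s, x, f]`` counts birds caught only once, not recaught within
    the first season, by first occasion; ``n_w1`` / ``n_w0_seen`` count
    residency outcomes among first captures.
    """

    sites: list[str]
    years: np.ndarray
    op: np.ndarray
    M: np.ndarray
    z: np.ndarray
    u0: np.ndarray
    n_w1: np.ndarray
    n_w0_seen: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_years(self) -> int:
        return len(self.years)


def prepare_stats(dataset: CesDataset) -> SufficientStats:
    sites = sorted(dataset.sites)
    all_years = sorted({y for s in dataset.sites.values() for y in s.years_operated})
    years = np.arange(all_years[0], all_years[-1] + 1)
    yidx = {int(y): i for i, y in enumerate(years)}
    S, T = len(sites), len(years)
    sidx = {s: i for i, s in enumerate(sites)}

    op = np.zeros((S, T), dtype=bool)
    for s in sites:
        for y in dataset.sites[s].years_operated:
            op[sidx[s], yidx[y]] = True

    M = np.zeros((S, 2, T, T))
    z = np.zeros((S, 2, T))
    u0 = np.zeros((S, 2, T))
    n_w1 = np.zeros((S, 2))
    n_w0_seen = np.zeros((S, 2))

    for h in dataset.histories:
        if h.sex not in _SEX_INDEX:
            raise ValueError(f"individual {h.individual_id} is unsexed; "
                             "drop unsexed birds before fitting")
        s, x = sidx[h.site_id], _SEX_INDEX[h.sex]
        det = sorted(yidx[y] for y in h.detection_years)
        f = det[0]
        w = bool(h.within_first_season_recapture)
        if w:
            n_w1[s, x] += 1
        if len(det) == 1 and not w:
            u0[s, x, f] += 1
            continue
        if not w:
            n_w0_seen[s, x] += 1
        for i, j in zip(det[:-1], det[1:]):
            M[s, x, i, j] += 1
        z[s, x, det[-1]] += 1
    return SufficientStats(sites, years, op, M, z, u0, n_w1, n_w0_seen)


# ---------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------

def _cell_loglik(stats: SufficientStats, lphi: np.ndarray, eps: np.ndarray,
                 p: np.ndarray, r: np.ndarray, p_within: np.ndarray,
                 cells_s: np.ndarray, cells_x: np.ndarray) -> np.ndarray:
    """Log-likelihood per (site, sex) cell for the selected cells.

    ``lphi`` and ``p`` are (S, 2); ``r``/``p_within`` are (2,).
    """
    T = stats.n_years
    lphi_c = lphi[cells_s, cells_x]                       # (C,)
    p_c = p[cells_s, cells_x]
    r_c = r[cells_x]
    pw_c = p_within[cells_x]
    op_c = stats.op[cells_s]                              # (C, T)

    phi_t = expit(lphi_c[:, None] + eps[None, :])         # (C, T-1)
    log_phi = np.log(phi_t)
    # cumulative survival: cphi[:, k] = sum_{t<k} log phi_t, k = 0..T-1
    cphi = np.concatenate([np.zeros((len(lphi_c), 1)), np.cumsum(log_phi, axis=1)],
                          axis=1)
    # miss probability per occasion (0 where site closed -> certain miss of p)
    q = np.log1p(-p_c[:, None] * op_c)                    # (C, T)
    cq = np.concatenate([np.zeros((len(p_c), 1)), np.cumsum(q, axis=1)], axis=1)

    # chi[i]: P(never detected after occasion i | alive resident at i)
    chi = np.ones((len(p_c), T))
    for i in range(T - 2, -1, -1):
        chi[:, i] = (1.0 - phi_t[:, i]) + phi_t[:, i] * np.exp(q[:, i + 1]) * chi[:, i + 1]

    # log nu[c, i, j] = log P(next detection at j | detected at i, resident)
    #                 = sum_{t=i..j-1} log phi_t + sum_{k=i+1..j-1} log(1 - p op_k)
    #                   + log p
    idx = np.arange(T)
    log_nu = (cphi[:, None, idx] - cphi[:, idx, None]
              + (cq[:, None, idx] - cq[:, idx + 1, None])
              + np.log(p_c)[:, None, None])                  # axes [cell, i, j]

    M_c = stats.M[cells_s, cells_x]                       # (C, T, T)
    z_c = stats.z[cells_s, cells_x]                       # (C, T)
    u0_c = stats.u0[cells_s, cells_x]

    ll = np.einsum("cij,cij->c", M_c, np.where(M_c > 0, log_nu, 0.0))
    ll += np.einsum("ci,ci->c", z_c, np.log(chi))
    mix = (1.0 - r_c)[:, None] + (r_c * (1.0 - pw_c))[:, None] * chi
    ll += np.einsum("ci,ci->c", u0_c, np.log(mix))
    ll += stats.n_w1[cells_s, cells_x] * np.log(r_c * pw_c)
    ll += stats.n_w0_seen[cells_s, cells_x] * np.log(r_c * (1.0 - pw_c))
    return ll


def _all_cells(stats: SufficientStats) -> tuple[np.ndarray, np.ndarray]:
    s, x = np.meshgrid(np.arange(stats.n_sites), np.arange(2), indexing="ij")
    return s.ravel(), x.ravel()


def loglik(dataset_or_stats, params: ModelParams) -> float:
    """Total log-likelihood of the dataset at a parameter point.

    Accepts a :class:`CesDataset` or precomputed :class:`SufficientStats`.
    Returns ``-inf`` for parameters outside their support.
    """
    stats = (dataset_or_stats if isinstance(dataset_or_stats, SufficientStats)
             else prepare_stats(dataset_or_stats))
    phi = np.asarray(params.phi, dtype=float)
    p = np.asarray(params.p, dtype=float)
    r = np.asarray(params.r, dtype=float)
    pw = np.asarray(params.p_within, dtype=float)
    eps = np.asarray(params.eps, dtype=float)
    for arr in (phi, p, r, pw):
        if np.any(arr <= 0) or np.any(arr >= 1):
            return -np.inf
    if not np.all(np.isfinite(eps)):
        return -np.inf
    cs, cx = _all_cells(stats)
    ll = _cell_loglik(stats, logit(phi), eps, p, r, pw, cs, cx)
    total = float(ll.sum())
    if not np.isfinite(total):
        return -np.inf
    return total


def history_loglik(h: CaptureHistory, years: Sequence[int], phi_t: np.ndarray,
                   p: float, r: float, p_within: float,
                   op: np.ndarray | None = None) -> float:
    """Per-individual reference log-likelihood (conditional on first capture).

    ``years`` is the global calendar grid, ``phi_t[t]`` the survival
    probability over interval ``years[t] -> years[t+1]``, ``op[t]``
    whether the site operated in ``years[t]`` (default: all years).
    Algebraically identical to the sufficient-statistic form; kept as an
    independently readable reference implementation.
    """
    years = list(years)
    T = len(years)
    if op is None:
        op = np.ones(T, dtype=bool)
    yidx = {int(y): i for i, y in enumerate(years)}
    det = sorted(yidx[y] for y in h.detection_years)
    f = det[0]
    w = bool(h.within_first_season_recapture)

    chi = np.ones(T)
    for i in range(T - 2, -1, -1):
        chi[i] = (1 - phi_t[i]) + phi_t[i] * (1 - p * op[i + 1]) * chi[i + 1]

    if not w and len(det) == 1:
        return float(np.log((1 - r) + r * (1 - p_within) * chi[f]))

    ll = np.log(r) + (np.log(p_within) if w else np.log1p(-p_within))
    for i, j in zip(det[:-1], det[1:]):
        seg = np.sum(np.log(phi_t[i:j]))
        seg += np.sum(np.log1p(-p * op[i + 1:j]))
        seg += np.log(p)
        ll += seg
    ll += np.log(chi[det[-1]])
    return float(ll)


# ---------------------------------------------------------------------
# Posterior container
# ---------------------------------------------------------------------

@dataclass
class SurvivalPosterior:
    """Posterior draws from the transient-CJS model.

    Arrays are stacked over chains: the first axis has length
    ``chains * draws_per_chain``; ``chain_id`` records provenance.
    """

    sites: list[str]
    years: np.ndarray
    chain_id: np.ndarray
    phi: np.ndarray        # (n, S, 2) interval-mean survival
    eps: np.ndarray        # (n, T-1)
    sigma_year: np.ndarray
    p: np.ndarray          # (n, S, 2)
    mu_p: np.ndarray       # (n, 2)
    sigma_p: np.ndarray    # (n, 2)
    r: np.ndarray          # (n, 2)
    p_within: np.ndarray   # (n, 2)
    config: McmcConfig = field(default_factory=McmcConfig)

    @property
    def n_draws(self) -> int:
        return len(self.chain_id)

    def _named(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for s, sid in enumerate(self.sites):
            for x, sex in enumerate(SEXES):
                out[f"phi[{sid},{sex}]"] = self.phi[:, s, x]
                out[f"p[{sid},{sex}]"] = self.p[:, s, x]
        for t in range(self.eps.shape[1]):
            out[f"eps[{int(self.years[t])}]"] = self.eps[:, t]
        out["sigma_year"] = self.sigma_year
        for x, sex in enumerate(SEXES):
            out[f"mu_p[{sex}]"] = self.mu_p[:, x]
            out[f"sigma_p[{sex}]"] = self.sigma_p[:, x]
            out[f"r[{sex}]"] = self.r[:, x]
            out[f"p_within[{sex}]"] = self.p_within[:, x]
        return out

    def summary(self) -> pd.DataFrame:
        """Posterior mean/sd/CRI plus split-chain R-hat and bulk ESS."""
        import arviz as az

        n_chains = len(np.unique(self.chain_id))
        rows = []
        for name, v in self._named().items():
            per_chain = v.reshape(n_chains, -1)
            if per_chain.shape[1] >= 4:
                ds = az.convert_to_dataset(per_chain)
                rhat = float(az.rhat(ds)["x"].values)
                ess = float(az.ess(ds)["x"].values)
            else:
                rhat = ess = np.nan
            rows.append((name, v.mean(), v.std(ddof=1),
                         np.quantile(v, 0.025), np.quantile(v, 0.975), rhat, ess))
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd",
                                           "q2.5", "q97.5", "rhat", "ess_bulk"])

    def convergence_warnings(self, rhat_threshold: float = 1.1) -> list[str]:
        summ = self.summary()
        bad = summ[summ["rhat"] > rhat_threshold]
        return [f"{r.parameter}: rhat={r.rhat:.3f}" for r in bad.itertuples()]

    def site_average_phi(self) -> np.ndarray:
        """Across-site mean survival per draw, shape (n, 2)."""
        return self.phi.mean(axis=1)

    # -- persistence ---------------------------------------------------
    def to_tidy(self) -> pd.DataFrame:
        named = self._named()
        n = self.n_draws
        frames = []
        for name, v in named.items():
            frames.append(pd.DataFrame({
                "chain": self.chain_id, "draw": np.arange(n),
                "parameter": name, "value": v}))
        return pd.concat(frames, ignore_index=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_tidy().to_csv(outdir / "posterior_draws.csv", index=False)
        self.summary().to_csv(outdir / "posterior_summary.csv", index=False)
        meta = pd.DataFrame({"site_id": self.sites})
        meta.to_csv(outdir / "posterior_sites.csv", index=False)
        pd.DataFrame({"year": self.years}).to_csv(outdir / "posterior_years.csv",
                                                  index=False)

    @classmethod
    def read(cls, indir: str | Path) -> "SurvivalPosterior":
        indir = Path(indir)
        tidy = pd.read_csv(indir / "posterior_draws.csv")
        sites = pd.read_csv(indir / "posterior_sites.csv", dtype={"site_id": str}
                            )["site_id"].tolist()
        years = pd.read_csv(indir / "posterior_years.csv")["year"].to_numpy()
        wide = tidy.pivot_table(index=["chain", "draw"], columns="parameter",
                                values="value", sort=False)
        wide = wide.sort_index()
        n = len(wide)
        chain_id = wide.index.get_level_values("chain").to_numpy()
        S, T = len(sites), len(years)

        def by_site_sex(fmt):
            out = np.empty((n, S, 2))
            for s, sid in enumerate(sites):
                for x, sex in enumerate(SEXES):
                    out[:, s, x] = wide[fmt.format(sid=sid, sex=sex)].to_numpy()
            return out

        def by_sex(fmt):
            out = np.empty((n, 2))
            for x, sex in enumerate(SEXES):
                out[:, x] = wide[fmt.format(sex=sex)].to_numpy()
            return out

        eps = np.empty((n, T - 1))
        for t in range(T - 1):
            eps[:, t] = wide[f"eps[{int(years[t])}]"].to_numpy()

        return cls(
            sites=sites, years=years, chain_id=chain_id,
            phi=by_site_sex("phi[{sid},{sex}]"),
            eps=eps,
            sigma_year=wide["sigma_year"].to_numpy(),
            p=by_site_sex("p[{sid},{sex}]"),
            mu_p=by_sex("mu_p[{sex}]"),
            sigma_p=by_sex("sigma_p[{sex}]"),
            r=by_sex("r[{sex}]"),
            p_within=by_sex("p_within[{sex}]"),
        )


# ---------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------

class _AdaptiveScale:
    """Robbins–Monro adaptation of (a vector of) log proposal scales
    during burn-in."""

    def __init__(self, scale: float, target: float, shape=()):
        self.log_scale = np.full(shape, np.log(scale))
        self.target = target
        self.n = 0

    def update(self, accepted) -> None:
        self.n += 1
        self.log_scale += (np.asarray(accepted, float) - self.target) \
            / max(1.0, self.n ** 0.6)
        self.log_scale = np.clip(self.log_scale, -10.0, 3.0)

    @property
    def scale(self):
        return np.exp(self.log_scale)


def _log_jacobian_logit(z: np.ndarray) -> np.ndarray:
    """log |d expit(z) / dz| — the U(0,1)-prior density on the logit scale."""
    return z - 2.0 * np.logaddexp(0.0, z)


def fit(dataset: CesDataset | SufficientStats, spec: ModelSpec | None = None,
        mcmc: McmcConfig | None = None, progress: bool = False) -> SurvivalPosterior:
    """Fit the transient-CJS model by adaptive Metropolis-within-Gibbs MCMC.

    The default MCMC configuration runs two chains of 60 000 iterations,
    discards 20 000 as burn-in and keeps every 10th draw; pass a smaller
    :class:`McmcConfig` for test-scale runs.  Non-convergence (split
    R-hat above 1.1) is reported via ``warnings``, never silently.
    """
    import warnings as _warnings

    spec = spec or ModelSpec()
    mcmc = mcmc or McmcConfig()
    stats = (dataset if isinstance(dataset, SufficientStats)
             else prepare_stats(dataset))
    S, T = stats.n_sites, stats.n_years
    sd_upper = spec.prior_sd_upper

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    keep = (mcmc.iterations - mcmc.burnin) // mcmc.thin
    store = {k: [] for k in ("phi", "eps", "sigma_year", "p", "mu_p",
                             "sigma_p", "r", "p_within", "chain")}

    cells_s, cells_x = _all_cells(stats)

    for chain in range(mcmc.chains):
        rng = np.random.default_rng(seeds[chain])

        # state (transformed scale)
        lphi = logit(0.45) + 0.2 * rng.standard_normal((S, 2))
        eps = np.zeros(T - 1)
        sig_y = 0.3 * np.exp(0.3 * rng.standard_normal())
        lmu_p = logit(0.45) + 0.2 * rng.standard_normal(2)
        eta = np.zeros((S, 2))
        sig_p = 0.3 * np.exp(0.3 * rng.standard_normal(2))
        lr = logit(0.7) + 0.2 * rng.standard_normal(2)
        lpw = logit(0.4) + 0.2 * rng.standard_normal(2)

        def p_mat(lmu, e):
            return expit(lmu[None, :] + e)

        cell_ll = _cell_loglik(stats, lphi, eps, p_mat(lmu_p, eta),
                               expit(lr), expit(lpw), cells_s, cells_x
                               ).reshape(S, 2)

        sc_cell = _AdaptiveScale(0.3, 0.35, shape=(S, 2))
        sc_eps = _AdaptiveScale(0.05, 0.25)
        sc_shift = _AdaptiveScale(0.1, 0.35)
        sc_sex = _AdaptiveScale(0.15, 0.3, shape=(2,))
        sc_sig_y = _AdaptiveScale(0.5, 0.4)
        sc_sig_p = _AdaptiveScale(0.5, 0.4, shape=(2,))

        for it in range(mcmc.iterations):
            adapting = it < mcmc.burnin

            # --- (logit phi, eta) for every site-sex cell --------------
            # cell likelihoods factorize given (eps, mu_p, r, p_within),
            # so all cells are proposed at once and accepted independently
            d = sc_cell.scale[..., None] * rng.standard_normal((S, 2, 2))
            lphi_new = lphi + d[..., 0]
            eta_new = eta + d[..., 1]
            ll_new = _cell_loglik(stats, lphi_new, eps, p_mat(lmu_p, eta_new),
                                  expit(lr), expit(lpw), cells_s, cells_x
                                  ).reshape(S, 2)
            dprior = (_log_jacobian_logit(lphi_new) - _log_jacobian_logit(lphi)
                      - 0.5 * (eta_new ** 2 - eta ** 2) / sig_p[None, :] ** 2)
            accept = np.log(rng.random((S, 2))) < ll_new - cell_ll + dprior
            lphi = np.where(accept, lphi_new, lphi)
            eta = np.where(accept, eta_new, eta)
            cell_ll = np.where(accept, ll_new, cell_ll)
            if adapting:
                sc_cell.update(accept)

            # --- year-effect vector ------------------------------------
            if T > 1:
                eps_new = eps + sc_eps.scale * rng.standard_normal(T - 1)
                ll_new = _cell_loglik(stats, lphi, eps_new, p_mat(lmu_p, eta),
                                      expit(lr), expit(lpw), cells_s, cells_x
                                      ).reshape(S, 2)
                dprior = -0.5 * (np.sum(eps_new ** 2) - np.sum(eps ** 2)) / sig_y ** 2
                loga = ll_new.sum() - cell_ll.sum() + dprior
                if np.log(rng.random()) < loga:
                    eps, cell_ll = eps_new, ll_new
                    acc = 1.0
                else:
                    acc = 0.0
                if adapting:
                    sc_eps.update(acc)

                # shift move: likelihood-invariant exchange between eps
                # and the survival intercepts
                delta = sc_shift.scale * rng.standard_normal()
                lphi_new = lphi - delta
                eps_new = eps + delta
                dprior = (np.sum(_log_jacobian_logit(lphi_new))
                          - np.sum(_log_jacobian_logit(lphi))
                          - 0.5 * (np.sum(eps_new ** 2) - np.sum(eps ** 2)) / sig_y ** 2)
                if np.log(rng.random()) < dprior:
                    lphi, eps = lphi_new, eps_new
                    acc = 1.0
                else:
                    acc = 0.0
                if adapting:
                    sc_shift.update(acc)

            # --- per-sex (mu_p, r, p_within) ---------------------------
            # sexes share no parameters here, so both proposals are
            # evaluated in one pass and accepted independently
            d = sc_sex.scale[:, None] * rng.standard_normal((2, 3))
            lmu_new = lmu_p + d[:, 0]
            lr_new = lr + d[:, 1]
            lpw_new = lpw + d[:, 2]
            ll_new = _cell_loglik(stats, lphi, eps, p_mat(lmu_new, eta),
                                  expit(lr_new), expit(lpw_new),
                                  cells_s, cells_x).reshape(S, 2)
            dprior = (_log_jacobian_logit(lmu_new) - _log_jacobian_logit(lmu_p)
                      + _log_jacobian_logit(lr_new) - _log_jacobian_logit(lr)
                      + _log_jacobian_logit(lpw_new) - _log_jacobian_logit(lpw))
            loga = ll_new.sum(axis=0) - cell_ll.sum(axis=0) + dprior
            accept = np.log(rng.random(2)) < loga
            lmu_p = np.where(accept, lmu_new, lmu_p)
            lr = np.where(accept, lr_new, lr)
            lpw = np.where(accept, lpw_new, lpw)
            cell_ll = np.where(accept[None, :], ll_new, cell_ll)
            if adapting:
                sc_sex.update(accept)

            # --- hyper-SDs (prior-conditional, no likelihood) ----------
            sig_y, a = _update_sd(sig_y, eps, sd_upper, float(sc_sig_y.scale), rng)
            if adapting:
                sc_sig_y.update(a)
            acc_sd = np.zeros(2)
            for x in range(2):
                sig_p[x], acc_sd[x] = _update_sd(sig_p[x], eta[:, x], sd_upper,
                                                 float(sc_sig_p.scale[x]), rng)
            if adapting:
                sc_sig_p.update(acc_sd)

            if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0:
                store["phi"].append(expit(lphi))
                store["eps"].append(eps.copy())
                store["sigma_year"].append(sig_y)
                store["p"].append(p_mat(lmu_p, eta))
                store["mu_p"].append(expit(lmu_p))
                store["sigma_p"].append(sig_p.copy())
                store["r"].append(expit(lr))
                store["p_within"].append(expit(lpw))
                store["chain"].append(chain)

    posterior = SurvivalPosterior(
        sites=stats.sites, years=stats.years,
        chain_id=np.array(store["chain"]),
        phi=np.array(store["phi"]), eps=np.array(store["eps"]),
        sigma_year=np.array(store["sigma_year"]), p=np.array(store["p"]),
        mu_p=np.array(store["mu_p"]), sigma_p=np.array(store["sigma_p"]),
        r=np.array(store["r"]), p_within=np.array(store["p_within"]),
        config=mcmc)
    assert posterior.n_draws == mcmc.chains * keep

    msgs = posterior.convergence_warnings()
    if msgs:
        _warnings.warn("possible non-convergence (R-hat > 1.1): "
                       + "; ".join(msgs[:10]), stacklevel=2)
    return posterior


def _update_sd(sig: float, effects: np.ndarray, upper: float, scale: float,
               rng: np.random.Generator) -> tuple[float, float]:
    """MH update of a random-effect SD with U(0, upper) prior (log-scale walk)."""
    k = len(effects)
    ssq = float(np.sum(effects ** 2))
    log_new = np.log(sig) + scale * rng.standard_normal()
    sig_new = float(np.exp(log_new))
    if sig_new >= upper or sig_new < 1e-8:
        return sig, 0.0

    def logpost(s):
        return -k * np.log(s) - 0.5 * ssq / s ** 2 + np.log(s)  # + Jacobian

    loga = logpost(sig_new) - logpost(sig)
    if np.log(rng.random()) < loga:
        return sig_new, 1.0
    return sig, 0.0
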