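"""Transient-CJS likelihood and MCMC fit.

The likelihood is checked three ways: against brute-force enumeration
over latent resident/alive sequences, against the per-individual
reference recursion, and via probability conservation over the full
history space.  The sampler is checked for seed reproducibility and
behaviour on an information-free dataset.
"""

import numpy as np
import pytest
from scipy.special import expit, logit

from cesmark.data import CesDataset
from cesmark.survival import (McmcConfig, ModelParams, augment_history, fit,
                              history_loglik, loglik, prepare_stats)

from conftest import (brute_force_loglik, make_history, make_site,
                      random_tiny_dataset)


def params_for(n_sites, phi_t, p, r, pw):
    """ModelParams with one shared year-varying survival vector."""
    phi_t = np.asarray(phi_t, dtype=float)
    lphi0 = logit(phi_t[0])
    return ModelParams(
        phi=np.full((n_sites, 2), phi_t[0]),
        eps=logit(phi_t) - lphi0,
        p=np.full((n_sites, 2), p),
        r=np.array([r, r]),
        p_within=np.array([pw, pw]),
    )


# ---------------------------------------------------------------------
# History augmentation
# ---------------------------------------------------------------------

@pytest.mark.parametrize("detections,within,years,expected", [
    ([2000], False, range(2000, 2004), "10|000"),
    ([2000, 2002], True, range(2000, 2004), "11|010"),
    ([2001, 2002, 2003], False, range(2000, 2005), "10|110"),
])
def test_augmented_history_layout(detections, within, years, expected):
    h = make_history("I1", "A", "male", detections, within)
    aug = augment_history(h, years)
    assert str(aug) == expected
    assert aug.occasions[1] == "residency"


def test_last_year_first_capture_has_only_pseudo_occasion():
    h = make_history("I1", "A", "male", [2004], within=True)
    aug = augment_history(h, range(2000, 2005))
    assert aug.detections == (1, 1)
    assert aug.occasions == ("2004", "residency")


# ---------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------

def test_single_history_one_year_is_residency_product():
    """T=1 history caught and recaught within season: P = r * p_within."""
    site = make_site("A", [2000])
    ds = CesDataset([make_history("I1", "A", "male", [2000], within=True)],
                    {"A": site})
    params = ModelParams(phi=np.full((1, 2), 0.5), eps=np.zeros(0),
                         p=np.full((1, 2), 0.5), r=np.array([0.7, 0.7]),
                         p_within=np.array([0.4, 0.4]))
    assert loglik(ds, params) == pytest.approx(np.log(0.7 * 0.4), abs=1e-12)


def test_loglik_matches_brute_force_enumeration(rng):
    years = list(range(2000, 2006))
    worst = 0.0
    for _ in range(40):
        phi_t = rng.uniform(0.05, 0.95, len(years) - 1)
        p, r, pw = rng.uniform(0.05, 0.95, 3)
        ds = random_tiny_dataset(rng, n_individuals=12, years=years)
        ll = loglik(ds, params_for(1, phi_t, p, r, pw))
        bf = brute_force_loglik(ds.histories, years, phi_t, p, r, pw)
        worst = max(worst, abs(ll - bf))
    assert worst < 1e-10


def test_sufficient_stats_equal_per_individual_form(rng):
    years = list(range(2000, 2007))
    for _ in range(20):
        phi_t = rng.uniform(0.05, 0.95, len(years) - 1)
        p, r, pw = rng.uniform(0.05, 0.95, 3)
        ds = random_tiny_dataset(rng, n_individuals=20, years=years)
        ll = loglik(ds, params_for(1, phi_t, p, r, pw))
        per = sum(history_loglik(h, years, phi_t, p, r, pw)
                  for h in ds.histories)
        assert ll == pytest.approx(per, abs=1e-10)


def test_certain_residency_reduces_to_plain_cjs(rng):
    """With r=1, the transient model is a CJS likelihood plus the
    within-season Bernoulli terms."""

    def plain_cjs(histories, years, phi_t, p):
        # standard conditional-on-first-capture CJS, coded independently
        T = len(years)
        yidx = {y: i for i, y in enumerate(years)}
        chi = np.ones(T)
        for i in range(T - 2, -1, -1):
            chi[i] = (1 - phi_t[i]) + phi_t[i] * (1 - p) * chi[i + 1]
        total = 0.0
        for h in histories:
            det = sorted(yidx[y] for y in h.detection_years)
            for i, j in zip(det[:-1], det[1:]):
                total += np.sum(np.log(phi_t[i:j])) + (j - i - 1) * np.log(1 - p) \
                    + np.log(p)
            total += np.log(chi[det[-1]])
        return total

    years = list(range(2000, 2006))
    for _ in range(10):
        phi_t = rng.uniform(0.1, 0.9, len(years) - 1)
        p, pw = rng.uniform(0.1, 0.9, 2)
        ds = random_tiny_dataset(rng, n_individuals=15, years=years)
        r_near_one = 1 - 1e-12
        ll = loglik(ds, params_for(1, phi_t, p, r_near_one, pw))
        n_w1 = sum(h.within_first_season_recapture for h in ds.histories)
        n_w0 = len(ds.histories) - n_w1
        bern = n_w1 * np.log(pw) + n_w0 * np.log(1 - pw)
        assert ll == pytest.approx(plain_cjs(ds.histories, years, phi_t, p) + bern,
                                   abs=1e-9)


def test_probability_conservation_over_history_space(rng):
    """Modelled probabilities of all augmented histories sum to 1."""
    import itertools

    years = list(range(2000, 2004))
    T = len(years)
    site = make_site("A", years)
    for _ in range(5):
        phi_t = rng.uniform(0.05, 0.95, T - 1)
        p, r, pw = rng.uniform(0.05, 0.95, 3)
        params = params_for(1, phi_t, p, r, pw)
        for f in range(T):
            total = 0.0
            later = list(range(f + 1, T))
            for w in (False, True):
                for bits in itertools.product([0, 1], repeat=len(later)):
                    det = [years[f]] + [years[j] for j, b in zip(later, bits) if b]
                    ds = CesDataset([make_history("I1", "A", "male", det, w)],
                                    {"A": site})
                    total += np.exp(loglik(ds, params))
            assert total == pytest.approx(1.0, abs=1e-10)


def test_loglik_order_invariant_and_additive(rng):
    years = list(range(2000, 2006))
    phi_t = rng.uniform(0.2, 0.8, len(years) - 1)
    params = params_for(1, phi_t, 0.45, 0.7, 0.4)
    ds = random_tiny_dataset(rng, n_individuals=16, years=years)
    site = ds.sites["A"]
    ll = loglik(ds, params)
    shuffled = CesDataset(list(reversed(ds.histories)), {"A": site})
    assert loglik(shuffled, params) == pytest.approx(ll, abs=1e-12)
    half_a = CesDataset(ds.histories[:8], {"A": site})
    half_b = CesDataset(ds.histories[8:], {"A": site})
    assert loglik(half_a, params) + loglik(half_b, params) \
        == pytest.approx(ll, abs=1e-10)


def test_higher_p_raises_likelihood_of_all_detected_history():
    years = list(range(2000, 2005))
    ds = CesDataset([make_history("I1", "A", "male", years, within=True)],
                    {"A": make_site("A", years)})
    phi_t = np.full(len(years) - 1, 0.5)
    lls = [loglik(ds, params_for(1, phi_t, p, 0.7, 0.4))
           for p in (0.2, 0.4, 0.6, 0.8)]
    assert np.all(np.diff(lls) > 0)


def test_gap_year_site_blocks_detection_but_not_survival():
    """A closed season contributes no detection term; the oracle agrees."""
    years = list(range(2000, 2005))
    op = np.array([True, True, False, True, True])
    site = make_site("A", [2000, 2001, 2003, 2004])
    ds = CesDataset([make_history("I1", "A", "male", [2000, 2003]),
                     make_history("I2", "A", "male", [2001], within=True)],
                    {"A": site})
    phi_t = np.array([0.6, 0.5, 0.4, 0.7])
    p, r, pw = 0.45, 0.8, 0.35
    stats = prepare_stats(ds)
    assert list(stats.years) == years
    ll = loglik(stats, params_for(1, phi_t, p, r, pw))
    bf = brute_force_loglik(ds.histories, years, phi_t, p, r, pw, op=op)
    assert ll == pytest.approx(bf, abs=1e-10)


def test_out_of_support_parameters_give_neg_inf():
    ds = random_tiny_dataset(np.random.default_rng(0))
    params = params_for(1, np.full(5, 0.5), 0.5, 0.7, 0.4)
    params.p = np.full((1, 2), 1.5)
    assert loglik(ds, params) == -np.inf


# ---------------------------------------------------------------------
# MCMC fit
# ---------------------------------------------------------------------

def small_dataset(seed=3):
    from cesmark.data import drop_unsexed
    from cesmark.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(n_sites=3, n_years=6, mean_new_adults_per_site_year=40,
                           prop_unsexed=0.0, seed=seed,
                           abundance_surface=lambda lon, lat:
                               np.ones_like(np.asarray(lon)))
    ds, _ = drop_unsexed(simulate_dataset(cfg).dataset)
    return ds


def test_fixed_seed_mcmc_is_draw_for_draw_reproducible():
    ds = small_dataset()
    mcmc = McmcConfig(chains=2, iterations=600, burnin=200, thin=4, seed=99)
    a = fit(ds, mcmc=mcmc)
    b = fit(ds, mcmc=mcmc)
    assert a.n_draws == 2 * (600 - 200) // 4
    np.testing.assert_array_equal(a.phi, b.phi)
    np.testing.assert_array_equal(a.p, b.p)
    np.testing.assert_array_equal(a.sigma_year, b.sigma_year)
    np.testing.assert_array_equal(a.chain_id, b.chain_id)


def test_posterior_roundtrip_through_tidy_csv(tmp_path):
    from cesmark.survival import SurvivalPosterior

    ds = small_dataset()
    post = fit(ds, mcmc=McmcConfig(chains=2, iterations=400, burnin=200,
                                   thin=4, seed=7))
    post.write(tmp_path)
    back = SurvivalPosterior.read(tmp_path)
    np.testing.assert_allclose(back.phi, post.phi)
    np.testing.assert_allclose(back.eps, post.eps)
    np.testing.assert_allclose(back.r, post.r)
    assert back.sites == post.sites


def test_no_recapture_dataset_is_prior_dominated():
    """All single-capture histories carry almost no survival information:
    the transient mixture prefers low residency/survival, and the
    recapture posterior stays wide like its prior."""
    years = list(range(2000, 2006))
    site = make_site("A", years)
    hists = [make_history(f"I{i}", "A", "male" if i % 2 else "female",
                          [years[i % 5]]) for i in range(40)]
    ds = CesDataset(hists, {"A": site})
    post = fit(ds, mcmc=McmcConfig(chains=2, iterations=1500, burnin=500,
                                   thin=2, seed=11))
    p_draws = post.p.reshape(post.n_draws, -1)
    # prior-like spread: a Beta(1,1) has sd ~0.29
    assert p_draws.std() > 0.15
    assert post.phi.mean() < 0.5
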