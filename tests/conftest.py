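"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cesmark.data import CaptureHistory, CesDataset, Site


def make_site(site_id="A", years=range(2000, 2006), visits=10,
              lon=0.0, lat=52.0) -> Site:
    years = list(years)
    if isinstance(visits, int):
        visits = {y: visits for y in years}
    return Site(site_id, lon, lat, tuple(years), visits)


def make_history(iid, site_id, sex, detection_years, within=False) -> CaptureHistory:
    detection_years = sorted(detection_years)
    return CaptureHistory(iid, site_id, sex, detection_years[0],
                          frozenset(detection_years), within)


def brute_force_loglik(histories, years, phi_t, p, r, p_within, op=None) -> float:
    """Transient-CJS log-likelihood by enumeration over latent states.

    For each individual, sums the probability of its observed history
    over the latent residency indicator and every possible death
    interval, conditioning on first capture.  Exponential in nothing —
    O(T^2) per individual — but derived directly from the process
    description, independently of the package's recursions.
    """
    T = len(years)
    if op is None:
        op = np.ones(T, bool)
    yidx = {int(y): i for i, y in enumerate(years)}
    total = 0.0
    for h in histories:
        det = sorted(yidx[y] for y in h.detection_years)
        f = det[0]
        w = int(h.within_first_season_recapture)
        prob = 0.0
        if w == 0 and len(det) == 1:
            prob += 1.0 - r  # transient branch
        for d in range(f, T):  # resident, last year alive = d
            pr = r * (p_within if w else 1.0 - p_within)
            for t in range(f, d):
                pr *= phi_t[t]
            if d < T - 1:
                pr *= 1.0 - phi_t[d]
            consistent = max(det) <= d
            for t in range(f + 1, d + 1):
                if t in det:
                    if not op[t]:
                        consistent = False
                        break
                    pr *= p
                else:
                    pr *= 1.0 - p * op[t]
            if consistent:
                prob += pr
        total += np.log(prob)
    return float(total)


def random_tiny_dataset(rng, n_individuals=15, years=range(2000, 2006),
                        sex="male", site_id="A"):
    """Random capture histories on one site (for likelihood oracles)."""
    years = list(years)
    T = len(years)
    histories = []
    for i in range(n_individuals):
        f = int(rng.integers(0, T))
        w = bool(rng.integers(0, 2))
        later = []
        if f + 1 < T:
            k = int(rng.integers(0, T - f))
            later = list(rng.choice(np.arange(f + 1, T), size=k, replace=False))
        det = [years[f]] + [years[j] for j in later]
        histories.append(make_history(f"I{i}", site_id, sex, det, w))
    site = make_site(site_id, years)
    return CesDataset(histories, {site_id: site})


@pytest.fixture(scope="session")
def default_sim():
    """One paper-scale simulation shared by read-only tests."""
    from cesmark.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(seed=1234))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
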