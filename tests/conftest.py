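"""Shared fixtures and independent oracles.

The oracle functions here are deliberately coded straight from the
published closed forms (template) or as brute-force searches (grid
minimization, profiled linear least squares), independent of the package's
implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import curve_fit

import actionspec as ax


# ---------------------------------------------------------------- oracles

def oracle_alpha(lam, lmax):
    x = lmax / np.asarray(lam, dtype=float)
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    return 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                  + np.exp(-14.9 * (1.104 - x)) + 0.674)


def oracle_beta(lam, lmax):
    lam = np.asarray(lam, dtype=float)
    lmb = 189.0 + 0.315 * lmax
    bb = -40.5 + 0.195 * lmax
    return 0.26 * np.exp(-(((lam - lmb) / bb) ** 2))


def oracle_template(lam, lmax, beta=True):
    tot = lambda l: oracle_alpha(l, lmax) + (oracle_beta(l, lmax) if beta else 0.0)
    grid = np.arange(300.0, 800.0001, 0.01)
    return tot(np.asarray(lam, dtype=float)) / tot(grid).max()


def oracle_calibrate_fit_rss(candidate, lam, irr, resp):
    """Independently coded calibrate-then-fit: template weighting plus a
    bounded curve_fit of the generalized log-logistic, returning the RSS."""
    dose = np.maximum(10.0 ** irr * oracle_template(lam, candidate), 1e-30)
    lnx = np.log(dose)

    def model(ln_dose, b, c, d, ln_e, ln_f):
        t = b * (ln_dose - ln_e)
        return c + (d - c) * np.exp(-np.exp(ln_f) * np.logaddexp(0.0, t))

    lo = [-20.0, -0.5, 0.5, lnx.min() - np.log(1e3), np.log(0.1)]
    hi = [20.0, 0.5, 2.0, lnx.max() + np.log(1e3), np.log(10.0)]
    half = 0.5 * (resp.min() + resp.max())
    p0 = np.clip(
        [-1.0, float(resp.min()), float(resp.max()),
         float(lnx[np.argmin(np.abs(resp - half))]), 0.0],
        np.array(lo) + 1e-9, np.array(hi) - 1e-9)
    popt, _ = curve_fit(model, lnx, resp, p0=p0, bounds=(lo, hi), maxfev=2000)
    return float(np.sum((model(lnx, *popt) - resp) ** 2))


def oracle_grid_lambda(dataset, lo=350.0, hi=550.0, step=1.0):
    """Exhaustive grid search over candidate lambda_max."""
    grid = np.arange(lo, hi + 1e-9, step)
    rss = np.array([ax.rss_objective(g, dataset) for g in grid])
    i = int(np.argmin(rss))
    return float(grid[i]), float(rss[i])


def oracle_5pl_grid_rss(doses, responses):
    """Brute-force coarse grid over (b, e, f) with (c, d) profiled by linear
    least squares, clipped to the fit bounds; returns the minimum RSS."""
    lnx = np.log(np.maximum(np.asarray(doses, float), 1e-30))
    y = np.asarray(responses, float)
    best = np.inf
    for b in np.concatenate([-np.geomspace(0.1, 10, 13), np.geomspace(0.1, 10, 13)]):
        for ln_e in np.linspace(lnx.min() - 2, lnx.max() + 2, 25):
            for f in np.geomspace(0.1, 10, 9):
                g = np.exp(-f * np.logaddexp(0.0, b * (lnx - ln_e)))
                # y ~ c + (d - c) g  =>  linear in (c, d-c)
                X = np.column_stack([np.ones_like(g), g])
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                c, span = coef
                c = float(np.clip(c, -0.5, 0.5))
                d = float(np.clip(c + span, 0.5, 2.0))
                rss = float(np.sum((c + (d - c) * g - y) ** 2))
                best = min(best, rss)
    return best


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def toy_5pl_points():
    """12-point noisy dose-response set from a known truth (fixed seed)."""
    rng = np.random.default_rng(2718)
    truth = ax.FivePLParams(b=-1.5, c=0.0, d=1.0, e=10 ** 14.2, f=1.3)
    doses = np.logspace(12.5, 16.0, 12)
    responses = ax.five_pl(doses, truth) + rng.normal(0, 0.04, size=12)
    return doses, np.clip(responses, 0.0, None), truth


@pytest.fixture(scope="session")
def noisy_dataset():
    """Noisy simulated experiment, truth 420 nm, blue-shifted design."""
    cfg = ax.SimulationConfig(true_lambda_max=420.0, noise_sd=0.05, seed=11)
    return ax.generate_dataset(cfg, wavelength_subset=ax.SHIFTED_WAVELENGTH_SUBSET)


@pytest.fixture(scope="session")
def noiseless_dataset_420():
    cfg = ax.SimulationConfig(true_lambda_max=420.0, noise_sd=0.0, seed=0)
    return ax.generate_dataset(cfg, wavelength_subset=ax.SHIFTED_WAVELENGTH_SUBSET)
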