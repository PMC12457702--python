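"""Visual-pigment sensitivity templates.

The spectral sensitivity of a retinal-based pigment is well described by a
closed-form nomogram fully determined by its wavelength of maximum
absorbance (lambda_max) and chromophore type.  This module implements the
standard A1 (11-cis-retinal) rhodopsin template of Govardovskii et al.
(2000): a main alpha-band plus an optional short-wavelength beta-band
(cis-peak), renormalized to unit peak.  The template serves two roles in
this package: it converts measured photon fluxes into effective intensities
inside the lambda_max estimator, and it is the generative absorbance curve
of the synthetic-data module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["PigmentTemplate", "template_sensitivity", "template_curve"]

# Valid lambda_max domain (nm): wider than the 350-550 nm search range used
# for estimation, with margin; the nomogram fit loses validity outside.
LAMBDA_MAX_DOMAIN = (330.0, 600.0)
# Wavelength evaluation domain (nm).
WAVELENGTH_DOMAIN = (300.0, 800.0)

# Alpha-band shape constants of the A1 template.
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104


def _a_param(lambda_max: float) -> float:
    """UV band-narrowing correction: the alpha-band position parameter ``a``
    drifts slowly with lambda_max."""
    return 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)


def _alpha_band(wavelength, lambda_max: float, a: float | None = None):
    """Unnormalized alpha-band. ``a`` may be pinned to study the pure
    x = lambda_max/lambda scale invariance of the band shape."""
    x = lambda_max / np.asarray(wavelength, dtype=float)
    if a is None:
        a = _a_param(lambda_max)
    return 1.0 / (
        np.exp(_A * (a - x))
        + np.exp(_B * (_b - x))
        + np.exp(_C * (_c - x))
        + _D
    )


def _beta_band(wavelength, lambda_max: float):
    """Unnormalized beta-band (cis-peak): a Gaussian whose position and
    width track lambda_max."""
    lam = np.asarray(wavelength, dtype=float)
    lmb = 189.0 + 0.315 * lambda_max
    bb = -40.5 + 0.195 * lambda_max
    return 0.26 * np.exp(-(((lam - lmb) / bb) ** 2))


def _raw_sensitivity(wavelength, lambda_max: float, include_beta: bool):
    s = _alpha_band(wavelength, lambda_max)
    if include_beta:
        s = s + _beta_band(wavelength, lambda_max)
    return s


@lru_cache(maxsize=4096)
def _peak_value(lambda_max: float, include_beta: bool) -> float:
    """Maximum of the unnormalized template over the wavelength domain.

    Coarse grid scan followed by a bounded scalar refinement, so normalized
    templates peak at 1 to full floating precision.
    """
    grid = np.arange(WAVELENGTH_DOMAIN[0], WAVELENGTH_DOMAIN[1] + 0.5, 0.5)
    values = _raw_sensitivity(grid, lambda_max, include_beta)
    i = int(np.argmax(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda lam: -_raw_sensitivity(lam, lambda_max, include_beta),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(max(-res.fun, values[i]))


@dataclass(frozen=True)
class PigmentTemplate:
    """An A1 visual-pigment template keyed by its lambda_max.

    Parameters
    ----------
    lambda_max
        Wavelength of maximum sensitivity, nm. Must lie in [330, 600].
    chromophore
        Only ``"A1"`` (11-cis retinal) is implemented; ``"A2"`` is reserved.
    include_beta_band
        Whether the short-wavelength beta-band is added to the alpha-band.
        Defaults on: UV/violet stimuli interact with the beta-band of
        blue-shifted pigments.
    normalized
        If true (default) sensitivities are scaled to unit peak over the
        300-800 nm domain.
    """

    lambda_max: float
    chromophore: str = "A1"
    include_beta_band: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.chromophore == "A2":
            raise NotImplementedError("A2 (porphyropsin) templates are reserved, not implemented")
        if self.chromophore != "A1":
            raise ValueError(f"unknown chromophore {self.chromophore!r}; only 'A1' is supported")
        lo, hi = LAMBDA_MAX_DOMAIN
        if not np.isfinite(self.lambda_max) or not (lo <= self.lambda_max <= hi):
            raise ValueError(
                f"lambda_max={self.lambda_max} nm outside template validity domain [{lo}, {hi}] nm"
            )

    def sensitivity(self, wavelength):
        """Relative sensitivity S(wavelength), vectorized over wavelength."""
        return template_sensitivity(self, wavelength)


def _check_wavelength_domain(wavelength) -> np.ndarray:
    lam = np.asarray(wavelength, dtype=float)
    lo, hi = WAVELENGTH_DOMAIN
    if lam.size == 0:
        raise ValueError("wavelength grid is empty")
    tol = 1e-6  # absorb grid-accumulation fuzz at the domain edges
    if not np.all(np.isfinite(lam)) or np.any(lam < lo - tol) or np.any(lam > hi + tol):
        bad = lam[~(np.isfinite(lam) & (lam >= lo - tol) & (lam <= hi + tol))]
        raise ValueError(
            f"wavelength(s) {np.atleast_1d(bad)[:5].tolist()} nm outside evaluation domain [{lo}, {hi}] nm"
        )
    return np.clip(lam, lo, hi)


def template_sensitivity(template: PigmentTemplate, wavelength):
    """Evaluate the template at one or more wavelengths (nm).

    Returns a scalar for scalar input, an ndarray otherwise; values lie in
    (0, 1] for a normalized template.
    """
    lam = _check_wavelength_domain(wavelength)
    s = _raw_sensitivity(lam, float(template.lambda_max), template.include_beta_band)
    if template.normalized:
        s = s / _peak_value(float(template.lambda_max), template.include_beta_band)
    if np.isscalar(wavelength) or np.ndim(wavelength) == 0:
        return float(s)
    return s


def template_curve(template: PigmentTemplate, wavelength_grid) -> np.ndarray:
    """Elementwise sensitivities on a wavelength grid (nm)."""
    lam = _check_wavelength_domain(wavelength_grid)
    if lam.ndim == 0:
        lam = lam.reshape(1)
    return np.asarray(template_sensitivity(template, lam), dtype=float)
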