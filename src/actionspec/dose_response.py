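"""Five-parameter logistic irradiance-response model.

Responses in the aequorin Ca2+ assay are normalized per independent
experiment (replicate) to the maximum observed across all wavelength and
intensity combinations.  Against effective light intensity (photon flux
weighted by the pigment template) the normalized response follows an
asymmetric sigmoid; we use the generalized log-logistic 5PL form

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))**f

with lower/upper asymptotes c and d, slope b (negative for an increasing
curve), inflection dose e (linear scale) and asymmetry f > 0.  Fitting is
unweighted nonlinear least squares with bounded parameters and heuristic
starts, multi-started on failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ResponsePoint",
    "ResponseDataset",
    "FivePLParams",
    "normalize_responses",
    "five_pl",
    "fit_5pl",
]

LOG10_IRRADIANCE_BOUNDS = (10.0, 20.0)  # sanity window; assays span 12.5-16
DOSE_FLOOR = 1e-30  # linear-scale floor for "this stimulus is ineffective"

# excluded from estimation by default: responses there are far from
# saturation in every design the assay uses
DEFAULT_EXCLUDED_WAVELENGTHS = frozenset({525.0})


@dataclass(frozen=True)
class ResponsePoint:
    """One normalized peak Ca2+ response to one flash."""

    genotype: str
    replicate: str
    wavelength_nm: float
    log10_irradiance: float
    response: float

    def __post_init__(self) -> None:
        lo, hi = LOG10_IRRADIANCE_BOUNDS
        if not (lo <= self.log10_irradiance <= hi):
            raise ValueError(
                f"log10_irradiance={self.log10_irradiance} outside sanity bounds [{lo}, {hi}]"
            )
        if not np.isfinite(self.response) or self.response < 0:
            raise ValueError(f"response must be finite and >= 0, got {self.response}")


@dataclass(frozen=True)
class ResponseDataset:
    """The unit of lambda_max estimation: all points of one opsin variant.

    ``wavelength_subset`` lists the stimulus wavelengths admitted to
    estimation; by default every wavelength present except 525 nm.
    """

    points: tuple[ResponsePoint, ...]
    genotype: str
    wavelength_subset: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        present = sorted({p.wavelength_nm for p in pts})
        if not self.wavelength_subset:
            subset = tuple(w for w in present if w not in DEFAULT_EXCLUDED_WAVELENGTHS)
            object.__setattr__(self, "wavelength_subset", subset)
        else:
            subset = tuple(sorted(set(float(w) for w in self.wavelength_subset)))
            missing = set(subset) - set(present)
            if missing:
                raise ValueError(f"wavelength_subset {sorted(missing)} nm not present in data")
            object.__setattr__(self, "wavelength_subset", subset)

    def subset_points(self) -> tuple[ResponsePoint, ...]:
        admitted = set(self.wavelength_subset)
        return tuple(p for p in self.points if p.wavelength_nm in admitted)

    def validate_for_estimation(self) -> None:
        pts = self.subset_points()
        wavelengths = {p.wavelength_nm for p in pts}
        intensities = {p.log10_irradiance for p in pts}
        if len(wavelengths) < 2:
            raise ValueError(
                f"dataset {self.genotype!r}: lambda_max is not identifiable from "
                f"{len(wavelengths)} distinct wavelength(s); need >= 2"
            )
        if len(intensities) < 4:
            raise ValueError(
                f"dataset {self.genotype!r}: need >= 4 distinct intensities, got {len(intensities)}"
            )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(wavelength_nm, log10_irradiance, response) for admitted points."""
        pts = self.subset_points()
        lam = np.array([p.wavelength_nm for p in pts])
        irr = np.array([p.log10_irradiance for p in pts])
        resp = np.array([p.response for p in pts])
        return lam, irr, resp

    def resample(self, rng: np.random.Generator) -> "ResponseDataset":
        """Bootstrap resample: admitted rows drawn with replacement to the
        original admitted count."""
        pool = self.subset_points()
        idx = rng.integers(0, len(pool), size=len(pool))
        pts = tuple(pool[i] for i in idx)
        present = {p.wavelength_nm for p in pts}
        subset = tuple(w for w in self.wavelength_subset if w in present)
        return ResponseDataset(points=pts, genotype=self.genotype, wavelength_subset=subset)


@dataclass(frozen=True)
class FivePLParams:
    """5PL parameters plus fit diagnostics."""

    b: float
    c: float
    d: float
    e: float
    f: float
    rss: float = math.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged:
            if not (self.e > 0 and self.f > 0):
                raise ValueError("5PL requires e > 0 and f > 0")
            if not (self.d > self.c):
                raise ValueError("5PL requires d > c")
            if np.isfinite(self.rss) and self.rss < 0:
                raise ValueError("rss must be >= 0")


def normalize_responses(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-experiment normalization of raw peak responses.

    Within each (genotype, replicate) group every raw peak is divided by the
    group maximum, so the maximum maps to exactly 1.  Input frame needs
    columns genotype, replicate, wavelength_nm, log10_irradiance, raw_peak;
    the result carries a ``response`` column instead of ``raw_peak``.
    """
    required = {"genotype", "replicate", "wavelength_nm", "log10_irradiance", "raw_peak"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"missing column(s) {sorted(missing)} in raw response table")
    if (raw["raw_peak"] < 0).any():
        bad = raw.index[raw["raw_peak"] < 0][0]
        raise ValueError(f"negative raw peak at row {bad}")
    out = raw.copy()
    gmax = out.groupby(["genotype", "replicate"])["raw_peak"].transform("max")
    zero = gmax <= 0
    if zero.any():
        g, r = out.loc[zero.idxmax(), ["genotype", "replicate"]]
        raise ValueError(f"replicate {r!r} of genotype {g!r} has no positive raw peak")
    out["response"] = out["raw_peak"] / gmax
    return out.drop(columns=["raw_peak"])


def dataset_from_frame(df: pd.DataFrame, genotype: str,
                       wavelength_subset=()) -> ResponseDataset:
    """Build a ResponseDataset for one genotype from a tidy normalized table."""
    sub = df[df["genotype"] == genotype]
    if sub.empty:
        raise ValueError(f"no rows for genotype {genotype!r}")
    pts = tuple(
        ResponsePoint(
            genotype=str(r.genotype),
            replicate=str(r.replicate),
            wavelength_nm=float(r.wavelength_nm),
            log10_irradiance=float(r.log10_irradiance),
            response=float(r.response),
        )
        for r in sub.itertuples()
    )
    return ResponseDataset(points=pts, genotype=genotype,
                           wavelength_subset=tuple(wavelength_subset))


def five_pl(dose, params: FivePLParams):
    """Evaluate the 5PL at linear-scale dose(s); dose = 0 maps to the limit
    asymptote rather than overflowing."""
    x = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        lnx = np.log(x)
    t = params.b * (lnx - math.log(params.e))
    # (1+exp(t))^-f computed as exp(-f*softplus(t)); stable for any t
    val = params.c + (params.d - params.c) * np.exp(-params.f * np.logaddexp(0.0, t))
    if np.isscalar(dose) or np.ndim(dose) == 0:
        return float(val)
    return val


def _residuals(theta: np.ndarray, lnx: np.ndarray, y: np.ndarray) -> np.ndarray:
    b, c, d, ln_e, ln_f = theta
    t = b * (lnx - ln_e)
    return c + (d - c) * np.exp(-math.exp(ln_f) * np.logaddexp(0.0, t)) - y


def _jacobian(theta: np.ndarray, lnx: np.ndarray, y: np.ndarray) -> np.ndarray:
    b, c, d, ln_e, ln_f = theta
    u = lnx - ln_e
    t = b * u
    F = math.exp(ln_f)
    sp = np.logaddexp(0.0, t)          # softplus; d(sp)/dt = sigmoid(t)
    sig = np.exp(t - sp)               # sigmoid computed without overflow
    G = np.exp(-F * sp)
    span = d - c
    J = np.empty((len(lnx), 5))
    J[:, 0] = -span * G * F * sig * u        # d/db
    J[:, 1] = 1.0 - G                        # d/dc
    J[:, 2] = G                              # d/dd
    J[:, 3] = span * G * F * sig * b         # d/d ln_e
    J[:, 4] = -span * G * sp * F             # d/d ln_f
    return J


def _start_values(lnx: np.ndarray, y: np.ndarray) -> np.ndarray:
    c0 = float(np.min(y))
    d0 = float(np.max(y))
    half = 0.5 * (c0 + d0)
    e0_ln = float(lnx[np.argmin(np.abs(y - half))])
    # slope of y against ln dose decides the sign convention (b<0: increasing)
    trend = np.polyfit(lnx, y, 1)[0] if np.ptp(lnx) > 0 else 0.0
    b0 = -1.0 if trend >= 0 else 1.0
    return np.array([b0, c0, d0, e0_ln, 0.0])


def fit_5pl(doses, responses, max_nfev: int = 400,
            start: FivePLParams | None = None) -> FivePLParams:
    """Unweighted least-squares fit of the 5PL.

    Parameters are bounded to the physically meaningful basin for
    max-normalized responses: c in [-0.5, 0.5], d in [0.5, 2], f in
    [0.1, 10], e within three decades of the observed dose range.  On
    non-convergence two perturbed restarts are tried; the converged flag is
    honest (never fabricated parameters).
    """
    x = np.maximum(np.asarray(doses, dtype=float), DOSE_FLOOR)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("doses and responses must be 1-d arrays of equal length")
    if len(x) < 6:
        raise ValueError(f"need >= 6 points to fit 5 parameters, got {len(x)}")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.ptp(y) < 1e-12:
        # constant responses: no dose dependence, parameters unidentifiable
        return FivePLParams(b=-1.0, c=0.0, d=1.0, e=float(np.median(x)), f=1.0,
                            rss=float(np.sum((y - y.mean()) ** 2)), converged=False)

    lnx = np.log(x)
    lo = np.array([-20.0, -0.5, 0.5, lnx.min() - math.log(1e3), math.log(0.1)])
    hi = np.array([20.0, 0.5, 2.0, lnx.max() + math.log(1e3), math.log(10.0)])
    if start is not None:
        theta0 = np.array([start.b, start.c, start.d,
                           math.log(start.e), math.log(start.f)])
    else:
        theta0 = _start_values(lnx, y)
    theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)

    best = None
    starts = [theta0]
    rng = np.random.default_rng(0)  # fixed: fitting must be deterministic
    for attempt, start in enumerate(starts):
        try:
            res = least_squares(_residuals, start, jac=_jacobian, args=(lnx, y),
                                bounds=(lo, hi), method="trf", max_nfev=max_nfev)
        except Exception:
            res = None
        if res is not None:
            rss = float(np.sum(res.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, res)
        ok = res is not None and res.success
        if not ok and attempt < 2 and len(starts) < 3:
            jitter = rng.normal(scale=0.3, size=5)
            starts.append(np.clip(theta0 + jitter, lo + 1e-9, hi - 1e-9))

    if best is None:
        return FivePLParams(b=-1.0, c=0.0, d=1.0, e=float(np.median(x)), f=1.0,
                            rss=math.inf, converged=False)
    rss, res = best
    b, c, d, ln_e, ln_f = res.x
    return FivePLParams(b=float(b), c=float(c), d=float(d), e=float(math.exp(ln_e)),
                        f=float(math.exp(ln_f)), rss=rss,
                        converged=bool(res.success and np.isfinite(rss)))
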