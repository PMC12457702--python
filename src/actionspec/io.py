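"""Tidy-CSV readers/writers and JSON result serialization.

One CSV schema serves both measured and simulated data: columns
``genotype, replicate, wavelength_nm, log10_irradiance`` plus either
``response`` (already normalized) or ``raw_peak`` (pre-normalization).
Results are JSON with every configuration default materialized, so a run
is fully reproducible from its output alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import LOG10_IRRADIANCE_BOUNDS, normalize_responses
from .estimator import LambdaEstimate

__all__ = ["read_response_table", "write_estimate", "read_estimate", "write_template_curve"]

KEY_COLUMNS = ["genotype", "replicate", "wavelength_nm", "log10_irradiance"]


def read_response_table(path, mode: str = "normalized") -> pd.DataFrame:
    """Read and validate a tidy response table.

    ``mode="normalized"`` expects a ``response`` column; ``mode="raw"``
    expects ``raw_peak`` and applies per-replicate max-normalization.
    Errors cite the offending 1-based data row.
    """
    if mode not in ("normalized", "raw"):
        raise ValueError(f"mode must be 'normalized' or 'raw', got {mode!r}")
    value_col = "response" if mode == "normalized" else "raw_peak"
    df = pd.read_csv(path)
    required = KEY_COLUMNS + [value_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    for col in ["wavelength_nm", "log10_irradiance", value_col]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric or missing {col!r} at line {row}")
        df[col] = numeric

    lo, hi = LOG10_IRRADIANCE_BOUNDS
    out_of_range = (df["log10_irradiance"] < lo) | (df["log10_irradiance"] > hi)
    if out_of_range.any():
        row = int(out_of_range.idxmax()) + 2
        raise ValueError(f"{path}: log10_irradiance outside [{lo}, {hi}] at line {row}")
    negative = df[value_col] < 0
    if negative.any():
        row = int(negative.idxmax()) + 2
        raise ValueError(f"{path}: negative {value_col} at line {row}")

    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise ValueError(
            f"{path}: duplicate (genotype, replicate, wavelength, intensity) key at line {row}"
        )

    if mode == "raw":
        df = normalize_responses(df)
    return df


def _estimate_to_dict(result: LambdaEstimate, config_echo: dict | None = None) -> dict:
    if len(result.bootstrap_values) != result.n_boot_converged:
        raise ValueError("bootstrap_values length must equal n_boot_converged")
    payload = {
        "point_estimate_nm": result.point_estimate,
        "ci_low_nm": result.ci_low,
        "ci_high_nm": result.ci_high,
        "n_boot_requested": result.n_boot_requested,
        "n_boot_converged": result.n_boot_converged,
        "rss_at_estimate": result.rss_at_estimate,
        "search_range_nm": list(result.search_range),
        "seed": result.seed,
        "warnings": list(result.warnings),
        "bootstrap_values": list(result.bootstrap_values),
    }
    if config_echo is not None:
        payload["config"] = config_echo
    return payload


def write_estimate(result: LambdaEstimate, path, config_echo: dict | None = None) -> None:
    """Serialize a LambdaEstimate to JSON (round-trip safe)."""
    Path(path).write_text(json.dumps(_estimate_to_dict(result, config_echo), indent=2) + "\n")


def read_estimate(path) -> LambdaEstimate:
    """Read back an estimate JSON written by :func:`write_estimate`."""
    data = json.loads(Path(path).read_text())
    return LambdaEstimate(
        point_estimate=data["point_estimate_nm"],
        bootstrap_values=tuple(data["bootstrap_values"]),
        n_boot_requested=data["n_boot_requested"],
        n_boot_converged=data["n_boot_converged"],
        ci_low=data["ci_low_nm"],
        ci_high=data["ci_high_nm"],
        search_range=tuple(data["search_range_nm"]),
        rss_at_estimate=data["rss_at_estimate"],
        seed=data["seed"],
        warnings=tuple(data.get("warnings", ())),
    )


def write_template_curve(wavelengths, sensitivities, path) -> None:
    """Two-column CSV export (wavelength_nm, sensitivity)."""
    pd.DataFrame({
        "wavelength_nm": np.asarray(wavelengths, dtype=float),
        "sensitivity": np.asarray(sensitivities, dtype=float),
    }).to_csv(path, index=False)


def write_response_table(df: pd.DataFrame, path) -> None:
    """Write a tidy response table CSV."""
    df.to_csv(path, index=False)
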