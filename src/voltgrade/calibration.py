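"""Analytic sensor-calibration utilities.

Standard electroanalytical figures of merit for a dose–response panel:
ordinary least-squares calibration line, limit of detection by the
3.3·σ/slope convention (ICH Q2; a 3·σ multiplier is available), electrode
area-normalized sensitivity, and a selectivity ratio of the target response
against an interferent panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationFit",
    "fit_calibration",
    "limit_of_detection",
    "selectivity",
]


@dataclass(frozen=True)
class CalibrationFit:
    """OLS calibration line and derived figures of merit.

    ``sigma_blank`` is the blank-response standard deviation used for the
    LOD; when no blank replicates are supplied it falls back to the
    residual standard error of the fit (``sigma_source`` records which).
    ``sensitivity_per_area`` is slope divided by electrode area, reported
    in the slope's response/concentration units per cm².
    """

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    linear_range: tuple[float, float]
    sigma_blank: float
    sigma_source: str
    lod: float
    sensitivity_per_area: float
    electrode_area: float
    degenerate: bool = False


def fit_calibration(
    concentrations,
    responses,
    electrode_area: float = 2.0,
    sigma_blank: float | None = None,
    lod_multiplier: float = 3.3,
) -> CalibrationFit:
    """Fit the linear dose–response and derive LOD and sensitivity.

    Requires at least three distinct concentrations.  A flat (zero-slope)
    response yields ``r_squared = 0`` with the degenerate flag and an
    infinite LOD rather than an error, mirroring how a dead electrode shows
    up in practice.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise ValueError("concentrations and responses must be equal-length 1-D")
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if electrode_area <= 0:
        raise ValueError("electrode area must be positive")
    fit = stats.linregress(c, r)
    slope, intercept = float(fit.slope), float(fit.intercept)
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    resid = r - (intercept + slope * c)
    ss_res = float(np.sum(resid**2))
    degenerate = ss_tot == 0.0
    r_squared = 0.0 if degenerate else 1.0 - ss_res / ss_tot
    dof = max(c.size - 2, 1)
    sigma_resid = float(np.sqrt(ss_res / dof))
    if sigma_blank is None:
        sigma, source = sigma_resid, "residual"
    else:
        if sigma_blank < 0:
            raise ValueError("sigma_blank must be ≥ 0")
        sigma, source = float(sigma_blank), "blank"
    lod = (
        limit_of_detection(sigma, slope, multiplier=lod_multiplier)
        if slope > 0
        else float("inf")
    )
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        r_squared=float(np.clip(r_squared, 0.0, 1.0)),
        slope_stderr=float(fit.stderr),
        linear_range=(float(c.min()), float(c.max())),
        sigma_blank=sigma,
        sigma_source=source,
        lod=lod,
        sensitivity_per_area=slope / electrode_area,
        electrode_area=float(electrode_area),
        degenerate=degenerate or slope == 0.0,
    )


def limit_of_detection(
    sigma_blank: float, slope: float, multiplier: float = 3.3
) -> float:
    """LOD = multiplier·σ_blank / slope (concentration units of the slope)."""
    if slope <= 0:
        raise ValueError(f"slope must be positive (got {slope})")
    if sigma_blank < 0:
        raise ValueError("sigma_blank must be ≥ 0")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return multiplier * sigma_blank / slope


def selectivity(target_delta: float, interferent_deltas) -> float:
    """|target response| / mean |interferent response|.

    The ratio definition is the simplest one consistent with quoting a
    single "selectivity value" per analyte; it is not an IUPAC-sanctioned
    quantity and should be read comparatively, not absolutely.
    """
    deltas = np.asarray(interferent_deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("need at least one interferent response")
    denom = float(np.mean(np.abs(deltas)))
    if denom == 0:
        raise ValueError("selectivity undefined: all interferent responses zero")
    return abs(float(target_delta)) / denom
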