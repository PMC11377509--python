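"""Voltammogram container, CSV I/O and engineered CV descriptors.

A cyclic-voltammetry trace is a current-vs-potential curve recorded while
the electrode potential is swept at a fixed scan rate.  Fourteen scalar
descriptors summarise each trace: the signed charge passed during the sweep,
peak positions and magnitudes, half-height peak geometry, distributional
moments of the current samples, and extrema of the first two derivatives of
current with respect to potential.  Together they feed the correlation and
classification stages downstream.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Voltammogram",
    "CVFeatureVector",
    "FEATURE_NAMES",
    "read_voltammogram",
    "write_voltammogram",
    "charge",
    "peak_descriptors",
    "distribution_moments",
    "derivative_extrema",
    "extract_features",
    "extract_feature_matrix",
]

#: Canonical order of the 14 engineered descriptors.
FEATURE_NAMES: tuple[str, ...] = (
    "charge_Q",
    "half_peak_potential",
    "peak_width_half_height",
    "mean_current",
    "median_current",
    "std_current",
    "kurtosis",
    "skewness",
    "peak_derivative",
    "peak_second_derivative",
    "positive_peak_current",
    "negative_peak_current",
    "positive_peak_potential",
    "negative_peak_potential",
)

MIN_POINTS = 16


class VoltammogramError(ValueError):
    """Raised when a trace violates its structural invariants."""


@dataclass(frozen=True)
class Voltammogram:
    """One CV trace: potential sweep (V), current response (µA), scan rate (V/s).

    The potential must be strictly monotone (rising or falling sweep); the
    time axis is reconstructed from ``|dE| / scan_rate`` because instruments
    export only potential and current.
    """

    potential: np.ndarray
    current: np.ndarray
    scan_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pot = np.asarray(self.potential, dtype=float)
        cur = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "potential", pot)
        object.__setattr__(self, "current", cur)
        if pot.ndim != 1 or cur.ndim != 1:
            raise VoltammogramError("potential and current must be 1-D series")
        if pot.size != cur.size:
            raise VoltammogramError(
                f"length mismatch: {pot.size} potentials vs {cur.size} currents"
            )
        if pot.size < MIN_POINTS:
            raise VoltammogramError(
                f"fewer than {MIN_POINTS} samples ({pot.size} rows)"
            )
        if not (np.isfinite(pot).all() and np.isfinite(cur).all()):
            bad = int(np.flatnonzero(~(np.isfinite(pot) & np.isfinite(cur)))[0])
            raise VoltammogramError(f"non-finite value at row {bad}")
        dE = np.diff(pot)
        if not (np.all(dE > 0) or np.all(dE < 0)):
            bad = int(np.flatnonzero(np.sign(dE) != np.sign(dE[0]))[0]) + 1
            raise VoltammogramError(
                f"potential not strictly monotone (direction change at row {bad})"
            )
        if not (np.isfinite(self.scan_rate) and self.scan_rate > 0):
            raise VoltammogramError("scan_rate must be a positive finite number")

    @property
    def time(self) -> np.ndarray:
        """Elapsed time (s) at each sample, reconstructed from the sweep."""
        dt = np.abs(np.diff(self.potential)) / self.scan_rate
        return np.concatenate([[0.0], np.cumsum(dt)])

    def __len__(self) -> int:
        return int(self.potential.size)


@dataclass(frozen=True)
class CVFeatureVector:
    """The 14 engineered descriptors of one voltammogram.

    ``degenerate`` flags traces with (near-)zero variance or a vanishing
    baseline-corrected peak, for which the half-height geometry and the
    standardized moments are reported as zeros instead of raising.
    """

    charge_Q: float
    half_peak_potential: float
    peak_width_half_height: float
    mean_current: float
    median_current: float
    std_current: float
    kurtosis: float
    skewness: float
    peak_derivative: float
    peak_second_derivative: float
    positive_peak_current: float
    negative_peak_current: float
    positive_peak_potential: float
    negative_peak_potential: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: optional leading comment lines "#key=value" carrying metadata
# (scan_rate_V_s is recognised), then a header "potential_V,current_uA".


def write_voltammogram(vg: Voltammogram, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#scan_rate_V_s={vg.scan_rate!r}\n")
        for key, value in vg.meta.items():
            fh.write(f"#{key}={value}\n")
        fh.write("potential_V,current_uA\n")
        for e, i in zip(vg.potential, vg.current):
            fh.write(f"{float(e)!r},{float(i)!r}\n")


def read_voltammogram(
    path: str | os.PathLike, scan_rate: float | None = None
) -> Voltammogram:
    """Read a two-column trace CSV, honouring ``#key=value`` header lines.

    ``scan_rate`` overrides (or supplies, if absent from the file) the
    ``scan_rate_V_s`` metadata entry.
    """
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
            else:
                body_lines.append(line)
    try:
        frame = pd.read_csv(
            io.StringIO("".join(body_lines)), float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise VoltammogramError(f"unparseable trace file {path}: {exc}") from exc
    for col in ("potential_V", "current_uA"):
        if col not in frame.columns:
            raise VoltammogramError(f"{path}: missing required column '{col}'")
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
            raise VoltammogramError(
                f"{path}: non-numeric value in column '{col}' at row {int(bad[0])}"
            )
    if scan_rate is None:
        raw = meta.pop("scan_rate_V_s", None)
        if raw is None:
            raise VoltammogramError(f"{path}: no scan rate in file or arguments")
        scan_rate = float(raw)
    else:
        meta.pop("scan_rate_V_s", None)
    return Voltammogram(
        potential=frame["potential_V"].to_numpy(float),
        current=frame["current_uA"].to_numpy(float),
        scan_rate=float(scan_rate),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Descriptors


def charge(vg: Voltammogram) -> float:
    """Signed charge (µC): trapezoidal integral of current over sweep time."""
    return float(np.trapezoid(vg.current, vg.time))


def _baseline(vg: Voltammogram) -> np.ndarray:
    # Straight line through the mean (E, I) of the first and last 10% of
    # samples; half-height geometry is meaningless without some baseline.
    k = max(2, len(vg) // 10)
    e0, i0 = vg.potential[:k].mean(), vg.current[:k].mean()
    e1, i1 = vg.potential[-k:].mean(), vg.current[-k:].mean()
    slope = (i1 - i0) / (e1 - e0)
    return i0 + slope * (vg.potential - e0)


def _cross(pot: np.ndarray, sig: np.ndarray, j: int, k: int, half: float) -> float:
    # Linear interpolation of the potential where sig crosses `half`
    # between samples j and k (k = j±1).
    s0, s1 = sig[j], sig[k]
    if s1 == s0:
        return float(pot[k])
    t = (half - s0) / (s1 - s0)
    return float(pot[j] + t * (pot[k] - pot[j]))


def peak_descriptors(vg: Voltammogram) -> dict[str, float | bool]:
    """Peak currents/potentials and baseline-corrected half-height geometry.

    The positive (negative) peak is the raw maximum (minimum) of the current.
    The *dominant* peak — the extremum of the baseline-corrected signal with
    the larger magnitude — defines the half-height quantities: the half-peak
    potential is the interpolated crossing of half the corrected peak height
    on the flank preceding the peak in sweep order, and the width at half
    height spans the two crossings bracketing the peak.  A flat trace yields
    zeros and the degenerate flag.
    """
    pot, cur = vg.potential, vg.current
    i_max = int(np.argmax(cur))
    i_min = int(np.argmin(cur))
    out: dict[str, float | bool] = {
        "positive_peak_current": float(cur[i_max]),
        "positive_peak_potential": float(pot[i_max]),
        "negative_peak_current": float(cur[i_min]),
        "negative_peak_potential": float(pot[i_min]),
    }

    corrected = cur - _baseline(vg)
    j_max, j_min = int(np.argmax(corrected)), int(np.argmin(corrected))
    scale = max(abs(corrected[j_max]), abs(corrected[j_min]))
    span = cur.max() - cur.min()
    if scale <= 1e-12 * max(1.0, span) or scale == 0.0:
        out.update(half_peak_potential=0.0, peak_width_half_height=0.0,
                   degenerate=True)
        return out

    if abs(corrected[j_max]) >= abs(corrected[j_min]):
        peak_idx, sig = j_max, corrected
    else:
        peak_idx, sig = j_min, -corrected
    half = sig[peak_idx] / 2.0

    # Walk outward from the peak to the bracketing half-height crossings;
    # clamp to the sweep ends when a flank never drops below half height.
    left = float(pot[0])
    for j in range(peak_idx, 0, -1):
        if sig[j - 1] <= half:
            left = _cross(pot, sig, j - 1, j, half)
            break
    right = float(pot[-1])
    for j in range(peak_idx, len(sig) - 1):
        if sig[j + 1] <= half:
            right = _cross(pot, sig, j + 1, j, half)
            break
    out["peak_width_half_height"] = abs(right - left)
    # Flank preceding the peak in sweep order = the side toward sample 0.
    out["half_peak_potential"] = left
    out["degenerate"] = False
    return out


def distribution_moments(vg: Voltammogram) -> dict[str, float | bool]:
    """Mean/median/std (n−1) and standardized skewness / excess kurtosis."""
    cur = vg.current
    std = float(np.std(cur, ddof=1))
    out: dict[str, float | bool] = {
        "mean_current": float(np.mean(cur)),
        "median_current": float(np.median(cur)),
        "std_current": std,
        "degenerate": False,
    }
    if std == 0.0:
        out.update(skewness=0.0, kurtosis=0.0, degenerate=True)
    else:
        out["skewness"] = float(stats.skew(cur, bias=True))
        out["kurtosis"] = float(stats.kurtosis(cur, fisher=True, bias=True))
    return out


def derivative_extrema(vg: Voltammogram) -> dict[str, float]:
    """Signed extrema of dI/dE and d²I/dE² (central differences).

    Each value is the derivative at the point where its absolute value is
    largest, keeping the sign it attains there.
    """
    d1 = np.gradient(vg.current, vg.potential)
    d2 = np.gradient(d1, vg.potential)
    return {
        "peak_derivative": float(d1[np.argmax(np.abs(d1))]),
        "peak_second_derivative": float(d2[np.argmax(np.abs(d2))]),
    }


def extract_features(vg: Voltammogram) -> CVFeatureVector:
    """Assemble the full 14-descriptor vector for one trace."""
    peaks = peak_descriptors(vg)
    moments = distribution_moments(vg)
    derivs = derivative_extrema(vg)
    degenerate = bool(peaks.pop("degenerate")) or bool(moments.pop("degenerate"))
    return CVFeatureVector(
        charge_Q=charge(vg), **peaks, **moments, **derivs, degenerate=degenerate
    )


def extract_feature_matrix(
    voltammograms: Iterable[Voltammogram],
    labels: Iterable | None = None,
) -> pd.DataFrame:
    """Feature matrix with the 14 canonical columns, one row per trace."""
    rows = [extract_features(vg).as_dict() for vg in voltammograms]
    frame = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if labels is not None:
        frame["label"] = list(labels)
        if len(frame["label"]) != len(rows):
            raise ValueError("labels length does not match number of traces")
    return frame
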