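"""Seeded generators for voltammograms and clinical cohorts.

The study data behind the immunosensor (raw CV curves and the measured
biomarker responses) were never deposited, so this module provides the
statistical stand-ins every other stage is tested against:

* single-sweep voltammograms modelled as a linear baseline plus a Gaussian
  redox peak plus i.i.d. Gaussian noise, over the instrument window of
  −0.05 V to −0.45 V at 50 mV/s;
* a linear dose–response mapping biomarker concentration (U/mL) to peak
  amplitude over the sensor's 5–100 U/mL linear range, saturating outside it;
* labelled datasets in which each class (control, grade I–III) draws
  concentrations from a lognormal distribution with class-specific median,
  mirroring the observation that redox peaks rise with both concentration
  and grade;
* synthetic clinical cohorts with a tunable monotone coupling between each
  clinical variable and grade, for exercising the rank-correlation stage.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .clinical import ClinicalRecord
from .features import Voltammogram

__all__ = [
    "PeakModel",
    "ResponseParams",
    "ClassSpec",
    "concentration_to_peak",
    "simulate_voltammogram",
    "simulate_labeled_dataset",
    "simulate_cohort",
    "default_peak_model",
    "default_response",
    "grade_class_specs",
]


@dataclass(frozen=True)
class PeakModel:
    """Parametric envelope of one simulated sweep.

    ``peak_tau`` > 0 switches the peak to an exponentially modified Gaussian
    (tail decay constant in V, in sweep direction) so that skewness and
    kurtosis can carry class signal; 0 keeps the symmetric Gaussian.
    """

    baseline_intercept: float = 0.05   # µA
    baseline_slope: float = -0.1       # µA per V
    peak_center: float = -0.25         # V
    peak_sd: float = 0.04              # V
    peak_amplitude: float = 0.3        # µA
    noise_sd: float = 0.005            # µA
    n_points: int = 256
    e_start: float = -0.05             # V
    e_end: float = -0.45               # V
    scan_rate: float = 0.05            # V/s
    peak_tau: float = 0.0              # V; 0 = symmetric Gaussian

    def validate(self) -> None:
        problems = []
        if not self.peak_sd > 0:
            problems.append(f"peak_sd must be > 0 (got {self.peak_sd})")
        if self.n_points < 16:
            problems.append(f"n_points must be ≥ 16 (got {self.n_points})")
        if self.e_start == self.e_end:
            problems.append("e_start and e_end must differ")
        if not self.scan_rate > 0:
            problems.append(f"scan_rate must be > 0 (got {self.scan_rate})")
        if self.noise_sd < 0:
            problems.append(f"noise_sd must be ≥ 0 (got {self.noise_sd})")
        if self.peak_tau < 0:
            problems.append(f"peak_tau must be ≥ 0 (got {self.peak_tau})")
        if problems:
            raise ValueError("invalid PeakModel: " + "; ".join(problems))


@dataclass(frozen=True)
class ResponseParams:
    """Linear concentration→amplitude response inside the sensor's range."""

    intercept: float = 0.05    # µA
    slope: float = 0.004       # µA per (U/mL)
    linear_min: float = 5.0    # U/mL
    linear_max: float = 100.0  # U/mL

    def validate(self) -> None:
        if not self.linear_min < self.linear_max:
            raise ValueError(
                f"linear_min ({self.linear_min}) must be < linear_max "
                f"({self.linear_max})"
            )
        if not math.isfinite(self.slope):
            raise ValueError("slope must be finite")


@dataclass(frozen=True)
class ClassSpec:
    """Maps a class label to a concentration distribution.

    Concentrations are lognormal with mean ``concentration_mean`` and
    coefficient of variation ``concentration_cv``; ``nuisance_jitter`` is the
    fractional perturbation applied to peak centre, width and baseline so
    that classes differ by more than amplitude alone.
    """

    label: str
    concentration_mean: float       # U/mL
    concentration_cv: float = 0.25
    nuisance_jitter: float = 0.05

    def validate(self) -> None:
        if self.concentration_mean < 0:
            raise ValueError("concentration_mean must be ≥ 0")
        if self.concentration_cv < 0:
            raise ValueError("concentration_cv must be ≥ 0")


def default_peak_model(**overrides) -> PeakModel:
    """The instrument-window defaults (−0.05 → −0.45 V at 50 mV/s)."""
    return replace(PeakModel(), **overrides)


def default_response(**overrides) -> ResponseParams:
    return replace(ResponseParams(), **overrides)


def grade_class_specs() -> list[ClassSpec]:
    """Control + grade I–III with increasing concentration medians.

    Means span the sensor's linear window: the control sits below the
    5 U/mL quantitation floor, the grades climb toward saturation.
    """
    return [
        ClassSpec("control", 2.0),
        ClassSpec("grade I", 20.0),
        ClassSpec("grade II", 45.0),
        ClassSpec("grade III", 80.0),
    ]


def concentration_to_peak(concentration: float, params: ResponseParams) -> float:
    """Peak amplitude (µA) for a concentration via the clamped linear response.

    Outside [linear_min, linear_max] the response saturates at the boundary
    value, so the map is monotone non-decreasing for positive slope.
    """
    params.validate()
    if concentration < 0:
        raise ValueError(f"concentration must be ≥ 0 (got {concentration})")
    c = min(max(concentration, params.linear_min), params.linear_max)
    return params.intercept + params.slope * c


def simulate_voltammogram(
    model: PeakModel, seed: int | np.random.Generator
) -> Voltammogram:
    """One noisy sweep: baseline + (exponentially modified) Gaussian peak.

    Identical (model, seed) pairs reproduce bit-identical traces.
    """
    model.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pot = np.linspace(model.e_start, model.e_end, model.n_points)
    z = (pot - model.peak_center) / model.peak_sd
    if model.peak_tau > 0:
        # Exponentially modified Gaussian, exponent in sweep direction.
        s = np.sign(model.e_end - model.e_start)
        tau = model.peak_tau
        sig = model.peak_sd
        arg = sig / tau * 0.7071067811865476  # sigma/(tau*sqrt2)
        u = s * (pot - model.peak_center) / (sig * 1.4142135623730951)
        from scipy.special import erfc

        shape = (
            0.5 * sig / tau
            * np.exp(0.5 * (sig / tau) ** 2 - s * (pot - model.peak_center) / tau)
            * erfc(arg - u)
        )
        peak = model.peak_amplitude * shape / max(shape.max(), 1e-300)
    else:
        peak = model.peak_amplitude * np.exp(-0.5 * z * z)
    current = (
        model.baseline_intercept
        + model.baseline_slope * pot
        + peak
        + rng.normal(0.0, model.noise_sd, size=model.n_points)
    )
    return Voltammogram(
        potential=pot,
        current=current,
        scan_rate=model.scan_rate,
        meta={"peak_center": model.peak_center, "peak_sd": model.peak_sd},
    )


def simulate_labeled_dataset(
    class_specs: list[ClassSpec],
    n_per_class: int | Sequence[int],
    params: ResponseParams | None = None,
    base_model: PeakModel | None = None,
    seed: int = 0,
) -> tuple[list[Voltammogram], list[str]]:
    """Labelled traces, ``n_per_class`` per class (scalar or per-class list);
    each trace's amplitude comes from its class's concentration draw."""
    if not class_specs:
        raise ValueError("need at least one class spec")
    if len(class_specs) < 2:
        raise ValueError("need at least two classes for a labelled dataset")
    counts = (
        [int(n_per_class)] * len(class_specs)
        if isinstance(n_per_class, int)
        else [int(c) for c in n_per_class]
    )
    if len(counts) != len(class_specs):
        raise ValueError("per-class counts must align with class_specs")
    if min(counts) < 1:
        raise ValueError("n_per_class must be ≥ 1")
    params = params or ResponseParams()
    base_model = base_model or PeakModel()
    params.validate()
    base_model.validate()
    rng = np.random.default_rng(seed)
    traces: list[Voltammogram] = []
    labels: list[str] = []
    for spec, count in zip(class_specs, counts):
        spec.validate()
        for _ in range(count):
            conc = _draw_concentration(spec, rng)
            amp = concentration_to_peak(conc, params)
            j = spec.nuisance_jitter
            model = replace(
                base_model,
                peak_amplitude=amp,
                peak_center=base_model.peak_center
                * (1 + j * rng.uniform(-1, 1)),
                peak_sd=base_model.peak_sd * (1 + j * rng.uniform(-1, 1)),
                baseline_intercept=base_model.baseline_intercept
                * (1 + j * rng.uniform(-1, 1)),
            )
            vg = simulate_voltammogram(model, rng)
            vg.meta.update(label=spec.label, concentration=conc)
            traces.append(vg)
            labels.append(spec.label)
    return traces, labels


def _draw_concentration(spec: ClassSpec, rng: np.random.Generator) -> float:
    if spec.concentration_cv == 0 or spec.concentration_mean == 0:
        return spec.concentration_mean
    sigma2 = math.log1p(spec.concentration_cv**2)
    mu = math.log(spec.concentration_mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


# ---------------------------------------------------------------------------
# Synthetic clinical cohorts

#: Cohort variables and their category values (ordered low→high).
_COHORT_LEVELS = {
    "location": (3, 4, 5),
    "size": (1, 2),
    "lymph_node": (0, 1),
    "lung": (0, 1),
    "muc1": (0, 1, 2, 3),
}
#: Marginal probabilities matching the packaged cohort's rough shape.
_COHORT_MARGINALS = {
    "location": (0.2, 0.3, 0.5),
    "size": (0.6, 0.4),
    "lymph_node": (0.65, 0.35),
    "lung": (0.85, 0.15),
    "muc1": (0.35, 0.40, 0.10, 0.15),
}


def simulate_cohort(
    n: int,
    assoc: dict[str, float] | float | None = None,
    seed: int = 0,
) -> list[ClinicalRecord]:
    """Synthetic cohort with monotone variable↔grade coupling.

    ``assoc`` maps variable name → coupling in [−1, 1] (a scalar applies to
    all variables).  Coupling works through a Gaussian copula: each
    variable's latent score is ``a·z_grade + sqrt(1−a²)·ε`` and is then cut
    at the variable's marginal quantiles, so 0 gives independence and values
    near ±1 give strong monotone association in rank terms.
    """
    if n < 3:
        raise ValueError(f"cohort size must be ≥ 3 (got {n})")
    if assoc is None:
        assoc = {}
    if isinstance(assoc, (int, float)):
        assoc = {name: float(assoc) for name in _COHORT_LEVELS}
    for name, a in assoc.items():
        if name not in _COHORT_LEVELS:
            raise ValueError(f"unknown cohort variable '{name}'")
        if not -1.0 <= a <= 1.0:
            raise ValueError(f"coupling for '{name}' outside [-1, 1]: {a}")
    rng = np.random.default_rng(seed)
    grades = rng.integers(1, 4, size=n)
    z_grade = (grades - grades.mean()) / max(grades.std(), 1e-12)
    records = []
    draws = {}
    for name, levels in _COHORT_LEVELS.items():
        a = assoc.get(name, 0.0)
        latent = a * z_grade + math.sqrt(1.0 - a * a) * rng.normal(size=n)
        cuts = np.quantile(latent, np.cumsum(_COHORT_MARGINALS[name])[:-1])
        draws[name] = np.asarray(levels)[np.searchsorted(cuts, latent)]
    ages = np.clip(np.round(rng.normal(11.0, 1.8, size=n)), 6, 16).astype(int)
    weights = np.clip(np.round(rng.normal(17.5, 8.0, size=n), 1), 3.0, 60.0)
    sides = rng.choice(["L", "R"], size=n)
    for i in range(n):
        records.append(
            ClinicalRecord(
                case_id=i + 1,
                age=int(ages[i]),
                breed="Synthetic",
                weight=float(weights[i]),
                side=str(sides[i]),
                lobe=int(draws["location"][i]),
                t_stage=int(draws["size"][i]),
                n_stage=int(draws["lymph_node"][i]),
                m_stage=int(draws["lung"][i]),
                grade=int(grades[i]),
                siln_metastasis=int(draws["lymph_node"][i]),
                muc1_score=int(draws["muc1"][i]),
                is_control=False,
            )
        )
    return records
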