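"""The 17-case canine mammary-tumor cohort and its rank-correlation analysis.

Ships the published clinical/histopathological tables as a package fixture
(17 malignant cases plus one healthy control) and reproduces the Spearman
correlation of each clinical variable against histological grade, together
with the descriptive cohort summary.

Variable coding for the correlation analysis (the coding that reproduces the
published coefficients): location = mammary lobe number (3 cranioabdominal,
4 caudoabdominal, 5 inguinal), size = T stage (1/2), lymph-node and lung
metastasis = binary N/M, MUC-1 = immunohistochemistry score 0–3, grade =
1–3.  The control animal is excluded (n = 17).
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClinicalRecord",
    "CorrelationResult",
    "CLINICAL_VARIABLES",
    "load_packaged_cohort",
    "encode_cohort",
    "spearman",
    "correlation_table",
    "cohort_summary",
]

#: Clinical variables correlated against grade, in report order.
CLINICAL_VARIABLES = ("location", "size", "lymph_node", "lung", "muc1")

#: SHA-256 of the packaged cohort CSV; guards against silent fixture edits.
_COHORT_SHA256 = "78655e8e551e7588257a674e7595f81385ca5c346be08aacbaff96db3d6e5fbf"

_STAGING_RE = re.compile(
    r"^\s*(?P<side>[LR])\s*(?P<lobe>[345])\s*/\s*"
    r"(?:T(?P<t>[12])N(?P<n>[01])M(?P<m>[01])|-)\s*$"
)


class CohortIntegrityError(RuntimeError):
    """Packaged cohort file does not match its recorded checksum."""


@dataclass(frozen=True)
class ClinicalRecord:
    """One cohort animal; staging fields are None only for the control."""

    case_id: int
    age: int
    breed: str
    weight: float
    side: str
    lobe: int
    t_stage: int | None
    n_stage: int | None
    m_stage: int | None
    grade: int | None
    siln_metastasis: int
    muc1_score: int | None
    is_control: bool = False

    def __post_init__(self) -> None:
        if not self.is_control:
            missing = [
                name
                for name in ("t_stage", "n_stage", "m_stage", "grade", "muc1_score")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(
                    f"case {self.case_id}: tumour record missing {missing}"
                )
            if self.grade not in (1, 2, 3):
                raise ValueError(f"case {self.case_id}: grade must be 1–3")
        if self.lobe not in (3, 4, 5):
            raise ValueError(f"case {self.case_id}: lobe must be 3, 4 or 5")


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho with its two-sided p-value and significance label."""

    rho: float
    p_value: float
    n: int
    label: str  # NS (p > 0.05), + (p ≤ 0.05), ++ (p ≤ 0.01)

    @staticmethod
    def significance_label(p: float) -> str:
        if p <= 0.01:
            return "++"
        if p <= 0.05:
            return "+"
        return "NS"


def _parse_staging(text: str) -> dict:
    m = _STAGING_RE.match(text)
    if m is None:
        raise ValueError(f"unparseable location/staging string: {text!r}")
    return {
        "side": m["side"],
        "lobe": int(m["lobe"]),
        "t_stage": int(m["t"]) if m["t"] else None,
        "n_stage": int(m["n"]) if m["n"] else None,
        "m_stage": int(m["m"]) if m["m"] else None,
    }


def load_packaged_cohort(verify_checksum: bool = True) -> list[ClinicalRecord]:
    """Load the packaged 17-case + control cohort fixture.

    The fixture transcribes the published clinical and histopathology
    tables; a checksum mismatch raises ``CohortIntegrityError``.
    """
    ref = resources.files("voltgrade.data").joinpath("canine_cohort.csv")
    raw = ref.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _COHORT_SHA256:
            raise CohortIntegrityError(
                f"cohort fixture checksum mismatch: {digest}"
            )
    frame = pd.read_csv(ref)
    records = []
    for row in frame.itertuples(index=False):
        staging = _parse_staging(row.staging)
        control = bool(row.is_control)
        records.append(
            ClinicalRecord(
                case_id=int(row.case_id),
                age=int(row.age_years),
                breed=row.breed,
                weight=float(row.weight_kg),
                grade=None if control else int(row.grade),
                siln_metastasis=int(row.siln_metastasis),
                muc1_score=None if control else int(row.muc1_score),
                is_control=control,
                **staging,
            )
        )
    tumours = [r for r in records if not r.is_control]
    if len(tumours) != 17 or len(records) - len(tumours) != 1:
        raise CohortIntegrityError(
            f"expected 17 tumour cases + 1 control, found {len(tumours)}"
            f" + {len(records) - len(tumours)}"
        )
    for r in tumours:
        if r.n_stage != r.siln_metastasis:
            raise CohortIntegrityError(
                f"case {r.case_id}: N stage and SILN metastasis disagree"
            )
    return records


def encode_cohort(
    records: list[ClinicalRecord],
    coding: str = "default",
    include_control: bool = False,
) -> pd.DataFrame:
    """Numeric matrix (location, size, lymph_node, lung, muc1, grade).

    Only the ``default`` coding is defined: lobe number, T stage, binary
    N/M, 0–3 IHC score, 1–3 grade.  The control is excluded by default and
    carries NaN where its fields are undefined.
    """
    if coding != "default":
        raise KeyError(f"unknown coding '{coding}' (known: 'default')")
    rows = []
    for r in records:
        if r.is_control and not include_control:
            continue
        rows.append(
            {
                "case_id": r.case_id,
                "location": r.lobe,
                "size": np.nan if r.t_stage is None else r.t_stage,
                "lymph_node": np.nan if r.n_stage is None else r.n_stage,
                "lung": np.nan if r.m_stage is None else r.m_stage,
                "muc1": np.nan if r.muc1_score is None else r.muc1_score,
                "grade": np.nan if r.grade is None else r.grade,
            }
        )
    return pd.DataFrame(rows).set_index("case_id")


def _rank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    # Pearson correlation of tie-averaged ranks, written so that the
    # expression is symmetric in (x, y) to the last ulp.
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float(np.sum(dx * dy) / math.sqrt(np.sum(dx * dx) * np.sum(dy * dy)))


def spearman(x, y, method: str = "t") -> CorrelationResult:
    """Spearman rank correlation with tie-averaged ranks.

    ``method='t'`` (default) computes the two-sided p-value from
    ``t = rho·sqrt((n−2)/(1−rho²))`` on n−2 degrees of freedom, the
    approximation that reproduces the published table; ``'permutation'``
    runs an exact/Monte-Carlo permutation test for small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations (got {n})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = _rank_pearson(x, y)
    if method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    elif method == "permutation":
        res = stats.permutation_test(
            (x,),
            lambda xs: _rank_pearson(np.asarray(xs), y),
            permutation_type="pairings",
            n_resamples=9999,
            alternative="two-sided",
            rng=np.random.default_rng(0),
        )
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown p-value method '{method}'")
    return CorrelationResult(
        rho=float(rho),
        p_value=float(p),
        n=int(n),
        label=CorrelationResult.significance_label(float(p)),
    )


def correlation_table(
    records: list[ClinicalRecord],
    coding: str = "default",
    method: str = "t",
) -> pd.DataFrame:
    """Per-variable Spearman correlation against grade (control excluded).

    Returns a DataFrame indexed by variable with columns
    ``rho, p_value, n, label``; rho and p are reported to three decimals.
    """
    matrix = encode_cohort(records, coding=coding, include_control=False)
    rows = {}
    for name in CLINICAL_VARIABLES:
        res = spearman(matrix[name], matrix["grade"], method=method)
        rows[name] = {
            "rho": round(res.rho, 3),
            "p_value": round(res.p_value, 3),
            "n": res.n,
            "label": res.label,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def cohort_summary(records: list[ClinicalRecord]) -> dict:
    """Descriptive statistics of the tumour cases (control excluded).

    Note: the published text labels the age figure a "median" although the
    printed numbers equal the arithmetic mean ± SD; both are reported here.
    The MUC-1 "stained" count uses score > 0.
    """
    tumours = [r for r in records if not r.is_control]
    if not tumours:
        raise ValueError("cohort summary needs at least one tumour record")
    ages = np.array([r.age for r in tumours], dtype=float)
    weights = np.array([r.weight for r in tumours], dtype=float)
    lobes = [r.lobe for r in tumours]
    grades = [r.grade for r in tumours]
    sd = lambda v: float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return {
        "n": len(tumours),
        "age_mean": float(ages.mean()),
        "age_sd": sd(ages),
        "age_median": float(np.median(ages)),
        "weight_mean": float(weights.mean()),
        "weight_sd": sd(weights),
        "lobe_counts": {lobe: lobes.count(lobe) for lobe in (5, 4, 3)},
        "siln_positive": sum(r.siln_metastasis for r in tumours),
        "muc1_stained": sum(1 for r in tumours if (r.muc1_score or 0) > 0),
        "grade_counts": {g: grades.count(g) for g in (1, 2, 3)},
    }
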