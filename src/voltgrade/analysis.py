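"""Feature ranking: rank correlation with grade and forest importance.

Two complementary views of which CV descriptors carry grade information:
per-feature Spearman correlation against the ordinal grade, and
impurity-based importance from a seeded random forest.  Feature selection
applies a fixed importance cutoff (0.08 in the published analysis) with a
strict inequality — a feature must *surpass* the threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from importlib import resources
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .clinical import CorrelationResult, spearman
from .features import FEATURE_NAMES

__all__ = [
    "feature_target_correlations",
    "rf_importance",
    "select_features",
    "load_printed_importances",
    "load_printed_correlations",
    "IMPORTANCE_THRESHOLD",
]

#: Published feature-selection cutoff on normalized forest importance.
IMPORTANCE_THRESHOLD = 0.08


def _as_feature_frame(feature_matrix) -> pd.DataFrame:
    frame = pd.DataFrame(feature_matrix)
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if missing and len(frame.columns) == len(FEATURE_NAMES):
        frame.columns = list(FEATURE_NAMES)
    elif missing:
        raise ValueError(f"feature matrix missing columns: {missing}")
    return frame[list(FEATURE_NAMES)]


def feature_target_correlations(feature_matrix, grades) -> pd.DataFrame:
    """Spearman rho of every descriptor against grade, sorted by rho.

    Constant feature columns are kept in the table but flagged
    ``undefined`` with NaN rho rather than silently dropped.
    """
    frame = _as_feature_frame(feature_matrix)
    grades = np.asarray(grades, dtype=float)
    if len(frame) != grades.size:
        raise ValueError("grades length does not match feature matrix")
    if len(frame) < 3:
        raise ValueError("need at least 3 samples for correlation analysis")
    rows = {}
    for name in FEATURE_NAMES:
        col = frame[name].to_numpy(float)
        if np.ptp(col) == 0:
            rows[name] = {"rho": np.nan, "p_value": np.nan,
                          "n": grades.size, "label": "undefined"}
            continue
        res: CorrelationResult = spearman(col, grades)
        rows[name] = {"rho": res.rho, "p_value": res.p_value,
                      "n": res.n, "label": res.label}
    table = pd.DataFrame.from_dict(rows, orient="index")
    return table.sort_values("rho", ascending=False, na_position="last")


def rf_importance(
    feature_matrix,
    labels,
    n_trees: int = 500,
    seed: int = 0,
    method: str = "impurity",
) -> pd.DataFrame:
    """Normalized random-forest feature importances with 1-based ranks.

    ``method='impurity'`` is the mean-decrease-in-impurity score native to
    the forest; ``'permutation'`` scores out-of-sample shuffling loss on the
    training data instead.  Scores are normalized to sum to 1 and returned
    as a DataFrame indexed by feature with columns ``importance, rank``.
    """
    frame = _as_feature_frame(feature_matrix)
    y = np.asarray(labels)
    if frame.shape[0] < 6:
        raise ValueError("need at least 6 samples to estimate importances")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(frame.to_numpy(), y)
    if method == "impurity":
        scores = forest.feature_importances_
    elif method == "permutation":
        scores = permutation_importance(
            forest, frame.to_numpy(), y, n_repeats=10, random_state=seed
        ).importances_mean
        scores = np.clip(scores, 0.0, None)
    else:
        raise ValueError(f"unknown importance method '{method}'")
    total = scores.sum()
    if total <= 0:
        raise ValueError("degenerate importances: all scores zero")
    scores = scores / total
    table = pd.DataFrame({"importance": scores}, index=list(FEATURE_NAMES))
    table["rank"] = (
        table["importance"].rank(ascending=False, method="first").astype(int)
    )
    return table.sort_values("rank")


def select_features(importances: pd.DataFrame, threshold: float) -> list[str]:
    """Features whose importance strictly exceeds ``threshold``, rank order."""
    if threshold < 0:
        raise ValueError(f"threshold must be ≥ 0 (got {threshold})")
    if "importance" not in importances.columns:
        raise ValueError("importance table must have an 'importance' column")
    table = importances
    if "rank" in table.columns:
        table = table.sort_values("rank")
    return [
        str(name)
        for name, row in table.iterrows()
        if row["importance"] > threshold
    ]


def load_printed_importances() -> pd.DataFrame:
    """Published importance table (both biomarkers), as a package fixture.

    Indexed by canonical feature name with columns
    ``rank, importance_ca15_3, importance_muc1``.  Shipped for schema and
    selection-logic tests; the raw CV dataset behind it was not deposited.
    """
    ref = resources.files("voltgrade.data").joinpath("printed_importances.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path).set_index("feature")


def load_printed_correlations() -> pd.DataFrame:
    """Published feature–grade correlation table for both biomarkers."""
    ref = resources.files("voltgrade.data").joinpath(
        "printed_feature_correlations.csv"
    )
    with resources.as_file(ref) as path:
        return pd.read_csv(path).set_index("feature")
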