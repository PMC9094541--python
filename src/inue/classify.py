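"""High/Low classification of per-site iNUE decline from weather and soil.

Each screened site-year has a per-kg iNUE slope ``2 * a * k`` (k = grain
N content), expressed in percentage points per kg N — a negative number
whose magnitude measures how fast efficiency declines with fertilization.
Sites are labelled "High" (fast decline) or "Low" against the ensemble
median of the magnitudes, and a random forest or decision tree is trained
to predict the label from windowed weather features and soil covariates:
60/40 train/validation split, hyperparameters tuned by 10-fold
cross-validation repeated 5 times (50 tuning folds), accuracy = correct /
total on the held-out portion, importance by mean Gini decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score
from sklearn.model_selection import GridSearchCV, RepeatedKFold, train_test_split
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier, export_text

__all__ = [
    "SlopeLabelSet",
    "CVProtocol",
    "ProtocolResult",
    "label_slopes",
    "run_protocol",
    "coefficient_relationships",
]

DEFAULT_FOREST_GRID = {"max_features": ["sqrt", 0.3, 0.6]}
DEFAULT_TREE_GRID = {
    "max_depth": [2, 3, 4, 5],
    "min_samples_split": [2, 10, 20],
    "min_samples_leaf": [1, 5, 10],
    "ccp_alpha": [0.0, 0.005, 0.02],
}


@dataclass
class SlopeLabelSet:
    """Signed slopes, their magnitudes and High/Low labels.

    ``threshold`` keeps the signed convention (slopes are negative);
    comparisons are on magnitudes: |slope| strictly above the threshold
    magnitude is "High", ties go to "Low".
    """

    table: pd.DataFrame  # columns: slope, magnitude, label
    threshold: float  # signed
    threshold_magnitude: float

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]


def label_slopes(slopes: pd.Series, threshold: Optional[float] = None) -> SlopeLabelSet:
    """Label per-site iNUE slopes High/Low against a median threshold.

    ``slopes`` are the signed per-kg declines (grain-N percentage points
    per kg N). When ``threshold`` is omitted the ensemble median of the
    magnitudes is used, which balances the classes to within one site.
    """
    slopes = pd.Series(slopes, dtype=float)
    if len(slopes) < 2:
        raise ValueError("need at least 2 sites to label")
    mags = slopes.abs()
    if threshold is None:
        if mags.nunique() == 1:
            raise ValueError("all slopes identical: median split is degenerate")
        thr_mag = float(mags.median())
    else:
        thr_mag = abs(float(threshold))
    labels = np.where(mags > thr_mag, "High", "Low")
    table = pd.DataFrame({"slope": slopes, "magnitude": mags, "label": labels})
    return SlopeLabelSet(table=table, threshold=-thr_mag, threshold_magnitude=thr_mag)


@dataclass
class CVProtocol:
    """Split and tuning protocol for the slope classifiers."""

    train_fraction: float = 0.60
    folds: int = 10
    repeats: int = 5
    seed: int = 0
    stratified: bool = False  # simple random split by default
    n_estimators: int = 300

    @property
    def n_tuning_folds(self) -> int:
        return self.folds * self.repeats


@dataclass
class ProtocolResult:
    """Fitted model, held-out accuracy and importance ranking."""

    model_type: str
    estimator: object
    accuracy: float
    cv_mean_accuracy: float
    best_params: dict
    importances: pd.Series  # Gini decrease, descending
    n_tuning_folds: int
    train_index: np.ndarray
    test_index: np.ndarray
    rules: Optional[str] = None  # human-readable tree paths
    cv_results: dict = field(default_factory=dict, repr=False)


def _encode(features: pd.DataFrame) -> pd.DataFrame:
    X = pd.get_dummies(features, dtype=float)
    return X.reindex(sorted(X.columns), axis=1)


def run_protocol(
    features: pd.DataFrame,
    labels: pd.Series,
    protocol: CVProtocol = CVProtocol(),
    model: str = "forest",
    param_grid: Optional[dict] = None,
) -> ProtocolResult:
    """Train, tune and validate a High/Low slope classifier.

    Splits 60/40 by the protocol seed, tunes hyperparameters with
    repeated k-fold CV on the training portion (highest mean accuracy
    over all folds wins), then reports accuracy on the held-out 40% and
    the Gini importance ranking. Fully reproducible from the seed.
    """
    if model not in ("forest", "tree"):
        raise ValueError("model must be 'forest' or 'tree'")
    X = _encode(features)
    if X.isna().any().any():
        raise ValueError("missing feature values; impute or drop upstream")
    y = pd.Series(labels).astype(str).to_numpy()
    idx = np.arange(len(X))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=protocol.train_fraction,
        random_state=protocol.seed,
        shuffle=True,
        stratify=y if protocol.stratified else None,
    )
    y_train = y[train_idx]
    if len(np.unique(y_train)) < 2:
        raise ValueError(
            "one class absent from the training split; re-seed or enable "
            "stratification"
        )
    if model == "forest":
        est = RandomForestClassifier(
            n_estimators=protocol.n_estimators, random_state=protocol.seed
        )
        grid = param_grid if param_grid is not None else DEFAULT_FOREST_GRID
    else:
        est = DecisionTreeClassifier(random_state=protocol.seed)
        grid = param_grid if param_grid is not None else DEFAULT_TREE_GRID
    cv = RepeatedKFold(
        n_splits=protocol.folds,
        n_repeats=protocol.repeats,
        random_state=protocol.seed,
    )
    search = GridSearchCV(est, grid, scoring="accuracy", cv=cv, refit=True)
    search.fit(X.iloc[train_idx], y_train)
    best = search.best_estimator_
    accuracy = float(accuracy_score(y[test_idx], best.predict(X.iloc[test_idx])))
    importances = pd.Series(
        best.feature_importances_, index=X.columns, name="gini_importance"
    ).sort_values(ascending=False)
    rules = None
    if model == "tree":
        rules = export_text(best, feature_names=list(X.columns))
    return ProtocolResult(
        model_type=model,
        estimator=best,
        accuracy=accuracy,
        cv_mean_accuracy=float(search.best_score_),
        best_params=dict(search.best_params_),
        importances=importances,
        n_tuning_folds=cv.get_n_splits(),
        train_index=train_idx,
        test_index=test_idx,
        rules=rules,
        cv_results={k: v for k, v in search.cv_results_.items() if k.startswith(("mean_", "param"))},
    )


def coefficient_relationships(fits_df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise r-squared among QP coefficients (a, b, c) and EONR.

    ``fits_df`` needs numeric columns ``a, b, c, eonr``. Pairs with
    degenerate variance are omitted.
    """
    cols = [c for c in ("a", "b", "c", "eonr") if c in fits_df.columns]
    if len(fits_df) < 3:
        raise ValueError("need >= 3 screened fits")
    rows = []
    for v1, v2 in combinations(cols, 2):
        x = fits_df[v1].to_numpy(dtype=float)
        y = fits_df[v2].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"var1": v1, "var2": v2, "r": r, "r2": r * r})
    return pd.DataFrame(rows)
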