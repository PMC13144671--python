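"""Per-feature nine-class classifiers (healthy + eight cancer types) with
cross-validated candidate selection by macro one-vs-rest AUC."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

__all__ = [
    "CLASS_ORDER",
    "DEFAULT_CANDIDATES",
    "ModelBundle",
    "select_best_model",
    "predict_proba",
    "oof_proba",
    "feature_csd_score",
    "conditional_too_proba",
]

# healthy first, then the eight cancer types in fixed alphabetical order
CLASS_ORDER = (
    "healthy", "breast", "colorectal", "gastric", "liver",
    "lung", "ovarian", "pancreatic", "prostate",
)
DEFAULT_CANDIDATES = ("logreg", "rf", "gboost", "svm_linear")


def _make_candidate(name: str, seed: int):
    if name == "logreg":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=3000, C=1.0, random_state=seed),
        )
    if name == "rf":
        return RandomForestClassifier(n_estimators=150, random_state=seed, n_jobs=1)
    if name == "gboost":
        return HistGradientBoostingClassifier(max_iter=60, random_state=seed)
    if name == "svm_linear":
        svc = LinearSVC(C=1.0, random_state=seed, max_iter=5000)
        return make_pipeline(
            StandardScaler(),
            CalibratedClassifierCV(svc, cv=3, method="sigmoid"),
        )
    raise ValueError(f"unknown candidate {name!r}")


@dataclass
class ModelBundle:
    namespace: str  # amf | cnv | fsr | fsd
    algorithm: str
    model: object
    classes: tuple
    folds: int
    fold_aucs: list[float]
    mean_auc: float
    candidate_aucs: dict = field(default_factory=dict)
    training_ids: list[str] = field(default_factory=list)
    feature_columns: list[str] = field(default_factory=list)
    seed: int = 0


def _macro_ovr_auc(y_true: np.ndarray, proba: np.ndarray, classes) -> float:
    """Mean one-vs-rest AUC over classes present with both outcomes."""
    aucs = []
    for k, cls in enumerate(classes):
        pos = (y_true == cls)
        if pos.any() and (~pos).any():
            aucs.append(roc_auc_score(pos, proba[:, k]))
    if not aucs:
        return float("nan")
    return float(np.mean(aucs))


def _aligned_proba(model, X: np.ndarray, classes) -> np.ndarray:
    raw = model.predict_proba(X)
    out = np.zeros((raw.shape[0], len(classes)))
    pos = {c: i for i, c in enumerate(model.classes_)}
    for k, cls in enumerate(classes):
        if cls in pos:
            out[:, k] = raw[:, pos[cls]]
    # renormalize in case some class was absent from training
    out /= out.sum(axis=1, keepdims=True)
    return out


def select_best_model(
    features: pd.DataFrame,
    labels: pd.Series,
    candidates=DEFAULT_CANDIDATES,
    folds: int = 4,
    seed: int = 0,
    namespace: str = "",
) -> ModelBundle:
    """Stratified k-fold CV per candidate; select by mean macro OvR AUC.

    Ties break by candidate order; the winner is refit on all the data.
    Every class must have at least ``folds`` members.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list must be non-empty")
    labels = labels.loc[features.index]
    counts = labels.value_counts()
    small = counts[counts < folds]
    if not small.empty:
        raise ValueError(
            f"class {small.index[0]!r} has {int(small.iloc[0])} samples; "
            f"need at least {folds} per class"
        )
    classes = tuple(c for c in CLASS_ORDER if c in set(labels))
    X = features.to_numpy(dtype=float)
    y = labels.to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    candidate_aucs: dict[str, tuple[float, list[float]]] = {}
    for name in candidates:
        fold_aucs = []
        for tr, te in splits:
            model = _make_candidate(name, seed)
            model.fit(X[tr], y[tr])
            proba = _aligned_proba(model, X[te], classes)
            fold_aucs.append(_macro_ovr_auc(y[te], proba, classes))
        candidate_aucs[name] = (float(np.nanmean(fold_aucs)), fold_aucs)

    # first candidate reaching the best mean AUC wins (order-stable tie-break)
    best_auc = max(v[0] for v in candidate_aucs.values())
    best = next(n for n in candidates if candidate_aucs[n][0] >= best_auc - 1e-12)

    final = _make_candidate(best, seed)
    final.fit(X, y)
    return ModelBundle(
        namespace=namespace,
        algorithm=best,
        model=final,
        classes=classes,
        folds=folds,
        fold_aucs=candidate_aucs[best][1],
        mean_auc=candidate_aucs[best][0],
        candidate_aucs={k: v[0] for k, v in candidate_aucs.items()},
        training_ids=list(features.index),
        feature_columns=list(features.columns),
        seed=seed,
    )


def predict_proba(bundle: ModelBundle, features: pd.DataFrame) -> pd.DataFrame:
    """Class probabilities in the bundle's class order; rows sum to 1."""
    if list(features.columns) != bundle.feature_columns:
        raise ValueError(f"feature columns do not match the {bundle.namespace} bundle")
    proba = _aligned_proba(bundle.model, features.to_numpy(dtype=float), bundle.classes)
    return pd.DataFrame(proba, index=features.index, columns=list(bundle.classes))


def oof_proba(bundle: ModelBundle, features: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Out-of-fold probabilities for the bundle's training samples, using the
    same algorithm, fold count and seed as model selection. Keeps downstream
    meta-model fitting leakage-free."""
    labels = labels.loc[features.index]
    X = features.to_numpy(dtype=float)
    y = labels.to_numpy()
    skf = StratifiedKFold(n_splits=bundle.folds, shuffle=True, random_state=bundle.seed)
    out = np.zeros((len(features), len(bundle.classes)))
    for tr, te in skf.split(X, y):
        model = _make_candidate(bundle.algorithm, bundle.seed)
        model.fit(X[tr], y[tr])
        out[te] = _aligned_proba(model, X[te], bundle.classes)
    return pd.DataFrame(out, index=features.index, columns=list(bundle.classes))


def feature_csd_score(proba: pd.DataFrame) -> pd.Series:
    """Cancer-signal score: cumulative cancer probability = 1 - p(healthy)."""
    if "healthy" not in proba.columns:
        raise ValueError("probability matrix lacks a healthy column")
    return 1.0 - proba["healthy"]


def conditional_too_proba(proba: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Cancer-class probabilities renormalized to sum to one.

    Rows where every cancer probability is zero fall back to uniform 1/8 and
    are flagged in the returned boolean series.
    """
    cancer_cols = [c for c in proba.columns if c != "healthy"]
    sub = proba[cancer_cols].to_numpy(dtype=float)
    totals = sub.sum(axis=1)
    flagged = totals == 0
    safe = np.where(flagged, 1.0, totals)
    cond = sub / safe[:, None]
    cond[flagged] = 1.0 / len(cancer_cols)
    return (pd.DataFrame(cond, index=proba.index, columns=cancer_cols),
            pd.Series(flagged, index=proba.index))
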