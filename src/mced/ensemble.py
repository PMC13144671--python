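"""The cancer-signature ensemble: a logistic meta-model over logit-normalized
per-feature scores plus age and sex, with a specificity-calibrated decision
threshold; weighted conditional-probability aggregation for tissue-of-origin
with top-1/top-2 calls and an ambiguity ("in between") rule; and evaluation
metrics with Wilson confidence intervals."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "FEATURES",
    "EnsembleModel",
    "logit",
    "fit_cse_csd",
    "predict_csd",
    "calibrate_threshold",
    "predict_too",
    "evaluate",
]

FEATURES = ("amf", "cnv", "fsr", "fsd")


def logit(p, eps: float = 1e-6):
    """log(p/(1-p)) with p clipped into [eps, 1-eps]; accepts arrays."""
    if not (0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    clipped = np.clip(arr, eps, 1 - eps)
    out = np.log(clipped / (1 - clipped))
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(out)
    return out


@dataclass
class EnsembleModel:
    coef: np.ndarray  # over (logit per-feature scores..., age, sex)
    intercept: float
    feature_names: tuple
    threshold: float
    target_specificity: float
    too_weights: dict
    delta: float
    eps: float
    design_sd: np.ndarray | None = None  # train sd per design column
    training_ids: list[str] = field(default_factory=list)

    def standardized_coef(self) -> dict:
        """Coefficients scaled by each design column's training sd, making
        per-feature weights comparable across differently spread inputs."""
        if self.design_sd is None:
            raise ValueError("model lacks design-column statistics")
        names = list(self.feature_names) + ["age", "sex"]
        return dict(zip(names, self.coef * self.design_sd))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "coef": list(map(float, self.coef)),
                "intercept": float(self.intercept),
                "feature_names": list(self.feature_names),
                "threshold": float(self.threshold),
                "target_specificity": float(self.target_specificity),
                "too_weights": {k: float(v) for k, v in self.too_weights.items()},
                "delta": float(self.delta),
                "eps": float(self.eps),
                "design_sd": None if self.design_sd is None else list(map(float, self.design_sd)),
                "training_ids": list(self.training_ids),
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EnsembleModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
            feature_names=tuple(d["feature_names"]),
            threshold=float(d["threshold"]),
            target_specificity=float(d["target_specificity"]),
            too_weights=d["too_weights"],
            delta=float(d["delta"]),
            eps=float(d["eps"]),
            design_sd=(None if d.get("design_sd") is None
                       else np.asarray(d["design_sd"], dtype=float)),
            training_ids=list(d.get("training_ids", [])),
        )


def _design(feature_scores: pd.DataFrame, age, sex, feature_names, eps: float) -> np.ndarray:
    missing = [f for f in feature_names if f not in feature_scores.columns]
    if missing:
        raise ValueError(f"missing feature scores: {missing}")
    na = feature_scores[list(feature_names)].isna()
    if na.any().any():
        bad = feature_scores.index[na.any(axis=1)][0]
        raise ValueError(f"missing feature score for sample {bad!r} (no imputation)")
    X = logit(feature_scores[list(feature_names)].to_numpy(dtype=float), eps)
    age = np.asarray(age, dtype=float).reshape(-1, 1)
    sex = np.asarray(sex, dtype=float).reshape(-1, 1)
    return np.hstack([X, age, sex])


def calibrate_threshold(healthy_scores: np.ndarray, target_spec: float) -> float:
    """Smallest observed score t with P(train-healthy score > t) <= 1 - target."""
    h = np.sort(np.asarray(healthy_scores, dtype=float))
    if h.size == 0:
        raise ValueError("no healthy scores to calibrate on")
    budget = 1.0 - target_spec
    for t in h:
        if np.mean(h > t) <= budget:
            return float(t)
    return float(h[-1])


def fit_cse_csd(
    feature_scores: pd.DataFrame,
    age,
    sex,
    labels,
    target_spec: float = 0.95,
    seed: int = 0,
    feature_names=FEATURES,
    eps: float = 1e-6,
    too_weights: dict | None = None,
    delta: float = 0.07,
) -> EnsembleModel:
    """Fit the logistic meta-model and calibrate its decision threshold.

    ``labels`` is binary (1 = cancer). The threshold is chosen so that the
    fraction of training healthy samples scoring strictly above it is at most
    ``1 - target_spec`` (smallest such observed score).
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to fit the ensemble")
    X = _design(feature_scores, age, sex, feature_names, eps)
    # fit on z-scored columns so the ridge penalty treats the differently
    # scaled logit/age/sex covariates symmetrically, then fold the scaling
    # back into raw-scale coefficients (same model, comparable weights)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    clf = LogisticRegression(max_iter=5000, random_state=seed)
    clf.fit((X - mean) / sd_safe, y)
    coef_std = clf.coef_.ravel()
    coef_raw = coef_std / sd_safe
    intercept = float(clf.intercept_[0] - np.dot(coef_std, mean / sd_safe))
    scores = 1.0 / (1.0 + np.exp(-(X @ coef_raw + intercept)))
    threshold = calibrate_threshold(scores[y == 0], target_spec)
    return EnsembleModel(
        coef=coef_raw.copy(),
        intercept=intercept,
        feature_names=tuple(feature_names),
        threshold=threshold,
        target_specificity=target_spec,
        too_weights=dict(too_weights or {f: 1 / len(feature_names) for f in feature_names}),
        delta=delta,
        eps=eps,
        design_sd=sd,
        training_ids=list(feature_scores.index),
    )


def predict_csd(model: EnsembleModel, feature_scores: pd.DataFrame, age, sex):
    """(score, call) per sample; call is strict score > threshold."""
    X = _design(feature_scores, age, sex, model.feature_names, model.eps)
    z = X @ model.coef + model.intercept
    score = 1.0 / (1.0 + np.exp(-z))
    score = pd.Series(score, index=feature_scores.index, name="csd_score")
    call = score > model.threshold
    return score, call.rename("csd_call")


def predict_too(
    weights: dict,
    conditional_probas: dict[str, pd.DataFrame],
    delta: float = 0.07,
) -> pd.DataFrame:
    """Weighted aggregation of per-feature conditional cancer-type probabilities.

    Returns top-1/top-2 labels and probabilities plus the ``in_between`` flag
    (top1 - top2 strictly below ``delta``). Ties break by label order.
    """
    if set(weights) != set(conditional_probas):
        raise ValueError("weights and conditional probability features do not match")
    feats = sorted(weights)
    first = conditional_probas[feats[0]]
    cols = list(first.columns)
    idx = first.index
    agg = np.zeros(first.shape)
    for f in feats:
        mat = conditional_probas[f]
        if list(mat.columns) != cols or not mat.index.equals(idx):
            raise ValueError("conditional probability matrices are not aligned")
        agg += weights[f] * mat.to_numpy(dtype=float)

    # stable ranking: descending probability, ascending label on ties
    order = np.lexsort((np.arange(len(cols))[None, :].repeat(len(idx), 0), -agg), axis=1)
    top1 = order[:, 0]
    top2 = order[:, 1]
    p1 = agg[np.arange(len(idx)), top1]
    p2 = agg[np.arange(len(idx)), top2]
    labels = np.asarray(cols, dtype=object)
    return pd.DataFrame({
        "too_top1": labels[top1],
        "too_top1_prob": p1,
        "too_top2": labels[top2],
        "too_top2_prob": p2,
        "in_between": (p1 - p2) < delta,
    }, index=idx)


def _wilson(k: int, n: int):
    if n == 0:
        return (np.nan, np.nan)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _rate_row(metric, group, k, n):
    lo, hi = _wilson(k, n)
    value = k / n if n else np.nan
    return {"metric": metric, "group": group, "value": value,
            "n": n, "ci_low": lo, "ci_high": hi}


def evaluate(predictions: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Metrics table from per-sample predictions and the truth sample sheet.

    Expects prediction columns ``sample_id``, ``csd_score``, ``csd_call`` and,
    for cancer samples, ``too_top1``/``too_top2``/``in_between``. Reports
    overall / per-type / per-stage sensitivity, specificity, ROC AUC, TOO
    top-1 and top-2 accuracy (overall and on the unambiguous subset), each
    with Wilson 95% CIs.
    """
    merged = predictions.merge(truth, on="sample_id", how="left", validate="1:1")
    if merged["label"].isna().any():
        bad = merged.loc[merged["label"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"no truth label for sample {bad!r}")

    is_cancer = merged["label"] != "healthy"
    rows = []

    k = int((merged.loc[is_cancer, "csd_call"]).sum())
    rows.append(_rate_row("sensitivity", "overall", k, int(is_cancer.sum())))
    k = int((~merged.loc[~is_cancer, "csd_call"]).sum())
    rows.append(_rate_row("specificity", "overall", k, int((~is_cancer).sum())))

    for ctype, grp in merged[is_cancer].groupby("label"):
        rows.append(_rate_row("sensitivity", f"type:{ctype}",
                              int(grp["csd_call"].sum()), len(grp)))
    for stage, grp in merged[is_cancer].groupby("stage"):
        rows.append(_rate_row("sensitivity", f"stage:{stage}",
                              int(grp["csd_call"].sum()), len(grp)))

    if is_cancer.any() and (~is_cancer).any():
        auc = roc_auc_score(is_cancer.to_numpy(), merged["csd_score"].to_numpy())
        rows.append({"metric": "roc_auc", "group": "overall", "value": float(auc),
                     "n": len(merged), "ci_low": np.nan, "ci_high": np.nan})

    cancer = merged[is_cancer]
    if "too_top1" in cancer.columns and cancer["too_top1"].notna().any():
        sub = cancer[cancer["too_top1"].notna()]
        hit1 = (sub["too_top1"] == sub["label"])
        hit2 = hit1 | (sub["too_top2"] == sub["label"])
        rows.append(_rate_row("too_top1_accuracy", "overall", int(hit1.sum()), len(sub)))
        rows.append(_rate_row("too_top2_accuracy", "overall", int(hit2.sum()), len(sub)))
        clear = sub[~sub["in_between"].astype(bool)]
        if len(clear):
            h1 = (clear["too_top1"] == clear["label"])
            h2 = h1 | (clear["too_top2"] == clear["label"])
            rows.append(_rate_row("too_top1_accuracy", "unambiguous", int(h1.sum()), len(clear)))
            rows.append(_rate_row("too_top2_accuracy", "unambiguous", int(h2.sum()), len(clear)))
        rows.append(_rate_row("too_in_between_rate", "overall",
                              int(sub["in_between"].astype(bool).sum()), len(sub)))

    return pd.DataFrame(rows, columns=["metric", "group", "value", "n", "ci_low", "ci_high"])
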