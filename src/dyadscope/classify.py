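"""Pain-state discrimination from patient AU time courses.

Frames from moderate-pain and innocuous-pressure blocks are classified with a
gradient-boosted tree ensemble (XGBoost); performance is assessed with
grouped (leave-subjects-out) cross-validation so no subject contributes to
both the training and test side of a fold, and feature importance is ranked
by mean absolute SHAP value per AU (exact TreeSHAP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import precision_score, recall_score, roc_auc_score
from sklearn.model_selection import GroupKFold

from .datatypes import AURecording, EventTable, PAIN_CONDITIONS
from .exceptions import CVError, DegenerateLabelError, EmptyInputError, SchemaError
from .io import _event_frames

DEFAULT_HYPERPARAMS = {
    "n_estimators": 200,
    "max_depth": 3,
    "learning_rate": 0.1,
    "tree_method": "hist",
    "n_jobs": 1,
}

META_COLUMNS = ("subject_id", "block_index", "label")


@dataclass
class ClassifierReport:
    """Pooled grouped-CV metrics plus per-fold details and held-out predictions."""

    auc: float
    precision: float
    recall: float
    threshold: float
    cv_scheme: str
    per_fold: list[dict]
    predictions: pd.DataFrame
    model: xgb.XGBClassifier | None = None
    feature_names: tuple[str, ...] = field(default_factory=tuple)


def assemble_frames(rec: AURecording, events: EventTable, subject_id: str | None = None) -> pd.DataFrame:
    """One row per frame inside a labelled pain/innocuous block.

    Rest, rating, and anticipation frames are excluded.  The label column is
    binary (pain = 1).
    """
    rows = events.select(PAIN_CONDITIONS)
    if len(rows) == 0:
        raise EmptyInputError("no pain_moderate/pain_innocuous blocks in the event table")
    sid = subject_id if subject_id is not None else rec.subject_id
    parts = []
    for k, row in enumerate(rows.itertuples(index=False)):
        a, b = _event_frames(row.onset, row.duration, rec.sampling_rate_hz)
        seg = rec.values[a - rec.frame_start : b - rec.frame_start]
        df = pd.DataFrame(seg, columns=list(rec.au_labels))
        df.insert(0, "label", 1 if row.condition == "pain_moderate" else 0)
        df.insert(0, "block_index", k)
        df.insert(0, "subject_id", sid)
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


def _check_frames(frames: pd.DataFrame) -> list[str]:
    feature_cols = [c for c in frames.columns if c not in META_COLUMNS]
    missing = set(META_COLUMNS) - set(frames.columns)
    if missing:
        raise SchemaError(f"frame table missing columns {sorted(missing)}")
    if frames["label"].nunique() < 2:
        raise DegenerateLabelError("frame table contains a single class")
    return feature_cols


def train_classify(
    frames: pd.DataFrame,
    n_splits: int = 5,
    hyperparams: dict | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> ClassifierReport:
    """Grouped-CV gradient-boosted classification of pain vs innocuous frames.

    Folds are grouped by ``subject_id`` (no identity leakage); AUC, precision
    and recall are pooled over all held-out predictions, with precision and
    recall evaluated at the stated posterior ``threshold``.  A final model is
    fit on all rows for SHAP ranking.
    """
    feature_cols = _check_frames(frames)
    groups = frames["subject_id"].to_numpy()
    n_groups = len(np.unique(groups))
    if n_groups < 2:
        raise CVError("grouped CV requires at least 2 subjects")
    n_splits = min(n_splits, n_groups)
    X = frames[feature_cols].to_numpy(dtype=float)
    y = frames["label"].to_numpy(dtype=int)
    params = {**DEFAULT_HYPERPARAMS, **(hyperparams or {})}

    preds = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1)
    per_fold = []
    cv = GroupKFold(n_splits=n_splits)
    for fold, (tr, te) in enumerate(cv.split(X, y, groups)):
        if len(np.unique(y[tr])) < 2:
            raise DegenerateLabelError(f"training fold {fold} contains a single class")
        model = xgb.XGBClassifier(random_state=seed, **params)
        model.fit(X[tr], y[tr])
        prob = model.predict_proba(X[te])[:, 1]
        preds[te] = prob
        fold_of[te] = fold
        fold_metrics = {"fold": fold, "n_test": int(len(te))}
        if len(np.unique(y[te])) == 2:
            fold_metrics["auc"] = float(roc_auc_score(y[te], prob))
        per_fold.append(fold_metrics)

    auc = float(roc_auc_score(y, preds))
    hard = (preds >= threshold).astype(int)
    precision = float(precision_score(y, hard, zero_division=0))
    recall = float(recall_score(y, hard, zero_division=0))

    final = xgb.XGBClassifier(random_state=seed, **params)
    final.fit(X, y)
    final.get_booster().feature_names = list(feature_cols)

    pred_df = frames[list(META_COLUMNS)].copy()
    pred_df["probability"] = preds
    pred_df["fold"] = fold_of
    return ClassifierReport(
        auc=auc, precision=precision, recall=recall, threshold=threshold,
        cv_scheme=f"grouped:{n_splits}", per_fold=per_fold,
        predictions=pred_df, model=final, feature_names=tuple(feature_cols),
    )


def rank_shap(model: xgb.XGBClassifier, frames: pd.DataFrame) -> pd.DataFrame:
    """Rank AUs by mean absolute SHAP value over all rows of ``frames``.

    Returns a DataFrame with columns ``au_label, mean_abs_shap, rank`` sorted
    by descending importance; ties are broken deterministically by AU label.
    SHAP values come from XGBoost's exact TreeSHAP (``pred_contribs``).
    """
    feature_cols = [c for c in frames.columns if c not in META_COLUMNS]
    booster = model.get_booster()
    if booster.feature_names is not None and list(booster.feature_names) != feature_cols:
        raise SchemaError(
            "feature mismatch between model and frame table: "
            f"{booster.feature_names} vs {feature_cols}"
        )
    X = frames[feature_cols].to_numpy(dtype=float)
    dmat = xgb.DMatrix(X, feature_names=feature_cols)
    contribs = booster.predict(dmat, pred_contribs=True)  # (n, n_features + bias)
    mean_abs = np.abs(contribs[:, : len(feature_cols)]).mean(axis=0)
    out = pd.DataFrame({"au_label": feature_cols, "mean_abs_shap": mean_abs})
    out = out.sort_values(["mean_abs_shap", "au_label"], ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
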