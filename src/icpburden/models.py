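"""Small-cohort outcome classifiers on the three burden predictors.

Two tree ensembles — a random forest and gradient-boosted trees — predict
death (mRS = 6) from exactly three per-patient features: the normalized
ICP-AUC, the maximum ICP, and the fraction of time above a configured
threshold (15 or 20 mmHg).  With n around 17 the only defensible validation
is leave-one-out: each patient is predicted by a model trained on the
others, and precision / recall / F1 / ROC-AUC are computed once from the
pooled out-of-fold predictions.  Resubstitution ("apparent") and stratified
k-fold schemes exist for comparison.

Hyperparameters are pinned (forest: 100 trees, unlimited depth; boosting:
100 rounds, depth 3, learning rate 0.1) — no tuning is performed, both
because n is tiny and so that reports are reproducible from the seed alone.

F1 is the harmonic mean of precision and recall.  When a denominator is
zero (e.g. no positive predictions) the metric is reported as 0.0 with an
explicit flag rather than NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .burden import BurdenSummary
from .exceptions import DegenerateDataError
from .io import OutcomeRecord
from .stats import roc

log = logging.getLogger("icpburden")

PREDICTORS = ("normalized_auc", "max_icp", "frac_above_threshold")
MODEL_NAMES = ("forest", "boosting")
SCHEMES = ("loo", "stratified_kfold", "apparent")
PROB_CUTOFF = 0.5


@dataclass(frozen=True)
class FeatureRow:
    """One patient's predictor triple and death label."""

    patient_id: str
    normalized_auc: float
    max_icp: float
    frac_above_threshold: float
    label: bool


@dataclass
class ModelReport:
    """Cross-validated predictions and pooled classification metrics."""

    model_name: str
    threshold_mmHg: float
    scheme: str
    seed: int
    patient_ids: list[str]
    prob: np.ndarray
    pred: np.ndarray
    label: np.ndarray
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    roc_auc: float
    precision_defined: bool
    f1_defined: bool
    feature_importances: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "threshold_mmHg": self.threshold_mmHg,
            "scheme": self.scheme,
            "seed": self.seed,
            "patient_ids": self.patient_ids,
            "prob": [float(p) for p in self.prob],
            "pred": [bool(p) for p in self.pred],
            "label": [bool(y) for y in self.label],
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "roc_auc": None if math.isnan(self.roc_auc) else self.roc_auc,
            "precision_defined": self.precision_defined,
            "f1_defined": self.f1_defined,
            "feature_importances": self.feature_importances,
        }


def build_features(
    summaries: Mapping[str, BurdenSummary],
    outcomes: Mapping[str, OutcomeRecord],
    threshold: float = 20.0,
) -> list[FeatureRow]:
    """Join summaries and outcomes into predictor rows for one threshold.

    Patients missing either table (incomplete outcome data) are excluded
    with a logged message, mirroring complete-case analysis.
    """
    threshold = float(threshold)
    ids = sorted(set(summaries) & set(outcomes))
    excluded = sorted((set(summaries) | set(outcomes)) - set(ids))
    if excluded:
        log.info("excluding %d patient(s) without complete data: %s", len(excluded), excluded)
    if not ids:
        raise ValueError("no patients with both summary and outcome")
    rows = []
    for pid in ids:
        s = summaries[pid]
        if threshold not in s.frac_above:
            raise KeyError(f"summary for {pid!r} lacks frac_above[{threshold:g}]")
        rows.append(
            FeatureRow(
                patient_id=pid,
                normalized_auc=s.normalized_auc,
                max_icp=s.max_icp,
                frac_above_threshold=s.frac_above[threshold],
                label=outcomes[pid].poor_outcome,
            )
        )
    return rows


def _design(rows: Sequence[FeatureRow]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[r.normalized_auc, r.max_icp, r.frac_above_threshold] for r in rows])
    y = np.array([r.label for r in rows], dtype=bool)
    return X, y


def _make_model(model_name: str, seed: int):
    if model_name == "forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if model_name == "boosting":
        return XGBClassifier(
            n_estimators=100,
            max_depth=3,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    raise ValueError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")


def classification_metrics(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Precision, recall and harmonic-mean F1 from confusion counts.

    Undefined ratios (zero denominator) are reported as 0.0 with the
    corresponding ``*_defined`` flag set to False.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1_defined = (precision + recall) > 0
    f1 = 2 * precision * recall / (precision + recall) if f1_defined else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "precision_defined": precision_defined,
        "f1_defined": f1_defined,
    }


def _oof_probabilities(
    X: np.ndarray, y: np.ndarray, model_name: str, scheme: str, seed: int
) -> tuple[np.ndarray, str]:
    n = y.size
    if scheme == "apparent":
        model = _make_model(model_name, seed)
        model.fit(X, y)
        return model.predict_proba(X)[:, 1], scheme

    if scheme == "stratified_kfold":
        n_splits = 5
        if int(y.sum()) < n_splits or int((~y).sum()) < n_splits:
            log.warning(
                "stratified %d-fold would leave a fold without both classes; "
                "falling back to leave-one-out", n_splits,
            )
            scheme = "loo"
        else:
            prob = np.empty(n)
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            for train, test in skf.split(X, y):
                model = _make_model(model_name, seed)
                model.fit(X[train], y[train])
                prob[test] = model.predict_proba(X[test])[:, 1]
            return prob, "stratified_kfold"

    # leave-one-out: training folds may be single-class, in which case the
    # fold's prediction is that class's probability (0 or 1)
    prob = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if y_train.all():
            prob[i] = 1.0
        elif not y_train.any():
            prob[i] = 0.0
        else:
            model = _make_model(model_name, seed)
            model.fit(X[mask], y_train)
            prob[i] = model.predict_proba(X[i : i + 1])[:, 1][0]
    return prob, "loo"


def _fit_importances(X: np.ndarray, y: np.ndarray, model_name: str, seed: int) -> dict[str, float]:
    model = _make_model(model_name, seed)
    model.fit(X, y)
    if model_name == "forest":
        imp = np.asarray(model.feature_importances_, dtype=float)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        return dict(zip(PREDICTORS, (float(w) for w in imp)))
    # boosting: raw total gain per feature, zero for unused features
    gain = model.get_booster().get_score(importance_type="gain")
    return {name: float(gain.get(f"f{k}", 0.0)) for k, name in enumerate(PREDICTORS)}


def crossval_evaluate(
    rows: Sequence[FeatureRow],
    model_name: str = "forest",
    scheme: str = "loo",
    seed: int = 0,
    threshold_mmHg: float = 20.0,
) -> ModelReport:
    """Out-of-fold evaluation of one classifier on the feature rows.

    Class predictions use a fixed probability cutoff of 0.5; all metrics are
    pooled over folds.  Fully reproducible given (rows, model, scheme, seed).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    X, y = _design(rows)
    n = y.size
    if n < 6:
        raise ValueError("need at least 6 patients to evaluate a classifier")
    if y.all() or not y.any():
        raise DegenerateDataError("both outcome classes must be present")

    prob, scheme_used = _oof_probabilities(X, y, model_name, scheme, seed)
    pred = prob >= PROB_CUTOFF
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    metrics = classification_metrics(tp, fp, fn, tn)
    try:
        roc_auc = roc(prob, y).auc
    except DegenerateDataError:  # pragma: no cover - guarded above
        roc_auc = math.nan

    return ModelReport(
        model_name=model_name,
        threshold_mmHg=float(threshold_mmHg),
        scheme=scheme_used,
        seed=seed,
        patient_ids=[r.patient_id for r in rows],
        prob=prob,
        pred=pred,
        label=y,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=metrics["precision"],
        recall=metrics["recall"],
        f1=metrics["f1"],
        roc_auc=roc_auc,
        precision_defined=metrics["precision_defined"],
        f1_defined=metrics["f1_defined"],
        feature_importances=_fit_importances(X, y, model_name, seed),
    )


def importances(report: ModelReport) -> list[tuple[str, float]]:
    """Predictor weights from the full-data fit, heaviest first."""
    return sorted(report.feature_importances.items(), key=lambda kv: -kv[1])
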