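"""Necrosis / vital-tissue classification of standardized Raman spectra.

The central estimator is :class:`NecrosisRandomForest`, a random-forest
binary classifier whose ``fit`` performs grid search with repeated,
patient-grouped, stratified internal cross-validation and derives an
f1-optimal decision threshold from the pooled out-of-fold scores.  The score
convention is fixed throughout: the model emits the probability of the
NECROSIS class and a spectrum is labeled necrotic when its score is greater
than or equal to the threshold.

Module functions (`split_patientwise`, `tune_and_fit`, `optimal_threshold`,
`evaluate`, `feature_importance_report`) wrap the estimator for
:class:`~ramahet.dataset.SpectraSet` inputs and enforce the patient-level
leakage guard.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (average_precision_score, f1_score,
                             precision_recall_fscore_support, roc_auc_score)
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.utils.validation import check_is_fitted

from .dataset import SpectraSet

__all__ = [
    "POSITIVE_CLASS", "NEGATIVE_CLASS", "DEFAULT_PARAM_GRID",
    "SplitPlan", "ClassMetrics", "FeatureImportanceReport",
    "NecrosisRandomForest", "split_patientwise", "tune_and_fit",
    "optimal_threshold", "evaluate", "feature_importance_report",
    "metrics_from_scores", "save_model", "load_model",
]

POSITIVE_CLASS = "necrosis"
NEGATIVE_CLASS = "vital"

#: hyperparameter search space for internal CV
DEFAULT_PARAM_GRID = {
    "n_estimators": [100, 500],
    "max_depth": [None, 20],
    "max_features": ["sqrt", 0.1],
}


# ---------------------------------------------------------------------------
# Patient-wise splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Patient-disjoint train/validation split with a per-patient cap."""

    train_patients: frozenset
    validation_patients: frozenset
    per_patient_cap: int
    train_ids: list[str]
    validation_ids: list[str]
    counts: pd.DataFrame  # rows: split, columns: class, values: n spectra

    def __post_init__(self) -> None:
        if self.train_patients & self.validation_patients:
            raise ValueError("train and validation patient sets overlap")


def _cap_per_patient(meta: pd.DataFrame, cap: int,
                     rng: np.random.Generator) -> list[str]:
    """Subsample spectrum ids to at most *cap* per patient, without replacement."""
    kept: list[str] = []
    for _, grp in meta.groupby("patient_id", sort=True):
        ids = grp.index.to_numpy()
        if len(ids) > cap:
            ids = rng.choice(ids, size=cap, replace=False)
        kept.extend(sorted(ids))
    return kept


def split_patientwise(sset: SpectraSet, validation_fraction: float = 0.25,
                      train_patients=None, validation_patients=None,
                      per_patient_cap: int = 15,
                      rng: np.random.Generator | int | None = None) -> SplitPlan:
    """Assign whole patients to train or validation and cap spectra per patient.

    Either pass explicit patient lists, or a ``validation_fraction`` and the
    split is drawn at random, stratified by each patient's majority class so
    both splits contain both classes.
    """
    rng = np.random.default_rng(rng)
    labels = set(sset.class_labels)
    if not labels <= {POSITIVE_CLASS, NEGATIVE_CLASS}:
        raise ValueError(f"split restricted to {POSITIVE_CLASS}/{NEGATIVE_CLASS} "
                         f"records; found {sorted(labels)}")
    meta = sset.meta
    per_class_patients = meta.groupby("class_label")["patient_id"].nunique()
    if (per_class_patients < 2).any():
        bad = per_class_patients[per_class_patients < 2].index.tolist()
        raise ValueError(f"classes {bad} have a single patient and cannot be "
                         f"split patient-wise")

    if train_patients is not None or validation_patients is not None:
        if train_patients is None or validation_patients is None:
            raise ValueError("pass both explicit patient lists or neither")
        train_p, val_p = frozenset(train_patients), frozenset(validation_patients)
    else:
        # majority class per patient as the stratum
        strata = (meta.groupby("patient_id")["class_label"]
                  .agg(lambda s: s.value_counts().idxmax()))
        val_set: set = set()
        for cls, patients in strata.groupby(strata):
            pats = np.array(sorted(patients.index))
            n_val = max(1, int(round(validation_fraction * len(pats))))
            n_val = min(n_val, len(pats) - 1)  # keep >=1 patient in train
            val_set.update(rng.choice(pats, size=n_val, replace=False))
        val_p = frozenset(val_set)
        train_p = frozenset(strata.index) - val_p

    train_meta = meta[meta["patient_id"].isin(train_p)]
    val_meta = meta[meta["patient_id"].isin(val_p)]
    train_ids = _cap_per_patient(train_meta, per_patient_cap, rng)
    val_ids = _cap_per_patient(val_meta, per_patient_cap, rng)
    counts = pd.DataFrame({
        "train": meta.loc[train_ids, "class_label"].value_counts(),
        "validation": meta.loc[val_ids, "class_label"].value_counts(),
    }).T.fillna(0).astype(int)
    return SplitPlan(train_p, val_p, per_patient_cap, train_ids, val_ids, counts)


# ---------------------------------------------------------------------------
# Threshold search
# ---------------------------------------------------------------------------

def optimal_threshold(scores, labels, positive: str = POSITIVE_CLASS) -> float:
    """f1-optimal decision threshold over out-of-fold necrosis scores.

    Candidates are 0, 1 and the midpoints between consecutive distinct
    sorted scores; a sample is predicted positive when ``score >= t``.  Ties
    in f1 are broken toward the LOWER threshold (more sensitive to the
    positive class).  Degenerate all-equal scores return 0.5 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([lab == positive if isinstance(lab, str) else bool(lab)
                    for lab in np.asarray(labels).ravel()])
    if scores.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present to tune the threshold")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        warnings.warn("all scores identical; returning threshold 0.5")
        return 0.5
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    best_t, best_f1 = candidates[0], -1.0
    for t in candidates:  # ascending: first argmax = lowest threshold
        pred = scores >= t
        tp = np.sum(pred & y)
        fp = np.sum(pred & ~y)
        fn = np.sum(~pred & y)
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1 + 1e-12:
            best_t, best_f1 = float(t), float(f1)
    return best_t


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassMetrics:
    """Per-class and aggregate validation metrics.

    ``per_class`` maps class name to a dict with auroc, aupr, precision,
    recall, f1 and misclassification_ratio (= 1 - recall); ``macro`` and
    ``weighted`` average precision/recall/f1 over classes (weighted by class
    support).
    """

    accuracy: float
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    weighted: dict[str, float]
    support: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "per_class": self.per_class,
                "macro": self.macro, "weighted": self.weighted,
                "support": self.support}


def metrics_from_scores(labels, scores, threshold: float,
                        positive: str = POSITIVE_CLASS,
                        negative: str = NEGATIVE_CLASS) -> ClassMetrics:
    """Compute the full metric panel from necrosis scores and a threshold."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([lab == positive if isinstance(lab, str) else bool(lab)
                    for lab in np.asarray(labels).ravel()])
    pred = scores >= threshold
    classes = [positive, negative]
    y_true = np.where(y, positive, negative)
    y_pred = np.where(pred, positive, negative)
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0)
    per_class = {}
    for i, cls in enumerate(classes):
        y_cls = y if cls == positive else ~y
        s_cls = scores if cls == positive else 1.0 - scores
        per_class[cls] = {
            "auroc": float(roc_auc_score(y_cls, s_cls)) if 0 < y_cls.sum() < len(y_cls) else float("nan"),
            "aupr": float(average_precision_score(y_cls, s_cls)) if 0 < y_cls.sum() < len(y_cls) else float("nan"),
            "precision": float(prec[i]),
            "recall": float(rec[i]),
            "f1": float(f1[i]),
            "misclassification_ratio": float(1.0 - rec[i]),
        }
    accuracy = float((y == pred).mean())
    macro = {"precision": float(prec.mean()), "recall": float(rec.mean()),
             "f1": float(f1.mean())}
    w = supp / supp.sum()
    weighted = {"precision": float(prec @ w), "recall": float(rec @ w),
                "f1": float(f1 @ w)}
    return ClassMetrics(accuracy, per_class, macro, weighted,
                        {c: int(s) for c, s in zip(classes, supp)})


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class NecrosisRandomForest(ClassifierMixin, BaseEstimator):
    """Random-forest necrosis/vital classifier with internal grouped CV.

    ``fit(X, y, groups=patient_ids)`` runs a grid search over ``param_grid``
    using ``n_splits``-fold stratified, patient-grouped cross-validation
    repeated ``n_repeats`` times; the best grid point (by mean out-of-fold
    f1 of the necrosis class) is refit on all training data and the
    f1-optimal decision threshold is computed on its pooled out-of-fold
    scores.

    Fitted attributes: ``forest_``, ``threshold_``, ``best_params_``,
    ``cv_results_`` (DataFrame), ``oof_scores_`` / ``oof_labels_``,
    ``train_patients_``, ``grid_hash_``, ``classes_``.
    """

    def __init__(self, param_grid: dict | None = None, n_splits: int = 5,
                 n_repeats: int = 3, random_state: int | None = None,
                 grid_hash: str | None = None):
        self.param_grid = param_grid
        self.n_splits = n_splits
        self.n_repeats = n_repeats
        self.random_state = random_state
        self.grid_hash = grid_hash

    @staticmethod
    def _grid_points(param_grid: dict) -> list[dict]:
        from itertools import product
        keys = list(param_grid)
        return [dict(zip(keys, vals)) for vals in product(*(param_grid[k] for k in keys))]

    def _cv_splits(self, y: np.ndarray, groups: np.ndarray):
        """Patient-grouped stratified folds, ``n_splits x n_repeats``.

        Folds whose training half lost a class are reshuffled (fresh seed).
        """
        n_groups = len(np.unique(groups))
        n_splits = self.n_splits
        if n_groups < n_splits:
            warnings.warn(f"only {n_groups} patients; reducing internal CV to "
                          f"{n_groups} folds")
            n_splits = n_groups
        base = 0 if self.random_state is None else int(self.random_state)
        splits = []
        for rep in range(self.n_repeats):
            fallback = None
            for attempt in range(20):
                cv = StratifiedGroupKFold(n_splits=n_splits, shuffle=True,
                                          random_state=base + 1000 * rep + attempt)
                folds = list(cv.split(np.zeros_like(y), y, groups))
                train_ok = all(len(np.unique(y[tr])) == 2 and len(te) > 0
                               for tr, te in folds)
                test_ok = all(len(np.unique(y[te])) == 2 for tr, te in folds)
                if train_ok and fallback is None:
                    fallback = folds
                if train_ok and test_ok:
                    splits.append(folds)
                    break
            else:
                if fallback is None:
                    raise ValueError("could not build two-class grouped folds; "
                                     "too few patients per class")
                # some test folds stay single-class (too few patients of one
                # class); scoring skips folds without positives
                splits.append(fallback)
        return splits

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        y_bin = np.asarray([lab == POSITIVE_CLASS if isinstance(lab, str)
                            else bool(lab) for lab in y])
        if len(y_bin) != len(X):
            raise ValueError("X and y differ in length")
        if y_bin.all() or not y_bin.any():
            raise ValueError("training data must contain both classes")
        if groups is None:
            groups = np.arange(len(y))  # degenerate: every spectrum its own patient
        groups = np.asarray(groups)
        param_grid = self.param_grid if self.param_grid else DEFAULT_PARAM_GRID
        points = self._grid_points(param_grid)
        if not points:
            raise ValueError("empty hyperparameter grid")
        repeats = self._cv_splits(y_bin, groups)

        rows = []
        oof_by_point: list[np.ndarray] = []
        rs = 0 if self.random_state is None else int(self.random_state)
        for ip, params in enumerate(points):
            oof = np.full((self.n_repeats, len(y_bin)), np.nan)
            f1s = []
            for rep, folds in enumerate(repeats):
                for tr, te in folds:
                    rf = RandomForestClassifier(random_state=rs + ip, n_jobs=1,
                                                **params)
                    rf.fit(X[tr], y_bin[tr])
                    pos_col = list(rf.classes_).index(True)
                    s = rf.predict_proba(X[te])[:, pos_col]
                    oof[rep, te] = s
                    if y_bin[te].any():  # f1 undefined without positives
                        f1s.append(f1_score(y_bin[te], s >= 0.5, zero_division=0))
            rows.append({**params, "mean_f1": float(np.mean(f1s)),
                         "std_f1": float(np.std(f1s))})
            oof_by_point.append(oof)

        self.cv_results_ = pd.DataFrame(rows)
        best = int(np.argmax(self.cv_results_["mean_f1"].to_numpy()))
        self.best_params_ = points[best]
        oof = oof_by_point[best]
        valid = ~np.isnan(oof)
        self.oof_scores_ = oof[valid]
        self.oof_labels_ = np.broadcast_to(y_bin, oof.shape)[valid]
        self.threshold_ = optimal_threshold(self.oof_scores_, self.oof_labels_,
                                            positive=True)
        self.forest_ = RandomForestClassifier(random_state=rs + best, n_jobs=1,
                                              **self.best_params_)
        self.forest_.fit(X, y_bin)
        self._pos_col = list(self.forest_.classes_).index(True)
        self.classes_ = np.array([NEGATIVE_CLASS, POSITIVE_CLASS])
        self.train_patients_ = frozenset(np.unique(groups).tolist())
        self.n_features_in_ = X.shape[1]
        return self

    def score_samples(self, X) -> np.ndarray:
        """Probability of the necrosis class for each spectrum."""
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("grid mismatch with the fitted model")
        return self.forest_.predict_proba(X)[:, self._pos_col]

    def predict_proba(self, X) -> np.ndarray:
        s = self.score_samples(X)
        return np.column_stack([1.0 - s, s])  # columns follow self.classes_

    def predict(self, X) -> np.ndarray:
        s = self.score_samples(X)
        return np.where(s >= self.threshold_, POSITIVE_CLASS, NEGATIVE_CLASS)

    @property
    def feature_importances_(self) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.feature_importances_


#: the fitted estimator *is* the classifier model artifact
ClassifierModel = NecrosisRandomForest


@dataclass
class FeatureImportanceReport:
    """Normalized impurity-based importance per frequency bin."""

    importances: np.ndarray           # sums to 1
    ranking: np.ndarray               # bin indices, most important first
    top_k: int
    top_k_share: float
    max_share: float

    def to_dict(self) -> dict:
        return {"top_k": self.top_k, "top_k_share": self.top_k_share,
                "max_share": self.max_share,
                "ranking_head": self.ranking[:self.top_k].tolist()}


# ---------------------------------------------------------------------------
# SpectraSet wrappers
# ---------------------------------------------------------------------------

def tune_and_fit(train: SpectraSet, split: SplitPlan,
                 param_grid: dict | None = None, n_splits: int = 5,
                 n_repeats: int = 3,
                 rng: int | None = 0) -> NecrosisRandomForest:
    """Grid-search + fit a :class:`NecrosisRandomForest` on the training split."""
    subset = train.subset(split.train_ids)
    model = NecrosisRandomForest(param_grid=param_grid, n_splits=n_splits,
                                 n_repeats=n_repeats, random_state=rng,
                                 grid_hash=train.grid.hash())
    model.fit(subset.intensities, subset.class_labels,
              groups=subset.patient_ids)
    return model


def evaluate(model: NecrosisRandomForest, validation: SpectraSet) -> ClassMetrics:
    """Score the held-out validation split; refuses any patient overlap."""
    check_is_fitted(model, "forest_")
    overlap = set(validation.patient_ids) & set(model.train_patients_)
    if overlap:
        raise ValueError(f"leakage guard: validation shares patients with "
                         f"training: {sorted(overlap)[:5]}")
    if model.grid_hash is not None and validation.grid.hash() != model.grid_hash:
        raise ValueError("validation grid differs from the training grid")
    scores = model.score_samples(validation.intensities)
    return metrics_from_scores(validation.class_labels, scores, model.threshold_)


def feature_importance_report(model: NecrosisRandomForest,
                              top_k: int = 20) -> FeatureImportanceReport:
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    ranking = np.argsort(imp)[::-1]
    return FeatureImportanceReport(
        importances=imp, ranking=ranking, top_k=top_k,
        top_k_share=float(imp[ranking[:top_k]].sum()),
        max_share=float(imp[ranking[0]]))


def save_model(model: NecrosisRandomForest, path) -> None:
    """Persist the model (joblib) with a JSON metadata sidecar."""
    joblib.dump(model, path)
    meta = {
        "threshold": float(model.threshold_),
        "best_params": {k: (v if v is None or isinstance(v, (int, str)) else float(v))
                        for k, v in model.best_params_.items()},
        "grid_hash": model.grid_hash,
        "n_features": int(model.n_features_in_),
        "train_patients": sorted(model.train_patients_),
        "score_convention": "probability of necrosis; necrotic iff score >= threshold",
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path) -> NecrosisRandomForest:
    return joblib.load(path)


def param_grid_hash(param_grid: dict) -> str:
    return hashlib.sha256(json.dumps(param_grid, sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]
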