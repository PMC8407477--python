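"""Disease-state classification from strain-level features.

Feature matrices are assembled from estimated strain coverages, depths,
abundances, or their column-wise combination; SVM and random-forest models
are evaluated with stratified k-fold cross-validation, running a randomized
hyperparameter search on the training folds of each split and scoring AUC on
the held-out fold.  The headline statistic is the median of the per-fold
AUCs.  Single-strain feature matrices support the "one indicator strain"
use case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .profiling import StrainProfileMatrix

__all__ = ["FeatureMatrix", "ModelReport", "build_feature_matrix", "train_evaluate", "roc_auc"]

FEATURE_SETS = ("coverage", "depth", "abundance", "combined")


@dataclass
class FeatureMatrix:
    X: pd.DataFrame  # samples x features, no missing values
    labels: pd.Series  # sample -> group label
    feature_set: str

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")
        self.labels = self.labels.reindex(self.X.index)
        if self.labels.isna().any():
            raise ValueError("every sample needs a label")


@dataclass
class ModelReport:
    model: str
    fold_aucs: list
    median_auc: float
    best_params: list
    seed: int
    feature_importances: pd.Series | None = None


def build_feature_matrix(
    profile: StrainProfileMatrix,
    feature_set: str,
    strain_subset: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Assemble a samples x features matrix from a strain profile.

    Columns are ordered strain-major ("<strain>:<quantity>"); ``combined``
    concatenates coverage, depth, and abundance per strain.  Strains absent
    from a sample contribute zeros by construction of the profile matrix.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    if profile.groups is None:
        raise ValueError("profile matrix must carry group labels")
    strains = list(strain_subset) if strain_subset is not None else profile.strains
    if not strains:
        raise ValueError("strain_subset must be non-empty")
    unknown = [s for s in strains if s not in profile.coverage.columns]
    if unknown:
        raise ValueError(f"unknown strain ids: {unknown}")
    quantities = (
        ("coverage", "depth", "abundance") if feature_set == "combined" else (feature_set,)
    )
    blocks = {}
    for strain in strains:
        for q in quantities:
            blocks[f"{strain}:{q}"] = getattr(profile, q)[strain]
    X = pd.DataFrame(blocks, index=profile.coverage.index)
    return FeatureMatrix(X=X, labels=profile.groups.copy(), feature_set=feature_set)


def _svm_search_space():
    return {
        "C": loguniform(1e-2, 1e3),
        "gamma": loguniform(1e-4, 1e1),
        "kernel": ["rbf", "linear"],
        "class_weight": [None, "balanced"],
    }


def _rf_search_space():
    return {
        "n_estimators": randint(50, 501),
        "max_depth": [None, *range(2, 21)],
        "max_features": ["sqrt", "log2", None],
        "max_leaf_nodes": [None, 10, 20, 50, 100],
        "min_samples_split": randint(2, 11),
        "bootstrap": [True, False],
    }


def train_evaluate(
    features: FeatureMatrix,
    model: str = "svm",
    folds: int = 5,
    search_iterations: int = 30,
    seed: int = 0,
    inner_folds: int = 3,
) -> ModelReport:
    """Cross-validated AUC with per-fold randomized hyperparameter search.

    For each of ``folds`` stratified splits, a randomized search (scored by
    inner-CV AUC) selects hyperparameters on the training portion only; AUC
    is then computed on the held-out fold.  Deterministic for a fixed seed.
    """
    X = features.X.to_numpy(dtype=float)
    classes = sorted(features.labels.unique())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, found {classes}")
    y = (features.labels == classes[1]).to_numpy().astype(int)
    if min(np.bincount(y)) < folds:
        raise ValueError("each class needs at least `folds` samples")
    if model == "svm":
        estimator, space = SVC(), _svm_search_space()
    elif model == "rf":
        estimator, space = RandomForestClassifier(), _rf_search_space()
    else:
        raise ValueError("model must be 'svm' or 'rf'")

    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs, best_params, importances = [], [], []
    for fold_i, (train, test) in enumerate(outer.split(X, y)):
        search = RandomizedSearchCV(
            estimator,
            space,
            n_iter=search_iterations,
            scoring="roc_auc",
            cv=StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed),
            random_state=seed + fold_i,
            n_jobs=1,
        )
        search.fit(X[train], y[train])
        fitted = search.best_estimator_
        if model == "svm":
            scores = fitted.decision_function(X[test])
        else:
            scores = fitted.predict_proba(X[test])[:, 1]
            importances.append(fitted.feature_importances_)
        fold_aucs.append(float(roc_auc_score(y[test], scores)))
        best_params.append(dict(search.best_params_))
    fi = None
    if importances:
        fi = pd.Series(np.mean(importances, axis=0), index=features.X.columns)
    return ModelReport(
        model=model,
        fold_aucs=fold_aucs,
        median_auc=float(np.median(fold_aucs)),
        best_params=best_params,
        seed=seed,
        feature_importances=fi,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability that a random positive outscores a random negative
    (ties count half) — the rescaled Mann-Whitney U statistic."""
    y = np.asarray(labels)
    uniq = np.unique(y)
    if uniq.size != 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))
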