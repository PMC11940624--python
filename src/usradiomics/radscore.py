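"""Rad-Score computation and multi-classifier evaluation.

A Rad-Score is the linear combination of the selected radiomic features
weighted by their LASSO coefficients (no intercept; downstream classifiers
absorb any offset).  ``radscore1`` denotes a tumor-only signature,
``radscore2`` a tumor+peritumoral one.

Classifier evaluation follows the study protocol this pipeline mirrors:
a stratified 75/25 split, four classifiers (random forest, gradient
boosting on stumps, k-nearest neighbours, RBF support-vector machine) on
the predictors {Rad-Score, Ki67-high}, and a metric panel of AUC,
specificity, sensitivity, PPV, NPV and accuracy with an exact
Clopper-Pearson 95% CI, plus permutation "1 - AUC" predictor importances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.base import BaseEstimator
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .selection import CascadeConfig, SelectionResult, run_cascade

__all__ = [
    "RadScoreModel",
    "ClassifierReport",
    "REFERENCE_RADSCORE1",
    "REFERENCE_RADSCORE2",
    "rad_score",
    "split_cohort",
    "roc_points",
    "trapezoidal_auc",
    "clopper_pearson",
    "train_and_evaluate",
    "importance_1auc",
    "RadiomicsSignature",
    "CLASSIFIER_KINDS",
]

# Published reference coefficient sets for the worked example: a tumor-only
# signature (seven features) and a tumor+peritumoral signature (five
# features) from a breast-ultrasound study of pathogenic-variant status.
REFERENCE_RADSCORE1: Mapping[str, float] = {
    "S(0,1)Contrast": 0.11,
    "S(2,2)AngScMom": 0.94,
    "S(5,5)SumVarnc": -0.01,
    "135dr_GLevNonU": -0.49,
    "Teta2": -0.29,
    "WavEnLL_s6": -0.73,
    "WavEnLH_s6": -0.32,
}
REFERENCE_RADSCORE2: Mapping[str, float] = {
    "Perc.01.": -0.59,
    "S(5,5)SumEntrp": -0.31,
    "Horzl_RLNonUni": -0.03,
    "WavEnHL_s3": -0.38,
    "WavEnHH_s6": -0.04,
}


@dataclass
class RadScoreModel:
    """Named LASSO coefficients defining one radiomic signature.

    When ``feature_means``/``feature_sds`` are set, inputs are
    standardized before weighting (matching coefficients fitted on
    standardized features); otherwise raw values are weighted directly.
    """

    coefficients: dict[str, float]
    lam: float | None = None
    scope: Literal["radscore1", "radscore2"] = "radscore1"
    feature_means: dict[str, float] = field(default_factory=dict)
    feature_sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.coefficients.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite coefficient for {k!r}")

    @classmethod
    def from_selection(
        cls, result: SelectionResult, scope: Literal["radscore1", "radscore2"]
    ) -> "RadScoreModel":
        return cls(
            coefficients=dict(result.final_features),
            lam=result.lambda_,
            scope=scope,
            feature_means={k: result.feature_means[k] for k in result.final_features},
            feature_sds={k: result.feature_sds[k] for k in result.final_features},
        )


def rad_score(x, model: RadScoreModel):
    """Linear Rad-Score: sum_i beta_i * x_i (optionally standardized), no
    intercept.

    ``x`` may be a mapping, a pandas Series/DataFrame, for one lesion or a
    table of lesions.  A model feature missing from ``x`` raises an error
    naming it.
    """
    if isinstance(x, Mapping):
        x = pd.Series(x)
    if isinstance(x, pd.Series):
        frame, squeeze = x.to_frame().T, True
    else:
        frame, squeeze = pd.DataFrame(x), False
    missing = [k for k in model.coefficients if k not in frame.columns]
    if missing:
        raise ValueError(f"feature(s) missing from input: {missing}")
    total = np.zeros(len(frame))
    for name, b in model.coefficients.items():
        v = frame[name].to_numpy(dtype=np.float64)
        if model.feature_means:
            v = (v - model.feature_means[name]) / model.feature_sds[name]
        total += b * v
    return float(total[0]) if squeeze else total


# ---------------------------------------------------------------------------
# Split and metrics


def split_cohort(labels, ratio: float = 0.75, seed: int = 0):
    """Stratified train/test split of indices; disjoint and exhaustive."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("binary labels required")
    if counts.min() < 4:
        raise ValueError("need at least 4 samples per class to stratify a 3:1 split")
    idx = np.arange(labels.size)
    tr, te = train_test_split(
        idx, train_size=ratio, stratify=labels, random_state=seed, shuffle=True
    )
    return np.sort(tr), np.sort(te)


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC curve at all unique thresholds (threshold, fpr, tpr)."""
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, dtype=np.float64))
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def trapezoidal_auc(scores, labels) -> float:
    pts = roc_points(scores, labels)
    return float(np.trapezoid(pts["tpr"], pts["fpr"]))


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval for k/n."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


ClassifierKind = Literal["random_forest", "boosting", "knn", "svm"]
CLASSIFIER_KINDS: tuple[ClassifierKind, ...] = (
    "random_forest",
    "boosting",
    "knn",
    "svm",
)


@dataclass
class ClassifierCfg:
    """Hyperparameters for the four evaluation classifiers (defaults:
    500 trees, 100 boosting rounds on stumps, k=5, RBF kernel)."""

    n_trees: int = 500
    n_boost_rounds: int = 100
    knn_k: int = 5
    svm_kernel: str = "rbf"


@dataclass
class ClassifierReport:
    """Held-out metric panel for one classifier.

    The identities sens = TP/(TP+FN), spec = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), accuracy = (TP+TN)/n hold exactly by construction;
    ``accuracy_ci`` is the exact binomial interval.  ``auc`` is NaN when
    the test partition is single-class.
    """

    kind: ClassifierKind
    auc: float
    specificity: float
    sensitivity: float
    ppv: float
    npv: float
    accuracy: float
    accuracy_ci: tuple[float, float]
    tp: int
    fp: int
    tn: int
    fn: int
    importances: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls, kind: ClassifierKind, tp: int, fp: int, tn: int, fn: int,
        auc: float = np.nan, importances: dict[str, float] | None = None,
    ) -> "ClassifierReport":
        n = tp + fp + tn + fn

        def ratio(num, den):
            return num / den if den > 0 else np.nan

        return cls(
            kind=kind,
            auc=auc,
            specificity=ratio(tn, tn + fp),
            sensitivity=ratio(tp, tp + fn),
            ppv=ratio(tp, tp + fp),
            npv=ratio(tn, tn + fn),
            accuracy=(tp + tn) / n,
            accuracy_ci=clopper_pearson(tp + tn, n),
            tp=tp, fp=fp, tn=tn, fn=fn,
            importances=importances or {},
        )

    def as_row(self) -> dict:
        lo, hi = self.accuracy_ci
        return {
            "classifier": self.kind,
            "AUC": self.auc,
            "Specificity": self.specificity,
            "Sensitivity": self.sensitivity,
            "PPV": self.ppv,
            "NPV": self.npv,
            "Accuracy": self.accuracy,
            "CI_low": lo,
            "CI_high": hi,
            **{f"importance_{k}": v for k, v in self.importances.items()},
        }


def _make_classifier(kind: ClassifierKind, cfg: ClassifierCfg, seed: int):
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=cfg.n_trees, random_state=seed)
    if kind == "boosting":
        return GradientBoostingClassifier(
            n_estimators=cfg.n_boost_rounds, max_depth=1, random_state=seed
        )
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=cfg.knn_k)
    if kind == "svm":
        return SVC(kernel=cfg.svm_kernel, probability=True, random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}")


def train_and_evaluate(
    kind: ClassifierKind,
    predictors: pd.DataFrame,
    labels,
    split: tuple[np.ndarray, np.ndarray],
    cfg: ClassifierCfg | None = None,
    seed: int = 0,
    importance_permutations: int = 100,
) -> ClassifierReport:
    """Fit on the training partition and report held-out metrics.

    The confusion threshold is a 0.5 posterior; AUC uses the continuous
    score.  When the test partition contains a single class the AUC is an
    undefined (NaN) marker while the count-based metrics are still
    reported.
    """
    cfg = cfg or ClassifierCfg()
    labels = np.asarray(labels)
    tr, te = split
    X = predictors.to_numpy(dtype=np.float64)
    clf = _make_classifier(kind, cfg, seed)
    clf.fit(X[tr], labels[tr])
    scores = clf.predict_proba(X[te])[:, 1]
    y_te = labels[te]
    pred = (scores >= 0.5).astype(int)
    tp = int(((pred == 1) & (y_te == 1)).sum())
    fp = int(((pred == 1) & (y_te == 0)).sum())
    tn = int(((pred == 0) & (y_te == 0)).sum())
    fn = int(((pred == 0) & (y_te == 1)).sum())
    auc = trapezoidal_auc(scores, y_te) if np.unique(y_te).size == 2 else np.nan
    imps = importance_1auc(
        clf, predictors.iloc[te], y_te, n_permutations=importance_permutations,
        seed=seed,
    ) if np.unique(y_te).size == 2 else {}
    return ClassifierReport.from_counts(kind, tp, fp, tn, fn, auc=auc,
                                        importances=imps)


def importance_1auc(
    model, predictors_test: pd.DataFrame, labels_test,
    n_permutations: int = 100, seed: int = 0,
) -> dict[str, float]:
    """Permutation predictor importance on the 1 - AUC scale.

    Importance of predictor j = 1 - mean AUC of the fitted model's scores
    on the test partition after permuting column j (seeded, averaged over
    ``n_permutations`` draws).  Permuting a non-influential predictor
    leaves the AUC unchanged, so its importance equals 1 - AUC_full.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(labels_test)
    X = predictors_test.to_numpy(dtype=np.float64)
    out: dict[str, float] = {}
    for j, name in enumerate(predictors_test.columns):
        aucs = np.empty(n_permutations)
        for r in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            aucs[r] = trapezoidal_auc(model.predict_proba(Xp)[:, 1], y)
        out[name] = float(1.0 - aucs.mean())
    return out


# ---------------------------------------------------------------------------
# End-to-end estimator


class RadiomicsSignature(BaseEstimator):
    """Feature table -> cascade -> Rad-Score, as an sklearn estimator.

    ``fit(X, y)`` runs the three-step selection cascade on a named feature
    DataFrame and stores the resulting :class:`RadScoreModel`;
    ``decision_function(X)`` returns per-lesion Rad-Scores.  If the
    cascade survives no feature, scores are identically zero (the
    signature carries no information).
    """

    def __init__(self, cascade: CascadeConfig | None = None,
                 scope: Literal["radscore1", "radscore2"] = "radscore1"):
        self.cascade = cascade
        self.scope = scope

    def fit(self, X: pd.DataFrame, y):
        cfg = self.cascade or CascadeConfig()
        self.selection_ = run_cascade(X, y, cfg)
        self.model_ = RadScoreModel.from_selection(self.selection_, self.scope)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        if not self.model_.coefficients:
            return np.zeros(len(X))
        return np.asarray(rad_score(X, self.model_))
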