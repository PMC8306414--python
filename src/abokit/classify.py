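"""Multinomial ABO blood-type prediction from tag-SNP dosages, with the
full evaluation battery: prevalence-threshold binary metrics, ROC/AUC and
precision-recall points, confusion matrix, accuracy and micro/macro F1.

The classifier is a ridge-penalized multinomial log-linear model with type
O as the reference level.  The small ridge (default 1e-4) is mandatory:
noiseless tagging makes the four types linearly separable, so the
unpenalized maximum-likelihood estimate does not exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.utils.validation import check_is_fitted

from ._glm import fit_multinomial
from .data import BLOOD_TYPES

PROB_COLUMNS = ["pO", "pA", "pB", "pAB"]


class ABOGenotypeClassifier(BaseEstimator, ClassifierMixin):
    """Predict ABO blood type from minor-allele dosages of selected SNPs.

    Parameters
    ----------
    ridge : float
        L2 penalty on all coefficients.  Must be positive: with perfect tag
        SNPs the classes are separable and the unpenalized fit diverges.
    snp_ids : list of str, optional
        Column labels for the dosage matrix; purely descriptive.

    Attributes
    ----------
    classes_ : ndarray of shape (4,)
        Always ``["O", "A", "B", "AB"]`` (O is the reference level).
    coef_ : ndarray of shape (3, n_features)
        Per-class (A, B, AB vs. O) dosage coefficients.
    intercept_ : ndarray of shape (3,)
    prevalences_ : dict
        Training prevalence of each blood type (used as the default binary
        decision threshold and as the argmax tie-break).
    training_combinations_ : set of tuple
        Joint dosage combinations seen in training; predictions outside
        this set are extrapolations.
    """

    def __init__(self, ridge: float = 1e-4, snp_ids: list[str] | None = None):
        self.ridge = ridge
        self.snp_ids = snp_ids

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=object)
        if self.ridge <= 0:
            raise ValueError("ridge must be positive (separable classes)")
        if np.isnan(X).any():
            raise ValueError("missing dosages not allowed in training data")
        present = set(y)
        absent = [t for t in BLOOD_TYPES if t not in present]
        if absent:
            raise ValueError(f"blood types absent from training data: {absent}")
        unknown = present - set(BLOOD_TYPES)
        if unknown:
            raise ValueError(f"unknown blood types: {sorted(unknown)}")
        y_index = np.array([BLOOD_TYPES.index(t) for t in y])
        design = np.column_stack([np.ones(len(X)), X])
        # separable classes converge slowly once saturated: the ridge-only
        # curvature makes Newton creep, so the iteration cap is generous
        fit = fit_multinomial(
            design, y_index, n_classes=4, ridge=self.ridge, max_iter=3000,
            tol=1e-8,
        )
        if not fit.converged:
            raise RuntimeError(
                f"multinomial fit failed to converge after {fit.n_iter} "
                f"iterations (ridge={fit.ridge})"
            )
        self.classes_ = np.array(BLOOD_TYPES, dtype=object)
        self.intercept_ = fit.beta[:, 0].copy()
        self.coef_ = fit.beta[:, 1:].copy()
        self.n_features_in_ = X.shape[1]
        n = len(y)
        self.prevalences_ = {t: float(np.mean(y == t)) for t in BLOOD_TYPES}
        self.training_combinations_ = {tuple(row) for row in X}
        self.converged_ = fit.converged
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} dosage columns, got "
                f"{X.shape[1]}"
            )
        if np.isnan(X).any():
            raise ValueError(
                "missing dosage in prediction input; impute or drop the "
                "sample explicitly (no silent imputation)"
            )
        return X

    def decision_function(self, X) -> np.ndarray:
        """Linear predictors of A, B, AB relative to the O reference (0)."""
        X = self._check_X(X)
        return self.intercept_ + X @ self.coef_.T

    def predict_proba(self, X) -> np.ndarray:
        """Softmax probabilities over (O, A, B, AB); rows sum to 1."""
        eta = self.decision_function(X)
        full = np.column_stack([np.zeros(len(eta)), eta])
        full -= full.max(axis=1, keepdims=True)
        e = np.exp(full)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        """Argmax blood type; exact ties go to the more prevalent type."""
        proba = self.predict_proba(X)
        prev = np.array([self.prevalences_[t] for t in BLOOD_TYPES])
        best = proba.max(axis=1, keepdims=True)
        tie_mask = np.isclose(proba, best)
        keyed = np.where(tie_mask, prev[None, :], -1.0)
        return self.classes_[np.argmax(keyed, axis=1)]

    def is_extrapolation(self, X) -> np.ndarray:
        """True where the joint dosage combination was unseen in training."""
        X = self._check_X(X)
        return np.array(
            [tuple(row) not in self.training_combinations_ for row in X]
        )


def fit_abo_classifier(
    dosages, serotypes, ridge: float = 1e-4,
    snp_ids: list[str] | None = None,
) -> ABOGenotypeClassifier:
    """Convenience wrapper returning a fitted :class:`ABOGenotypeClassifier`."""
    return ABOGenotypeClassifier(ridge=ridge, snp_ids=snp_ids).fit(
        dosages, serotypes
    )


def predict_probabilities(
    model: ABOGenotypeClassifier, dosages
) -> pd.DataFrame:
    """Per-sample type probabilities plus an extrapolation flag."""
    proba = model.predict_proba(dosages)
    df = pd.DataFrame(proba, columns=PROB_COLUMNS)
    df["extrapolated"] = model.is_extrapolation(dosages)
    return df


def binary_metrics(
    prob_of_type: np.ndarray,
    truth_indicator: np.ndarray,
    threshold: float,
) -> dict[str, float]:
    """2x2-table metrics at a fixed probability threshold.

    A sample is called positive when its probability is >= the threshold
    (boundary inclusive).  Ratios with zero denominators are reported as
    NaN rather than 0.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0,1)")
    prob = np.asarray(prob_of_type, float)
    truth = np.asarray(truth_indicator).astype(bool)
    pred = prob >= threshold
    tp = int(np.sum(pred & truth))
    fn = int(np.sum(~pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    return _table_metrics(tp, fn, fp, tn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else np.nan


def _table_metrics(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    if np.isnan(ppv) or np.isnan(sens) or (ppv + sens) == 0:
        f1 = np.nan
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    return {
        "accuracy": _safe_div(tp + tn, tp + fn + fp + tn),
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "f1": f1,
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
    }


def roc_auc(
    prob_of_type: np.ndarray, truth_indicator: np.ndarray
) -> tuple[float, pd.DataFrame]:
    """AUC by the rank (Mann-Whitney) statistic with midrank ties, plus the
    ROC curve swept over the unique probability thresholds."""
    truth = np.asarray(truth_indicator).astype(int)
    prob = np.asarray(prob_of_type, float)
    if len(np.unique(truth)) < 2:
        raise ValueError("AUC undefined: truth contains a single class")
    from scipy.stats import rankdata

    ranks = rankdata(prob)  # midranks for ties
    n_pos = truth.sum()
    n_neg = len(truth) - n_pos
    auc = (ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(truth, prob)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return float(auc), curve


def pr_points(
    prob_of_type: np.ndarray, truth_indicator: np.ndarray
) -> pd.DataFrame:
    """Precision-recall curve points (plot-ready)."""
    precision, recall, _ = precision_recall_curve(
        np.asarray(truth_indicator).astype(int), np.asarray(prob_of_type)
    )
    return pd.DataFrame({"recall": recall, "precision": precision})


@dataclass
class ClassificationReport:
    """Per-type and overall multi-class performance."""

    confusion: pd.DataFrame          # rows true type, columns predicted
    per_type: pd.DataFrame           # accuracy..auc per blood type
    accuracy: float
    f1_micro: float
    f1_macro: float

    def validate(self) -> None:
        trace = np.trace(self.confusion.to_numpy())
        total = self.confusion.to_numpy().sum()
        if total and abs(self.accuracy - trace / total) > 1e-12:
            raise ValueError("accuracy does not equal confusion trace/total")


def multiclass_metrics(
    probabilities,
    serotypes,
    train_prevalences: dict[str, float] | None = None,
) -> ClassificationReport:
    """Argmax-assignment multi-class report.

    Micro F1 pools the one-vs-rest tables (equal to accuracy for
    single-label assignment); macro F1 averages the defined per-type F1
    values, warning when any type's F1 is undefined.  Per-type AUC uses the
    type's predicted probability against its one-vs-rest indicator.
    """
    proba = np.asarray(probabilities, float)
    sero = np.asarray(serotypes, dtype=object)
    if train_prevalences is None:
        train_prevalences = {
            t: float(np.mean(sero == t)) for t in BLOOD_TYPES
        }
    prev = np.array([train_prevalences[t] for t in BLOOD_TYPES])
    best = proba.max(axis=1, keepdims=True)
    tie_mask = np.isclose(proba, best)
    keyed = np.where(tie_mask, prev[None, :], -1.0)
    pred = np.array(BLOOD_TYPES, dtype=object)[np.argmax(keyed, axis=1)]

    conf = pd.DataFrame(
        0, index=BLOOD_TYPES, columns=BLOOD_TYPES, dtype=int
    )
    for t, p in zip(sero, pred):
        conf.loc[t, p] += 1

    n = len(sero)
    accuracy = float(np.trace(conf.to_numpy())) / n
    rows = []
    pooled = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    f1s = []
    for i, t in enumerate(BLOOD_TYPES):
        tp = int(conf.loc[t, t])
        fn = int(conf.loc[t].sum() - tp)
        fp = int(conf[t].sum() - tp)
        tn = n - tp - fn - fp
        m = _table_metrics(tp, fn, fp, tn)
        for k in pooled:
            pooled[k] += m[k]
        if len(np.unique(sero == t)) == 2:
            auc, _ = roc_auc(proba[:, i], sero == t)
        else:
            auc = np.nan
        m["auc"] = auc
        m["type"] = t
        rows.append(m)
        if np.isnan(m["f1"]):
            warnings.warn(
                f"F1 undefined for type {t}; excluded from macro average",
                stacklevel=2,
            )
        else:
            f1s.append(m["f1"])
    micro = _table_metrics(**pooled)["f1"]
    per_type = pd.DataFrame(rows).set_index("type")[
        ["accuracy", "sensitivity", "specificity", "ppv", "npv", "f1", "auc"]
    ]
    report = ClassificationReport(
        confusion=conf,
        per_type=per_type,
        accuracy=accuracy,
        f1_micro=float(micro),
        f1_macro=float(np.mean(f1s)) if f1s else np.nan,
    )
    report.validate()
    return report


def probability_pattern_table(
    model: ABOGenotypeClassifier, dosages
) -> pd.DataFrame:
    """Predicted probabilities per observed joint genotype combination.

    For k biallelic SNPs at most 3^k rows; each row carries the dosage
    combination, its observed count, the four predicted probabilities and
    the argmax type.
    """
    X = np.asarray(dosages, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    snp_ids = model.snp_ids or [f"snp{i + 1}" for i in range(X.shape[1])]
    combos, counts = np.unique(X, axis=0, return_counts=True)
    proba = model.predict_proba(combos)
    pred = model.predict(combos)
    df = pd.DataFrame(combos, columns=snp_ids)
    df["count"] = counts
    for j, c in enumerate(PROB_COLUMNS):
        df[c] = proba[:, j]
    df["predicted_type"] = pred
    return df
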