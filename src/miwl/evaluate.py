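"""Model zoo, validation schemes, metrics and statistical comparisons.

Five model families are supported with fixed study hyperparameters: linear
regression (LnR), logistic regression (LgR, balanced class weights + L2),
a multilayer perceptron (MLP, hidden layers 32/16/4, ReLU, Adam, batch
128), a random forest (RF, 100 trees, depth 5, bootstrap) and an RBF
support vector machine (degree 3, C = 1.0, epsilon = 0.2).  Validation
schemes: 10-fold CV, leave-one-subject-out, and a stratified 10% holdout.

Statistics: ROC/AUC via the Mann-Whitney statistic (ties counted half),
the Wilcoxon signed-rank test with exact enumeration of the null for
n <= 12, and DeLong's placement-value test for comparing two correlated
AUCs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold, StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.svm import SVC, SVR

MODEL_NAMES = ("LnR", "LgR", "MLP", "RF", "SVM")


@dataclass
class ModelSpec:
    """A named model family with its task and (fixed) hyperparameters."""

    name: str
    task: str  # "regression" | "classification"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.name == "LnR" and self.task != "regression":
            raise ValueError("LnR is a regression model")
        if self.name == "LgR" and self.task != "classification":
            raise ValueError("LgR is a classification model")


def build_model(spec: ModelSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator for a spec, seeded."""
    hp = dict(spec.hyperparameters)
    if spec.name == "LnR":
        return LinearRegression(**hp)
    if spec.name == "LgR":
        hp.setdefault("class_weight", "balanced")
        hp.setdefault("max_iter", 2000)  # L2 regularization is sklearn's default
        return LogisticRegression(random_state=seed, **hp)
    if spec.name == "MLP":
        hp.setdefault("hidden_layer_sizes", (32, 16, 4))
        hp.setdefault("activation", "relu")
        hp.setdefault("solver", "adam")
        hp.setdefault("batch_size", 128)
        hp.setdefault("max_iter", 500)
        hp.setdefault("tol", 1e-4)
        cls = MLPRegressor if spec.task == "regression" else MLPClassifier
        return cls(random_state=seed, **hp)
    if spec.name == "RF":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("max_depth", 5)
        hp.setdefault("bootstrap", True)
        cls = RandomForestRegressor if spec.task == "regression" else RandomForestClassifier
        return cls(random_state=seed, **hp)
    if spec.name == "SVM":
        hp.setdefault("kernel", "rbf")
        hp.setdefault("degree", 3)
        hp.setdefault("C", 1.0)
        if spec.task == "regression":
            hp.setdefault("epsilon", 0.2)
            return SVR(**hp)
        hp.pop("epsilon", None)
        return SVC(random_state=seed, **hp)
    raise ValueError(f"unknown model {spec.name!r}")


def split_scheme(
    n: int, scheme: str, seed: int = 0,
    labels: np.ndarray | None = None, subjects: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_idx, test_idx) pairs for kfold10, loo_subject or holdout10."""
    idx = np.arange(n)
    if scheme == "kfold10":
        kf = KFold(n_splits=10, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in kf.split(idx)]
    if scheme == "loo_subject":
        if subjects is None:
            raise ValueError("loo_subject requires subject IDs")
        subjects = np.asarray(subjects)
        return [
            (idx[subjects != s], idx[subjects == s]) for s in np.unique(subjects)
        ]
    if scheme == "holdout10":
        if labels is None:
            raise ValueError("holdout10 requires labels for stratification")
        sss = StratifiedShuffleSplit(n_splits=1, test_size=0.1, random_state=seed)
        tr, te = next(sss.split(idx, labels))
        return [(tr, te)]
    raise ValueError(f"unknown scheme {scheme!r}")


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("inputs must be non-empty and equal-length")
    d = y_pred - y_true
    return {"mae": float(np.abs(d).mean()), "mse": float((d**2).mean())}


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int
    positive_class_label: object = 1

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive_label=1) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive_label
        pos_p = y_pred == positive_label
        return cls(
            tp=int((pos_t & pos_p).sum()), fn=int((pos_t & ~pos_p).sum()),
            fp=int((~pos_t & pos_p).sum()), tn=int((~pos_t & ~pos_p).sum()),
            positive_class_label=positive_label,
        )


def _safe_ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Sensitivity, specificity, precision, recall, F1, accuracy, balanced accuracy.

    Ratios with a zero denominator are reported as None (undefined), never 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _safe_ratio(cm.tp, cm.tp + cm.fn)
    spec = _safe_ratio(cm.tn, cm.tn + cm.fp)
    prec = _safe_ratio(cm.tp, cm.tp + cm.fp)
    f1 = None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    bal = None if (sens is None or spec is None) else (sens + spec) / 2
    return {
        "sensitivity": sens, "specificity": spec, "precision": prec,
        "recall": sens, "f1": f1,
        "accuracy": (cm.tp + cm.tn) / cm.total, "balanced_accuracy": bal,
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> dict:
    """ROC curve and AUC = Mann-Whitney statistic / (n_pos * n_neg), ties half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    from sklearn.metrics import roc_curve
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return {"auc": float(auc), "fpr": fpr, "tpr": tpr, "thresholds": thresholds}


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test

def _signed_rank_parts(x, y=None):
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return d, ranks, w_plus, w_minus


def wilcoxon_signed_rank(
    x, y=None, alternative: str = "two_sided", mode: str = "auto",
) -> dict:
    """Wilcoxon signed-rank test on paired samples (or pre-paired differences).

    The reported statistic is min(W+, W-) for the two-sided test and W+ for
    "greater" (H1: x > y).  For n <= 12 (or ``mode="exact"``) the null
    distribution of W+ is enumerated over all 2^n sign assignments, which is
    exact even with tied ranks; otherwise a normal approximation with tie and
    continuity corrections is used.
    """
    if alternative not in ("two_sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d, ranks, w_plus, w_minus = _signed_rank_parts(x, y)
    n = d.size
    exact = mode == "exact" or (mode == "auto" and n <= 12)
    if exact:
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])  # 2^n rank sums
        if alternative == "greater":
            stat = w_plus
            p = float((totals >= w_plus - 1e-9).mean())
        else:
            stat = min(w_plus, w_minus)
            w_tot = ranks.sum()
            p = float(
                (totals <= stat + 1e-9).mean() + (totals >= w_tot - stat - 1e-9).mean()
            )
            p = min(p, 1.0)
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the variance
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
        sd = np.sqrt(var)
        if alternative == "greater":
            stat = w_plus
            z = (w_plus - mean - 0.5) / sd
            p = float(stats.norm.sf(z))
        else:
            stat = min(w_plus, w_minus)
            z = (stat - mean + 0.5) / sd
            p = float(min(2 * stats.norm.cdf(z), 1.0))
    return {"statistic": float(stat), "p": p, "n": int(n), "exact": exact}


# ---------------------------------------------------------------------------
# DeLong's test for two correlated AUCs

def _placements(scores: np.ndarray, labels: np.ndarray):
    """Placement values (structural components) and the AUC via midranks."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v_pos = (all_ranks[:m] - pos_ranks) / n          # V10 components
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m    # V01 components
    auc = v_pos.mean()
    return auc, v_pos, v_neg


def delong_auc_test(
    scores_a, scores_b, labels, alternative: str = "greater",
) -> dict:
    """Paired DeLong comparison of two AUCs computed on the same labels.

    One-sided ``alternative="greater"`` tests H1: AUC_a > AUC_b (the study's
    hypothesis when a carries the MI-based scores); "two_sided" is also
    available.  Returns z, p, both AUCs and their individual 95% CIs.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores_a.shape != labels.shape or scores_b.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    auc_a, va_pos, va_neg = _placements(scores_a, labels)
    auc_b, vb_pos, vb_neg = _placements(scores_b, labels)
    m, n = va_pos.size, va_neg.size
    V10 = np.vstack([va_pos, vb_pos])
    V01 = np.vstack([va_neg, vb_neg])
    s10 = np.cov(V10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(V01) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var_diff = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var_diff)
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "two_sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    zq = stats.norm.ppf(0.975)
    ci_a = (auc_a - zq * np.sqrt(max(S[0, 0], 0.0)), auc_a + zq * np.sqrt(max(S[0, 0], 0.0)))
    ci_b = (auc_b - zq * np.sqrt(max(S[1, 1], 0.0)), auc_b + zq * np.sqrt(max(S[1, 1], 0.0)))
    return {
        "auc_a": float(auc_a), "auc_b": float(auc_b), "z": float(z), "p": p,
        "ci95_a": tuple(map(float, ci_a)), "ci95_b": tuple(map(float, ci_b)),
    }


# ---------------------------------------------------------------------------
# experiment driver

def _decision_scores(model, X):
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    return model.predict(X)


@dataclass
class EvaluationReport:
    """Per-model fold metrics, pooled confusion matrices and ROC curves."""

    scheme: str
    task: str
    fold_metrics: pd.DataFrame              # one row per (model, fold)
    confusion: dict = field(default_factory=dict)   # model -> ConfusionMatrix (pooled)
    roc: dict = field(default_factory=dict)         # model -> roc_auc() output

    def summary(self) -> pd.DataFrame:
        """min / max / mean of each metric per model across folds."""
        metrics = [c for c in self.fold_metrics.columns if c not in ("model", "fold")]
        return self.fold_metrics.groupby("model")[metrics].agg(["min", "max", "mean"])


def run_experiment(
    features: np.ndarray, targets: np.ndarray, specs: list[ModelSpec],
    scheme: str = "kfold10", seed: int = 0,
    subjects: np.ndarray | None = None, positive_label=1,
) -> EvaluationReport:
    """Train and evaluate every spec under one validation scheme.

    Regression targets are continuous workload scores; classification
    targets are binary labels with the study's positive-class conventions
    (Low workload positive for workload classification, Car positive for
    event classification).  Out-of-fold predictions are pooled per model for
    the confusion matrix and ROC curve.  Deterministic for a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and targets are misaligned")
    tasks = {s.task for s in specs}
    if len(tasks) != 1:
        raise ValueError("all specs in one experiment must share a task")
    task = tasks.pop()
    labels = None
    if task == "classification":
        labels = (y == positive_label).astype(int)
    folds = split_scheme(X.shape[0], scheme, seed=seed, labels=labels, subjects=subjects)

    rows = []
    confusion: dict = {}
    rocs: dict = {}
    pooled_scores: dict = {k.name: [] for k in specs}
    pooled_pred: dict = {k.name: [] for k in specs}
    pooled_true: list = []
    for fold_i, (tr, te) in enumerate(folds):
        for spec in specs:
            model = build_model(spec, seed=seed)
            if task == "regression":
                model.fit(X[tr], y[tr].astype(float))
                pred = model.predict(X[te])
                row = regression_metrics(y[te].astype(float), pred)
            else:
                model.fit(X[tr], labels[tr])
                pred = model.predict(X[te])
                cm = ConfusionMatrix.from_predictions(labels[te], pred)
                row = {
                    k: v for k, v in classification_metrics(cm).items()
                    if v is not None
                }
                pooled_scores[spec.name].append(_decision_scores(model, X[te]))
                pooled_pred[spec.name].append(pred)
            rows.append({"model": spec.name, "fold": fold_i, **row})
        pooled_true.append(te)
    if task == "classification":
        true_all = labels[np.concatenate(pooled_true)]
        for spec in specs:
            pred_all = np.concatenate(pooled_pred[spec.name])
            confusion[spec.name] = ConfusionMatrix.from_predictions(true_all, pred_all)
            scores_all = np.concatenate(pooled_scores[spec.name])
            rocs[spec.name] = roc_auc(scores_all, true_all)
    return EvaluationReport(
        scheme=scheme, task=task,
        fold_metrics=pd.DataFrame(rows), confusion=confusion, roc=rocs,
    )
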