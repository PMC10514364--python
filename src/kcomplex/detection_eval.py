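"""Classifier harness, 5-fold cross-validation, and the evaluation metrics.

Three linear-ish classifiers (LDA, linear SVM, decision tree) are evaluated
under stratified k-fold cross-validation.  Per fold the confusion matrix
yields

    sensitivity = TP / (TP + FN)          (true positive rate)
    specificity = TN / (TN + FP)          (true negative rate)
    accuracy    = (TP + TN) / n
    F_beta      = (1 + b^2) TP / ((1 + b^2) TP + b^2 FN + FP)
    kappa       = (p_o - p_e) / (1 - p_e)   (Cohen's chance-corrected agreement)

plus the fold mean and standard deviation of each.  Division-by-zero
branches return 0 with a flag instead of NaN.

Feature screening statistics mirror the per-feature analysis used to rank
candidate features: Spearman correlation with the label, one-way ANOVA
p-value, and the Fisher separability criterion J1 = tr(S_w^-1 S_m) with
scatter matrices normalized by n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .feature_selection import FeatureMatrix, SelectionResult

MODELS = ("lda", "lsvm", "dt")


# ---------------------------------------------------------------------------
# confusion matrix and metric bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, int)
        y_pred = np.asarray(y_pred, int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


@dataclass
class MetricBundle:
    sensitivity: float
    specificity: float
    accuracy: float
    fscore: float
    kappa: float
    beta: float = 1.0
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "fscore": self.fscore,
            "kappa": self.kappa,
            "beta": self.beta,
            "flags": list(self.flags),
        }


def metrics(cm: ConfusionMatrix, beta: float = 1.0) -> MetricBundle:
    """Evaluate the full metric bundle on one confusion matrix."""
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    n = cm.n
    flags: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(f"{name}_undefined")
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    acc = (tp + tn) / n
    b2 = beta * beta
    fscore = ratio((1 + b2) * tp, (1 + b2) * tp + b2 * fn + fp, "fscore")
    p_o = acc
    p_e = ((tp + fn) * (tp + fp) + (fn + tn) * (fp + tn)) / (n * n)
    if p_e == 1.0:
        flags.append("kappa_undefined")
        kappa = 0.0
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return MetricBundle(sens, spec, acc, fscore, kappa, beta, flags)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def make_model(model: str, seed: int | None = 0, svm_c: float = 1.0,
               dt_max_depth: int | None = None):
    """Standardize-then-classify pipeline for one of lda / lsvm / dt."""
    if model == "lda":
        clf = LinearDiscriminantAnalysis()
    elif model == "lsvm":
        clf = LinearSVC(C=svm_c, random_state=seed)
    elif model == "dt":
        clf = DecisionTreeClassifier(criterion="gini", max_depth=dt_max_depth,
                                     random_state=seed)
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    return make_pipeline(StandardScaler(), clf)


def train_predict(
    model: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int | None = 0,
    **model_kw,
) -> np.ndarray:
    """Fit on the training fold (standardization included) and predict.

    Standardization statistics come from the training fold only.
    """
    y_train = np.asarray(y_train, int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training fold contains a single class")
    est = make_model(model, seed=seed, **model_kw)
    est.fit(X_train, y_train)
    return est.predict(X_test)


@dataclass
class EvalReport:
    """Cross-validation outcome: per-fold confusion matrices and metrics."""

    folds: list[ConfusionMatrix]
    per_fold: list[MetricBundle]
    mean: dict
    sd: dict
    model: str
    selected: list[str] | None = None
    selection: SelectionResult | None = None

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "folds": [
                {"tp": c.tp, "fn": c.fn, "fp": c.fp, "tn": c.tn} for c in self.folds
            ],
            "per_fold": [m.as_dict() for m in self.per_fold],
            "mean": self.mean,
            "sd": self.sd,
            "selected_features": self.selected,
        }


def crossvalidate(
    fm: FeatureMatrix,
    model: str = "dt",
    k: int = 5,
    seed: int | None = 42,
    selector=None,
    beta: float = 1.0,
    **model_kw,
) -> EvalReport:
    """Stratified k-fold cross-validation with in-fold selection.

    ``selector`` is an optional callable ``FeatureMatrix -> SelectionResult``
    fitted inside every training fold only, so no information from the test
    fold leaks into feature selection or standardization.
    """
    fm.require_both_classes()
    if fm.n < k:
        raise ValueError(f"n={fm.n} too small for {k}-fold CV")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[ConfusionMatrix] = []
    bundles: list[MetricBundle] = []
    last_selection: SelectionResult | None = None
    for fold_i, (tr, te) in enumerate(cv.split(fm.X, fm.y)):
        y_tr = fm.y[tr]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"fold {fold_i} has a single training class")
        X_tr, X_te = fm.X[tr], fm.X[te]
        if selector is not None:
            sel = selector(FeatureMatrix(X_tr, y_tr, fm.names))
            idx = sel.indices(fm.names)
            if not idx:  # selector chose nothing: keep all features
                idx = list(range(fm.n_features))
            X_tr, X_te = X_tr[:, idx], X_te[:, idx]
            last_selection = sel
        pred = train_predict(model, X_tr, y_tr, X_te, seed=seed, **model_kw)
        cm = ConfusionMatrix.from_labels(fm.y[te], pred)
        folds.append(cm)
        bundles.append(metrics(cm, beta=beta))
    keys = ("sensitivity", "specificity", "accuracy", "fscore", "kappa")
    arr = {k_: np.array([getattr(b, k_) for b in bundles]) for k_ in keys}
    mean = {k_: float(v.mean()) for k_, v in arr.items()}
    sd = {k_: float(v.std(ddof=1)) for k_, v in arr.items()}
    return EvalReport(
        folds=folds,
        per_fold=bundles,
        mean=mean,
        sd=sd,
        model=model,
        selected=list(last_selection.selected) if last_selection else None,
        selection=last_selection,
    )


# ---------------------------------------------------------------------------
# separability screening
# ---------------------------------------------------------------------------

def j1_value(fm: FeatureMatrix, subset: list[str] | None = None,
             ridge: float = 1e-9) -> float:
    """Fisher separability J1 = tr(S_w^-1 S_m).

    S_w is the pooled within-class scatter / n, S_m the weighted
    between-class scatter of class means about the grand mean.  A singular
    S_w is regularized with ridge * trace * I (flagged via logging).
    """
    sub = fm if subset is None else fm.subset(subset)
    X, y = sub.X, sub.y
    classes = np.unique(y)
    if len(classes) < 2:
        return 0.0
    n, F = X.shape
    mu = X.mean(axis=0)
    Sw = np.zeros((F, F))
    Sm = np.zeros((F, F))
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        D = Xc - mc
        Sw += D.T @ D / n
        d = (mc - mu)[:, None]
        Sm += (Xc.shape[0] / n) * (d @ d.T)
    try:
        SwI = np.linalg.inv(Sw)
    except np.linalg.LinAlgError:
        Sw = Sw + ridge * max(np.trace(Sw), 1.0) * np.eye(F)
        SwI = np.linalg.inv(Sw)
    return float(np.trace(SwI @ Sm))


@dataclass
class ScreeningReport:
    names: list[str]
    spearman_rho: np.ndarray
    anova_f: np.ndarray
    anova_p: np.ndarray
    j1: np.ndarray
    significant_05: np.ndarray
    significant_005: np.ndarray
    flags: dict

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature": self.names,
                "spearman_rho": self.spearman_rho,
                "anova_f": self.anova_f,
                "anova_p": self.anova_p,
                "j1": self.j1,
                "sig_05": self.significant_05,
                "sig_005": self.significant_005,
            }
        )


def screen_features(fm: FeatureMatrix) -> ScreeningReport:
    """Per-feature screening: Spearman rho vs. label, one-way ANOVA, J1."""
    fm.require_both_classes()
    for c in np.unique(fm.y):
        if np.sum(fm.y == c) < 3:
            raise ValueError("need at least 3 instances per class")
    rho = np.zeros(fm.n_features)
    fstat = np.zeros(fm.n_features)
    pval = np.ones(fm.n_features)
    j1 = np.zeros(fm.n_features)
    flags: dict[str, str] = {}
    for j, name in enumerate(fm.names):
        x = fm.X[:, j]
        if np.ptp(x) == 0:
            flags[name] = "constant_feature"
            continue
        rho[j] = stats.spearmanr(x, fm.y).statistic
        groups = [x[fm.y == c] for c in np.unique(fm.y)]
        f, p = stats.f_oneway(*groups)
        fstat[j], pval[j] = float(f), float(p)
        j1[j] = j1_value(fm, subset=[name])
    return ScreeningReport(
        names=list(fm.names),
        spearman_rho=rho,
        anova_f=fstat,
        anova_p=pval,
        j1=j1,
        significant_05=pval < 0.05,
        significant_005=pval < 0.005,
        flags=flags,
    )
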