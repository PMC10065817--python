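"""L1-penalized logistic classification of AMR versus everything else.

Features are log2(normalized + 1) endogenous values keyed by gene symbol
(symbols, not probe ids, so a model trained on one panel can score another
panel of the same transcripts).  Preprocessing removes near-zero-variance
genes (caret-style frequency-ratio rule) and one member of every highly
correlated pair, then standardizes each gene; the standardization
parameters are frozen into the model.

The penalty weight lambda multiplies the L1 norm in
``(1/n) * deviance + lambda * sum|beta|`` and is chosen on a descending
grid by stratified 10-fold cross-validation (minimum mean deviance).
Evaluation pools out-of-fold predicted probabilities, with standardization
and fitting redone inside each training fold so no test-fold statistic
leaks into training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .refnorm import NormalizedMatrix

NZV_FREQ_RATIO = 95 / 5
NZV_UNIQUE_FRACTION = 0.10
CORR_CUTOFF = 0.9
POSITIVE_CLASS = "AMR"


class MappingError(KeyError):
    """A model's genes cannot all be mapped onto the target panel."""


def feature_matrix(norm: NormalizedMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Samples x genes feature frame (log2 scale), columns = gene symbols."""
    vals = norm.log_endogenous(pseudocount)
    vals.index = [norm.panel.probe(pid).gene_symbol for pid in vals.index]
    return vals.T


def amr_labels(samples: pd.DataFrame, positive: str = POSITIVE_CLASS) -> np.ndarray:
    return (samples["diagnosis"] == positive).to_numpy(dtype=int)


# ---------------------------------------------------------------------------
# Predictor filters


def near_zero_variance_filter(
    x: pd.DataFrame,
    freq_ratio: float = NZV_FREQ_RATIO,
    unique_fraction: float = NZV_UNIQUE_FRACTION,
) -> tuple[list[str], list[str]]:
    """Split genes into (kept, removed) by the near-zero-variance rule.

    A gene is removed iff the ratio of its most common to second most
    common value exceeds ``freq_ratio`` AND its distinct-value fraction is
    below ``unique_fraction``.  ``x`` is samples x genes.
    """
    kept, removed = [], []
    n = len(x)
    for gene in x.columns:
        counts = x[gene].value_counts().values
        distinct = len(counts)
        if distinct == 1:
            removed.append(gene)
            continue
        ratio = counts[0] / counts[1]
        if ratio > freq_ratio and distinct / n < unique_fraction:
            removed.append(gene)
        else:
            kept.append(gene)
    return kept, removed


def correlation_filter(
    x: pd.DataFrame, cutoff: float = CORR_CUTOFF
) -> tuple[list[str], list[str]]:
    """Greedily drop one member of each |r| > cutoff gene pair.

    At each step the offending pair with the largest |r| is found and the
    member with the larger mean absolute correlation to all remaining
    genes is removed (ties: the lexicographically later symbol goes).
    """
    corr = x.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    corr = corr.fillna(0.0)
    removed: list[str] = []
    while True:
        peak = corr.values.max() if corr.size else 0.0
        if peak <= cutoff:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        mean_a, mean_b = corr[a].mean(), corr[b].mean()
        if mean_a > mean_b:
            victim = a
        elif mean_b > mean_a:
            victim = b
        else:
            victim = max(a, b)
        removed.append(victim)
        corr = corr.drop(index=victim, columns=victim)
    kept = [g for g in x.columns if g not in set(removed)]
    return kept, removed


def apply_filters(x: pd.DataFrame) -> tuple[pd.DataFrame, list[str], list[str]]:
    kept, nzv_removed = near_zero_variance_filter(x)
    kept2, corr_removed = correlation_filter(x[kept])
    return x[kept2], nzv_removed, corr_removed


# ---------------------------------------------------------------------------
# Model


@dataclass
class ClassifierModel:
    panel_name: str
    nzv_removed: list[str]
    corr_removed: list[str]
    feature_means: pd.Series  # frozen standardization, by gene symbol
    feature_sds: pd.Series
    lambda_: float
    coefficients: dict[str, float]  # nonzero only, standardized units
    intercept: float
    cv_spec: dict = field(default_factory=dict)
    cv_deviance: dict[float, float] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return sorted(self.coefficients)

    def coefficients_raw(self) -> tuple[dict[str, float], float]:
        """Coefficients on the unstandardized (log2 expression) scale."""
        raw = {g: b / float(self.feature_sds[g]) for g, b in self.coefficients.items()}
        shift = sum(
            b * float(self.feature_means[g]) / float(self.feature_sds[g])
            for g, b in self.coefficients.items()
        )
        return raw, self.intercept - shift

    def decision_scores(self, x: pd.DataFrame) -> pd.Series:
        """Linear predictor for a samples x genes frame (columns = symbols)."""
        missing = [g for g in self.genes if g not in x.columns]
        if missing:
            raise MappingError(
                f"genes absent from target matrix: {missing}"
            )
        score = np.full(len(x), self.intercept, dtype=float)
        for g, b in self.coefficients.items():
            z = (x[g].to_numpy(float) - float(self.feature_means[g])) / float(
                self.feature_sds[g]
            )
            score += b * z
        return pd.Series(score, index=x.index)

    def predict_proba(self, x: pd.DataFrame) -> pd.Series:
        return 1.0 / (1.0 + np.exp(-self.decision_scores(x)))

    def to_json(self, path) -> None:
        raw, raw_intercept = self.coefficients_raw()
        payload = {
            "panel_name": self.panel_name,
            "nzv_removed": self.nzv_removed,
            "corr_removed": self.corr_removed,
            "feature_means": {g: float(v) for g, v in self.feature_means.items()},
            "feature_sds": {g: float(v) for g, v in self.feature_sds.items()},
            "lambda": self.lambda_,
            "coefficients": self.coefficients,
            "coefficients_raw": raw,
            "intercept": self.intercept,
            "intercept_raw": raw_intercept,
            "cv_spec": self.cv_spec,
            "cv_deviance": {repr(k): v for k, v in self.cv_deviance.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            panel_name=p["panel_name"],
            nzv_removed=p["nzv_removed"],
            corr_removed=p["corr_removed"],
            feature_means=pd.Series(p["feature_means"], dtype=float),
            feature_sds=pd.Series(p["feature_sds"], dtype=float),
            lambda_=float(p["lambda"]),
            coefficients={g: float(v) for g, v in p["coefficients"].items()},
            intercept=float(p["intercept"]),
            cv_spec=p.get("cv_spec", {}),
            cv_deviance={float(k): v for k, v in p.get("cv_deviance", {}).items()},
        )


def _standardize(x: pd.DataFrame, means=None, sds=None):
    if means is None:
        means = x.mean(axis=0)
        sds = x.std(axis=0, ddof=0)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ValueError(f"constant features survived filtering: {bad[:5]}")
    return (x - means) / sds, means, sds


def _sklearn_lasso(n: int, lam: float, fast: bool = False,
                   **kwargs) -> LogisticRegression:
    # (1/n) deviance + lam * |beta|  <=>  sklearn C = 1 / (n * lam)
    # fold-level path fits use a looser tolerance than the final refit
    return LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (n * lam),
        solver="saga",
        max_iter=3000 if fast else 20000,
        tol=1e-3 if fast else 1e-5,
        random_state=0,
        **kwargs,
    )


def _fit(clf: LogisticRegression, x: np.ndarray, y: np.ndarray) -> LogisticRegression:
    # near-separable data at tiny penalties never meets the strict tolerance;
    # warm-started path fits are still accurate enough for selection
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x, y)
    if not np.any(clf.coef_):
        # fully shrunk model: the unpenalized intercept MLE is analytic,
        # and saga's step size degenerates in this regime
        prevalence = float(np.mean(y))
        clf.intercept_[:] = np.log(prevalence / (1.0 - prevalence))
    return clf


def default_lambda_grid(x_std: np.ndarray, y: np.ndarray,
                        n_points: int = 25, ratio: float = 0.01) -> np.ndarray:
    """Descending log grid from the smallest all-zero lambda downward."""
    n = len(y)
    lam_max = np.abs(x_std.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * ratio, n_points)


def _mean_deviance(y_true: np.ndarray, prob: np.ndarray) -> float:
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    return float(-2.0 * np.mean(y_true * np.log(prob) + (1 - y_true) * np.log(1 - prob)))


def fit_lasso(
    x: pd.DataFrame,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    lambda_override: float | None = None,
    panel_name: str = "panel",
    nzv_removed: list[str] | None = None,
    corr_removed: list[str] | None = None,
) -> ClassifierModel:
    """Fit the penalized model, choosing lambda by cross-validated deviance.

    ``x`` is the filtered samples x genes frame; standardization happens
    inside (full-data parameters are frozen into the returned model;
    fold-level fits standardize on their own training split).
    ``lambda_override`` skips selection and fits at the given value.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    n = len(y)
    if lambda_override is None and n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV")

    x_std_full, means, sds = _standardize(x)
    cv_dev: dict[float, float] = {}
    if lambda_override is not None:
        chosen = float(lambda_override)
    else:
        if lambda_grid is None:
            lambda_grid = default_lambda_grid(x_std_full.values, y)
        lambda_grid = np.sort(np.asarray(lambda_grid, float))[::-1]
        dev_sum = np.zeros(len(lambda_grid))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for train, test in skf.split(x, y):
            x_tr, m_tr, s_tr = _standardize(x.iloc[train])
            x_te = (x.iloc[test] - m_tr) / s_tr
            clf = _sklearn_lasso(len(train), lambda_grid[0], fast=True,
                                 warm_start=True)
            for i, lam in enumerate(lambda_grid):
                clf.C = 1.0 / (len(train) * lam)
                _fit(clf, x_tr.values, y[train])
                prob = clf.predict_proba(x_te.values)[:, 1]
                dev_sum[i] += _mean_deviance(y[test], prob) * len(test)
        mean_dev = dev_sum / n
        cv_dev = {float(l): float(d) for l, d in zip(lambda_grid, mean_dev)}
        # minimum mean deviance; ties resolve to the larger (sparser) lambda
        chosen = float(lambda_grid[int(np.argmin(mean_dev))])

    clf = _sklearn_lasso(n, chosen)
    _fit(clf, x_std_full.values, y)
    coefs = {
        g: float(b)
        for g, b in zip(x.columns, clf.coef_.ravel())
        if b != 0.0
    }
    return ClassifierModel(
        panel_name=panel_name,
        nzv_removed=nzv_removed or [],
        corr_removed=corr_removed or [],
        feature_means=means,
        feature_sds=sds,
        lambda_=chosen,
        coefficients=coefs,
        intercept=float(clf.intercept_[0]),
        cv_spec={"folds": folds, "seed": seed},
        cv_deviance=cv_dev,
    )


def train_panel_classifier(
    norm: NormalizedMatrix,
    folds: int = 10,
    seed: int = 0,
    lambda_override: float | None = None,
) -> tuple[ClassifierModel, pd.DataFrame]:
    """Filters + fit on a normalized matrix; returns (model, filtered features)."""
    x = feature_matrix(norm)
    y = amr_labels(norm.samples)
    x_f, nzv, corr = apply_filters(x)
    model = fit_lasso(
        x_f, y, folds=folds, seed=seed, lambda_override=lambda_override,
        panel_name=norm.panel.name, nzv_removed=nzv, corr_removed=corr,
    )
    return model, x_f


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class EvalResult:
    roc_points: np.ndarray  # (FPR, TPR) rows
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float
    probabilities: pd.Series
    labels: np.ndarray

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": self.confusion.tolist(),
            "youden_threshold": self.youden_threshold,
            "youden_sensitivity": self.youden_sensitivity,
            "youden_specificity": self.youden_specificity,
        }


def evaluate_predictions(y, prob, threshold: float = 0.5) -> EvalResult:
    """ROC / AUC / operating-point metrics for predicted probabilities."""
    y = np.asarray(y, dtype=int)
    prob = np.asarray(prob, dtype=float) if not isinstance(prob, pd.Series) else prob
    p = np.asarray(prob, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation needs both classes present")
    fpr, tpr, thr = roc_curve(y, p)
    area = float(trapezoid_auc(fpr, tpr))

    def point(cut: float):
        pred = (p >= cut).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        return sens, spec, np.array([[tn, fp], [fn, tp]])

    sens, spec, conf = point(threshold)
    youden_i = int(np.argmax(tpr - fpr))
    youden_cut = float(min(thr[youden_i], 1.0))
    ysens, yspec, _ = point(youden_cut)
    probs = prob if isinstance(prob, pd.Series) else pd.Series(p)
    return EvalResult(
        roc_points=np.column_stack([fpr, tpr]),
        auc=area,
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        confusion=conf,
        youden_threshold=youden_cut,
        youden_sensitivity=ysens,
        youden_specificity=yspec,
        probabilities=probs,
        labels=y,
    )


def cv_evaluate(
    x: pd.DataFrame,
    y: np.ndarray,
    lambda_: float,
    folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvalResult:
    """Pooled out-of-fold evaluation at a fixed penalty.

    Standardization and fitting are redone inside every training fold;
    each sample's probability comes from the one model that never saw it.
    """
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    prob = np.full(len(y), np.nan)
    for train, test in skf.split(x, y):
        if len(np.unique(y[train])) < 2:
            raise ValueError("a training fold lost one class; reduce folds")
        x_tr, m_tr, s_tr = _standardize(x.iloc[train])
        x_te = (x.iloc[test] - m_tr) / s_tr
        clf = _sklearn_lasso(len(train), lambda_, fast=True)
        _fit(clf, x_tr.values, y[train])
        prob[test] = clf.predict_proba(x_te.values)[:, 1]
    return evaluate_predictions(y, pd.Series(prob, index=x.index), threshold)


def transfer_evaluate(
    model: ClassifierModel,
    other_norm: NormalizedMatrix,
    y: np.ndarray | None = None,
    threshold: float = 0.5,
) -> EvalResult:
    """Score another panel's cohort with a frozen model, mapping by symbol.

    The model's stored standardization is applied unchanged to the target
    panel's features; every coefficient gene must exist (by gene symbol)
    on the target panel.
    """
    x = feature_matrix(other_norm)
    if y is None:
        y = amr_labels(other_norm.samples)
    prob = model.predict_proba(x)  # raises MappingError if genes are missing
    return evaluate_predictions(y, prob, threshold)
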