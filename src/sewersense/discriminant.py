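"""Stepwise linear discriminant analysis of region from analyte loads.

Variable selection follows classical stepwise discriminant analysis: at each
forward step the candidate variable with the largest partial F-to-enter

    F = ((n - m - g) / (g - 1)) * (1 - L) / L,
    L = lambda(model + x) / lambda(model)

(``m`` variables already in the model, ``g`` groups) enters if its p-value
from F(g-1, n-m-g) is at or below the enter threshold; after each entry the
retained variable with the smallest F-to-remove leaves if its p-value exceeds
the stay threshold; the alternation stops when no entry or removal is
possible.  Wilks' lambda of a variable set is det(W)/det(T), the ratio of the
within-group to the total sum-of-squares-and-cross-products determinants.

Classification uses the pooled within-class covariance (n - g denominator)
linear discriminant: assign to the class with the largest
x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + log prior_k, equal priors by default.
Performance at n = 12 is assessed by leave-one-out cross-validation with the
selected variable set held fixed.

The user-facing surface is the statsmodels-style pair
:class:`StepwiseDiscriminantAnalysis` (model) and
:class:`DiscriminantResults` (estimates, trace, confusion matrices, metrics,
``summary()``); the underlying operations are module functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateDataError, DomainError, InsufficientDataError

#: F value reported when perfect separation drives partial lambda to zero.
F_SENTINEL = 1e12


# ---------------------------------------------------------------------------
# Wilks' lambda and stepwise selection

def _group_matrices(
    data: pd.DataFrame, labels: pd.Series, variables: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and total (T) SSCP matrices over ``variables``."""
    x = data.loc[:, list(variables)].to_numpy(dtype=float)
    y = np.asarray(labels)
    xc = x - x.mean(axis=0)
    t = xc.T @ xc
    w = np.zeros_like(t)
    for g in np.unique(y):
        xg = x[y == g]
        xgc = xg - xg.mean(axis=0)
        w += xgc.T @ xgc
    return w, t


def wilks_lambda(
    data: pd.DataFrame, labels: Sequence, variables: Sequence[str]
) -> float:
    """Wilks' lambda det(W)/det(T) for the given variable subset.

    An empty variable set gives lambda = 1 by convention.  For one variable
    this reduces to SS_within / SS_total.
    """
    variables = list(variables)
    if not variables:
        return 1.0
    labels = pd.Series(list(labels), index=data.index)
    counts = labels.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise InsufficientDataError("need at least 2 plants in each of 2 groups")
    w, t = _group_matrices(data, labels, variables)
    sign_t, logdet_t = np.linalg.slogdet(t)
    if sign_t <= 0 or logdet_t == -math.inf:
        raise DegenerateDataError(
            f"total SSCP matrix singular for variables {variables}"
        )
    sign_w, logdet_w = np.linalg.slogdet(w)
    if sign_w <= 0:
        return 0.0  # perfect separation: zero within-group scatter
    lam = math.exp(logdet_w - logdet_t)
    return min(lam, 1.0)


@dataclass(frozen=True)
class StepwiseStep:
    action: str  # "enter" | "remove"
    variable: str
    wilks_lambda: float  # model lambda after the action
    partial_f: float
    df: tuple[int, int]
    p_value: float


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [
            {
                "action": s.action,
                "variable": s.variable,
                "wilks_lambda": s.wilks_lambda,
                "partial_f": s.partial_f,
                "df1": s.df[0],
                "df2": s.df[1],
                "p_value": s.p_value,
            }
            for s in self.steps
        ]


def _partial_f(lam_partial: float, n: int, m: int, g: int) -> tuple[float, tuple[int, int], float]:
    """Partial F, its df and p for a partial lambda given m variables in model."""
    df1 = g - 1
    df2 = n - m - g
    if df2 < 1:
        return 0.0, (df1, max(df2, 0)), 1.0
    if lam_partial <= 0.0:
        return F_SENTINEL, (df1, df2), 0.0
    f = (df2 / df1) * (1.0 - lam_partial) / lam_partial
    p = float(stats.f.sf(f, df1, df2))
    return f, (df1, df2), p


def stepwise_select(
    data: pd.DataFrame,
    labels: Sequence,
    threshold_enter: float = 0.15,
    threshold_stay: float = 0.15,
    candidates: Sequence[str] | None = None,
) -> tuple[list[str], StepwiseTrace]:
    """Forward/backward Wilks-lambda stepwise selection.

    Returns the selected variables (in entry order) and the decision trace.
    Ties on F break by input column order.  An empty selection (nothing ever
    enters) is legal and returned with an empty-step trace.
    """
    for thr in (threshold_enter, threshold_stay):
        if not 0.0 < thr < 1.0:
            raise ConfigError(f"thresholds must be in (0, 1), got {thr}")
    labels = pd.Series(list(labels), index=data.index)
    groups = labels.unique()
    g = len(groups)
    n = len(data)
    cand_all = list(candidates) if candidates is not None else list(data.columns)
    model: list[str] = []
    lam_model = 1.0
    trace = StepwiseTrace()

    for _ in range(10 * len(cand_all) + 10):  # hard stop against cycling
        changed = False
        # forward step: best F-to-enter among remaining candidates
        remaining = [c for c in cand_all if c not in model]
        m = len(model)
        if remaining and n - m - g >= 1:
            best = None
            for c in remaining:
                lam_new = wilks_lambda(data, labels, model + [c])
                lam_partial = lam_new / lam_model if lam_model > 0 else 0.0
                f, df, p = _partial_f(lam_partial, n, m, g)
                if best is None or f > best[1] + 1e-12:
                    best = (c, f, df, p, lam_new)
            c, f, df, p, lam_new = best
            if p <= threshold_enter:
                model.append(c)
                lam_model = lam_new
                trace.steps.append(StepwiseStep("enter", c, lam_new, f, df, p))
                changed = True
        # backward step(s): weakest retained variable leaves while p > stay
        while len(model) > 1:
            m = len(model)
            worst = None
            for c in model:
                rest = [v for v in model if v != c]
                lam_rest = wilks_lambda(data, labels, rest)
                lam_partial = lam_model / lam_rest if lam_rest > 0 else 1.0
                f, df, p = _partial_f(lam_partial, n, m - 1, g)
                if worst is None or f < worst[1] - 1e-12:
                    worst = (c, f, df, p, lam_rest)
            c, f, df, p, lam_rest = worst
            if p > threshold_stay:
                model.remove(c)
                lam_model = lam_rest
                trace.steps.append(StepwiseStep("remove", c, lam_rest, f, df, p))
                changed = True
            else:
                break
        if not changed:
            break
    return model, trace


# ---------------------------------------------------------------------------
# Linear discriminant classifier

@dataclass
class LdaModel:
    """Two-class (or multi-class) pooled-covariance linear discriminant."""

    variables: list[str]
    classes: list[str]
    means: np.ndarray  # classes x variables
    pooled_cov: np.ndarray  # variables x variables
    priors: np.ndarray  # classes, sums to 1

    def discriminant_scores(self, x: np.ndarray) -> np.ndarray:
        """Linear discriminant score of each row for each class."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        try:
            inv = np.linalg.inv(self.pooled_cov)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded at fit
            raise DegenerateDataError("singular pooled covariance") from exc
        scores = np.empty((x.shape[0], len(self.classes)))
        for k, mu in enumerate(self.means):
            scores[:, k] = (
                x @ inv @ mu - 0.5 * mu @ inv @ mu + math.log(self.priors[k])
            )
        return scores

    def predict(self, x: np.ndarray | pd.DataFrame) -> list[str]:
        if isinstance(x, pd.DataFrame):
            x = x.loc[:, self.variables].to_numpy(dtype=float)
        scores = self.discriminant_scores(x)
        # ties break to the first class label in sorted order (classes sorted)
        idx = np.argmax(np.round(scores, 12), axis=1)
        return [self.classes[i] for i in idx]


def fit_lda(
    data: pd.DataFrame,
    labels: Sequence,
    variables: Sequence[str],
    priors: str | Mapping[str, float] = "equal",
    ridge: float = 0.0,
) -> LdaModel:
    """Fit the pooled-covariance linear discriminant on ``variables``.

    ``priors`` is ``"equal"`` (default), ``"proportional"`` or an explicit
    class -> probability mapping.  ``ridge`` adds eps*I to the pooled
    covariance (off by default; singularity raises instead).
    """
    variables = list(variables)
    if not variables:
        raise DomainError("fit_lda requires at least one variable")
    labels = pd.Series([str(v) for v in labels], index=data.index)
    classes = sorted(labels.unique())
    counts = labels.value_counts()
    if len(classes) < 2 or counts.min() < 2:
        raise InsufficientDataError("need at least 2 observations in each of 2 classes")
    x = data.loc[:, variables].to_numpy(dtype=float)
    n, g = len(x), len(classes)
    means = np.vstack([x[(labels == c).to_numpy()].mean(axis=0) for c in classes])
    w = np.zeros((len(variables), len(variables)))
    for c in classes:
        xc = x[(labels == c).to_numpy()]
        d = xc - xc.mean(axis=0)
        w += d.T @ d
    pooled = w / (n - g)
    if ridge > 0:
        pooled = pooled + ridge * np.eye(len(variables))
    sign, logdet = np.linalg.slogdet(pooled)
    if sign <= 0 or not np.isfinite(logdet):
        raise DegenerateDataError(
            "singular pooled covariance; consider the ridge option or fewer variables"
        )
    if priors == "equal":
        pr = np.full(g, 1.0 / g)
    elif priors == "proportional":
        pr = np.array([counts[c] / n for c in classes])
    else:
        pr = np.array([priors[c] for c in classes], dtype=float)
        if not math.isclose(pr.sum(), 1.0, rel_tol=1e-9):
            raise ConfigError("explicit priors must sum to 1")
    return LdaModel(variables, classes, means, pooled, pr)


# ---------------------------------------------------------------------------
# Cross-validation and metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = "west"
    n_unclassified: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DomainError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_predictions(
    truth: Sequence[str], predicted: Sequence[str | None], positive_class: str = "west"
) -> ConfusionMatrix:
    tp = fp = tn = fn = unc = 0
    for t, p in zip(truth, predicted):
        if p is None:
            unc += 1
        elif t == positive_class:
            tp += p == positive_class
            fn += p != positive_class
        else:
            tn += p != positive_class
            fp += p == positive_class
    return ConfusionMatrix(tp, fp, tn, fn, positive_class, unc)


def loocv(
    data: pd.DataFrame,
    labels: Sequence,
    variables: Sequence[str],
    priors: str | Mapping[str, float] = "equal",
    positive_class: str = "west",
) -> tuple[ConfusionMatrix, pd.Series]:
    """Leave-one-out cross-validation with the variable set held fixed.

    Each plant is predicted by a discriminant refit on the other n-1 plants.
    A fold whose training set collapses to one class (or fewer than 2 per
    class) leaves that plant unclassifiable (prediction None).
    """
    labels = pd.Series([str(v) for v in labels], index=data.index)
    preds: list[str | None] = []
    for i in range(len(data)):
        mask = np.ones(len(data), dtype=bool)
        mask[i] = False
        train_y = labels.iloc[mask.nonzero()[0]]
        try:
            model = fit_lda(data.iloc[mask], train_y, variables, priors)
            preds.append(model.predict(data.iloc[[i]])[0])
        except (InsufficientDataError, DegenerateDataError):
            preds.append(None)
    pred_series = pd.Series(preds, index=data.index, name="loocv_prediction")
    cm = confusion_from_predictions(labels, preds, positive_class)
    return cm, pred_series


@dataclass(frozen=True)
class ClassificationMetrics:
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    accuracy: float


def classification_metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Precision, sensitivity, specificity, F1 and accuracy from a confusion
    matrix.  Undefined ratios (zero denominator) come back as NaN, never 0."""
    if cm.total == 0:
        raise DomainError("empty confusion matrix")
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else math.nan
    sensitivity = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else math.nan
    specificity = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else math.nan
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    accuracy = (cm.tp + cm.tn) / cm.total
    return ClassificationMetrics(precision, sensitivity, specificity, f1, accuracy)


# ---------------------------------------------------------------------------
# Model / Results surface

class StepwiseDiscriminantAnalysis:
    """Stepwise discriminant model of a class label from analyte features.

    Parameters
    ----------
    data : plants x variables feature matrix (DataFrame).
    labels : class label per plant (e.g. region).
    threshold_enter, threshold_stay : stepwise p-value thresholds (default .15).
    priors : "equal" (default), "proportional", or explicit mapping.
    candidates : optional subset of columns eligible for selection.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        labels: Sequence,
        threshold_enter: float = 0.15,
        threshold_stay: float = 0.15,
        priors: str | Mapping[str, float] = "equal",
        candidates: Sequence[str] | None = None,
        positive_class: str = "west",
    ) -> None:
        self.data = data
        self.labels = pd.Series([str(v) for v in labels], index=data.index)
        self.threshold_enter = threshold_enter
        self.threshold_stay = threshold_stay
        self.priors = priors
        self.candidates = list(candidates) if candidates is not None else None
        self.positive_class = positive_class

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str, feature_cols: Sequence[str] | None = None, **kw
    ) -> "StepwiseDiscriminantAnalysis":
        features = (
            list(feature_cols)
            if feature_cols is not None
            else [c for c in df.columns if c != label_col]
        )
        return cls(df[features], df[label_col], **kw)

    def fit(self, run_loocv: bool = True, loocv_reselect: bool = False) -> "DiscriminantResults":
        selected, trace = stepwise_select(
            self.data,
            self.labels,
            self.threshold_enter,
            self.threshold_stay,
            self.candidates,
        )
        lda = resub_pred = resub_cm = None
        if selected:
            lda = fit_lda(self.data, self.labels, selected, self.priors)
            resub_pred = pd.Series(
                lda.predict(self.data), index=self.data.index, name="prediction"
            )
            resub_cm = confusion_from_predictions(
                self.labels, resub_pred, self.positive_class
            )
        cv_cm = cv_pred = None
        if run_loocv and selected:
            if loocv_reselect:
                preds: list[str | None] = []
                for i in range(len(self.data)):
                    mask = np.ones(len(self.data), dtype=bool)
                    mask[i] = False
                    sub = self.data.iloc[mask]
                    sub_y = self.labels.iloc[mask.nonzero()[0]]
                    sel_i, _ = stepwise_select(
                        sub, sub_y, self.threshold_enter, self.threshold_stay, self.candidates
                    )
                    if not sel_i:
                        preds.append(None)
                        continue
                    try:
                        m = fit_lda(sub, sub_y, sel_i, self.priors)
                        preds.append(m.predict(self.data.iloc[[i]])[0])
                    except (InsufficientDataError, DegenerateDataError):
                        preds.append(None)
                cv_pred = pd.Series(preds, index=self.data.index, name="loocv_prediction")
                cv_cm = confusion_from_predictions(self.labels, preds, self.positive_class)
            else:
                cv_cm, cv_pred = loocv(
                    self.data, self.labels, selected, self.priors, self.positive_class
                )
        return DiscriminantResults(
            model=self,
            selected=selected,
            trace=trace,
            lda=lda,
            resub_predictions=resub_pred,
            resub_confusion=resub_cm,
            loocv_predictions=cv_pred,
            loocv_confusion=cv_cm,
        )


@dataclass
class DiscriminantResults:
    """Fitted stepwise discriminant: selection trace, classifier, validation."""

    model: StepwiseDiscriminantAnalysis
    selected: list[str]
    trace: StepwiseTrace
    lda: LdaModel | None
    resub_predictions: pd.Series | None
    resub_confusion: ConfusionMatrix | None
    loocv_predictions: pd.Series | None
    loocv_confusion: ConfusionMatrix | None

    @property
    def metrics(self) -> ClassificationMetrics | None:
        if self.loocv_confusion is None:
            return None
        return classification_metrics(self.loocv_confusion)

    @property
    def resub_metrics(self) -> ClassificationMetrics | None:
        if self.resub_confusion is None:
            return None
        return classification_metrics(self.resub_confusion)

    def to_dict(self) -> dict:
        def cm_dict(cm: ConfusionMatrix | None):
            if cm is None:
                return None
            return {
                "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                "positive_class": cm.positive_class,
                "n_unclassified": cm.n_unclassified,
            }

        def metrics_dict(m: ClassificationMetrics | None):
            if m is None:
                return None
            return {
                "precision": m.precision,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "f1": m.f1,
                "accuracy": m.accuracy,
            }

        return {
            "selected": list(self.selected),
            "trace": self.trace.to_records(),
            "loocv_predictions": None
            if self.loocv_predictions is None
            else self.loocv_predictions.to_dict(),
            "resub_predictions": None
            if self.resub_predictions is None
            else self.resub_predictions.to_dict(),
            "confusion_loocv": cm_dict(self.loocv_confusion),
            "confusion_resubstitution": cm_dict(self.resub_confusion),
            "metrics_loocv": metrics_dict(self.metrics),
            "metrics_resubstitution": metrics_dict(self.resub_metrics),
        }

    def summary(self) -> str:
        lines = ["Stepwise linear discriminant analysis", "=" * 42]
        lines.append(f"Enter/stay thresholds: p <= {self.model.threshold_enter:g} / "
                     f"p <= {self.model.threshold_stay:g}")
        lines.append(f"Priors: {self.model.priors}; positive class: "
                     f"{self.model.positive_class}")
        lines.append("")
        lines.append("Step  Action  Variable              Wilks lambda   F        p")
        for i, s in enumerate(self.trace.steps, start=1):
            lines.append(
                f"{i:>4}  {s.action:<6}  {s.variable:<20}  {s.wilks_lambda:>10.4f}"
                f"  {min(s.partial_f, 9999.99):>8.2f} {s.p_value:>8.4f}"
            )
        if not self.trace.steps:
            lines.append("  (no variable entered)")
        lines.append("")
        lines.append(f"Selected variables: {', '.join(self.selected) or '(none)'}")
        for name, cm, mt in (
            ("Resubstitution", self.resub_confusion, self.resub_metrics),
            ("Leave-one-out CV", self.loocv_confusion, self.metrics),
        ):
            if cm is None:
                continue
            lines.append("")
            lines.append(f"{name} (positive = {cm.positive_class}): "
                         f"tp={cm.tp} fp={cm.fp} tn={cm.tn} fn={cm.fn}")
            lines.append(
                f"  precision={mt.precision:.2f} sensitivity={mt.sensitivity:.2f} "
                f"specificity={mt.specificity:.2f} F1={mt.f1:.2f} "
                f"accuracy={mt.accuracy:.0%}"
            )
        return "\n".join(lines)
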