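"""ROC machinery, Youden threshold selection, and the logistic marker panel.

Single markers classify by a simple abundance cutoff ("higher abundance =>
case", since the screened markers are up-regulated); the cutoff is chosen at
the ROC operating point maximising Youden's J = sensitivity + specificity - 1
and placed at the midpoint between the adjacent distinct scores it
separates.  The multi-marker panel is a ridge-stabilised logistic regression
on raw abundances, evaluated by ROC/AUC on discovery and independent test
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .datamodel import CASE, ProfileMatrix


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    """An ROC curve: operating points at every distinct score, descending.

    ``thresholds[0]`` is +inf (the predict-nothing point); a sample is
    predicted case iff its score >= threshold.  ``auc`` is the trapezoidal
    area, identical to the Mann-Whitney concordance probability with ties
    counted one half.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_curve(values, labels) -> ROCResult:
    """ROC of per-sample scores against case/control labels."""
    values = np.asarray(values, dtype=float)
    y_true = np.asarray([g == CASE for g in labels])
    if y_true.all() or not y_true.any():
        raise ValueError("both case and control labels are required")
    fpr, tpr, thr = _sk_roc_curve(y_true, values, drop_intermediate=False)
    return ROCResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=float(_trapezoid_auc(fpr, tpr)),
    )


@dataclass(frozen=True)
class ThresholdChoice:
    """A classifying threshold chosen from an ROC curve."""

    threshold: float
    sensitivity: float
    specificity: float
    j: float
    degenerate: bool = False


def select_threshold(roc: ROCResult) -> ThresholdChoice:
    """Operating point maximising Youden's J; ties broken by higher
    specificity, then higher threshold.

    The returned cutoff is the midpoint between the adjacent distinct scores
    the chosen point separates (a printed threshold value cannot land on an
    observed score).  If no point beats J = 0 (scores carry no signal) the
    choice is flagged degenerate.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    order = sorted(
        range(len(j)),
        key=lambda i: (-j[i], -roc.specificity[i], -_finite(roc.thresholds[i])),
    )
    best = order[0]
    degenerate = j[best] <= 0
    thr = roc.thresholds[best]
    if not np.isfinite(thr):
        # predict-nothing point; report the highest observed score
        thr = float(roc.thresholds[1]) if len(roc.thresholds) > 1 else 0.0
    elif best + 1 < len(roc.thresholds):
        thr = (float(thr) + float(roc.thresholds[best + 1])) / 2.0
    else:
        thr = float(thr)
    return ThresholdChoice(
        threshold=float(thr),
        sensitivity=float(roc.sensitivity[best]),
        specificity=float(roc.specificity[best]),
        j=float(max(j[best], 0.0)),
        degenerate=bool(degenerate),
    )


def _finite(x: float) -> float:
    return float(x) if np.isfinite(x) else np.finfo(float).max


def youden_threshold(case_values, control_values) -> ThresholdChoice:
    """Convenience: ROC + Youden selection from raw group values."""
    values = np.concatenate([case_values, control_values])
    labels = [CASE] * len(case_values) + ["control"] * len(control_values)
    return select_threshold(roc_curve(values, labels))


# ---------------------------------------------------------------------------
# single-marker threshold classifier
# ---------------------------------------------------------------------------

def apply_threshold_classifier(
    pm_test: ProfileMatrix, compound_id: str, threshold: float
) -> tuple[float, float, float]:
    """Classify test samples as case iff abundance >= threshold.

    Returns (accuracy, sensitivity, specificity) on the test profile.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    row = pm_test.values(compound_id)
    truth = pm_test.case_mask
    pred = row >= threshold
    tp = int(np.count_nonzero(pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    accuracy = (tp + tn) / truth.size
    sensitivity = tp / truth.sum()
    specificity = tn / (~truth).sum()
    return float(accuracy), float(sensitivity), float(specificity)


# ---------------------------------------------------------------------------
# logistic-regression panel
# ---------------------------------------------------------------------------

@dataclass
class PanelModel:
    """A fitted logistic-regression marker panel.

    Coefficients are on the raw feature scale (log-odds per abundance unit,
    or per log-unit when ``log_transform`` is set); prediction is monotone
    in each feature with the sign of its coefficient.
    """

    marker_ids: list[str]
    intercept: float
    coefficients: np.ndarray
    ridge: float
    log_transform: bool = False
    training_roc: ROCResult | None = None
    test_roc: ROCResult | None = None

    def predict_proba(self, pm: ProfileMatrix) -> np.ndarray:
        """Per-sample case probability from the fitted panel."""
        X = _panel_features(pm, self.marker_ids, self.log_transform)
        z = self.intercept + X @ self.coefficients
        return 1.0 / (1.0 + np.exp(-z))


def _panel_features(
    pm: ProfileMatrix, marker_ids, log_transform: bool
) -> np.ndarray:
    rows = [pm.values(cid) for cid in marker_ids]  # raises on missing marker
    X = np.column_stack(rows)
    return np.log1p(X) if log_transform else X


def fit_logistic_panel(
    pm_discovery: ProfileMatrix,
    marker_ids,
    ridge: float | None = None,
    log_transform: bool = False,
    max_iter: int = 5000,
) -> PanelModel:
    """Maximum-likelihood logistic fit of the marker panel with a small
    ridge penalty for separation robustness.

    ``ridge`` defaults to 1e-6 * n_samples (essentially the unpenalised MLE
    on non-separable data, but finite coefficients under complete
    separation).  Features are standardised internally for optimisation; the
    returned coefficients are mapped back to the raw feature scale.
    """
    marker_ids = list(marker_ids)
    if not marker_ids:
        raise ValueError("at least one marker is required")
    X = _panel_features(pm_discovery, marker_ids, log_transform)
    y = pm_discovery.case_mask.astype(int)
    if ridge is None:
        ridge = 1e-6 * len(y)
    if ridge <= 0:
        raise ValueError("ridge strength must be positive")

    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    mean = X.mean(axis=0)
    Xs = (X - mean) / sd

    clf = LogisticRegression(
        C=1.0 / ridge, solver="lbfgs", max_iter=max_iter, tol=1e-10
    )
    clf.fit(Xs, y)
    if int(np.max(clf.n_iter_)) >= max_iter:
        raise RuntimeError(
            f"logistic panel failed to converge within {max_iter} iterations"
        )

    coef = clf.coef_[0] / sd
    intercept = float(clf.intercept_[0] - np.sum(clf.coef_[0] * mean / sd))
    model = PanelModel(
        marker_ids=marker_ids,
        intercept=intercept,
        coefficients=coef,
        ridge=float(ridge),
        log_transform=log_transform,
    )
    model.training_roc = roc_curve(model.predict_proba(pm_discovery), pm_discovery.groups)
    return model


def evaluate_panel(model: PanelModel, pm_test: ProfileMatrix) -> ROCResult:
    """ROC of the fitted panel's probabilities on an independent cohort."""
    roc = roc_curve(model.predict_proba(pm_test), pm_test.groups)
    model.test_roc = roc
    return roc
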