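"""Multivariate separation QC: PCA (R2X) and OPLS-DA (R2Y, cross-validated Q2).

Profiles are autoscaled (mean-centred, unit variance) before decomposition.
OPLS-DA follows the orthogonal-projections scheme: orthogonal components
strip class-uncorrelated variation from X before a single predictive
component is fitted against the centred +/-1 class code.  Q2 = 1 - PRESS/TSS
is estimated by stratified k-fold cross-validation with refitting (including
re-scaling) inside each fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .datamodel import ProfileMatrix


@dataclass
class LatentModel:
    """A fitted PCA or OPLS-DA model on an autoscaled profile."""

    kind: str  # "pca" | "oplsda"
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # compounds x components
    r2x: float
    n_predictive: int
    n_orthogonal: int
    scaling: str = "autoscale"
    r2y: float | None = None
    q2: float | None = None
    component_names: list[str] = field(default_factory=list)


def _autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centre and unit-variance scale columns; zero-variance columns are
    centred but left unscaled (scale 1) with a warning."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-variance compound(s) excluded from scaling",
            stacklevel=3,
        )
    scale = np.where(zero, 1.0, sd)
    return (X - mean) / scale, mean, scale


def fit_pca(pm: ProfileMatrix, n_components: int) -> LatentModel:
    """PCA of the autoscaled samples x compounds matrix.

    ``r2x`` is the cumulative explained-variance fraction of the retained
    components (the score-plot's R2X).
    """
    X = pm.abundance.T
    n, p = X.shape
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must be in [1, {max_rank}] for {n} samples x {p} compounds"
        )
    Xs, _, _ = _autoscale(X)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(Xs)
    return LatentModel(
        kind="pca",
        scores=scores,
        loadings=model.components_.T,
        r2x=float(model.explained_variance_ratio_.sum()),
        n_predictive=n_components,
        n_orthogonal=0,
        component_names=[f"PC{i + 1}" for i in range(n_components)],
    )


class _OPLS:
    """Single-response orthogonal projections to latent structures.

    Operates on an already centred/scaled X and centred y; extracts
    ``n_orthogonal`` y-uncorrelated components by deflation, then one
    predictive component.  Prediction deflates new observations with the
    stored orthogonal loadings before applying the predictive weights.
    """

    def __init__(self, n_orthogonal: int = 1):
        self.n_orthogonal = n_orthogonal

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_OPLS":
        Xs, self.x_mean_, self.x_scale_ = _autoscale(X)
        self.y_mean_ = y.mean()
        yc = y - self.y_mean_
        total_x = float((Xs**2).sum())

        w = Xs.T @ yc
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("response is uncorrelated with every compound")
        w /= norm

        W_o, P_o, T_o = [], [], []
        Xres = Xs
        for _ in range(self.n_orthogonal):
            t = Xres @ w
            p = Xres.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            norm_o = np.linalg.norm(w_o)
            if norm_o < 1e-12:  # no orthogonal variation left
                break
            w_o /= norm_o
            t_o = Xres @ w_o
            p_o = Xres.T @ t_o / (t_o @ t_o)
            Xres = Xres - np.outer(t_o, p_o)
            W_o.append(w_o)
            P_o.append(p_o)
            T_o.append(t_o)

        t = Xres @ w
        self.w_ = w
        self.p_ = Xres.T @ t / (t @ t)
        self.c_ = float(yc @ t / (t @ t))
        self.t_pred_ = t
        self.W_ortho_ = np.array(W_o).T if W_o else np.empty((X.shape[1], 0))
        self.P_ortho_ = np.array(P_o).T if P_o else np.empty((X.shape[1], 0))
        self.T_ortho_ = np.array(T_o).T if T_o else np.empty((X.shape[0], 0))

        resid = yc - t * self.c_
        self.r2y_ = float(1.0 - (resid @ resid) / (yc @ yc))
        explained = (t @ t) * (self.p_ @ self.p_) + sum(
            (T_o[k] @ T_o[k]) * (P_o[k] @ P_o[k]) for k in range(len(T_o))
        )
        self.r2x_ = float(explained / total_x)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous class-code prediction for new observations."""
        Xn = (X - self.x_mean_) / self.x_scale_
        for k in range(self.W_ortho_.shape[1]):
            t_o = Xn @ self.W_ortho_[:, k]
            Xn = Xn - np.outer(t_o, self.P_ortho_[:, k])
        return (Xn @ self.w_) * self.c_ + self.y_mean_


def fit_oplsda(
    pm: ProfileMatrix,
    n_orthogonal: int = 1,
    cv_folds: int = 7,
    seed: int = 0,
) -> LatentModel:
    """OPLS-DA of a two-group profile with cross-validated Q2.

    The class is coded +1 (case) / -1 (control) and centred.  R2Y is the
    explained y-variance of the training fit; Q2 = 1 - PRESS/TSS over
    stratified ``cv_folds``-fold cross-validation with per-fold refitting.
    Q2 <= 0 indicates no predictive power.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    X = pm.abundance.T
    y = np.where(pm.case_mask, 1.0, -1.0)
    n_min = min(int(pm.case_mask.sum()), int((~pm.case_mask).sum()))
    if n_min < cv_folds:
        raise ValueError(
            f"cannot stratify {cv_folds} folds with only {n_min} samples "
            "in the smaller group"
        )

    fitted = _OPLS(n_orthogonal=n_orthogonal).fit(X, y)

    press = 0.0
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        sub = _OPLS(n_orthogonal=n_orthogonal).fit(X[train], y[train])
        pred = sub.predict(X[test])
        press += float(((y[test] - pred) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / tss

    scores = np.column_stack([fitted.t_pred_, fitted.T_ortho_])
    loadings = np.column_stack([fitted.p_, fitted.P_ortho_])
    names = ["t_pred"] + [f"t_ortho{i + 1}" for i in range(fitted.T_ortho_.shape[1])]
    model = LatentModel(
        kind="oplsda",
        scores=scores,
        loadings=loadings,
        r2x=fitted.r2x_,
        r2y=fitted.r2y_,
        q2=float(q2),
        n_predictive=1,
        n_orthogonal=fitted.T_ortho_.shape[1],
        component_names=names,
    )
    model._opls = fitted  # retained for prediction / diagnostics
    return model
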