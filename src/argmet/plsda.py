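"""Two-class PLS discriminant analysis (PLS1/NIPALS with X-deflation).

The class membership is coded as a dummy binary response y ∈ {0, 1}.  PLS
projects the predictor matrix X onto A orthogonal latent variables with
scores T = X R (R the projection weights) and regresses the centred response
on the scores, y = T q.  Classification thresholds the predicted response at
0.5 by default.  The single predictive direction w_cv = R q (unit-normed,
sign fixed so the class-1 mean score is the larger) carries the sample
scores and variable weights used for interpretation.

With A = rank(X) the PLS prediction coincides with ordinary least squares on
the centred data; the test suite checks this identity and cross-checks
predictions against an independent PLS implementation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stats import DegenerateInputError


class SingleClassError(ValueError):
    """The response contains only one class."""


@dataclass
class Preprocessor:
    """Column-wise scaling fitted on training rows only.

    mode ``autoscale``: subtract the training mean and divide by the training
    SD (sample SD, ddof=1) — the chemometrics default for concentration
    panels whose analytes span orders of magnitude.  ``center`` subtracts the
    mean only; ``none`` is the identity (the caller must supply centred data
    for the PLS intercept to be meaningful).
    """

    mode: str = "autoscale"
    means_: np.ndarray | None = None
    sds_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Preprocessor":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        if self.mode not in ("autoscale", "center", "none"):
            raise ValueError(f"unknown scaling mode {self.mode!r}")
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0, ddof=1)
        if self.mode == "autoscale" and np.any(self.sds_ <= 0):
            bad = np.flatnonzero(self.sds_ <= 0)
            raise DegenerateInputError(
                f"constant column(s) {bad.tolist()}: autoscaling undefined"
            )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.mode == "none":
            return X.copy()
        if self.means_ is None:
            raise ValueError("preprocessor not fitted")
        Z = X - self.means_
        if self.mode == "autoscale":
            Z = Z / self.sds_
        return Z

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        if self.mode == "none":
            return np.asarray(Z, dtype=float).copy()
        X = np.asarray(Z, dtype=float)
        if self.mode == "autoscale":
            X = X * self.sds_
        return X + self.means_


def _nipals_pls1(
    Xc: np.ndarray, yc: np.ndarray, n_lv: int, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sequential PLS1 extraction with X-deflation.

    Returns (W, P, q, R, T, B_path) where B_path[:, k-1] is the regression
    vector of the k-component model, so one fit yields predictions for every
    component count up to ``n_lv``.  Extraction stops early when X carries no
    residual covariance with y (rank exhaustion).
    """
    n, p = Xc.shape
    A = min(n_lv, p, n - 1)
    W = np.empty((p, A))
    P = np.empty((p, A))
    q = np.empty(A)
    T = np.empty((n, A))
    Xa = Xc.copy()
    a = 0
    for i in range(A):
        w = Xa.T @ yc
        nw = np.linalg.norm(w)
        if nw < tol:
            break
        w /= nw
        t = Xa @ w
        tt = t @ t
        if tt < tol:
            break
        W[:, i] = w
        T[:, i] = t
        P[:, i] = (Xa.T @ t) / tt
        q[i] = (yc @ t) / tt
        Xa -= np.outer(t, P[:, i])
        a = i + 1
    if a == 0:
        raise DegenerateInputError("X carries no covariance with y")
    W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
    R = W @ np.linalg.inv(P.T @ W)
    B_path = np.cumsum(R * q, axis=1)
    return W, P, q, R, T, B_path


@dataclass
class PLSModel:
    """Fitted two-class PLS-DA model."""

    n_lv: int
    weights_R: np.ndarray          # p × n_lv projection weights, T = X R
    coefficients_q: np.ndarray     # n_lv inner regression coefficients
    x_weights_W: np.ndarray
    x_loadings_P: np.ndarray
    train_scores_T: np.ndarray
    coef_path_B: np.ndarray        # p × n_lv cumulative regression vectors
    y_mean: float
    cv_weights: np.ndarray         # unit-norm canonical-variate direction
    preprocessor: Preprocessor | None = None
    decision_threshold: float = 0.5
    class_codes: dict = field(default_factory=lambda: {"class1": 1, "class0": 0})

    @property
    def coef(self) -> np.ndarray:
        """Regression vector of the full n_lv-component model."""
        return self.coef_path_B[:, -1]

    def to_dict(self) -> dict:
        pre = self.preprocessor
        return {
            "n_lv": int(self.n_lv),
            "weights_R": self.weights_R.tolist(),
            "coefficients_q": self.coefficients_q.tolist(),
            "y_mean": float(self.y_mean),
            "cv_weights": self.cv_weights.tolist(),
            "decision_threshold": float(self.decision_threshold),
            "preprocessing": None if pre is None else {
                "mode": pre.mode,
                "means": pre.means_.tolist(),
                "sds": pre.sds_.tolist(),
            },
        }


def fit_pls(Xs: np.ndarray, y: np.ndarray, n_lv: int) -> PLSModel:
    """Fit PLS1-DA on an already-scaled (centred) predictor matrix.

    ``y`` is the 0/1 dummy response; it is centred internally and its mean is
    re-added at prediction time.  Requests for more components than the data
    rank are reduced with a warning.
    """
    Xs = np.asarray(Xs, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if Xs.shape[0] != y.size:
        raise ValueError("X and y disagree on n")
    if np.unique(y).size < 2:
        raise SingleClassError("both classes must be present in y")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    y_mean = float(y.mean())
    W, P, q, R, T, B_path = _nipals_pls1(Xs, y - y_mean, n_lv)
    if q.size < n_lv:
        warnings.warn(
            f"requested {n_lv} latent variables, rank supports {q.size}; reduced",
            stacklevel=2,
        )
    wcv = R @ q
    wcv = wcv / np.linalg.norm(wcv)
    scores = Xs @ wcv
    if scores[y == 1].mean() < scores[y == 0].mean():
        wcv = -wcv
    return PLSModel(
        n_lv=int(q.size), weights_R=R, coefficients_q=q, x_weights_W=W,
        x_loadings_P=P, train_scores_T=T, coef_path_B=B_path,
        y_mean=y_mean, cv_weights=wcv,
    )


def fit_plsda(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    scale: str = "autoscale",
    decision_threshold: float = 0.5,
) -> PLSModel:
    """Fit preprocessing + PLS1-DA on raw concentrations."""
    pre = Preprocessor(mode=scale).fit(np.asarray(X, dtype=float))
    model = fit_pls(pre.transform(X), y, n_lv)
    model.preprocessor = pre
    model.decision_threshold = decision_threshold
    return model


def _scaled(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.cv_weights.size:
        raise ValueError(
            f"expected {model.cv_weights.size} columns, got {X.shape[1]}"
        )
    return model.preprocessor.transform(X) if model.preprocessor else X.copy()


def predict(model: PLSModel, Xnew: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous predicted response and hard labels for new rows.

    y_hat = Xs B + mean(y_train); label = 1 iff y_hat >= decision_threshold.
    A row at the training centroid predicts exactly the training class
    prevalence.
    """
    Xs = _scaled(model, Xnew)
    y_hat = Xs @ model.coef + model.y_mean
    labels = (y_hat >= model.decision_threshold).astype(int)
    return y_hat, labels


def predict_components(model: PLSModel, Xnew: np.ndarray) -> np.ndarray:
    """n × n_lv matrix of predicted responses for 1..n_lv components."""
    Xs = _scaled(model, Xnew)
    return Xs @ model.coef_path_B + model.y_mean


def canonical_variate(
    model: PLSModel, X: np.ndarray | None = None
) -> tuple[np.ndarray | None, np.ndarray]:
    """Sample scores and variable weights along the predictive direction.

    The direction is R q normalised to unit length with its sign fixed at fit
    time so that class-1 training scores have the larger mean; weight plots
    are therefore reproducible up to data, not up to sign.
    """
    if X is None:
        return None, model.cv_weights.copy()
    scores = _scaled(model, X) @ model.cv_weights
    return scores, model.cv_weights.copy()
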