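"""Partial least squares regression (PLS1) with cross-validated rank choice.

Two numerically equivalent routes to the same regression vector live here:

* :func:`fit_plsr` -- classic NIPALS on the mean-centered data matrix. This
  is the canonical model object used for prediction, scores, loadings and
  the VIP statistics that variable selection needs.
* a cross-product ("kernel") coefficient path working only from X'X and X'y,
  which makes exact leave-one-out and k-fold cross-validation cheap: the
  training cross-products for each fold are rank-few downdates of the full
  ones, so a LOO curve over ``n`` refits costs O(n * ncomp * p^2) instead of
  O(n * ncomp * n * p).

Component choice follows the parsimonious near-minimum rule: the smallest
component count whose RMSECV is within a 2% tolerance of the curve minimum.
Fit quality is summarized by R2 = 1 - SSres/SStot and RMSE; validation R2 is
deliberately not clamped at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError, InvalidParameterError, SchemaError

__all__ = [
    "PLSRModel",
    "CVCurve",
    "fit_plsr",
    "predict",
    "loo_select_ncomp",
    "loo_rmsecv",
    "kfold_rmse",
    "fit_stats",
    "vip_scores",
]

_EPS = np.finfo(float).eps


@dataclass
class PLSRModel:
    """Fitted PLS1 model on mean-centered X and y.

    ``regression_vector`` maps centered spectra to centered response:
    yhat = y_mean + (X - x_mean) @ regression_vector.
    """

    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray      # W, (p, A)
    x_loadings: np.ndarray     # P, (p, A)
    y_loadings: np.ndarray     # q, (A,)
    x_scores: np.ndarray       # T, (n, A)
    regression_vector: np.ndarray
    n_components: int
    training_dims: tuple


@dataclass
class CVCurve:
    """RMSECV as a function of component count, including the 0-component
    (training-mean) model."""

    n_components: np.ndarray = field(default_factory=lambda: np.arange(0))
    rmsecv: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise InvalidParameterError("X must be a 2-D matrix")
    if y.size != X.shape[0]:
        raise InvalidParameterError(
            f"y length {y.size} does not match X rows {X.shape[0]}"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InvalidParameterError("X and y must be finite with no missing values")
    return X, y


def fit_plsr(X, y, ncomp: int) -> PLSRModel:
    """NIPALS PLS1 fit with ``ncomp`` latent components.

    Components whose residual covariance with y is numerically zero are not
    extracted (the model keeps the achieved count), so collinear or duplicate
    bands never produce non-finite coefficients.
    """
    X, y = _as_xy(X, y)
    n, p = X.shape
    if n < 2:
        raise InvalidParameterError("need at least 2 samples")
    if ncomp < 1:
        raise InvalidParameterError(f"ncomp must be >= 1, got {ncomp}")
    if ncomp > min(n - 1, p):
        raise InvalidParameterError(
            f"ncomp={ncomp} exceeds min(n-1, p) = {min(n - 1, p)}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    if np.allclose(yc, 0.0):
        raise DegenerateDataError("response has zero variance")

    scale = float(np.sqrt((yc @ yc) / max(n - 1, 1))) * max(
        1.0, float(np.abs(Xc).max())
    )
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    T = np.zeros((n, ncomp))
    Xd, yd = Xc.copy(), yc.copy()
    a = 0
    for _ in range(ncomp):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale + 1e-300:
            break  # residual X carries no covariance with y: rank exhausted
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt <= _EPS * n:
            break
        pvec = (Xd.T @ t) / tt
        qa = (yd @ t) / tt
        Xd -= np.outer(t, pvec)
        yd -= qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
        a += 1
    if a == 0:
        raise DegenerateDataError("no latent component could be extracted")
    W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
    # b = W (P'W)^{-1} q ; P'W is unit upper triangular for NIPALS PLS1
    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        regression_vector=b,
        n_components=a,
        training_dims=(n, p),
    )


def predict(model: PLSRModel, X_new) -> np.ndarray:
    """Predict the response for new spectra with a fitted model."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.training_dims[1]:
        raise SchemaError(
            f"band count {X_new.shape[1]} does not match training "
            f"p={model.training_dims[1]}"
        )
    return model.y_mean + (X_new - model.x_mean) @ model.regression_vector


def fit_stats(y, yhat) -> tuple[float, float]:
    """(R2, RMSE) of predictions against observations.

    R2 is computed about the mean of ``y`` and may be negative on validation
    data; it is never clamped.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size or y.size < 2:
        raise InvalidParameterError("y and yhat must have equal length >= 2")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        raise DegenerateDataError("zero total sum of squares: R2 undefined")
    ssres = float(np.sum((y - yhat) ** 2))
    return 1.0 - ssres / sstot, float(np.sqrt(ssres / y.size))


def _coef_path(XtX: np.ndarray, Xty: np.ndarray, ncomp: int) -> np.ndarray:
    """PLS1 regression-vector path from centered cross-products.

    Returns B of shape (p, ncomp) where B[:, k-1] is the coefficient vector
    of the k-component model. Cross-product (Dayal-MacGregor) recursion:
    identical coefficients to NIPALS, but O(p^2) per component.
    """
    p = XtX.shape[0]
    S = Xty.copy()
    R = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    B = np.zeros((p, ncomp))
    b = np.zeros(p)
    scale = float(np.linalg.norm(Xty)) + 1e-300
    a = 0
    for k in range(ncomp):
        w = S.copy()
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale:
            break
        w /= nw
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        Xr = XtX @ r
        tt = float(r @ Xr)
        if tt <= 0.0:
            break
        pvec = Xr / tt
        qa = float(S @ r) / tt
        S -= tt * qa * pvec
        b = b + qa * r
        R[:, a], P[:, a] = r, pvec
        B[:, k] = b
        a += 1
    for k in range(a, ncomp):
        B[:, k] = b  # rank exhausted: path flattens
    return B


def loo_rmsecv(X, y, max_ncomp: int) -> CVCurve:
    """Exact leave-one-out RMSECV for component counts 0..max_ncomp.

    Each held-out fit is reconstructed from rank-one downdates of the full
    uncentered cross-products, with exact re-centering on the n-1 training
    samples; predictions equal brute-force refits to floating-point accuracy.
    """
    X, y = _as_xy(X, y)
    n, p = X.shape
    if n < 3:
        raise InvalidParameterError("leave-one-out needs at least 3 samples")
    kmax = min(max_ncomp, n - 2, p)
    if kmax < max_ncomp:
        warnings.warn(
            f"max_ncomp={max_ncomp} clipped to {kmax} for n={n}, p={p}",
            stacklevel=2,
        )
    XtX_u = X.T @ X
    Xty_u = X.T @ y
    sx = X.sum(axis=0)
    sy = float(y.sum())

    err = np.zeros((n, kmax + 1))
    nt = n - 1
    for i in range(n):
        xi, yi = X[i], y[i]
        m = (sx - xi) / nt
        ybar = (sy - yi) / nt
        XtX_c = XtX_u - np.outer(xi, xi) - nt * np.outer(m, m)
        Xty_c = Xty_u - xi * yi - nt * m * ybar
        B = _coef_path(XtX_c, Xty_c, kmax)
        pred = ybar + (xi - m) @ B
        err[i, 0] = yi - ybar
        err[i, 1:] = yi - pred
    rmse = np.sqrt(np.mean(err**2, axis=0))
    return CVCurve(n_components=np.arange(kmax + 1), rmsecv=rmse)


def loo_select_ncomp(
    X, y, max_ncomp: int = 20, tol: float = 0.02
) -> tuple[int, CVCurve]:
    """Pick the PLS rank by leave-one-out cross-validation.

    Returns the smallest component count whose RMSECV is within ``tol``
    (relative) of the curve minimum, together with the full curve. Ties and
    near-ties resolve toward fewer components.
    """
    curve = loo_rmsecv(X, y, max_ncomp)
    best = int(np.argmax(curve.rmsecv <= (1.0 + tol) * curve.rmsecv.min()))
    return best, curve


def kfold_rmse(
    X, y, ncomp: int, n_folds: int = 10, rng: np.random.Generator | None = None
) -> float:
    """K-fold CV RMSE of a ``ncomp``-component PLS1 model.

    Fold assignment is a seeded permutation split into contiguous chunks;
    pass an explicit ``rng`` to make folds reproducible (or shared across
    competing band subsets). Uses the same cross-product downdating as
    :func:`loo_rmsecv`.
    """
    X, y = _as_xy(X, y)
    n, p = X.shape
    n_folds = min(n_folds, n)
    if n_folds < 2:
        raise InvalidParameterError("need at least 2 folds")
    if rng is None:
        rng = np.random.default_rng(0)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    XtX_u = X.T @ X
    Xty_u = X.T @ y
    sx = X.sum(axis=0)
    sy = float(y.sum())
    sse = 0.0
    for idx in folds:
        Xf, yf = X[idx], y[idx]
        nt = n - idx.size
        if nt < 2:
            continue
        m = (sx - Xf.sum(axis=0)) / nt
        ybar = (sy - yf.sum()) / nt
        XtX_c = XtX_u - Xf.T @ Xf - nt * np.outer(m, m)
        Xty_c = Xty_u - Xf.T @ yf - nt * m * ybar
        kmax = min(ncomp, nt - 1, p)
        B = _coef_path(XtX_c, Xty_c, kmax)
        pred = ybar + (Xf - m) @ B[:, -1]
        sse += float(np.sum((yf - pred) ** 2))
    return float(np.sqrt(sse / n))


def vip_scores(model: PLSRModel) -> np.ndarray:
    """Variable importance in projection for each band of a fitted model.

    Normalized so that mean(VIP^2) = 1 across bands.
    """
    W = model.x_weights
    ss = model.y_loadings**2 * np.sum(model.x_scores**2, axis=0)  # per component
    wn2 = W**2 / np.maximum(np.sum(W**2, axis=0), _EPS)
    p = W.shape[0]
    denom = float(ss.sum())
    if denom <= 0:
        raise DegenerateDataError("model explains no response variance")
    return np.sqrt(p * (wn2 @ ss) / denom)
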