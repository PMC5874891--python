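"""NIPALS partial least squares (PLS1) regression for spectral data.

The latent-variable regression used to predict viable cell
concentration from Raman spectra.  Factors are extracted sequentially
by the NIPALS recursion with deflation:

    w = X' y / ||X' y||        (weights, unit norm)
    t = X w                    (scores)
    p = X' t / (t' t)          (predictor loadings)
    q = y' t / (t' t)          (response loading)
    X <- X - t p',  y <- y - t q

Regression coefficients for k factors are assembled as
``B_k = W_k (P_k' W_k)^-1 q_k`` on the centered scales.  The factor
count is chosen at the minimum cross-validated RMSE (leave-one-out by
default; ties resolved toward fewer factors).

This is the package's own implementation; established PLS libraries
are used only as independent cross-checks in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PlsModel", "fit_pls", "predict", "diagnostics"]


@dataclass
class PlsModel:
    """Fitted NIPALS PLS1 model (centered, optionally scaled)."""

    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray | None
    weights: np.ndarray      # (n_channels, n_extracted), unit-norm columns
    loadings: np.ndarray     # (n_channels, n_extracted)
    scores: np.ndarray       # (n_train, n_extracted)
    y_loadings: np.ndarray   # (n_extracted,)
    coef: np.ndarray         # (n_channels,) for the selected factor count
    n_factors: int
    rmse_c: float
    rmse_cv: np.ndarray      # per factor count 1..n_extracted
    explained_y_variance: np.ndarray  # cumulative %, per factor count
    cv_scheme: str = "loo"
    meta: dict = field(default_factory=dict)

    def coefficients_for(self, k: int) -> np.ndarray:
        """Centered-scale regression vector using the first k factors."""
        if not 1 <= k <= self.weights.shape[1]:
            raise ValueError(f"k must be in [1, {self.weights.shape[1]}]")
        W, P, q = self.weights[:, :k], self.loadings[:, :k], self.y_loadings[:k]
        return W @ np.linalg.solve(P.T @ W, q)

    def to_json(self, path) -> None:
        payload = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "x_scale": None if self.x_scale is None else self.x_scale.tolist(),
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "n_factors": int(self.n_factors),
            "rmse_c": self.rmse_c,
            "rmse_cv": self.rmse_cv.tolist(),
            "explained_y_variance": self.explained_y_variance.tolist(),
            "cv_scheme": self.cv_scheme,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlsModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            x_mean=np.asarray(d["x_mean"]),
            y_mean=d["y_mean"],
            x_scale=None if d["x_scale"] is None else np.asarray(d["x_scale"]),
            weights=np.asarray(d["weights"]),
            loadings=np.asarray(d["loadings"]),
            scores=np.empty((0, np.asarray(d["weights"]).shape[1])),
            y_loadings=np.asarray(d["y_loadings"]),
            coef=np.asarray(d["coef"]),
            n_factors=d["n_factors"],
            rmse_c=d["rmse_c"],
            rmse_cv=np.asarray(d["rmse_cv"]),
            explained_y_variance=np.asarray(d["explained_y_variance"]),
            cv_scheme=d["cv_scheme"],
            meta=d.get("meta", {}),
        )


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, max_factors: int):
    """Extract up to max_factors NIPALS components from centered data.

    For a single response the weight step is closed-form, so no inner
    iteration is required.  Extraction stops early if the residual
    covariance vanishes (rank exhausted).
    """
    X = Xc.copy()
    y = yc.copy()
    n, m = X.shape
    W, T, P, Q = [], [], [], []
    norm0 = np.linalg.norm(Xc.T @ yc)
    for _ in range(max_factors):
        cov = X.T @ y
        norm = np.linalg.norm(cov)
        if norm <= 1e-12 * max(norm0, 1e-300):
            break
        w = cov / norm
        t = X @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        p = X.T @ t / tt
        q = float(y @ t / tt)
        X = X - np.outer(t, p)
        y = y - t * q
        W.append(w)
        T.append(t)
        P.append(p)
        Q.append(q)
    if not W:
        raise ValueError("degenerate response: X'y vanishes (constant y?)")
    return (np.column_stack(W), np.column_stack(T), np.column_stack(P),
            np.asarray(Q))


def _coefs_all(W, P, Q):
    """Regression vectors for every truncation 1..k (centered scales)."""
    k = W.shape[1]
    out = np.empty((W.shape[0], k))
    for j in range(1, k + 1):
        out[:, j - 1] = W[:, :j] @ np.linalg.solve(P[:, :j].T @ W[:, :j], Q[:j])
    return out


def _cv_folds(n: int, cv_scheme, seed):
    if cv_scheme == "loo":
        return [np.array([i]) for i in range(n)]
    k = int(cv_scheme)
    if not 2 <= k <= n:
        raise ValueError(f"k-fold cv needs 2 <= k <= n, got k={k}, n={n}")
    idx = np.arange(n)
    rng = np.random.default_rng(seed)
    rng.shuffle(idx)
    return [np.sort(f) for f in np.array_split(idx, k)]


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    max_factors: int = 6,
    cv_scheme="loo",
    scale: bool = False,
    tol: float = 1e-10,
    max_iter: int = 500,
    seed: int | None = None,
) -> PlsModel:
    """Fit a PLS1 model with cross-validated factor selection.

    Predictors and response are mean-centered (unit-variance scaling of
    X optional).  The cross-validated RMSE is computed for every factor
    count up to ``max_factors``; the model keeps the count minimizing
    it, preferring fewer factors on ties.  ``tol``/``max_iter`` bound
    the NIPALS inner iteration (closed-form for a single response, so
    they only guard future multi-response use).

    ``cv_scheme`` is ``"loo"`` or an integer fold count (shuffled with
    ``seed``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per response value")
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: y is constant")
    max_factors = int(min(max_factors, n - 1, m))
    if max_factors < 1:
        raise ValueError("max_factors must allow at least one factor")
    if tol <= 0 or max_iter < 1:
        raise ValueError(f"invalid convergence settings tol={tol}, max_iter={max_iter}")

    x_mean = X.mean(axis=0)
    x_scale = None
    Xc = X - x_mean
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
        Xc = Xc / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean

    # cross-validated RMSE per factor count
    folds = _cv_folds(n, cv_scheme, seed)
    press = None
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        Xt = X[train]
        mt = Xt.mean(axis=0)
        Xtc = Xt - mt
        st = None
        if scale:
            st = Xt.std(axis=0, ddof=1)
            st[st == 0] = 1.0
            Xtc = Xtc / st
        ymt = y[train].mean()
        try:
            W, T, P, Q = _nipals_pls1(Xtc, y[train] - ymt, max_factors)
        except ValueError:
            continue
        B = _coefs_all(W, P, Q)  # (m, k_fold)
        Xv = X[test] - mt
        if scale:
            Xv = Xv / st
        preds = Xv @ B + ymt  # (n_test, k_fold)
        if press is None:
            press = np.zeros(max_factors)
            counts = np.zeros(max_factors, dtype=int)
        kf = B.shape[1]
        err = (preds - y[test][:, None]) ** 2
        press[:kf] += err.sum(axis=0)
        counts[:kf] += len(test)
    if press is None:
        raise ValueError("cross-validation failed on every fold")
    valid = counts > 0
    rmse_cv = np.full(max_factors, np.nan)
    rmse_cv[valid] = np.sqrt(press[valid] / counts[valid])

    # final model on all data
    W, T, P, Q = _nipals_pls1(Xc, yc, max_factors)
    k_extracted = W.shape[1]
    rmse_cv = rmse_cv[:k_extracted]
    n_factors = int(np.nanargmin(np.round(rmse_cv, 12)) + 1)

    B = _coefs_all(W, P, Q)
    fitted = Xc @ B  # (n, k)
    ss_tot = float(yc @ yc)
    ss_res = ((yc[:, None] - fitted) ** 2).sum(axis=0)
    explained = 100.0 * (1.0 - ss_res / ss_tot)
    rmse_c = float(np.sqrt(ss_res[n_factors - 1] / n))

    return PlsModel(
        x_mean=x_mean, y_mean=y_mean, x_scale=x_scale,
        weights=W, loadings=P, scores=T, y_loadings=Q,
        coef=B[:, n_factors - 1], n_factors=n_factors,
        rmse_c=rmse_c, rmse_cv=rmse_cv,
        explained_y_variance=explained,
        cv_scheme="loo" if cv_scheme == "loo" else f"{int(cv_scheme)}-fold",
        meta={"n_train": n, "n_channels": m, "scale": scale,
              "max_factors_requested": max_factors, "seed": seed},
    )


def predict(model: PlsModel, X_new: np.ndarray, n_factors: int | None = None) -> np.ndarray:
    """Predict responses for new spectra (channel axis must match training)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"channel mismatch: model has {model.x_mean.shape[0]} channels, "
            f"input has {X_new.shape[1]}")
    Xc = X_new - model.x_mean
    if model.x_scale is not None:
        Xc = Xc / model.x_scale
    coef = model.coef if n_factors is None else model.coefficients_for(n_factors)
    return Xc @ coef + model.y_mean


def diagnostics(model: PlsModel, X: np.ndarray, y: np.ndarray) -> dict:
    """RMSE, R^2 and the per-factor explained response variance.

    R^2 = 1 - SS_res/SS_tot over the supplied data; the explained
    variance curve is the model's cumulative calibration curve.
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    yhat = predict(model, X)
    return {
        "RMSE": rmse(yhat, y),
        "R2": r_squared(yhat, y),
        "explained_y_variance": model.explained_y_variance.tolist(),
        "n_factors": model.n_factors,
    }


def rmse(yhat, y) -> float:
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def r_squared(yhat, y) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot
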