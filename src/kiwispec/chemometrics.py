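"""Calibration model families: MLR, PLSR and LS-SVM.

All three regress one quality attribute on reflectance spectra:

* **MLR** — ordinary least squares on the selected bands.  Requires more
  samples than variables, hence is only usable after wavelength selection.
* **PLSR** — single-response NIPALS partial least squares.  Spectra are
  compressed into orthogonal latent variables (LVs) maximizing covariance
  with the response; the LV count is chosen by leave-one-out cross-validation
  on the calibration set.
* **LS-SVM** — least-squares support vector machine with an RBF kernel
  k(u, v) = exp(-||u - v||^2 / sigma2).  Training solves one linear system;
  the regularization gamma and bandwidth sigma2 are tuned by a two-step
  (coarse then refined) log-grid search under leave-one-out CV.

Preprocessing is mean-centering only; no SNV/MSC/derivative pretreatment is
applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np

__all__ = [
    "SpectralDataset",
    "RegressionModel",
    "fit_mlr",
    "fit_plsr",
    "fit_lssvm",
    "predict",
]


@dataclass
class SpectralDataset:
    """Mean-spectrum matrix X (n_samples x n_bands) paired with one attribute y."""

    X: np.ndarray
    y: np.ndarray
    wavelengths: np.ndarray
    attribute: str = "attribute"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("X rows and y length differ")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if len(self.wavelengths) != self.X.shape[1]:
            raise ValueError("wavelengths length and X columns differ")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("X/y contain missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def subset(self, rows=None, bands=None) -> "SpectralDataset":
        X, y, wl = self.X, self.y, self.wavelengths
        if rows is not None:
            X, y = X[rows], y[rows]
        if bands is not None:
            X, wl = X[:, bands], wl[bands]
        return SpectralDataset(X, y, wl, self.attribute)


@dataclass
class RegressionModel:
    """A fitted calibration model, carrying everything pixel-level
    prediction needs.

    MLR and PLSR expose a reduced linear form (intercept + one coefficient
    per band); LS-SVM stores its support values alpha, bias b, the tuned
    (gamma, sigma2) and the training spectra.
    """

    family: str
    wavelengths: np.ndarray
    attribute: str = "attribute"
    intercept: float = 0.0
    coefficients: np.ndarray | None = None
    n_lvs: int | None = None
    x_mean: np.ndarray | None = None
    y_mean: float | None = None
    # PLSR internals
    weights: np.ndarray | None = None
    loadings: np.ndarray | None = None
    scores: np.ndarray | None = None
    y_loadings: np.ndarray | None = None
    # LS-SVM
    alpha: np.ndarray | None = None
    b: float | None = None
    gamma: float | None = None
    sigma2: float | None = None
    X_train: np.ndarray | None = None
    # cross-validation record (leave-one-out on the calibration set)
    cv_predictions: np.ndarray | None = None
    cv_rmse: float | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        """Serialize the reduced linear form (MLR/PLSR).  LS-SVM additionally
        writes its support data to a .npz sidecar next to ``path``."""
        d = {
            "family": self.family,
            "attribute": self.attribute,
            "wavelengths": list(map(float, self.wavelengths)),
            "intercept": float(self.intercept),
        }
        if self.coefficients is not None:
            d["coefficients"] = list(map(float, self.coefficients))
        if self.n_lvs is not None:
            d["n_lvs"] = int(self.n_lvs)
        if self.family == "LSSVM":
            d.update(gamma=float(self.gamma), sigma2=float(self.sigma2))
            sidecar = Path(path).with_suffix(".npz")
            np.savez(sidecar, alpha=self.alpha, b=self.b, X_train=self.X_train)
            d["sidecar"] = sidecar.name
        Path(path).write_text(json.dumps(d, indent=2))


def _check_bands(model: RegressionModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.wavelengths):
        raise ValueError(
            f"model expects {len(model.wavelengths)} bands, got {X_new.shape[1]}"
        )
    return X_new


def predict(model: RegressionModel, X_new: np.ndarray) -> np.ndarray:
    """Apply a fitted model to new spectra (rows)."""
    X_new = _check_bands(model, X_new)
    if model.family in ("MLR", "PLSR"):
        return model.intercept + X_new @ model.coefficients
    if model.family == "LSSVM":
        K = _rbf_kernel(X_new - model.x_mean, model.X_train, model.sigma2)
        return K @ model.alpha + model.b
    raise ValueError(f"unknown model family {model.family!r}")


# ---------------------------------------------------------------------------
# MLR
# ---------------------------------------------------------------------------

def fit_mlr(ds: SpectralDataset) -> RegressionModel:
    """Ordinary least squares with intercept.

    Fails (by design) when variables outnumber samples; run wavelength
    selection first.  Leave-one-out CV predictions come from the hat-matrix
    identity e_loo = e / (1 - h_ii), at no extra fitting cost.
    """
    n, p = ds.X.shape
    if n <= p + 1:
        raise ValueError(
            f"MLR needs n_samples > n_bands + 1 (got n={n}, p={p}); "
            "select effective wavelengths first"
        )
    A = np.column_stack([np.ones(n), ds.X])
    # constant (zero-variance) columns degrade gracefully to the intercept;
    # genuine collinearity among varying bands is an error
    Xc = ds.X - ds.X.mean(axis=0)
    varying = np.flatnonzero(Xc.std(axis=0) > 0)
    if len(varying) and np.linalg.matrix_rank(Xc[:, varying]) < len(varying):
        raise ValueError(
            "design matrix is singular (collinear bands); apply variable selection first"
        )
    beta, *_ = np.linalg.lstsq(A, ds.y, rcond=None)
    fitted = A @ beta
    # LOO via leverages
    Q, _ = np.linalg.qr(A)
    h = np.sum(Q**2, axis=1)
    resid = ds.y - fitted
    loo_pred = ds.y - resid / (1.0 - h)
    cv_rmse = float(np.sqrt(np.mean((ds.y - loo_pred) ** 2)))
    return RegressionModel(
        family="MLR",
        wavelengths=ds.wavelengths.copy(),
        attribute=ds.attribute,
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        cv_predictions=loo_pred,
        cv_rmse=cv_rmse,
    )


# ---------------------------------------------------------------------------
# PLSR (NIPALS, single response)
# ---------------------------------------------------------------------------

def _nipals_coefs(X: np.ndarray, y: np.ndarray, max_lvs: int):
    """NIPALS decomposition of mean-centered data.

    Returns (coefs, internals) where ``coefs[a]`` is (intercept, B) of the
    reduced form using a+1 latent variables, on the original (uncentered)
    scale.  Extraction stops early if the deflated X or y collapses.
    """
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    n, p = X.shape
    W, P, T, Q = [], [], [], []
    R = []  # R = W (P'W)^-1, built incrementally
    coefs = []
    B = np.zeros(p)
    eps = np.finfo(float).eps
    for _ in range(max_lvs):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e3 * eps * max(1.0, np.linalg.norm(y)):
            break
        w /= nw
        t = Xc @ w
        tt = t @ t
        if tt < 1e3 * eps:
            break
        pvec = Xc.T @ t / tt
        q = (yc @ t) / tt
        Xc = Xc - np.outer(t, pvec)
        yc = yc - q * t
        r = w - sum((P[j] @ w) * R[j] for j in range(len(R)))
        W.append(w)
        P.append(pvec)
        T.append(t)
        Q.append(q)
        R.append(r)
        B = B + q * r
        coefs.append((float(y_mean - x_mean @ B), B.copy()))
    internals = {
        "weights": np.array(W).T if W else np.zeros((p, 0)),
        "loadings": np.array(P).T if P else np.zeros((p, 0)),
        "scores": np.array(T).T if T else np.zeros((n, 0)),
        "y_loadings": np.array(Q),
        "x_mean": x_mean,
        "y_mean": float(y_mean),
    }
    return coefs, internals


def fit_plsr(ds: SpectralDataset, max_lvs: int = 20) -> RegressionModel:
    """NIPALS PLSR with the LV count chosen by leave-one-out CV.

    ``n_lvs`` is the argmin of LOO RMSECV over 1..max_lvs (ties break to the
    smaller count).  The reduced-form coefficients at the chosen count are
    stored, alongside the full-data scores/loadings/weights.
    """
    n, p = ds.X.shape
    if np.std(ds.y) == 0:
        raise ValueError("y has zero variance")
    max_lvs = int(min(max_lvs, n - 1, p))
    if max_lvs < 1:
        raise ValueError("max_lvs must allow at least one latent variable")

    # LOO predictions for every candidate LV count
    preds = np.full((n, max_lvs), np.nan)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        coefs, _ = _nipals_coefs(ds.X[keep], ds.y[keep], max_lvs)
        for a in range(max_lvs):
            b0, B = coefs[min(a, len(coefs) - 1)]
            preds[i, a] = b0 + ds.X[i] @ B
    rmsecv = np.sqrt(np.mean((preds - ds.y[:, None]) ** 2, axis=0))
    n_lvs = int(np.argmin(rmsecv)) + 1

    coefs, internals = _nipals_coefs(ds.X, ds.y, max_lvs)
    b0, B = coefs[min(n_lvs, len(coefs)) - 1]
    return RegressionModel(
        family="PLSR",
        wavelengths=ds.wavelengths.copy(),
        attribute=ds.attribute,
        intercept=b0,
        coefficients=B,
        n_lvs=n_lvs,
        x_mean=internals["x_mean"],
        y_mean=internals["y_mean"],
        weights=internals["weights"],
        loadings=internals["loadings"],
        scores=internals["scores"],
        y_loadings=internals["y_loadings"],
        cv_predictions=preds[:, n_lvs - 1],
        cv_rmse=float(rmsecv[n_lvs - 1]),
        extras={"rmsecv_by_lv": rmsecv},
    )


# ---------------------------------------------------------------------------
# LS-SVM (RBF)
# ---------------------------------------------------------------------------

def _rbf_kernel(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-np.maximum(d2, 0.0) / sigma2)


def _lssvm_solve(K: np.ndarray, y: np.ndarray, gamma: float):
    """Solve the LS-SVM system; returns (alpha, b, loo_residuals).

    System:  [[0, 1'], [1, K + I/gamma]] [b; alpha] = [0; y].
    The leave-one-out residual is the closed form e_i = alpha_i / (A^-1)_ii
    (the LS-SVM analogue of the OLS hat-matrix identity), avoiding n refits
    per grid point.
    """
    n = len(y)
    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        A[1:, 1:] += 1e-8 * np.eye(n)  # ridge jitter retry
        Ainv = np.linalg.inv(A)
    rhs = np.concatenate([[0.0], y])
    sol = Ainv @ rhs
    b, alpha = sol[0], sol[1:]
    diag = np.diag(Ainv)[1:]
    loo_resid = alpha / diag
    return alpha, float(b), loo_resid


def _lssvm_loo_rmse(D2: np.ndarray, y: np.ndarray, gamma: float, sigma2: float) -> float:
    K = np.exp(-D2 / sigma2)
    _, _, e = _lssvm_solve(K, y, gamma)
    return float(np.sqrt(np.mean(e**2)))


def fit_lssvm(
    ds: SpectralDataset,
    grid_lo: float = 1e-2,
    grid_hi: float = 1e8,
    n_grid: int = 10,
) -> RegressionModel:
    """LS-SVM with RBF kernel, tuned by a two-step LOO-CV grid search.

    Step 1 scans an ``n_grid x n_grid`` log-uniform (gamma, sigma2) grid over
    [grid_lo, grid_hi]^2; step 2 re-scans an equally sized log grid spanning
    one coarse-grid cell on each side of the coarse optimum.  The coarse
    optimum itself is kept in the candidate set, so refinement never worsens
    the LOO RMSE.  Spectra are mean-centered before the kernel.
    """
    if not (grid_lo > 0 and grid_lo < grid_hi):
        raise ValueError("grid bounds must satisfy 0 < grid_lo < grid_hi")
    x_mean = ds.X.mean(axis=0)
    Xc = ds.X - x_mean
    d2 = (
        np.sum(Xc**2, axis=1)[:, None]
        + np.sum(Xc**2, axis=1)[None, :]
        - 2.0 * Xc @ Xc.T
    )
    D2 = np.maximum(d2, 0.0)

    lo, hi = np.log10(grid_lo), np.log10(grid_hi)
    coarse = np.logspace(lo, hi, n_grid)
    step = (hi - lo) / (n_grid - 1)

    def scan(gammas, sigma2s):
        best = (np.inf, None, None)
        for s2 in sigma2s:
            for g in gammas:
                r = _lssvm_loo_rmse(D2, ds.y, g, s2)
                if r < best[0]:
                    best = (r, g, s2)
        return best

    rmse1, g1, s1 = scan(coarse, coarse)

    def fine_axis(center):
        lg = np.log10(center)
        a, b = max(lo, lg - step), min(hi, lg + step)
        return np.logspace(a, b, n_grid)

    fine_g = fine_axis(g1)
    fine_s = fine_axis(s1)
    rmse2, g2, s2 = scan(np.append(fine_g, g1), np.append(fine_s, s1))
    gamma, sigma2 = (g2, s2) if rmse2 <= rmse1 else (g1, s1)

    K = np.exp(-D2 / sigma2)
    alpha, b, e = _lssvm_solve(K, ds.y, gamma)
    return RegressionModel(
        family="LSSVM",
        wavelengths=ds.wavelengths.copy(),
        attribute=ds.attribute,
        x_mean=x_mean,
        alpha=alpha,
        b=b,
        gamma=float(gamma),
        sigma2=float(sigma2),
        X_train=Xc,
        cv_predictions=ds.y - e,
        cv_rmse=float(np.sqrt(np.mean(e**2))),
        extras={"coarse_loo_rmse": rmse1, "refined_loo_rmse": min(rmse1, rmse2)},
    )
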