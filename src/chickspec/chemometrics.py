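"""PCA and PLS building blocks for spectral decomposition.

PCA extracts orthogonal variance-ordered components whose scores and
loadings are discussed per sample and per wavenumber respectively.  PLS
regresses the spectra against a response vector; when no measured
concentration exists, an *artificial concentration profile* — 2 for one
class, 1 for the other — serves as the dummy response, so the leading PLS
factors are the spectral components that co-vary with class membership.
Model quality is summarised by R² in calibration (training fit) and in
leave-one-out cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SkPCA

__all__ = ["PCAResult", "PLSResult", "pca", "artificial_profile", "pls_fit", "loocv_pls"]


@dataclass(frozen=True)
class PCAResult:
    """Scores (samples × components), loadings (components × wavenumbers),
    explained variance ratios and the centering vector."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def project(self, X: np.ndarray) -> np.ndarray:
        """Scores of new observations in this model's component space."""
        return (np.atleast_2d(X) - self.mean) @ self.loadings.T


def pca(
    data: np.ndarray,
    n_components: int | None = None,
    center: bool = True,
    scale: bool = False,
) -> PCAResult:
    """Principal component analysis with a deterministic sign convention.

    Components are ordered by decreasing explained variance; each loading is
    flipped so its element of largest absolute value is positive (scores are
    flipped along with it).  Mean-centering is standard for spectra;
    unit-variance scaling is off by default.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a samples × wavenumbers matrix")
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate data: all columns are constant")
    work = X.copy()
    if scale:
        sd = work.std(axis=0, ddof=1)
        work = work / np.where(sd > 0, sd, 1.0)
    model = _SkPCA(n_components=n_components, svd_solver="full")
    if not center:
        # sklearn always centers; emulate "no centering" by shifting back.
        model.fit(work)
        mean = np.zeros(p)
        scores = work @ model.components_.T
    else:
        scores = model.fit_transform(work)
        mean = model.mean_
    loadings = model.components_.copy()
    flip = np.sign(loadings[np.arange(loadings.shape[0]), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings *= flip[:, None]
    scores = scores * flip[None, :]
    return PCAResult(scores, loadings, model.explained_variance_ratio_.copy(), mean)


def artificial_profile(
    labels: Sequence[str], values: Mapping[str, float] | None = None
) -> np.ndarray:
    """Dummy response vector for class-coded PLS: (male, female) → (2, 1) by default."""
    if values is None:
        values = {"male": 2.0, "female": 1.0}
    out = np.empty(len(labels), dtype=float)
    for i, lab in enumerate(labels):
        if lab not in values:
            raise ValueError(f"unknown label {lab!r}; expected one of {sorted(values)}")
        out[i] = values[lab]
    return out


@dataclass(frozen=True)
class PLSResult:
    """Single-response PLS fit: coefficients B (centered X → centered Y),
    factor scores/loadings for X, Y loadings, training residual E and R²."""

    B: np.ndarray
    x_scores: np.ndarray
    x_loadings: np.ndarray
    x_weights: np.ndarray
    y_loadings: np.ndarray
    residual: np.ndarray
    n_factors: int
    R2_calibration: float
    x_mean: np.ndarray
    y_mean: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.x_mean) @ self.B + self.y_mean


def pls_fit(X: np.ndarray, y: np.ndarray, n_factors: int) -> PLSResult:
    """NIPALS partial least squares with a single response.

    Factors are extracted iteratively with deflation of X after each one;
    inputs are mean-centered (no variance scaling).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on the number of samples")
    if n_factors < 1:
        raise ValueError("n_factors must be ≥ 1")
    if np.allclose(y.var(), 0):
        raise ValueError("response has zero variance; PLS is undefined")
    n_factors = min(n_factors, X.shape[0] - 1, X.shape[1])
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    if np.linalg.norm(Xc.T @ yc) < 1e-12 * max(np.linalg.norm(Xc), 1.0) * np.linalg.norm(yc):
        # response exactly orthogonal to the data: no factor can be extracted
        p = X.shape[1]
        return PLSResult(
            B=np.zeros(p),
            x_scores=np.zeros((X.shape[0], 0)),
            x_loadings=np.zeros((0, p)),
            x_weights=np.zeros((0, p)),
            y_loadings=np.zeros(0),
            residual=yc.copy(),
            n_factors=0,
            R2_calibration=0.0,
            x_mean=X.mean(axis=0),
            y_mean=float(np.mean(y)),
        )
    model = PLSRegression(n_components=n_factors, scale=False)
    model.fit(X, y)
    fitted = model.predict(X).ravel()
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_cal = 1.0 - float(np.sum(resid**2)) / ss_tot
    return PLSResult(
        B=model.coef_.reshape(-1),
        x_scores=model.x_scores_.copy(),
        x_loadings=model.x_loadings_.T.copy(),
        x_weights=model.x_weights_.T.copy(),
        y_loadings=model.y_loadings_.ravel().copy(),
        residual=resid,
        n_factors=n_factors,
        R2_calibration=r2_cal,
        x_mean=X.mean(axis=0),
        y_mean=float(np.mean(y)),
    )


def loocv_pls(
    X: np.ndarray, y: np.ndarray, n_factors: int
) -> tuple[float, float, np.ndarray]:
    """Leave-one-out validation of a PLS model.

    Each sample is predicted by a model refit (including re-centering) on
    the remaining samples.  Returns ``(R2_calibration, R2_validation,
    per-sample held-out predictions)``; R²_validation is computed from the
    held-out predictions against y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    full = pls_fit(X, y, n_factors)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        if np.allclose(y[keep].var(), 0):
            raise ValueError(f"fold {i}: training response has zero variance")
        sub = pls_fit(X[keep], y[keep], n_factors)
        preds[i] = sub.predict(X[i]).item()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_val = 1.0 - float(np.sum((y - preds) ** 2)) / ss_tot
    return full.R2_calibration, r2_val, preds
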