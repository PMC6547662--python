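"""NIPALS partial least squares regression (PLS1) with cross-validation.

The classical NIPALS algorithm on column-centered X and centered y: each
component takes the weight vector w proportional to X'y, scores t = Xw,
loadings p = X't/t't and q = y't/t't, then deflates X.  Regression
coefficients for k components are B = W (P'W)^-1 q on the centered scale, so
predicting the training-mean spectrum returns the training-mean content.

Cross-validation refits everything that can leak — per-wavelength centering /
scaling and the PLS decomposition — inside each fold; per-spectrum transforms
(SNV, smoothing, derivatives) are row-wise and are safely applied once before
folding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import PreprocessRecipe

__all__ = ["PlsModel", "CvCurve", "fit_pls", "cross_validate", "select_components", "nipals"]

_EPS = np.finfo(np.float64).eps


def nipals(X, y, k_max: int):
    """Run NIPALS PLS1 on centered X, y; returns (W, P, q, n_extracted).

    Extraction stops early when X carries no further covariance with y
    (e.g. constant y, or k_max above the effective rank); callers decide
    whether truncation is an error.
    """
    X = np.array(X, dtype=np.float64)
    y = np.array(y, dtype=np.float64)
    n, p = X.shape
    W = np.zeros((p, k_max))
    P = np.zeros((p, k_max))
    q = np.zeros(k_max)
    scale0 = max(np.abs(X).max(initial=0.0) * np.abs(y).max(initial=0.0), _EPS)
    k = 0
    for j in range(k_max):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale0 or not np.isfinite(nw):
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt <= 1e-24 * max(scale0, 1.0):
            break
        pj = (X.T @ t) / tt
        qj = (y @ t) / tt
        X -= np.outer(t, pj)
        y = y - qj * t
        W[:, j], P[:, j], q[j] = w, pj, qj
        k += 1
    return W[:, :k], P[:, :k], q[:k], k


def _coefficients(W, P, q):
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    R = np.linalg.solve((P.T @ W), q.reshape(-1, 1))
    return (W @ R).ravel()


@dataclass
class PlsModel:
    """A fitted PLS calibration: preprocessing recipe + centered regression."""

    constituent: str
    k: int
    coefficients: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    recipe: PreprocessRecipe | None = None
    weights: np.ndarray | None = None
    x_loadings: np.ndarray | None = None
    y_loadings: np.ndarray | None = None
    training_ids: list | None = None
    training_range: tuple | None = None
    seed: int | None = None
    algorithm: str = "NIPALS"

    def predict_matrix(self, X) -> np.ndarray:
        """Predict contents from an already recipe-transformed matrix."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[-1] != self.coefficients.shape[0]:
            raise ValueError(
                f"wavelength-set mismatch: model expects {self.coefficients.shape[0]} "
                f"variables, got {X.shape[-1]}"
            )
        pred = (X - self.x_mean) @ self.coefficients + self.y_mean
        if self.training_range is not None:
            lo, hi = self.training_range
            if np.any(pred < lo) or np.any(pred > hi):
                warnings.warn(
                    f"{self.constituent}: predictions outside the training content "
                    f"range [{lo:.3g}, {hi:.3g}] (extrapolation)"
                )
        return pred

    def predict(self, X, wavelengths=None) -> np.ndarray:
        """Predict contents, applying the fitted recipe if one is attached."""
        if self.recipe is not None and wavelengths is not None:
            X, _ = self.recipe.transform(X, wavelengths)
        return self.predict_matrix(X)

    # -- plain-text persistence (JSON: full-precision float repr) -----------
    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "format": "foliarnirs-pls-model",
            "algorithm": self.algorithm,
            "constituent": self.constituent,
            "k": int(self.k),
            "seed": self.seed,
            "coefficients": arr(self.coefficients),
            "x_mean": arr(self.x_mean),
            "y_mean": float(self.y_mean),
            "weights": arr(self.weights),
            "x_loadings": arr(self.x_loadings),
            "y_loadings": arr(self.y_loadings),
            "training_ids": self.training_ids,
            "training_range": None if self.training_range is None else list(self.training_range),
            "recipe": None if self.recipe is None else self.recipe.to_dict(),
        }

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d) -> "PlsModel":
        def arr(a):
            return None if a is None else np.asarray(a, dtype=np.float64)

        return cls(
            constituent=d["constituent"],
            k=d["k"],
            coefficients=arr(d["coefficients"]),
            x_mean=arr(d["x_mean"]),
            y_mean=d["y_mean"],
            recipe=None if d.get("recipe") is None else PreprocessRecipe.from_dict(d["recipe"]),
            weights=arr(d.get("weights")),
            x_loadings=arr(d.get("x_loadings")),
            y_loadings=arr(d.get("y_loadings")),
            training_ids=d.get("training_ids"),
            training_range=None if d.get("training_range") is None else tuple(d["training_range"]),
            seed=d.get("seed"),
            algorithm=d.get("algorithm", "NIPALS"),
        )

    @classmethod
    def load(cls, path) -> "PlsModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_pls(X, y, k: int, constituent: str = "y", allow_truncation: bool = False, **meta) -> PlsModel:
    """Fit a k-component NIPALS PLS1 model (centers X and y internally)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    n, p = X.shape
    if not (1 <= k <= min(n - 1, p)):
        raise ValueError(f"k must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}], got {k}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, k_got = nipals(X - x_mean, y - y_mean, k)
    if k_got < k and not allow_truncation:
        raise ValueError(f"requested k={k} exceeds attained rank {k_got}")
    return PlsModel(
        constituent=constituent,
        k=k_got,
        coefficients=_coefficients(W, P, q),
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        training_range=(float(y.min()), float(y.max())),
        **meta,
    )


def _cv_predict_all_k(X_train, y_train, X_test, k_max, scale=False):
    """Held-out predictions for every k in 1..k_max from one NIPALS pass."""
    x_mean = X_train.mean(axis=0)
    y_mean = y_train.mean()
    Xt = X_train - x_mean
    Xs = X_test - x_mean
    if scale:
        sd = X_train.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xt = Xt / sd
        Xs = Xs / sd
    W, P, q, k_got = nipals(Xt, y_train - y_mean, k_max)
    preds = np.empty((X_test.shape[0], k_max))
    acc = np.full(X_test.shape[0], y_mean, dtype=np.float64)
    Xd = Xs.copy()
    for j in range(k_max):
        if j < k_got:
            t = Xd @ W[:, j]
            acc = acc + q[j] * t
            Xd = Xd - np.outer(t, P[:, j])
        preds[:, j] = acc
    return preds


@dataclass
class CvCurve:
    ks: np.ndarray
    rmsecv: np.ndarray
    r2_cval: np.ndarray
    folds: list  # list of index arrays
    k_max: int
    seed: int | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"k": self.ks, "rmsecv": self.rmsecv, "r2_cval": self.r2_cval})


def cross_validate(X, y, k_max: int, folds: int = 10, seed: int = 0,
                   groups=None, scale: bool = False) -> CvCurve:
    """K-fold cross-validation of NIPALS PLS over component counts 1..k_max.

    Fold assignment is a seeded random partition with sizes differing by at
    most one.  When *groups* is given (e.g. replicate scans of one sample),
    all members of a group share a fold so duplicates cannot leak.  Column
    centering (and scaling, if requested) is refitted inside every fold.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    if not (2 <= folds <= n):
        raise ValueError(f"need 2 <= folds <= n_samples, got folds={folds}, n={n}")
    rng = np.random.default_rng(seed)
    if groups is None:
        fold_sets = np.array_split(rng.permutation(n), folds)
    else:
        groups = np.asarray(groups)
        uniq = rng.permutation(np.unique(groups))
        group_sets = np.array_split(uniq, folds)
        fold_sets = [np.nonzero(np.isin(groups, gs))[0] for gs in group_sets]
    fold_sets = [f for f in fold_sets if f.size > 0]

    max_train = min(len(np.delete(np.arange(n), f)) - 1 for f in fold_sets)
    k_eff = min(k_max, max_train, X.shape[1])
    if k_eff < k_max:
        warnings.warn(f"k_max lowered from {k_max} to {k_eff} (fold training size limit)")

    preds = np.empty((n, k_eff))
    for f in fold_sets:
        train = np.delete(np.arange(n), f)
        preds[f] = _cv_predict_all_k(X[train], y[train], X[f], k_eff, scale=scale)

    resid = preds - y[:, None]
    rmsecv = np.sqrt(np.mean(resid**2, axis=0))
    sy = y.std()
    if sy > 0:
        with np.errstate(invalid="ignore"):
            r2 = np.array([np.corrcoef(preds[:, j], y)[0, 1] ** 2 for j in range(k_eff)])
    else:
        r2 = np.full(k_eff, np.nan)
    return CvCurve(
        ks=np.arange(1, k_eff + 1),
        rmsecv=rmsecv,
        r2_cval=r2,
        folds=[np.sort(f) for f in fold_sets],
        k_max=k_eff,
        seed=seed,
    )


def select_components(curve: CvCurve, tolerance: float = 0.02) -> int:
    """Most parsimonious k: smallest k with RMSECV <= (1+tolerance) * min RMSECV."""
    if curve.ks.size == 0:
        raise ValueError("empty cross-validation curve")
    best = curve.rmsecv.min()
    ok = np.nonzero(curve.rmsecv <= (1.0 + tolerance) * best)[0]
    return int(curve.ks[ok[0]])
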