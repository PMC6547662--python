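"""Calibration/validation sample selection and spectral outlier screening.

Kennard-Stone picks a calibration subset that spans the spectral space: the
first two samples are the most distant pair, and every further pick maximises
its minimum Euclidean distance to the already-selected set.  Outliers are
flagged by Mahalanobis distance in the space of the leading principal
components (the raw spectral space has p >> n, so the full covariance is
singular), against a chi-square quantile threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist
from scipy.stats import chi2

__all__ = ["SplitResult", "OutlierReport", "kennard_stone", "mahalanobis_outliers", "n_calibration"]


@dataclass
class SplitResult:
    calibration_indices: np.ndarray
    validation_indices: np.ndarray
    selection_order: np.ndarray
    ratio: float
    sample_ids: list | None = None

    @property
    def calibration_ids(self):
        return [self.sample_ids[i] for i in self.calibration_indices]

    @property
    def validation_ids(self):
        return [self.sample_ids[i] for i in self.validation_indices]

    def to_frame(self):
        import pandas as pd

        ids = self.sample_ids or list(range(len(self.calibration_indices) + len(self.validation_indices)))
        role = {i: "calibration" for i in self.calibration_indices}
        role.update({i: "validation" for i in self.validation_indices})
        return pd.DataFrame({"sample_id": ids, "role": [role[i] for i in range(len(ids))]})


@dataclass
class OutlierReport:
    distances: np.ndarray
    threshold: float
    flagged_indices: np.ndarray
    n_components: int
    alpha: float
    sample_ids: list | None = None

    @property
    def flagged_ids(self):
        return [self.sample_ids[i] for i in self.flagged_indices]

    def to_frame(self):
        import pandas as pd

        ids = self.sample_ids or list(range(len(self.distances)))
        flagged = np.zeros(len(self.distances), dtype=bool)
        flagged[self.flagged_indices] = True
        return pd.DataFrame({"sample_id": ids, "mahalanobis": self.distances, "flagged": flagged})


def n_calibration(n: int, ratio: float = 0.85) -> int:
    """Calibration subset size: round(ratio * n), round-half-up."""
    return int(math.floor(ratio * n + 0.5))


def kennard_stone(X, n_cal: int, sample_ids=None, ratio: float | None = None) -> SplitResult:
    """Greedy max-min-distance Kennard-Stone calibration/validation split.

    Ties in distance break toward the lowest input row index, so the split is
    deterministic for a given input ordering.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    n = X.shape[0]
    if not (2 <= n_cal <= n):
        raise ValueError(f"n_cal must be in [2, {n}], got {n_cal}")
    D = squareform(pdist(X))
    # first pair: maximum distance; flattened argmax = lexicographically lowest tie
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    min_dist[selected] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_dist))  # argmax takes the first (lowest index) on ties
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[nxt] = -np.inf
    order = np.asarray(selected, dtype=np.int64)
    cal = np.sort(order)
    val = np.setdiff1d(np.arange(n), cal)
    if val.size == 0:
        warnings.warn("Kennard-Stone selected every sample; validation set is empty")
    return SplitResult(
        calibration_indices=cal,
        validation_indices=val,
        selection_order=order,
        ratio=ratio if ratio is not None else n_cal / n,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
    )


def mahalanobis_outliers(
    X,
    n_components: int | None = None,
    alpha: float = 0.01,
    variance_explained: float = 0.99,
    max_components: int = 10,
    sample_ids=None,
) -> OutlierReport:
    """Flag spectral outliers by Mahalanobis distance on PCA scores.

    When *n_components* is None, the smallest number of leading principal
    components explaining at least *variance_explained* of the variance is
    used, capped at *max_components* (noise-dominated trailing components make
    the chi-square reference unstable).  The threshold is
    sqrt(chi2.ppf(1 - alpha, n_components)); distances exceed it iff flagged.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    if n_components is None:
        frac = np.cumsum(var) / var.sum()
        n_components = int(np.searchsorted(frac, variance_explained) + 1)
        n_components = min(n_components, max_components, n - 1)
    if not (1 <= n_components < n):
        raise ValueError(f"need 1 <= n_components < n_samples, got {n_components}")
    if var[n_components - 1] <= np.finfo(float).eps * var[0]:
        raise ValueError(
            f"component {n_components} has (numerically) zero variance; "
            "lower n_components"
        )
    scores = U[:, :n_components] * s[:n_components]
    d2 = np.sum(scores**2 / var[:n_components], axis=1)
    distances = np.sqrt(d2)
    threshold = float(np.sqrt(chi2.ppf(1.0 - alpha, df=n_components)))
    flagged = np.nonzero(distances > threshold)[0]
    return OutlierReport(
        distances=distances,
        threshold=threshold,
        flagged_indices=flagged,
        n_components=n_components,
        alpha=alpha,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
    )
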