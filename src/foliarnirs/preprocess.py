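"""Spectral preprocessing operators and composable recipes.

Operators fall into two classes.  Per-spectrum transforms (SNV, moving-average
smoothing, endpoint-anchored baseline removal, Savitzky-Golay derivatives) act
row-wise and need no fitting.  Per-wavelength transforms (centering, scaling)
are fitted on the calibration subset only and the fitted statistics are reused
verbatim on validation or prediction data — a :class:`PreprocessRecipe` keeps
that separation explicit.

Smoothing and derivatives never bridge a masked gap: each contiguous retained
wavelength segment is processed independently.  Savitzky-Golay edges where the
full window does not fit are dropped from the retained set, so the recipe's
output wavelength set can be a strict subset of its input.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy.signal import savgol_filter

from .spectra import contiguous_segments

__all__ = [
    "snv",
    "moving_average",
    "sg_derivative",
    "baseline",
    "PreprocessRecipe",
    "default_recipe_grid",
]


def _as_matrix(X):
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        return X[None, :], True
    return X, False


def snv(X) -> np.ndarray:
    """Standard normal variate: standardise each spectrum to mean 0, SD 1.

    Removes per-spectrum multiplicative scatter and additive offsets; the
    sample (n-1) standard deviation is used.
    """
    X, squeeze = _as_matrix(X)
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 retained wavelengths")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        rows = np.nonzero(sd.ravel() == 0)[0]
        raise ValueError(f"SNV undefined for constant spectrum (row {rows[0]})")
    out = (X - mu) / sd
    return out[0] if squeeze else out


def moving_average(X, window: int, segments=None) -> np.ndarray:
    """Centred moving-average smoothing; edges use the truncated window."""
    X, squeeze = _as_matrix(X)
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be an odd integer >= 1")
    segments = segments or [slice(0, X.shape[1])]
    half = window // 2
    out = np.empty_like(X)
    for seg in segments:
        seg_len = seg.stop - seg.start
        if window > seg_len:
            raise ValueError(
                f"window {window} exceeds segment length {seg_len} (cols {seg.start}:{seg.stop})"
            )
        block = X[:, seg]
        csum = np.cumsum(block, axis=1)
        csum = np.concatenate([np.zeros((X.shape[0], 1)), csum], axis=1)
        idx = np.arange(seg_len)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half, seg_len - 1) + 1
        out[:, seg] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out[0] if squeeze else out


def baseline(X, segments=None) -> np.ndarray:
    """Endpoint-anchored linear detrend per contiguous segment.

    Subtracts from each segment the straight line joining its first and last
    points, so segment endpoints map to zero and any constant offset or linear
    tilt is removed.
    """
    X, squeeze = _as_matrix(X)
    segments = segments or [slice(0, X.shape[1])]
    out = np.empty_like(X)
    for seg in segments:
        seg_len = seg.stop - seg.start
        if seg_len < 2:
            raise ValueError("baseline removal needs >= 2 retained wavelengths per segment")
        block = X[:, seg]
        frac = np.linspace(0.0, 1.0, seg_len)
        line = block[:, [0]] + (block[:, [-1]] - block[:, [0]]) * frac
        out[:, seg] = block - line
    return out[0] if squeeze else out


def sg_derivative(X, window: int, polyorder: int, order: int, segments=None):
    """Savitzky-Golay derivative (per-nm scale) over contiguous segments.

    Local least-squares polynomials of degree *polyorder* are fitted in a
    sliding window and differentiated *order* times.  Only interior points
    where the full window fits are kept: the function returns the transformed
    matrix together with a boolean column-keep mask.  Segments shorter than
    the window are dropped entirely (with a warning naming their bounds).
    """
    X, squeeze = _as_matrix(X)
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if polyorder < order:
        raise ValueError("polyorder must be >= derivative order")
    if window <= polyorder:
        raise ValueError("window must exceed polyorder")
    segments = segments or [slice(0, X.shape[1])]
    half = window // 2
    out = np.full_like(X, np.nan)
    keep = np.zeros(X.shape[1], dtype=bool)
    for seg in segments:
        seg_len = seg.stop - seg.start
        if seg_len < window:
            warnings.warn(
                f"segment of {seg_len} wavelengths (cols {seg.start}:{seg.stop}) "
                f"shorter than SG window {window}; segment dropped"
            )
            continue
        filtered = savgol_filter(
            X[:, seg], window_length=window, polyorder=polyorder, deriv=order,
            delta=1.0, axis=1, mode="interp",
        )
        inner = slice(seg.start + half, seg.stop - half)
        out[:, inner] = filtered[:, half:seg_len - half]
        keep[inner] = True
    if not keep.any():
        raise ValueError("no segment long enough for the SG window; nothing retained")
    out = out[:, keep]
    return (out[0] if squeeze else out), keep


# step spec = (name, *args); applied strictly in listed order
_PER_SPECTRUM = {"snv", "moving_average", "baseline", "sg_derivative"}
_FITTED = {"center", "scale"}


class PreprocessRecipe:
    """An ordered list of preprocessing steps with calibration-fitted statistics.

    Parameters
    ----------
    steps
        Sequence of tuples, e.g. ``[("snv",), ("sg_derivative", 11, 2, 1),
        ("center",)]``.  Recognised steps: ``snv``, ``moving_average(window)``,
        ``baseline``, ``sg_derivative(window, polyorder, order)``, ``center``,
        ``scale``.
    """

    def __init__(self, steps):
        steps = [tuple(s) for s in steps]
        for s in steps:
            if s[0] not in _PER_SPECTRUM | _FITTED:
                raise ValueError(f"unknown preprocessing step {s[0]!r}")
        self.steps = steps
        self.mean_ = None
        self.sd_ = None
        self.input_wavelengths_ = None
        self.output_wavelengths_ = None

    # -- per-spectrum stage ------------------------------------------------
    def row_transform(self, X, wavelengths):
        """Apply the per-spectrum (unfitted) steps; returns (X', wavelengths')."""
        X = np.asarray(X, dtype=np.float64)
        wl = np.asarray(wavelengths)
        for step in self.steps:
            name = step[0]
            if name in _FITTED:
                continue
            segs = contiguous_segments(wl)
            if name == "snv":
                X = snv(X)
            elif name == "moving_average":
                X = moving_average(X, step[1], segs)
            elif name == "baseline":
                X = baseline(X, segs)
            elif name == "sg_derivative":
                X, keep = sg_derivative(X, step[1], step[2], step[3], segs)
                wl = wl[keep]
        return X, wl

    # -- fitted stage ------------------------------------------------------
    def fit(self, X_cal, wavelengths):
        """Fit per-wavelength statistics on calibration rows only."""
        self.input_wavelengths_ = np.asarray(wavelengths).copy()
        Xr, wl_out = self.row_transform(X_cal, wavelengths)
        self.output_wavelengths_ = wl_out.copy()
        self.mean_ = Xr.mean(axis=0) if any(s[0] == "center" for s in self.steps) else None
        if any(s[0] == "scale" for s in self.steps):
            sd = Xr.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ValueError("zero-variance wavelength; cannot scale")
            self.sd_ = sd
        else:
            self.sd_ = None
        return self

    def apply_fitted(self, X_row_transformed):
        X = np.asarray(X_row_transformed, dtype=np.float64)
        if self.mean_ is not None:
            X = X - self.mean_
        if self.sd_ is not None:
            X = X / self.sd_
        return X

    def transform(self, X, wavelengths):
        """Row-transform then apply the fitted statistics (fit() must have run)."""
        if self.input_wavelengths_ is None:
            raise RuntimeError("recipe is not fitted; call fit() first")
        wl = np.asarray(wavelengths)
        if not np.array_equal(wl, self.input_wavelengths_):
            raise ValueError("wavelength set does not match the fitted recipe")
        Xr, wl_out = self.row_transform(X, wavelengths)
        return self.apply_fitted(Xr), wl_out

    # -- bookkeeping ---------------------------------------------------------
    def label(self) -> str:
        def fmt(s):
            return s[0] if len(s) == 1 else f"{s[0]}({','.join(map(str, s[1:]))})"
        return "+".join(fmt(s) for s in self.steps) or "raw"

    def to_dict(self) -> dict:
        d = {"steps": [list(s) for s in self.steps]}
        for key, val in (
            ("mean", self.mean_), ("sd", self.sd_),
            ("input_wavelengths", self.input_wavelengths_),
            ("output_wavelengths", self.output_wavelengths_),
        ):
            d[key] = None if val is None else np.asarray(val).tolist()
        return d

    @classmethod
    def from_dict(cls, d) -> "PreprocessRecipe":
        recipe = cls(d["steps"])
        recipe.mean_ = None if d.get("mean") is None else np.asarray(d["mean"], dtype=np.float64)
        recipe.sd_ = None if d.get("sd") is None else np.asarray(d["sd"], dtype=np.float64)
        if d.get("input_wavelengths") is not None:
            recipe.input_wavelengths_ = np.asarray(d["input_wavelengths"])
        if d.get("output_wavelengths") is not None:
            recipe.output_wavelengths_ = np.asarray(d["output_wavelengths"])
        return recipe

    def __repr__(self):
        return f"PreprocessRecipe({self.label()})"


def default_recipe_grid():
    """The default preprocessing search grid.

    The cross of three scatter treatments {none, SNV, baseline}, three
    smoothings {none, MA(5), MA(11)} and three derivative treatments
    {none, SG 1st(11,2), SG 2nd(11,2)}, each followed by per-wavelength
    centering (performed inside the PLS fit).  27 recipes, covering every
    operator family searched during calibration.
    """
    scatter = [(), (("snv",),), (("baseline",),)]
    smooth = [(), (("moving_average", 5),), (("moving_average", 11),)]
    deriv = [(), (("sg_derivative", 11, 2, 1),), (("sg_derivative", 11, 2, 2),)]
    grid = []
    for a, b, c in itertools.product(scatter, smooth, deriv):
        grid.append(PreprocessRecipe(list(a + b + c)))
    return grid
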