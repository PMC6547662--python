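"""Validation statistics and AOAC-style method-precision assessment.

Validation of a calibration is summarised the way chemometric method papers
tabulate it: RMSEP, bias (mean signed prediction error), and the intercept and
slope of the least-squares line of predicted on measured content, with R²
reported as the squared Pearson correlation.  Method precision is the relative
standard deviation (RSD) of replicate measurements, judged against the AOAC
acceptance ceiling RSD_accepted = 2 * C^-0.15 where C is the analyte MASS
FRACTION (content in % dry weight divided by 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelPerformance",
    "PrecisionReport",
    "validation_stats",
    "method_agreement",
    "rsd",
    "rsd_accepted",
    "within_lab_nirs_rsd",
]


@dataclass
class ModelPerformance:
    """Cross-validation and/or external-validation panel for one calibration."""

    constituent: str = ""
    k: int | None = None
    r2_cval: float | None = None
    rmsecv: float | None = None
    r2_val: float | None = None
    rmsep: float | None = None
    bias: float | None = None
    intercept: float | None = None
    slope: float | None = None
    n_cal: int | None = None
    n_val: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([self.to_dict()])


@dataclass
class PrecisionReport:
    """Within-laboratory replicate precision vs the AOAC acceptance ceiling."""

    constituent: str
    content_level: float        # mean content, % dry weight
    rsd_observed: float         # average replicate RSD, %
    rsd_accepted: float         # AOAC ceiling at content_level, %
    n_samples: int
    n_replicates: int
    per_sample_rsd: np.ndarray = field(default=None, repr=False)

    @property
    def passes(self) -> bool:
        return bool(self.rsd_observed <= self.rsd_accepted)


def validation_stats(measured, predicted, constituent: str = "", use_r2_sse: bool = False) -> ModelPerformance:
    """External-validation panel: R², RMSEP, bias, intercept/slope.

    R² defaults to the squared Pearson correlation of predicted vs measured;
    set ``use_r2_sse=True`` for the 1 - SSE/SST variant.
    """
    m = np.asarray(measured, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if m.shape != p.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {p.shape}")
    if m.size < 3:
        raise ValueError("need at least 3 measured/predicted pairs")
    if m.std() == 0:
        raise ValueError("measured values have zero variance")
    err = p - m
    rmsep = float(np.sqrt(np.mean(err**2)))
    bias = float(np.mean(err))
    slope, intercept = np.polyfit(m, p, 1)
    if use_r2_sse:
        r2 = float(1.0 - np.sum(err**2) / np.sum((m - m.mean()) ** 2))
    elif p.std() == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(m, p)[0, 1] ** 2)
    return ModelPerformance(
        constituent=constituent,
        r2_val=r2,
        rmsep=rmsep,
        bias=bias,
        intercept=float(intercept),
        slope=float(slope),
        n_val=m.size,
    )


def method_agreement(values_a, values_b, label: str = "") -> dict:
    """Among-method agreement panel; *values_b* plays the predicted role."""
    perf = validation_stats(values_a, values_b, constituent=label)
    return {
        "r2": perf.r2_val,
        "rmse": perf.rmsep,
        "bias": perf.bias,
        "slope": perf.slope,
        "intercept": perf.intercept,
    }


def rsd(replicate_values) -> float:
    """Relative standard deviation: 100 * sample SD / mean, in percent."""
    v = np.asarray(replicate_values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("RSD needs at least 2 replicates")
    mean = v.mean()
    if mean <= 0:
        raise ValueError(f"RSD undefined for non-positive mean ({mean})")
    return float(100.0 * v.std(ddof=1) / mean)


def rsd_accepted(content: float) -> float:
    """AOAC acceptance ceiling 2 * C^-0.15 (percent), C = mass fraction.

    *content* is in % dry weight; the formula takes the mass fraction
    content/100 (2 * 0.0018^-0.15 = 5.16% at 0.18% P, matching the published
    acceptance tables).
    """
    if not (0.0 < content < 100.0):
        raise ValueError(f"content must be in (0, 100) % dry weight, got {content}")
    return float(2.0 * (content / 100.0) ** (-0.15))


def within_lab_nirs_rsd(model, dataset, min_replicates: int = 2) -> PrecisionReport:
    """Within-laboratory NIRS precision from replicate-scan predictions.

    Each replicate scan is predicted independently (no averaging); the
    per-sample RSD of those predictions is averaged across samples and judged
    against the AOAC ceiling at the dataset's mean content (mean reference
    chemistry when available, otherwise mean prediction).
    """
    wl = dataset.grid
    mask = dataset.records[0].mean_spectrum.mask
    per_rsd = []
    contents = []
    n_rep = []
    for rec in dataset.records:
        if len(rec.replicate_spectra) < min_replicates:
            warnings.warn(f"sample {rec.sample_id!r} has a single scan; excluded from RSD")
            continue
        reps = np.vstack([s.values[mask] for s in rec.replicate_spectra])
        preds = model.predict(reps, wl[mask])
        if preds.mean() <= 0:
            warnings.warn(f"sample {rec.sample_id!r}: non-positive mean prediction; excluded")
            continue
        per_rsd.append(rsd(preds))
        n_rep.append(len(rec.replicate_spectra))
        c = rec.chemistry.get(model.constituent)
        contents.append(c if c is not None else preds.mean())
    if not per_rsd:
        raise ValueError("no sample has enough replicate scans for an RSD")
    level = float(np.mean(contents))
    return PrecisionReport(
        constituent=model.constituent,
        content_level=level,
        rsd_observed=float(np.mean(per_rsd)),
        rsd_accepted=rsd_accepted(level),
        n_samples=len(per_rsd),
        n_replicates=int(round(np.mean(n_rep))),
        per_sample_rsd=np.asarray(per_rsd),
    )
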