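"""Core data model for near-infrared foliar spectra.

A :class:`Spectrum` holds absorbance values (A = log10(1/R)) on an integer
nanometre wavelength grid together with a boolean retention mask.  Masked
wavelengths are kept in storage but excluded from all downstream mathematics,
so masking is reversible.  A :class:`SampleRecord` bundles the replicate scans
of one foliar sample with its reference chemistry (N, P, C in % dry weight)
and metadata; a :class:`SpectraDataset` is a collection of records sharing one
wavelength grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Spectrum",
    "SampleRecord",
    "SpectraDataset",
    "DEFAULT_EXCLUDED_REGIONS",
    "CONSTITUENTS",
    "absorbance_from_reflectance",
    "resample_to_1nm",
    "mask_excluded_regions",
    "average_replicates",
    "contiguous_segments",
]

#: Wavelength intervals (closed, nm) removed before any modelling: detector
#: overlap regions at 350-380, 760-840, 1700-1800 and 2450-2500 nm, plus the
#: visible region 380-720 nm whose absorption features reflect leaf structure
#: rather than constituent chemistry.
DEFAULT_EXCLUDED_REGIONS: tuple[tuple[int, int], ...] = (
    (350, 380),
    (380, 720),
    (760, 840),
    (1700, 1800),
    (2450, 2500),
)

CONSTITUENTS = ("N", "P", "C")


@dataclass(frozen=True)
class Spectrum:
    """One absorbance spectrum on an integer-nm grid with a retention mask."""

    wavelengths: np.ndarray
    values: np.ndarray
    mask: np.ndarray = None  # True = retained

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=np.int64)
        vals = np.asarray(self.values, dtype=np.float64)
        if wl.ndim != 1 or vals.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        mask = self.mask
        mask = np.ones(wl.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        if mask.shape != wl.shape:
            raise ValueError("mask must match the wavelength grid")
        if not np.all(np.isfinite(vals[mask])):
            raise ValueError("absorbance must be finite at all retained wavelengths")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mask", mask)

    @property
    def retained_wavelengths(self) -> np.ndarray:
        return self.wavelengths[self.mask]

    @property
    def retained_values(self) -> np.ndarray:
        return self.values[self.mask]

    def with_values(self, values: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavelengths, values, self.mask)


@dataclass
class SampleRecord:
    """Replicate scans + mean spectrum + chemistry + metadata for one sample."""

    sample_id: str
    replicate_spectra: list
    chemistry: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    mean_spectrum: Spectrum = None

    def __post_init__(self):
        if not self.replicate_spectra:
            raise ValueError(f"sample {self.sample_id!r}: at least one replicate scan required")
        grids = {tuple(s.wavelengths.tolist()) for s in self.replicate_spectra}
        if len(grids) != 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate scans on different grids")
        for name, value in self.chemistry.items():
            if value is not None and not (0.0 < value < 100.0):
                raise ValueError(
                    f"sample {self.sample_id!r}: {name} content {value} outside (0, 100) % dry weight"
                )
        if self.mean_spectrum is None:
            self.mean_spectrum = average_replicates(self.replicate_spectra)


@dataclass
class SpectraDataset:
    """A set of SampleRecords on one shared wavelength grid."""

    records: list
    provenance: str = ""

    def __post_init__(self):
        if not self.records:
            raise ValueError("dataset must contain at least one record")
        ids = [r.sample_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sample_ids: {sorted(dupes)}")
        grids = {tuple(r.mean_spectrum.wavelengths.tolist()) for r in self.records}
        if len(grids) != 1:
            raise ValueError("all records must share one wavelength grid")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def grid(self) -> np.ndarray:
        return self.records[0].mean_spectrum.wavelengths

    @property
    def sample_ids(self) -> list:
        return [r.sample_id for r in self.records]

    def subset(self, sample_ids) -> "SpectraDataset":
        wanted = set(sample_ids)
        records = [r for r in self.records if r.sample_id in wanted]
        missing = wanted - {r.sample_id for r in records}
        if missing:
            raise KeyError(f"sample_ids not in dataset: {sorted(missing)}")
        return SpectraDataset(records, provenance=self.provenance)

    def with_chemistry(self, constituent: str) -> "SpectraDataset":
        """Records carrying a reference value for *constituent*."""
        records = [r for r in self.records if r.chemistry.get(constituent) is not None]
        if not records:
            raise ValueError(f"no records with {constituent} chemistry")
        return SpectraDataset(records, provenance=self.provenance)

    def chemistry_array(self, constituent: str) -> np.ndarray:
        vals = [r.chemistry.get(constituent) for r in self.records]
        if any(v is None for v in vals):
            raise ValueError(f"some records lack {constituent} chemistry; use with_chemistry() first")
        return np.asarray(vals, dtype=np.float64)

    def absorbance_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """n_samples x n_retained matrix of mean spectra (masked columns dropped)."""
        if mask is None:
            mask = self.records[0].mean_spectrum.mask
        return np.vstack([r.mean_spectrum.values[mask] for r in self.records])

    def apply_mask(self, excluded=DEFAULT_EXCLUDED_REGIONS) -> "SpectraDataset":
        """Return a dataset with the exclusion mask applied to every spectrum."""
        records = []
        for r in self.records:
            reps = [mask_excluded_regions(s, excluded) for s in r.replicate_spectra]
            records.append(
                SampleRecord(
                    sample_id=r.sample_id,
                    replicate_spectra=reps,
                    chemistry=dict(r.chemistry),
                    metadata=dict(r.metadata),
                    mean_spectrum=mask_excluded_regions(r.mean_spectrum, excluded),
                )
            )
        return SpectraDataset(records, provenance=self.provenance)

    def concat(self, other: "SpectraDataset", provenance: str = "") -> "SpectraDataset":
        if not np.array_equal(self.grid, other.grid):
            raise ValueError("datasets must share one wavelength grid to be combined")
        return SpectraDataset(
            list(self.records) + list(other.records),
            provenance=provenance or f"{self.provenance}+{other.provenance}",
        )


def absorbance_from_reflectance(wavelengths, reflectance) -> Spectrum:
    """Convert reflectance fractions R in (0, 1] to absorbance A = log10(1/R)."""
    wl = np.asarray(wavelengths, dtype=np.int64)
    refl = np.asarray(reflectance, dtype=np.float64)
    bad = np.nonzero(~(refl > 0.0))[0]
    if bad.size:
        raise ValueError(
            f"non-positive reflectance at wavelength {int(wl[bad[0]])} nm "
            f"(R={refl[bad[0]]!r}); absorbance log10(1/R) requires R > 0"
        )
    if np.any(refl > 1.0):
        warnings.warn("reflectance above 1.0 encountered; absorbance will be negative")
    return Spectrum(wl, -np.log10(refl))


def resample_to_1nm(native_wavelengths, native_values, grid=None) -> Spectrum:
    """Linearly interpolate native-resolution values onto a 1-nm integer grid.

    Field spectrometers sample every ~1.4 nm below 1050 nm and every 2 nm
    above; downstream modelling assumes consecutive integer nanometres.
    """
    nwl = np.asarray(native_wavelengths, dtype=np.float64)
    nvals = np.asarray(native_values, dtype=np.float64)
    if nwl.ndim != 1 or nvals.shape != nwl.shape:
        raise ValueError("native wavelengths/values must be 1-D and equal length")
    if not np.all(np.diff(nwl) > 0):
        raise ValueError("native wavelengths must be strictly increasing")
    if grid is None:
        grid = np.arange(int(np.ceil(nwl[0])), int(np.floor(nwl[-1])) + 1)
    grid = np.asarray(grid, dtype=np.int64)
    if grid[0] < nwl[0] or grid[-1] > nwl[-1]:
        raise ValueError(
            f"requested grid [{grid[0]}, {grid[-1]}] extends beyond the native "
            f"range [{nwl[0]}, {nwl[-1]}]"
        )
    return Spectrum(grid, np.interp(grid, nwl, nvals))


def mask_excluded_regions(s: Spectrum, excluded=DEFAULT_EXCLUDED_REGIONS) -> Spectrum:
    """Flag wavelengths inside any closed [lo, hi] interval as excluded.

    Idempotent and order-independent; combines with any mask already present.
    """
    mask = s.mask.copy()
    for lo, hi in excluded:
        mask &= ~((s.wavelengths >= lo) & (s.wavelengths <= hi))
    if not mask.any():
        warnings.warn("masking excluded every wavelength; retained set is empty")
    return Spectrum(s.wavelengths, s.values, mask)


def average_replicates(scans) -> Spectrum:
    """Per-wavelength arithmetic mean of replicate scans on identical grids."""
    scans = list(scans)
    if not scans:
        raise ValueError("need at least one scan")
    first = scans[0]
    for s in scans[1:]:
        if not np.array_equal(s.wavelengths, first.wavelengths):
            raise ValueError("replicate scans must share one wavelength grid")
        if not np.array_equal(s.mask, first.mask):
            raise ValueError("replicate scans must share one mask")
    values = np.mean([s.values for s in scans], axis=0)
    return Spectrum(first.wavelengths, values, first.mask)


def contiguous_segments(wavelengths: np.ndarray) -> list:
    """Index slices of runs of consecutive integer nanometres.

    Derivative and smoothing filters must never bridge a masked gap, so all
    per-spectrum operators work segment by segment.
    """
    wl = np.asarray(wavelengths)
    if wl.size == 0:
        return []
    breaks = np.nonzero(np.diff(wl) != 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [wl.size]))
    return [slice(int(a), int(b)) for a, b in zip(starts, stops)]
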