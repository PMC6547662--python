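"""Reading and writing spectra datasets as plain CSV.

Two dialects:

* **wide** — one row per sample: ``sample_id, species, functional_group,
  region, phenology, N, P, C`` then one column per wavelength named
  ``wl_<nm>``.  Stores the mean spectrum only (replicate scans are not
  representable in this layout).
* **long** — two files: ``<stem>_spectra.csv`` with columns ``sample_id,
  replicate, wavelength_nm, absorbance`` (every replicate scan) and
  ``<stem>_samples.csv`` with the metadata/chemistry columns above.

Floats are written with full ``repr`` precision, so write -> read round-trips
bit-exactly.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .spectra import CONSTITUENTS, SampleRecord, SpectraDataset, Spectrum

__all__ = ["write_dataset", "read_dataset", "read_uit_deposit_layout"]

_META_COLS = ("species", "functional_group", "region", "phenology")


def _records_meta_frame(dataset: SpectraDataset) -> pd.DataFrame:
    rows = []
    for r in dataset.records:
        row = {"sample_id": r.sample_id}
        for m in _META_COLS:
            row[m] = r.metadata.get(m, "")
        for c in CONSTITUENTS:
            row[c] = r.chemistry.get(c, None)
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(dataset: SpectraDataset, path: str, layout: str = "wide") -> list:
    """Write a dataset; returns the list of files written."""
    if layout == "wide":
        meta = _records_meta_frame(dataset)
        grid = dataset.grid
        spec = pd.DataFrame(
            np.vstack([r.mean_spectrum.values for r in dataset.records]),
            columns=[f"wl_{w}" for w in grid],
        )
        pd.concat([meta, spec], axis=1).to_csv(path, index=False)
        return [path]
    if layout == "long":
        stem, _ = os.path.splitext(path)
        spectra_path, samples_path = f"{stem}_spectra.csv", f"{stem}_samples.csv"
        frames = []
        for r in dataset.records:
            for rep_idx, s in enumerate(r.replicate_spectra, start=1):
                frames.append(pd.DataFrame({
                    "sample_id": r.sample_id,
                    "replicate": rep_idx,
                    "wavelength_nm": s.wavelengths,
                    "absorbance": s.values,
                }))
        pd.concat(frames, ignore_index=True).to_csv(spectra_path, index=False)
        _records_meta_frame(dataset).to_csv(samples_path, index=False)
        return [spectra_path, samples_path]
    raise ValueError(f"unknown layout {layout!r} (expected 'wide' or 'long')")


def _parse_chemistry(row) -> dict:
    chem = {}
    for c in CONSTITUENTS:
        if c in row and pd.notna(row[c]) and row[c] != "":
            chem[c] = float(row[c])
    return chem


def _parse_metadata(row) -> dict:
    return {m: ("" if pd.isna(row.get(m, "")) else str(row.get(m, ""))) for m in _META_COLS}


def read_dataset(path: str, layout: str = "wide", provenance: str = "") -> SpectraDataset:
    """Read a dataset written by :func:`write_dataset`."""
    if layout == "wide":
        df = pd.read_csv(path, float_precision="round_trip")
        wl_cols = [c for c in df.columns if c.startswith("wl_")]
        if not wl_cols:
            raise ValueError(f"{path}: no wavelength columns (expected headers like 'wl_1500')")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"{path}: duplicate sample_ids {dupes}")
        wl = np.array([int(c[3:]) for c in wl_cols], dtype=np.int64)
        order = np.argsort(wl)
        wl = wl[order]
        values = df[wl_cols].to_numpy()
        try:
            values = values.astype(np.float64)[:, order]
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: non-numeric spectral cell ({exc})") from exc
        records = []
        for i, (_, row) in enumerate(df.iterrows()):
            if not np.all(np.isfinite(values[i])):
                col = wl[int(np.nonzero(~np.isfinite(values[i]))[0][0])]
                raise ValueError(f"{path}: non-finite absorbance for sample "
                                 f"{row['sample_id']!r} at wl_{col}")
            records.append(SampleRecord(
                sample_id=str(row["sample_id"]),
                replicate_spectra=[Spectrum(wl, values[i])],
                chemistry=_parse_chemistry(row),
                metadata=_parse_metadata(row),
            ))
        return SpectraDataset(records, provenance=provenance or path)
    if layout == "long":
        stem, _ = os.path.splitext(path)
        spectra = pd.read_csv(f"{stem}_spectra.csv", float_precision="round_trip")
        samples = pd.read_csv(f"{stem}_samples.csv", float_precision="round_trip").set_index("sample_id", drop=False)
        if samples.index.duplicated().any():
            raise ValueError(f"{stem}_samples.csv: duplicate sample_ids")
        records = []
        for sid, per_sample in spectra.groupby("sample_id", sort=False):
            reps = []
            for _, per_rep in per_sample.groupby("replicate", sort=True):
                per_rep = per_rep.sort_values("wavelength_nm")
                reps.append(Spectrum(per_rep["wavelength_nm"].to_numpy(np.int64),
                                     per_rep["absorbance"].to_numpy(np.float64)))
            row = samples.loc[str(sid)] if str(sid) in samples.index else samples.loc[sid]
            records.append(SampleRecord(
                sample_id=str(sid),
                replicate_spectra=reps,
                chemistry=_parse_chemistry(row),
                metadata=_parse_metadata(row),
            ))
        return SpectraDataset(records, provenance=provenance or path)
    raise ValueError(f"unknown layout {layout!r} (expected 'wide' or 'long')")


def read_uit_deposit_layout(path: str, column_map: dict | None = None) -> SpectraDataset:
    """Loader profile for externally deposited foliar NIRS tables.

    Maps a deposited wide table's columns onto this package's field names via
    *column_map* (deposit name -> canonical name); wavelength columns may be
    bare integers or ``X<nm>``/``wl_<nm>``.  The download is optional — nothing
    in the package requires it.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)

    def canon(col: str):
        c = str(col).strip()
        if c.startswith(("wl_", "X")) and c.lstrip("wl_X").isdigit():
            return f"wl_{c.lstrip('wl_X')}"
        if c.isdigit():
            return f"wl_{c}"
        return c

    df = df.rename(columns={c: canon(c) for c in df.columns})
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
        df.to_csv(fh.name, index=False)
        return read_dataset(fh.name, layout="wide", provenance=path)
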