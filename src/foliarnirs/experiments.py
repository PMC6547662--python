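"""Simulation experiments mirroring the study designs a calibration must survive.

These drivers run the full pipeline on the synthetic generator and measure:

* **parameter recovery** — can calibrate() recover constituent contents from
  spectra at the generator's default noise, and perfectly when noise is off?
* **transfer contrast** — with a region batch effect, cross-region prediction
  degrades relative to in-region validation, while a combined two-region
  calibration recovers per-region performance;
* **precision recovery** — the within-laboratory NIRS RSD computed from
  replicate-scan predictions matches a Monte-Carlo estimate implied by the
  generator's scan-noise parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .calibration import ExperimentConfig, calibrate, combine_and_calibrate
from .metrics import validation_stats, within_lab_nirs_rsd
from .pls import fit_pls
from .preprocess import PreprocessRecipe
from .selection import kennard_stone, n_calibration
from .simulate import GeneratorParams, generate_dataset, generate_two_region_dataset, render_spectrum
from .spectra import DEFAULT_EXCLUDED_REGIONS

__all__ = [
    "parameter_recovery",
    "noise_sweep",
    "transfer_contrast",
    "precision_recovery",
]

_SUBSEED_CAP = 2**31 - 1


def _subseed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % _SUBSEED_CAP)


def parameter_recovery(seed: int, n_per_region: int = 300, constituent: str = "N",
                       noise_scale: float = 1.0, config: ExperimentConfig | None = None) -> dict:
    """Calibrate region A of the default two-region study and report R²val/RMSEP."""
    regions = generate_two_region_dataset(
        _subseed(seed, 1), n_per_region=n_per_region,
        base_params=GeneratorParams().with_noise_scale(noise_scale),
    )
    dataset, _ = regions["A"]
    res = calibrate(dataset, config=config, constituent=constituent)
    return {
        "r2_val": res.performance.r2_val,
        "rmsep": res.performance.rmsep,
        "k": res.model.k,
        "recipe": res.model.recipe.label(),
        "n": len(dataset),
    }


def noise_sweep(seed: int, scan_noise_levels=(0.004, 0.04, 0.2),
                n_samples: int = 300, constituent: str = "N",
                config: ExperimentConfig | None = None) -> list:
    """External R²val at increasing replicate-scan noise (same seed throughout)."""
    out = []
    for sd in scan_noise_levels:
        params = replace(GeneratorParams(), n_samples=n_samples).with_scan_noise(sd)
        dataset, _ = generate_dataset(params, _subseed(seed, 2))
        res = calibrate(dataset, config=config, constituent=constituent)
        out.append({"scan_noise_sd": sd, "r2_val": res.performance.r2_val,
                    "rmsep": res.performance.rmsep})
    return out


def transfer_contrast(seed: int, n_per_region: int = 300, constituent: str = "N",
                      offset_scale: float = 0.02,
                      config: ExperimentConfig | None = None) -> dict:
    """Region-specific vs cross-region vs combined two-region calibration.

    Returns in-region validation panels for each region, cross-region transfer
    panels, and the combined model's per-region validation panels (computed on
    the combined model's own external-validation subset, split by region).
    """
    regions = generate_two_region_dataset(_subseed(seed, 3), n_per_region=n_per_region,
                                          offset_scale=offset_scale)
    ds_a, _ = regions["A"]
    ds_b, _ = regions["B"]
    res_a = calibrate(ds_a, config=config, constituent=constituent)
    res_b = calibrate(ds_b, config=config, constituent=constituent)
    cross_ab = res_a.transfer(ds_b)   # model A predicting region B samples
    cross_ba = res_b.transfer(ds_a)
    combined = combine_and_calibrate(ds_a, ds_b, config=config, constituent=constituent)

    val = combined.dataset.subset(combined.split.validation_ids)
    per_region = {}
    for name in ("A", "B"):
        recs = [r for r in val.records if r.metadata.get("region") == name]
        if len(recs) >= 3:
            sub = val.subset([r.sample_id for r in recs])
            table = combined.predict(sub)
            per_region[name] = validation_stats(
                table["measured"].to_numpy(np.float64),
                table["predicted"].to_numpy(np.float64), constituent=constituent)
        else:
            per_region[name] = None
    return {
        "in_region": {"A": res_a.performance, "B": res_b.performance},
        "cross_region": {"A->B": cross_ab, "B->A": cross_ba},
        "combined": combined.performance,
        "combined_per_region": per_region,
    }


def precision_recovery(seed: int, n_samples: int = 200, constituent: str = "N",
                       n_mc_replicates: int = 30) -> dict:
    """Observed vs noise-implied within-lab NIRS RSD on replicate-scan predictions.

    A single fixed-recipe PLS calibration is fitted on the sample mean spectra;
    the observed RSD averages per-sample RSDs over the dataset's own replicate
    scans, while the implied RSD is a Monte-Carlo estimate using fresh scans
    drawn from the generator at the same scan-noise parameter.
    """
    params = replace(GeneratorParams(), n_samples=n_samples)
    dataset, _ = generate_dataset(params, _subseed(seed, 4))
    masked = dataset.apply_mask(DEFAULT_EXCLUDED_REGIONS)
    mask = masked.records[0].mean_spectrum.mask
    wl = masked.grid[mask]
    X = masked.absorbance_matrix(mask)
    y = masked.chemistry_array(constituent)

    recipe = PreprocessRecipe([("snv",), ("center",)])
    split = kennard_stone(recipe.row_transform(X, wl)[0], n_calibration(len(y)))
    cal = split.calibration_indices
    recipe.fit(X[cal], wl)
    Xc, _ = recipe.transform(X[cal], wl)
    model = fit_pls(Xc, y[cal], k=min(10, cal.size // 3), constituent=constituent, recipe=recipe)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        observed = within_lab_nirs_rsd(model, masked)

        # Monte-Carlo noise-implied RSD: fresh replicate scans at the generator's
        # scan-noise parameter, predicted through the identical pipeline
        rng = np.random.default_rng(_subseed(seed, 5))
        mc_params = replace(params, n_replicates=n_mc_replicates)
        per_rsd = []
        for rec in dataset.records:
            record, _, _ = render_spectrum(rec.chemistry, mc_params, rng, sample_id=rec.sample_id)
            reps = np.vstack([s.values[mask] for s in record.replicate_spectra])
            preds = model.predict(reps, wl)
            if preds.mean() > 0:
                per_rsd.append(100.0 * preds.std(ddof=1) / preds.mean())
        implied = float(np.mean(per_rsd))
    return {
        "rsd_observed": observed.rsd_observed,
        "rsd_implied": implied,
        "ratio": observed.rsd_observed / implied,
        "rsd_accepted": observed.rsd_accepted,
        "content_level": observed.content_level,
        "n": observed.n_samples,
    }
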