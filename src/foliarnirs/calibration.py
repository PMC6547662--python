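"""The calibration workflow: model and results objects plus experiment drivers.

:class:`NirsCalibration` is built from a :class:`~foliarnirs.spectra.SpectraDataset`
and an :class:`ExperimentConfig`; :meth:`NirsCalibration.fit` runs the whole
procedure — wavelength masking, a grid search over preprocessing recipes with,
per recipe, Mahalanobis outlier screening, a Kennard-Stone 85:15
calibration/validation split, ten-fold cross-validated NIPALS PLS and
parsimonious component selection — then refits the winning recipe/k on the
calibration subset and evaluates it once on the held-out validation subset.
The returned :class:`NirsCalibrationResults` carries the fitted
:class:`~foliarnirs.pls.PlsModel`, the per-recipe search table, the split,
the outlier report, the performance panel, and a ``summary()`` table.

Recipe and component selection use cross-validated RMSECV only; the external
validation subset is never touched by any fitting or selection step, and that
is asserted structurally on every run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .metrics import ModelPerformance, validation_stats
from .pls import CvCurve, PlsModel, cross_validate, fit_pls, select_components
from .preprocess import PreprocessRecipe, default_recipe_grid
from .selection import OutlierReport, SplitResult, kennard_stone, mahalanobis_outliers, n_calibration
from .spectra import DEFAULT_EXCLUDED_REGIONS, SpectraDataset

__all__ = [
    "ExperimentConfig",
    "NirsCalibration",
    "NirsCalibrationResults",
    "calibrate",
    "transfer_predict",
    "combine_and_calibrate",
    "assess_new_samples",
]

logger = logging.getLogger("foliarnirs")


@dataclass(frozen=True)
class ExperimentConfig:
    """Every tunable of the calibration workflow, with recorded defaults."""

    constituent: str = "N"
    excluded_regions: tuple = DEFAULT_EXCLUDED_REGIONS
    recipes: tuple | None = None          # None -> default 27-recipe grid
    split_ratio: float = 0.85
    outlier_alpha: float = 0.01
    outlier_components: int | None = None  # None -> >=99% explained variance (capped)
    cv_folds: int = 10
    cv_seed: int = 20190604
    k_max: int | None = None               # None -> min(25, n_cal // 3)
    parsimony_tolerance: float = 0.02
    min_samples: int = 30

    def recipe_grid(self):
        return list(self.recipes) if self.recipes is not None else default_recipe_grid()

    def to_dict(self) -> dict:
        d = {
            "constituent": self.constituent,
            "excluded_regions": [list(r) for r in self.excluded_regions],
            "recipes": None if self.recipes is None else [list(r.steps) for r in self.recipes],
            "split_ratio": self.split_ratio,
            "outlier_alpha": self.outlier_alpha,
            "outlier_components": self.outlier_components,
            "cv_folds": self.cv_folds,
            "cv_seed": self.cv_seed,
            "k_max": self.k_max,
            "parsimony_tolerance": self.parsimony_tolerance,
            "min_samples": self.min_samples,
        }
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("excluded_regions") is not None:
            d["excluded_regions"] = tuple(tuple(r) for r in d["excluded_regions"])
        if d.get("recipes") is not None:
            d["recipes"] = tuple(PreprocessRecipe(steps) for steps in d["recipes"])
        return cls(**d)


@dataclass
class _RecipeSearchRow:
    recipe: PreprocessRecipe
    curve: CvCurve
    k: int
    rmsecv: float
    r2_cval: float
    outliers: OutlierReport
    split: SplitResult
    kept_ids: list


class NirsCalibrationResults:
    """Results of one fitted NIRS calibration (returned by NirsCalibration.fit)."""

    def __init__(self, model, config, performance, split, outliers, recipe_table,
                 curve, dataset, config_hash, audit):
        self.model: PlsModel = model
        self.config: ExperimentConfig = config
        self.performance: ModelPerformance = performance
        self.split: SplitResult = split
        self.outliers: OutlierReport = outliers
        self.recipe_table: pd.DataFrame = recipe_table
        self.cv_curve: CvCurve = curve
        self.dataset: SpectraDataset = dataset
        self.config_hash: str = config_hash
        self.audit: dict = audit

    # -- prediction ----------------------------------------------------------
    def _matrix_for(self, dataset: SpectraDataset) -> np.ndarray:
        grid = dataset.grid
        wl_in = self.model.recipe.input_wavelengths_
        idx = np.searchsorted(grid, wl_in)
        if np.any(idx >= grid.size) or not np.array_equal(grid[idx], wl_in):
            raise ValueError("foreign dataset grid does not cover the model's wavelength set")
        X = np.vstack([r.mean_spectrum.values[idx] for r in dataset.records])
        return X

    def predict(self, dataset: SpectraDataset) -> pd.DataFrame:
        """Predict contents for every record; returns sample_id/predicted (+measured)."""
        X = self._matrix_for(dataset)
        pred = self.model.predict(X, self.model.recipe.input_wavelengths_)
        measured = [r.chemistry.get(self.model.constituent) for r in dataset.records]
        return pd.DataFrame({
            "sample_id": dataset.sample_ids,
            "measured": measured,
            "predicted": pred,
            "residual": [p - m if m is not None else None for p, m in zip(pred, measured)],
        })

    def transfer(self, foreign: SpectraDataset) -> ModelPerformance:
        """Predict a foreign sample population and return the validation panel."""
        foreign = foreign.with_chemistry(self.model.constituent)
        table = self.predict(foreign)
        perf = validation_stats(table["measured"].to_numpy(np.float64),
                                table["predicted"].to_numpy(np.float64),
                                constituent=self.model.constituent)
        perf.k = self.model.k
        return perf

    # -- presentation ----------------------------------------------------------
    def summary(self) -> str:
        p = self.performance
        lines = [
            "NIRS calibration results",
            "=" * 60,
            f"constituent:        {self.model.constituent} (% dry weight)",
            f"dataset:            {self.dataset.provenance or '<unnamed>'}"
            f"  (n={len(self.dataset)})",
            f"config hash:        {self.config_hash}",
            f"recipe:             {self.model.recipe.label()}",
            f"latent variables k: {self.model.k}",
            f"outliers removed:   {len(self.outliers.flagged_indices)}"
            f" (Mahalanobis > {self.outliers.threshold:.2f},"
            f" {self.outliers.n_components} PCs, alpha={self.outliers.alpha})",
            f"split:              {p.n_cal} calibration / {p.n_val} validation"
            f" (Kennard-Stone, ratio {self.config.split_ratio})",
            "-" * 60,
            "Cross-validation      External validation",
            f"  R2cval  = {p.r2_cval:7.4f}     R2val     = {p.r2_val:8.4f}",
            f"  RMSECV  = {p.rmsecv:7.4f}     RMSEP     = {p.rmsep:8.4f}",
            f"                        Bias      = {p.bias:8.4f}",
            f"                        Intercept = {p.intercept:8.4f}",
            f"                        Slope     = {p.slope:8.4f}",
            "=" * 60,
        ]
        return "\n".join(lines)

    def performance_frame(self) -> pd.DataFrame:
        return self.performance.to_frame()

    def plot_predictions(self, ax=None):
        """Measured-vs-predicted scatter for the external validation subset."""
        from .plotting import plot_measured_vs_predicted

        val = self.dataset.subset(self.split.validation_ids)
        table = self.predict(val)
        return plot_measured_vs_predicted(
            table["measured"], table["predicted"],
            label=f"{self.model.constituent} external validation", ax=ax,
        )

    def save_model(self, path):
        self.model.save(path)


class NirsCalibration:
    """A NIRS calibration model specification: dataset + constituent + config.

    Examples
    --------
    >>> model = NirsCalibration(dataset, constituent="N")
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, dataset: SpectraDataset, constituent: str | None = None,
                 config: ExperimentConfig | None = None):
        self.config = config or ExperimentConfig()
        if constituent is not None:
            self.config = replace(self.config, constituent=constituent)
        self.constituent = self.config.constituent
        data = dataset.with_chemistry(self.constituent)
        if len(data) < self.config.min_samples:
            raise ValueError(
                f"need >= {self.config.min_samples} samples with {self.constituent} "
                f"chemistry, got {len(data)}"
            )
        self.dataset = data.apply_mask(self.config.excluded_regions)

    # -- the workflow --------------------------------------------------------
    def fit(self) -> NirsCalibrationResults:
        cfg = self.config
        data = self.dataset
        mask = data.records[0].mean_spectrum.mask
        wl = data.grid[mask]
        X_all = data.absorbance_matrix(mask)
        y_all = data.chemistry_array(self.constituent)
        ids = np.asarray(data.sample_ids)
        cfg_hash = cfg.hash()
        logger.info("calibrate %s: n=%d, %d retained wavelengths, config=%s",
                    self.constituent, len(data), wl.size, cfg_hash)

        rows = []
        for recipe in cfg.recipe_grid():
            rows.append(self._search_one_recipe(recipe, X_all, y_all, wl, ids))

        best = min(rows, key=lambda r: (r.rmsecv, r.k))  # grid order breaks residual ties
        table = pd.DataFrame({
            "recipe": [r.recipe.label() for r in rows],
            "k": [r.k for r in rows],
            "rmsecv": [r.rmsecv for r in rows],
            "r2_cval": [r.r2_cval for r in rows],
            "n_outliers": [len(r.outliers.flagged_indices) for r in rows],
        })
        logger.info("winning recipe %s (k=%d, RMSECV=%.4f)", best.recipe.label(), best.k, best.rmsecv)

        # final fit on the winner's calibration subset, single external evaluation
        kept = data.subset(best.kept_ids)
        cal_ids = [best.kept_ids[i] for i in best.split.calibration_indices]
        val_ids = [best.kept_ids[i] for i in best.split.validation_indices]
        X_kept = kept.absorbance_matrix(mask)
        y_kept = kept.chemistry_array(self.constituent)
        # subset() preserves input order, so split indices index kept rows directly
        assert kept.sample_ids == list(best.kept_ids)
        cal_rows = best.split.calibration_indices
        val_rows = best.split.validation_indices

        recipe = PreprocessRecipe(best.recipe.steps)
        recipe.fit(X_kept[cal_rows], wl)
        Xc, _ = recipe.transform(X_kept[cal_rows], wl)
        model = fit_pls(Xc, y_kept[cal_rows], best.k, constituent=self.constituent,
                        recipe=recipe, training_ids=list(cal_ids), seed=cfg.cv_seed)

        Xv, _ = recipe.transform(X_kept[val_rows], wl)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # extrapolation warnings are expected here
            pred_val = model.predict_matrix(Xv)
        perf = validation_stats(y_kept[val_rows], pred_val, constituent=self.constituent)
        k_idx = int(np.searchsorted(best.curve.ks, best.k))
        perf.k = best.k
        perf.rmsecv = float(best.curve.rmsecv[k_idx])
        perf.r2_cval = float(best.curve.r2_cval[k_idx])
        perf.n_cal = len(cal_ids)
        perf.n_val = len(val_ids)

        audit = self._audit(cal_ids, val_ids, model)
        split = SplitResult(
            calibration_indices=best.split.calibration_indices,
            validation_indices=best.split.validation_indices,
            selection_order=best.split.selection_order,
            ratio=cfg.split_ratio,
            sample_ids=best.kept_ids,
        )
        return NirsCalibrationResults(
            model=model, config=cfg, performance=perf, split=split,
            outliers=best.outliers, recipe_table=table, curve=best.curve,
            dataset=data, config_hash=cfg_hash, audit=audit,
        )

    def _search_one_recipe(self, recipe, X_all, y_all, wl, ids) -> _RecipeSearchRow:
        cfg = self.config
        Xr, wl_out = recipe.row_transform(X_all, wl)
        # outlier screening precedes splitting: extreme spectra would otherwise
        # be guaranteed Kennard-Stone calibration members
        outliers = mahalanobis_outliers(
            Xr, n_components=cfg.outlier_components, alpha=cfg.outlier_alpha, sample_ids=list(ids),
        )
        keep = np.setdiff1d(np.arange(len(ids)), outliers.flagged_indices)
        if keep.size < cfg.min_samples:
            raise ValueError(
                f"recipe {recipe.label()}: only {keep.size} samples remain after "
                f"outlier screening (need {cfg.min_samples})"
            )
        kept_ids = [ids[i] for i in keep]
        n_cal = n_calibration(keep.size, cfg.split_ratio)
        split = kennard_stone(Xr[keep], n_cal, sample_ids=kept_ids, ratio=cfg.split_ratio)
        cal = keep[split.calibration_indices]
        k_max = cfg.k_max if cfg.k_max is not None else min(25, max(1, cal.size // 3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = cross_validate(
                Xr[cal], y_all[cal], k_max=k_max, folds=cfg.cv_folds, seed=cfg.cv_seed,
                scale=any(s[0] == "scale" for s in recipe.steps),
            )
        k = select_components(curve, cfg.parsimony_tolerance)
        k_idx = int(np.searchsorted(curve.ks, k))
        return _RecipeSearchRow(
            recipe=recipe, curve=curve, k=k,
            rmsecv=float(curve.rmsecv[k_idx]), r2_cval=float(curve.r2_cval[k_idx]),
            outliers=outliers, split=split, kept_ids=kept_ids,
        )

    @staticmethod
    def _audit(cal_ids, val_ids, model) -> dict:
        """Structural no-leakage audit, asserted on every run."""
        cal, val = set(cal_ids), set(val_ids)
        assert not (cal & val), "calibration and validation subsets overlap"
        assert set(model.training_ids) == cal, "model trained on ids outside the calibration subset"
        assert not (set(model.training_ids) & val), "validation ids leaked into training"
        return {
            "calibration_ids": sorted(cal),
            "validation_ids": sorted(val),
            "disjoint": True,
        }


# -- module-level workflow operations ----------------------------------------

def calibrate(dataset: SpectraDataset, config: ExperimentConfig | None = None,
              constituent: str | None = None) -> NirsCalibrationResults:
    """Run the full calibration workflow on one dataset."""
    return NirsCalibration(dataset, constituent=constituent, config=config).fit()


def transfer_predict(result: NirsCalibrationResults, foreign: SpectraDataset) -> ModelPerformance:
    """Apply a fitted calibration to a foreign sample population."""
    return result.transfer(foreign)


def combine_and_calibrate(*datasets: SpectraDataset, config: ExperimentConfig | None = None,
                          constituent: str | None = None) -> NirsCalibrationResults:
    """Concatenate datasets (unique ids enforced) and calibrate the pool."""
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to combine")
    combined = datasets[0]
    for d in datasets[1:]:
        combined = combined.concat(d)
    combined.provenance = "+".join(d.provenance or "?" for d in datasets)
    return calibrate(combined, config=config, constituent=constituent)


def assess_new_samples(result: NirsCalibrationResults, new_dataset: SpectraDataset,
                       expand: bool = False):
    """Evaluate a calibration on a new sample type; optionally re-calibrate.

    Returns the prediction panel for the new samples, and with ``expand=True``
    also the re-calibrated results after appending the new samples to the
    original dataset.
    """
    perf = result.transfer(new_dataset)
    if not expand:
        return perf
    expanded = result.dataset.concat(new_dataset.with_chemistry(result.model.constituent))
    new_result = calibrate(expanded, config=result.config)
    return perf, new_result
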