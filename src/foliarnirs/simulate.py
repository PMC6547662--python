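"""Synthetic foliar NIR spectra with known ground truth.

The generator emulates the statistical structure a foliar NIRS calibration
assumes: per-sample constituent contents (N, P, C in % dry weight) drawn from
truncated log-normal distributions per plant functional group; a noiseless
absorbance core that is exactly linear in the contents (Beer-Lambert-style
additive Gaussian absorption bands on a smooth baseline); per-sample
multiplicative/additive scatter (alpha, beta); iid per-wavelength scan noise
for each replicate scan; and region-level batch effects (a spectral offset
plus a content-distribution shift) for calibration-transfer experiments.

The band centres are physically flavoured placements in N-H / C-H overtone
and combination regions; they are test fixtures, not spectroscopic claims.
Because the noiseless core is exactly linear in the contents, the generator is
the pipeline's recoverability oracle: with noise off, PLS must recover the
contents essentially perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import SampleRecord, SpectraDataset, Spectrum

__all__ = [
    "Band",
    "FunctionalGroupProfile",
    "RegionEffect",
    "GeneratorParams",
    "draw_contents",
    "render_spectrum",
    "generate_dataset",
    "generate_two_region_dataset",
    "generate_new_types",
    "ground_truth_frame",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: A(lambda) = amplitude_per_unit * content * g."""

    center_nm: float
    width_nm: float
    amplitude: float  # absorbance per % dry weight of the constituent

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((wavelengths - self.center_nm) ** 2) / (2.0 * self.width_nm**2))


@dataclass(frozen=True)
class FunctionalGroupProfile:
    name: str
    weight: float               # sampling proportion
    means: dict                 # constituent -> mean content (% dry weight)
    sigmas: dict                # constituent -> log-scale SD of the log-normal


@dataclass(frozen=True)
class RegionEffect:
    """Batch effect of one biogeographic region.

    ``offset_scale`` scales a smooth spectral offset (a Gaussian bump centred
    on the N-band region plus a broad tilt) added to every spectrum;
    ``content_shift`` multiplies the group mean contents per constituent.
    """

    name: str
    offset_scale: float = 0.0
    content_shift: dict = field(default_factory=dict)

    def offset(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=np.float64)
        bump = np.exp(-((wl - 2055.0) ** 2) / (2.0 * 80.0**2))
        tilt = 0.25 * (wl - 1400.0) / 1100.0
        return self.offset_scale * (bump + tilt)


#: Contents spanning the ranges observed across arctic-alpine functional
#: groups: overall N 0.34-6.01, P 0.04-0.70, C 32.56-56.22 % dry weight, with
#: 2-3-fold differences in group mean N and P and more uniform C.
DEFAULT_GROUPS = (
    FunctionalGroupProfile("forb", 0.35, {"N": 2.90, "P": 0.26, "C": 45.0},
                           {"N": 0.35, "P": 0.40, "C": 0.035}),
    FunctionalGroupProfile("grass", 0.25, {"N": 2.00, "P": 0.17, "C": 45.5},
                           {"N": 0.30, "P": 0.35, "C": 0.020}),
    FunctionalGroupProfile("deciduous_shrub", 0.25, {"N": 2.20, "P": 0.22, "C": 48.5},
                           {"N": 0.30, "P": 0.35, "C": 0.025}),
    FunctionalGroupProfile("evergreen_shrub", 0.15, {"N": 1.10, "P": 0.09, "C": 51.0},
                           {"N": 0.25, "P": 0.30, "C": 0.020}),
)

#: Band library (centres inside the retained windows): protein N-H combination
#: bands for N, weak P-linked bands, broad C-H bands for C.
DEFAULT_BANDS = {
    "N": (Band(1510.0, 25.0, 0.012), Band(2055.0, 30.0, 0.015), Band(2180.0, 35.0, 0.012)),
    "P": (Band(990.0, 25.0, 0.10), Band(2260.0, 35.0, 0.08)),
    "C": (Band(1690.0, 50.0, 0.0030), Band(2100.0, 60.0, 0.0035), Band(2310.0, 45.0, 0.0030)),
}

DEFAULT_RANGES = {"N": (0.34, 6.01), "P": (0.04, 0.70), "C": (32.56, 56.22)}


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic foliar-spectra generator."""

    n_samples: int = 300
    groups: tuple = DEFAULT_GROUPS
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    baseline_coefficients: tuple = (0.30, 8.0e-5, -2.0e-8)  # a + b*(wl-350) + c*(wl-1400)^2
    alpha_sigma: float = 0.03     # log-SD of per-sample multiplicative scatter
    beta_sigma: float = 0.01      # SD of per-sample additive offset (absorbance)
    scan_noise_sd: float = 0.004  # iid per-wavelength noise SD per replicate scan
    n_replicates: int = 3
    region: RegionEffect = RegionEffect("A")
    wavelengths: tuple = (350, 2500)
    phenology_stages: tuple = ("early", "mid", "late")

    def grid(self) -> np.ndarray:
        return np.arange(self.wavelengths[0], self.wavelengths[1] + 1)

    def baseline(self, wl: np.ndarray) -> np.ndarray:
        a, b, c = self.baseline_coefficients
        return a + b * (wl - 350.0) + c * (wl - 1400.0) ** 2

    def with_noise_scale(self, scale: float) -> "GeneratorParams":
        """Scale every stochastic spectral perturbation (scatter + scan noise)."""
        return replace(
            self,
            alpha_sigma=self.alpha_sigma * scale,
            beta_sigma=self.beta_sigma * scale,
            scan_noise_sd=self.scan_noise_sd * scale,
        )

    def with_scan_noise(self, scan_noise_sd: float) -> "GeneratorParams":
        return replace(self, scan_noise_sd=scan_noise_sd)


def _truncated_lognormal(rng, mean, sigma, lo, hi, size):
    """Log-normal with arithmetic mean *mean*, truncated to [lo, hi] by rejection."""
    if sigma == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    mu = np.log(mean) - 0.5 * sigma**2
    out = np.empty(size)
    todo = np.arange(size)
    for _ in range(1000):
        draw = rng.lognormal(mu, sigma, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
        if todo.size == 0:
            return out
    raise RuntimeError("truncated log-normal rejection sampling did not converge")


def draw_contents(params: GeneratorParams, seed: int) -> pd.DataFrame:
    """Draw per-sample constituent contents and metadata.

    Contents come from truncated log-normals (right-skewed, as trait data
    usually are) within the configured overall ranges; each sample gets a
    functional-group label, a synthetic species label, a phenology stage and
    the region name.
    """
    rng = np.random.default_rng(seed)
    weights = np.array([g.weight for g in params.groups], dtype=np.float64)
    weights /= weights.sum()
    g_idx = rng.choice(len(params.groups), size=params.n_samples, p=weights)
    rows = []
    for i in range(params.n_samples):
        g = params.groups[g_idx[i]]
        rows.append({"functional_group": g.name})
    df = pd.DataFrame(rows)
    for const, (lo, hi) in params.ranges.items():
        vals = np.empty(params.n_samples)
        for gi, g in enumerate(params.groups):
            sel = np.nonzero(g_idx == gi)[0]
            if sel.size == 0:
                continue
            mean = g.means[const] * params.region.content_shift.get(const, 1.0)
            mean = float(np.clip(mean, lo, hi))
            vals[sel] = _truncated_lognormal(rng, mean, g.sigmas[const], lo, hi, sel.size)
        df[const] = vals
    df["species"] = [f"sp{rng.integers(1, 25):02d}_{g}" for g in df["functional_group"]]
    df["phenology"] = rng.choice(params.phenology_stages, size=params.n_samples)
    df["region"] = params.region.name
    return df


def noiseless_spectrum(contents: dict, params: GeneratorParams) -> np.ndarray:
    """The deterministic absorbance core A0, exactly linear in the contents."""
    wl = params.grid().astype(np.float64)
    a0 = params.baseline(wl) + params.region.offset(wl)
    for const, bands in params.bands.items():
        c = contents.get(const, 0.0)
        for band in bands:
            a0 = a0 + c * band.profile(wl)
    return a0


def render_spectrum(contents: dict, params: GeneratorParams, rng, sample_id: str = "s0",
                    metadata: dict | None = None):
    """Render one SampleRecord with replicate scans; returns (record, alpha, beta).

    Each replicate scan is alpha*A0 + beta + eps with eps iid N(0, scan_sd);
    alpha and beta are drawn once per sample (scatter is a property of the
    pressed tablet, noise of the individual scan).
    """
    if any(v < 0 for v in contents.values()):
        raise ValueError("contents must be non-negative")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    wl = params.grid()
    a0 = noiseless_spectrum(contents, params)
    alpha = float(rng.lognormal(0.0, params.alpha_sigma)) if params.alpha_sigma > 0 else 1.0
    beta = float(rng.normal(0.0, params.beta_sigma)) if params.beta_sigma > 0 else 0.0
    reps = []
    for _ in range(params.n_replicates):
        eps = rng.normal(0.0, params.scan_noise_sd, wl.size) if params.scan_noise_sd > 0 else 0.0
        reps.append(Spectrum(wl, alpha * a0 + beta + eps))
    record = SampleRecord(
        sample_id=sample_id,
        replicate_spectra=reps,
        chemistry={k: float(v) for k, v in contents.items() if v > 0},
        metadata=dict(metadata or {}),
    )
    return record, alpha, beta


def generate_dataset(params: GeneratorParams, seed: int, id_prefix: str = ""):
    """Generate a full SpectraDataset plus its ground-truth table.

    Returns ``(dataset, truth)`` where *truth* holds the true contents and the
    per-sample scatter parameters (alpha, beta) for oracle tests.  Seeded and
    bit-reproducible (numpy Generator/PCG64 discipline).
    """
    contents = draw_contents(params, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    prefix = id_prefix or f"{params.region.name}_"
    records, truth_rows = [], []
    for i, row in contents.iterrows():
        sid = f"{prefix}{i:04d}"
        cdict = {c: row[c] for c in params.ranges}
        meta = {k: row[k] for k in ("species", "functional_group", "region", "phenology")}
        rec, alpha, beta = render_spectrum(cdict, params, rng, sample_id=sid, metadata=meta)
        records.append(rec)
        truth_rows.append({"sample_id": sid, **{f"true_{c}": row[c] for c in params.ranges},
                           "alpha": alpha, "beta": beta})
    dataset = SpectraDataset(records, provenance=f"synthetic:{params.region.name}:seed={seed}")
    return dataset, pd.DataFrame(truth_rows)


def generate_two_region_dataset(seed: int, n_per_region: int = 300,
                                offset_scale: float = 0.02,
                                n_shift: float = 0.9,
                                base_params: GeneratorParams | None = None):
    """Default two-region study: region A plain, region B batch-shifted.

    Region B adds a spectral offset (scaled Gaussian bump on the N-band region
    plus a broad tilt) and shifts the N content distribution, mimicking a
    second biogeographic region measured as a separate batch.  Returns
    ``{"A": (dataset, truth), "B": (dataset, truth)}``.
    """
    base = base_params or GeneratorParams()
    params_a = replace(base, n_samples=n_per_region, region=RegionEffect("A"))
    params_b = replace(
        base, n_samples=n_per_region,
        region=RegionEffect("B", offset_scale=offset_scale, content_shift={"N": n_shift}),
    )
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31 - 1)
    return {
        "A": generate_dataset(params_a, int(ss[0])),
        "B": generate_dataset(params_b, int(ss[1])),
    }


def generate_new_types(params: GeneratorParams, seed: int, kind: str = "senescent",
                       band_perturbation: float = 0.2):
    """Analogues of new sample types outside the calibration population.

    ``senescent``: N and P confined to the bottom decile of the configured
    ranges (C unchanged) — a new phenological stage with low, narrow contents.
    ``moss``: the same low contents plus a perturbed band library (centres
    shifted, amplitudes damped by *band_perturbation*) — an out-of-family
    functional group.  With ``band_perturbation=0`` the moss generator is
    statistically identical to the senescent one.
    """
    if kind not in ("senescent", "moss"):
        raise ValueError("kind must be 'senescent' or 'moss'")
    ranges = dict(params.ranges)
    for const in ("N", "P"):
        lo, hi = ranges[const]
        ranges[const] = (lo, lo + 0.1 * (hi - lo))
    groups = tuple(
        replace(g, means={**g.means,
                          "N": min(max(g.means["N"] * 0.3, ranges["N"][0] * 1.2), ranges["N"][1]),
                          "P": min(max(g.means["P"] * 0.3, ranges["P"][0] * 1.2), ranges["P"][1])})
        for g in params.groups
    )
    new = replace(params, ranges=ranges, groups=groups)
    if kind == "moss":
        bands = {
            const: tuple(
                Band(b.center_nm + 15.0 * band_perturbation,
                     b.width_nm * (1.0 + 0.3 * band_perturbation),
                     b.amplitude * (1.0 - 0.25 * band_perturbation))
                for b in bs
            )
            for const, bs in params.bands.items()
        }
        new = replace(new, bands=bands)
    return generate_dataset(new, seed, id_prefix=f"{kind}_")


def ground_truth_frame(truth: pd.DataFrame) -> pd.DataFrame:
    """Sidecar ground-truth table in its on-disk column order."""
    cols = ["sample_id"] + [c for c in truth.columns if c.startswith("true_")] + ["alpha", "beta"]
    return truth[cols]
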