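"""Synthetic foliar-spectra generator: contents, rendering, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from foliarnirs.simulate import (
    DEFAULT_RANGES,
    FunctionalGroupProfile,
    GeneratorParams,
    draw_contents,
    generate_dataset,
    generate_new_types,
    generate_two_region_dataset,
    noiseless_spectrum,
    render_spectrum,
)
from foliarnirs.spectra import DEFAULT_EXCLUDED_REGIONS, mask_excluded_regions


class TestDrawContents:
    def test_truncation_contract(self):
        params = replace(GeneratorParams(), n_samples=10_000)
        df = draw_contents(params, seed=11)
        for const, (lo, hi) in DEFAULT_RANGES.items():
            assert df[const].min() >= lo
            assert df[const].max() <= hi

    def test_point_mass_profile(self):
        group = FunctionalGroupProfile("only", 1.0,
                                       {"N": 2.0, "P": 0.2, "C": 45.0},
                                       {"N": 0.0, "P": 0.0, "C": 0.0})
        params = replace(GeneratorParams(), n_samples=50, groups=(group,))
        df = draw_contents(params, seed=1)
        assert (df["N"] == 2.0).all()

    def test_group_means_recovered_within_3se(self):
        groups = (
            FunctionalGroupProfile("lo", 0.5, {"N": 1.0, "P": 0.2, "C": 45.0},
                                   {"N": 0.1, "P": 0.1, "C": 0.01}),
            FunctionalGroupProfile("hi", 0.5, {"N": 3.0, "P": 0.2, "C": 45.0},
                                   {"N": 0.1, "P": 0.1, "C": 0.01}),
        )
        params = replace(GeneratorParams(), n_samples=4000, groups=groups)
        df = draw_contents(params, seed=5)
        for name, target in (("lo", 1.0), ("hi", 3.0)):
            sub = df[df["functional_group"] == name]["N"]
            se = sub.std() / np.sqrt(len(sub))
            assert abs(sub.mean() - target) < 3 * se


class TestRenderSpectrum:
    def test_zero_contents_zero_baseline_zero_noise(self):
        params = replace(GeneratorParams(), baseline_coefficients=(0.0, 0.0, 0.0),
                         alpha_sigma=0.0, beta_sigma=0.0, scan_noise_sd=0.0)
        rec, alpha, beta = render_spectrum({"N": 0.0, "P": 0.0, "C": 0.0}, params, 0)
        np.testing.assert_allclose(rec.mean_spectrum.values, 0.0)
        assert (alpha, beta) == (1.0, 0.0)

    def test_linearity_in_contents(self):
        params = replace(GeneratorParams(), baseline_coefficients=(0.0, 0.0, 0.0),
                         alpha_sigma=0.0, beta_sigma=0.0, scan_noise_sd=0.0)
        a1 = noiseless_spectrum({"N": 1.0}, params)
        a2 = noiseless_spectrum({"N": 2.0}, params)
        np.testing.assert_allclose(a2, 2.0 * a1, atol=1e-14)

    def test_band_centers_inside_retained_windows(self):
        from foliarnirs.spectra import Spectrum

        params = GeneratorParams()
        grid = params.grid()
        probe = mask_excluded_regions(Spectrum(grid, np.zeros(grid.size)),
                                      DEFAULT_EXCLUDED_REGIONS)
        retained = set(probe.retained_wavelengths.tolist())
        for bands in params.bands.values():
            for band in bands:
                assert int(round(band.center_nm)) in retained

    def test_replicate_noise_sd_matches_parameter(self):
        params = replace(GeneratorParams(), alpha_sigma=0.0, beta_sigma=0.0)
        rng = np.random.default_rng(2)
        resids = []
        for i in range(200):
            rec, _, _ = render_spectrum({"N": 2.0, "P": 0.2, "C": 45.0}, params, rng)
            reps = np.vstack([s.values for s in rec.replicate_spectra])
            resids.append(reps - reps.mean(axis=0))
        # replicate-mean residual SD underestimates scan_sd by sqrt((r-1)/r)
        sd = np.concatenate(resids).std(ddof=0) / np.sqrt(2.0 / 3.0)
        assert abs(sd - params.scan_noise_sd) / params.scan_noise_sd < 0.15

    def test_negative_contents_rejected(self):
        with pytest.raises(ValueError):
            render_spectrum({"N": -1.0}, GeneratorParams(), 0)


class TestGenerateDataset:
    def test_seed_determinism(self):
        params = replace(GeneratorParams(), n_samples=15)
        d1, t1 = generate_dataset(params, seed=9)
        d2, t2 = generate_dataset(params, seed=9)
        assert t1.equals(t2)
        for r1, r2 in zip(d1.records, d2.records):
            np.testing.assert_array_equal(r1.mean_spectrum.values, r2.mean_spectrum.values)

    def test_null_region_effect_leaves_spectra_unshifted(self):
        from foliarnirs.simulate import RegionEffect

        base = replace(GeneratorParams(), n_samples=150)
        d_a, _ = generate_dataset(replace(base, region=RegionEffect("A")), seed=3)
        d_b, _ = generate_dataset(replace(base, region=RegionEffect("B", offset_scale=0.0)),
                                  seed=3)
        mean_a = d_a.absorbance_matrix().mean(axis=0)
        mean_b = d_b.absorbance_matrix().mean(axis=0)
        # same seed, zero offset: identical content draws, identical spectra
        np.testing.assert_allclose(mean_a, mean_b, atol=1e-12)

    def test_ground_truth_matches_chemistry(self):
        params = replace(GeneratorParams(), n_samples=10)
        dataset, truth = generate_dataset(params, seed=21)
        truth = truth.set_index("sample_id")
        for rec in dataset.records:
            assert rec.chemistry["N"] == pytest.approx(truth.loc[rec.sample_id, "true_N"])

    def test_round_trip_through_io(self, tmp_path):
        from foliarnirs.io import read_dataset, write_dataset

        params = replace(GeneratorParams(), n_samples=8)
        dataset, _ = generate_dataset(params, seed=4)
        path = str(tmp_path / "ds.csv")
        write_dataset(dataset, path, layout="wide")
        back = read_dataset(path, layout="wide")
        np.testing.assert_array_equal(back.grid, dataset.grid)
        for a, b in zip(dataset.records, back.records):
            np.testing.assert_array_equal(a.mean_spectrum.values, b.mean_spectrum.values)
            assert a.chemistry == pytest.approx(b.chemistry)


class TestNewTypes:
    def test_senescent_contents_in_bottom_decile(self):
        params = replace(GeneratorParams(), n_samples=300)
        dataset, truth = generate_new_types(params, seed=13, kind="senescent")
        lo, hi = DEFAULT_RANGES["N"]
        assert truth["true_N"].max() <= lo + 0.1 * (hi - lo) + 1e-12  # 0.907 for defaults
        lo_p, hi_p = DEFAULT_RANGES["P"]
        assert truth["true_P"].max() <= lo_p + 0.1 * (hi_p - lo_p) + 1e-12

    def test_moss_with_zero_perturbation_matches_senescent_generator(self):
        params = replace(GeneratorParams(), n_samples=100)
        d_sen, t_sen = generate_new_types(params, seed=2, kind="senescent")
        d_moss, t_moss = generate_new_types(params, seed=2, kind="moss", band_perturbation=0.0)
        np.testing.assert_allclose(t_sen["true_N"], t_moss["true_N"])
        np.testing.assert_allclose(d_sen.absorbance_matrix(), d_moss.absorbance_matrix())

    def test_moss_band_perturbation_changes_spectra(self):
        params = replace(GeneratorParams(), n_samples=30)
        d_sen, _ = generate_new_types(params, seed=2, kind="senescent")
        d_moss, _ = generate_new_types(params, seed=2, kind="moss", band_perturbation=1.0)
        assert not np.allclose(d_sen.absorbance_matrix(), d_moss.absorbance_matrix())


def test_two_region_dataset_has_batch_offset():
    regions = generate_two_region_dataset(seed=5, n_per_region=60)
    mean_a = regions["A"][0].absorbance_matrix().mean(axis=0)
    mean_b = regions["B"][0].absorbance_matrix().mean(axis=0)
    assert np.abs(mean_a - mean_b).max() > 0.005
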