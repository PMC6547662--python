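"""Preprocessing operators: SNV, smoothing, baseline, SG derivatives, recipes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foliarnirs.preprocess import (
    PreprocessRecipe,
    baseline,
    default_recipe_grid,
    moving_average,
    sg_derivative,
    snv,
)
from foliarnirs.spectra import contiguous_segments


class TestSnv:
    def test_hand_example(self):
        np.testing.assert_allclose(snv(np.array([2.0, 4.0, 6.0])), [-1.0, 0.0, 1.0])

    def test_output_standardised(self, rng):
        x = rng.normal(size=(5, 40))
        out = snv(x)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_affine_invariance_and_idempotence(self, rng):
        x = rng.normal(size=30)
        np.testing.assert_allclose(snv(3.5 * x + 2.0), snv(x), atol=1e-10)
        np.testing.assert_allclose(snv(snv(x)), snv(x), atol=1e-12)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snv(np.ones(10))


class TestMovingAverage:
    def test_truncated_edges(self):
        out = moving_average(np.array([1.0, 2.0, 3.0, 4.0]), 3)
        np.testing.assert_allclose(out, [1.5, 2.0, 3.0, 3.5])

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=25)
        np.testing.assert_allclose(moving_average(x, 1), x)

    def test_constant_unchanged(self):
        np.testing.assert_allclose(moving_average(np.full(9, 2.5), 5), np.full(9, 2.5))

    def test_respects_segment_boundaries(self, rng):
        x = rng.normal(size=10)
        segs = [slice(0, 5), slice(5, 10)]
        out = moving_average(x, 3, segs)
        np.testing.assert_allclose(out[:5], moving_average(x[:5], 3))
        np.testing.assert_allclose(out[5:], moving_average(x[5:], 3))


class TestBaseline:
    def test_linear_spectrum_maps_to_zero(self):
        x = 2.0 * np.arange(10.0) + 5.0
        np.testing.assert_allclose(baseline(x), 0.0, atol=1e-12)

    def test_peak_preserved_when_endpoints_equal(self):
        np.testing.assert_allclose(baseline(np.array([0.0, 1.0, 0.0])), [0.0, 1.0, 0.0])

    def test_offset_invariance(self, rng):
        x = rng.normal(size=20)
        np.testing.assert_allclose(baseline(x + 3.7), baseline(x), atol=1e-12)


class TestSgDerivative:
    def test_exact_on_linear(self):
        wl = np.arange(100.0)
        out, keep = sg_derivative(3.0 * wl + 7.0, 11, 2, 1)
        np.testing.assert_allclose(out, 3.0, atol=1e-9)

    def test_exact_second_derivative_of_quadratic(self):
        wl = np.arange(60.0)
        out, keep = sg_derivative(wl**2, 11, 2, 2)
        np.testing.assert_allclose(out, 2.0, atol=1e-8)

    def test_matches_local_polyfit_oracle(self, rng):
        # brute force: fit a polynomial in each window and differentiate at centre
        x = rng.normal(size=41)
        window, poly, half = 11, 2, 5
        out, keep = sg_derivative(x, window, poly, 1)
        expected = []
        for c in range(half, 41 - half):
            t = np.arange(-half, half + 1, dtype=float)
            coef = np.polynomial.polynomial.polyfit(t, x[c - half:c + half + 1], poly)
            expected.append(coef[1])  # d/dt at t=0
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_edges_dropped(self):
        out, keep = sg_derivative(np.arange(20.0), 11, 2, 1)
        assert keep.sum() == 20 - 10
        assert not keep[:5].any() and not keep[-5:].any()

    def test_short_segment_dropped_with_warning(self):
        segs = [slice(0, 5), slice(5, 30)]
        with pytest.warns(UserWarning, match="0:5"):
            out, keep = sg_derivative(np.arange(30.0), 11, 2, 1, segs)
        assert not keep[:5].any()

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sg_derivative(np.arange(30.0), 10, 2, 1)  # even window
        with pytest.raises(ValueError):
            sg_derivative(np.arange(30.0), 11, 1, 2)  # polyorder < order


class TestRecipe:
    def test_fitted_statistics_come_from_calibration_only(self, rng):
        wl = np.arange(900, 960)
        X_cal = rng.normal(size=(10, 60))
        X_new = rng.normal(loc=5.0, size=(4, 60))
        recipe = PreprocessRecipe([("center",), ("scale",)]).fit(X_cal, wl)
        Xc, _ = recipe.transform(X_cal, wl)
        np.testing.assert_allclose(Xc.mean(axis=0), 0.0, atol=1e-12)
        Xn, _ = recipe.transform(X_new, wl)
        assert Xn.mean() > 1.0  # new data shifted by its own mean would be ~0

    def test_steps_apply_in_order(self, rng):
        wl = np.arange(900, 960)
        x = rng.normal(size=(3, 60))
        a = PreprocessRecipe([("snv",), ("baseline",)]).row_transform(x, wl)[0]
        b = PreprocessRecipe([("baseline",), ("snv",)]).row_transform(x, wl)[0]
        assert not np.allclose(a, b)

    def test_determinism(self, rng):
        wl = np.arange(900, 1000)
        x = rng.normal(size=(4, 100))
        r = PreprocessRecipe([("snv",), ("moving_average", 5), ("sg_derivative", 11, 2, 1)])
        out1, wl1 = r.row_transform(x, wl)
        out2, wl2 = r.row_transform(x.copy(), wl)
        np.testing.assert_array_equal(out1, out2)
        np.testing.assert_array_equal(wl1, wl2)

    def test_wavelength_mismatch_rejected(self, rng):
        wl = np.arange(900, 960)
        recipe = PreprocessRecipe([("center",)]).fit(rng.normal(size=(5, 60)), wl)
        with pytest.raises(ValueError, match="wavelength"):
            recipe.transform(rng.normal(size=(2, 59)), wl[:-1])

    def test_serialisation_round_trip(self, rng):
        wl = np.arange(900, 960)
        X = rng.normal(size=(8, 60))
        recipe = PreprocessRecipe([("snv",), ("center",), ("scale",)]).fit(X, wl)
        clone = PreprocessRecipe.from_dict(recipe.to_dict())
        np.testing.assert_array_equal(recipe.transform(X, wl)[0], clone.transform(X, wl)[0])

    def test_default_grid_covers_all_families(self):
        grid = default_recipe_grid()
        assert len(grid) == 27
        labels = " ".join(r.label() for r in grid)
        for fam in ("snv", "baseline", "moving_average(5)", "moving_average(11)",
                    "sg_derivative(11,2,1)", "sg_derivative(11,2,2)"):
            assert fam in labels


@settings(derandomize=True, max_examples=25)
@given(
    scale=st.floats(0.1, 50.0),
    offset=st.floats(-10.0, 10.0),
    seed=st.integers(0, 2**16),
)
def test_snv_affine_invariance_property(scale, offset, seed):
    """SNV is invariant to any positive affine rescaling of the spectrum."""
    x = np.random.default_rng(seed).normal(size=64)
    np.testing.assert_allclose(snv(scale * x + offset), snv(x), atol=1e-8)
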