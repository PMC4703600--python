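"""Color-map construction, gap filling, smoothing, tone mapping, application."""

import io

import numpy as np
import pytest

from endocolor.colormap import (
    EMPTY,
    OBSERVED,
    SMOOTHING_METHODS,
    ColorMap,
    SmoothingSpec,
    ThemeColorizer,
    accumulate_bins,
    apply_color_map,
    apply_tone_curve,
    average_collisions,
    build_color_map,
    interpolate_gaps,
    load_tone_curve,
    smooth_map,
)
from endocolor.io import rgb_to_luminance
from endocolor.synthetic import generate_colormap_fixture
from .conftest import random_gray


def partial_map(entries: dict[int, tuple]) -> ColorMap:
    cmap = ColorMap.empty()
    for y, rgb in entries.items():
        cmap.rows[y] = rgb
        cmap.provenance[y] = OBSERVED
    return cmap


def oracle_interpolate(cmap: ColorMap) -> np.ndarray:
    """Brute force: pin endpoints, then for each empty row find the nearest
    observed neighbors below and above and interpolate linearly."""
    rows = cmap.rows.copy()
    known = (cmap.provenance != EMPTY).copy()
    rows[0], rows[255] = (0, 0, 0), (255, 255, 255)
    known[0] = known[255] = True
    out = rows.copy()
    for y in range(256):
        if known[y]:
            continue
        lo = y - 1
        while not known[lo]:
            lo -= 1
        hi = y + 1
        while not known[hi]:
            hi += 1
        frac = (y - lo) / (hi - lo)
        out[y] = rows[lo] + frac * (rows[hi] - rows[lo])
    return out


class TestAccumulateBins:
    def test_single_pixel_collision_example(self):
        theme = np.array([[[0, 28, 0]]], dtype=np.uint8)
        bins = accumulate_bins(theme)
        assert list(bins) == [14]
        assert np.array_equal(bins[14], [[0, 28, 0]])

    def test_achromatic_ramp_bins(self, achromatic_ramp_theme):
        bins = accumulate_bins(achromatic_ramp_theme)
        assert set(bins) == set(range(256))
        for v in (0, 100, 255):
            assert np.all(bins[v] == v)

    def test_pixel_conservation(self, rng):
        theme = rng.integers(0, 256, size=(13, 17, 3), dtype=np.uint8)
        bins = accumulate_bins(theme)
        assert sum(len(v) for v in bins.values()) == 13 * 17

    def test_bins_keyed_by_luminance(self, rng):
        theme = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        lum = rgb_to_luminance(theme)
        bins = accumulate_bins(theme)
        assert set(bins) == set(np.unique(lum).tolist())


class TestAverageCollisions:
    def test_worked_collision_average(self):
        cmap = average_collisions({14: np.array([[32, 16, 8], [0, 28, 0]])})
        assert np.array_equal(cmap.rows[14], [16.0, 22.0, 4.0])

    def test_singleton_mean(self):
        cmap = average_collisions({7: np.array([[9, 8, 7]])})
        assert np.array_equal(cmap.rows[7], [9.0, 8.0, 7.0])

    def test_direct_mean(self):
        cmap = average_collisions(
            {50: np.array([[10, 10, 10], [20, 20, 20], [30, 30, 30]])})
        assert np.array_equal(cmap.rows[50], [20.0, 20.0, 20.0])

    def test_mean_inside_envelope(self, rng):
        for _ in range(20):
            trip = rng.integers(0, 256, size=(rng.integers(1, 9), 3))
            cmap = average_collisions({100: trip})
            assert np.all(cmap.rows[100] >= trip.min(axis=0) - 1e-12)
            assert np.all(cmap.rows[100] <= trip.max(axis=0) + 1e-12)


class TestInterpolateGaps:
    def test_two_row_gap(self):
        cmap = partial_map({10: (100, 100, 100), 13: (130, 130, 130)})
        out = interpolate_gaps(cmap)
        assert np.allclose(out.rows[11], 110.0)
        assert np.allclose(out.rows[12], 120.0)

    def test_complete_map_unchanged_in_interior(self):
        full = generate_colormap_fixture("identity")
        out = interpolate_gaps(full)
        assert np.array_equal(out.rows, full.rows)

    def test_single_mid_gray_theme_gives_two_ramps(self):
        theme = np.array([[[128, 128, 128]]], dtype=np.uint8)
        out = interpolate_gaps(average_collisions(accumulate_bins(theme)))
        v = np.arange(256)
        left = 128.0 * v[:129] / 128.0
        right = 128.0 + (255.0 - 128.0) * (v[129:] - 128) / (255 - 128)
        expected = np.concatenate([left, right])
        for c in range(3):
            assert np.allclose(out.rows[:, c], expected, atol=1e-9)

    def test_matches_brute_force_oracle_on_random_maps(self, rng):
        for _ in range(200):
            n_obs = rng.integers(1, 60)
            ys = rng.choice(np.arange(1, 255), size=n_obs, replace=False)
            cmap = partial_map(
                {int(y): tuple(rng.uniform(0, 255, 3)) for y in ys})
            out = interpolate_gaps(cmap)
            assert np.allclose(out.rows, oracle_interpolate(cmap), atol=1e-9)
            assert out.is_complete

    def test_printed_form_extrapolates_away(self):
        """The as-printed gap formula moves opposite to the next observed
        entry; kept only as an audit path and clipped to range."""
        cmap = partial_map({10: (100, 100, 100), 13: (130, 130, 130)})
        out = interpolate_gaps(cmap, printed_form=True)
        assert np.allclose(out.rows[11], 90.0)  # 100 + (100-130)/3 * 1
        assert np.allclose(out.rows[12], 80.0)  # 100 + (100-130)/3 * 2
        assert out.rows.min() >= 0 and out.rows.max() <= 255


class TestSmoothing:
    @pytest.mark.parametrize("method", SMOOTHING_METHODS)
    def test_constant_channel_unchanged(self, method):
        cmap = ColorMap(np.full((256, 3), 99.0),
                        np.array([OBSERVED] * 256, dtype=object))
        out = smooth_map(cmap, SmoothingSpec(method, 19))
        assert np.allclose(out.rows[1:255], 99.0, atol=1e-8)

    @pytest.mark.parametrize("method", ["moving_average",
                                        "linear_local_regression"])
    def test_linear_ramp_reproduced(self, method):
        cmap = generate_colormap_fixture("identity")
        out = smooth_map(cmap, SmoothingSpec(method, 19))
        v = np.arange(256, dtype=float)
        for c in range(3):
            assert np.allclose(out.rows[1:255, c], v[1:255], atol=1e-8)

    def test_linear_local_regression_matches_statsmodels(self, rng):
        """Independent cross-check of the LOWESS smoother."""
        sm = pytest.importorskip("statsmodels.api")
        from endocolor.colormap import _local_regression
        y = np.cumsum(rng.normal(0, 1, 256)) + 50
        mine = _local_regression(y, 19, degree=1, robust=False)
        ref = sm.nonparametric.lowess(y, np.arange(256.0), frac=19 / 256,
                                      it=0, return_sorted=False)
        assert np.allclose(mine, ref, atol=1e-8)

    def test_endpoints_repinned(self, rng):
        rows = rng.uniform(0, 255, size=(256, 3))
        cmap = ColorMap(rows, np.array([OBSERVED] * 256, dtype=object))
        for method in SMOOTHING_METHODS:
            out = smooth_map(cmap, SmoothingSpec(method, 9))
            assert np.array_equal(out.rows[0], [0, 0, 0])
            assert np.array_equal(out.rows[255], [255, 255, 255])
            assert out.rows.min() >= 0 and out.rows.max() <= 255

    def test_unknown_method_lists_valid_names(self):
        with pytest.raises(ValueError, match="moving_average"):
            SmoothingSpec("median", 19)

    def test_even_span_rejected(self):
        with pytest.raises(ValueError):
            SmoothingSpec("moving_average", 10)


class TestBuildColorMap:
    def test_identity_fixed_point(self, achromatic_ramp_theme):
        cmap = build_color_map(achromatic_ramp_theme)
        v = np.arange(256, dtype=float)
        for c in range(3):
            assert np.max(np.abs(cmap.rows[:, c] - v)) <= 1.0

    def test_single_hue_theme_preserves_hue_order(self, gray_ramp):
        lut = generate_colormap_fixture("single-hue").lookup_table()
        theme = lut[gray_ramp]
        cmap = build_color_map(theme)
        interior = cmap.rows[1:255]
        assert np.all(interior[:, 0] >= interior[:, 1] - 1e-6)
        assert np.all(interior[:, 1] >= interior[:, 2] - 1e-6)

    def test_finalized_invariants(self, small_scene):
        cmap = build_color_map(small_scene)
        cmap.validate_finalized()
        assert cmap.rows.shape == (256, 3)
        assert np.array_equal(cmap.rows[0], [0, 0, 0])
        assert np.array_equal(cmap.rows[255], [255, 255, 255])


class TestApply:
    def test_identity_map_yields_achromatic(self, rng):
        img = random_gray(rng)
        out = apply_color_map(img, generate_colormap_fixture("identity"))
        for c in range(3):
            assert np.array_equal(out[..., c], img)

    def test_lookup_is_row_of_map(self, small_scene):
        cmap = build_color_map(small_scene)
        img = np.full((2, 2), 100, dtype=np.uint8)
        out = apply_color_map(img, cmap)
        assert np.array_equal(out[0, 0], cmap.lookup_table()[100])

    def test_pointwise_purity_under_permutation(self, rng, small_scene):
        cmap = build_color_map(small_scene)
        img = random_gray(rng, 10, 10)
        perm = rng.permutation(100)
        out = apply_color_map(img, cmap)
        out_perm = apply_color_map(img.ravel()[perm].reshape(10, 10), cmap)
        assert np.array_equal(out.reshape(-1, 3)[perm], out_perm.reshape(-1, 3))


class TestToneCurve:
    def test_identity_curve_noop(self, small_scene):
        cmap = build_color_map(small_scene)
        out = apply_tone_curve(cmap, np.arange(256, dtype=float))
        assert np.allclose(out.rows[1:255], cmap.rows[1:255], atol=1e-9)

    def test_inversion_on_identity_interior(self):
        cmap = generate_colormap_fixture("identity")
        out = apply_tone_curve(cmap, 255.0 - np.arange(256, dtype=float))
        v = np.arange(1, 255, dtype=float)
        for c in range(3):
            assert np.allclose(out.rows[1:255, c], 255.0 - v, atol=1e-9)

    def test_gamma_half_brightens_interior(self):
        cmap = generate_colormap_fixture("identity")
        curve = 255.0 * (np.arange(256) / 255.0) ** 0.5
        out = apply_tone_curve(cmap, curve)
        assert np.all(out.rows[1:255] >= cmap.rows[1:255] - 1e-9)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            apply_tone_curve(generate_colormap_fixture("identity"),
                             np.arange(100, dtype=float))

    def test_tone_curve_csv_loading(self):
        buf = io.StringIO("Y,R,G,B\n" + "\n".join(
            f"{y},{y},{y},{y}" for y in range(256)))
        curve = load_tone_curve(buf)
        assert curve.shape == (256, 3)
        assert np.allclose(curve[:, 0], np.arange(256))


class TestSerialization:
    def test_csv_round_trip(self, small_scene):
        cmap = build_color_map(small_scene)
        buf = io.StringIO()
        cmap.to_csv(buf)
        buf.seek(0)
        back = ColorMap.from_csv(buf)
        assert np.allclose(back.rows, cmap.rows, atol=1e-6)
        assert np.array_equal(back.provenance, cmap.provenance)


class TestThemeColorizer:
    def test_unfitted_transform_raises(self, rng):
        with pytest.raises(ValueError, match="not fitted"):
            ThemeColorizer().transform(random_gray(rng))

    def test_fit_records_observed_bins(self, small_scene):
        col = ThemeColorizer().fit(small_scene)
        assert 0 < col.n_observed_bins_ <= 256
        col.color_map_.validate_finalized()

    def test_identity_theme_round_trip(self, gray_ramp, achromatic_ramp_theme):
        col = ThemeColorizer().fit(achromatic_ramp_theme)
        out = col.transform(gray_ramp)
        diff = np.abs(out.astype(int) - gray_ramp[..., None].astype(int))
        assert diff.max() <= 1

    def test_get_set_params(self):
        col = ThemeColorizer(span=15)
        assert col.get_params()["span"] == 15
        col.set_params(smoothing_method="moving_average")
        assert col.smoothing_method == "moving_average"

    def test_tone_curve_parameter_applied(self, small_scene, gray_ramp):
        inv = 255.0 - np.arange(256, dtype=float)
        plain = ThemeColorizer().fit(small_scene)
        toned = ThemeColorizer(tone_curve=inv).fit(small_scene)
        assert not np.array_equal(plain.color_map_.rows[1:255],
                                  toned.color_map_.rows[1:255])
        assert np.array_equal(toned.color_map_.rows[255], [255, 255, 255])
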