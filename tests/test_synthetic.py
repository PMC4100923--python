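"""Synthetic generators: determinism, stated structure, recoverability."""

import dataclasses

import numpy as np
import pytest

from trirgb import (
    ChannelSpec,
    PlanktonParams,
    TransectParams,
    UsageError,
    compose_transect,
    make_plankton_series,
    make_transect,
)


class TestMakeTransect:
    def test_seed_determinism(self):
        a = make_transect(30, 20, seed=11)
        b = make_transect(30, 20, seed=11)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.values, fb.values)
            np.testing.assert_array_equal(fa.mask, fb.mask)

    def test_different_seed_differs(self):
        a = make_transect(30, 20, seed=11)[0]
        b = make_transect(30, 20, seed=12)[0]
        assert not np.array_equal(a.values, b.values)

    def test_zero_noise_columns_follow_sigmoid(self):
        """With sigma = 0, every column is the stated sigmoid profile times
        its west-east factor — check against a direct recomputation."""
        p = dataclasses.replace(TransectParams(), noise_sigma=0.0)
        no3, _, _ = make_transect(20, 30, p, seed=0)
        z = no3.y_axis
        prof = p.surface_frac + (1 - p.surface_frac) / (
            1 + np.exp(-(z - p.nutricline_depth_m) / p.nutricline_width_m))
        u = no3.x_axis / p.x_max_km
        expected = p.deep_no3 * prof[:, None] * (1 - p.west_east_reduction * u)[None, :]
        np.testing.assert_allclose(no3.values, expected, rtol=1e-12)

    def test_horizontal_mean_increases_with_depth(self):
        """Strictly monotone without noise; an increasing trend with noise
        (the deep plateau rows are equal up to noise, so strict ordering
        cannot survive sigma > 0)."""
        p0 = dataclasses.replace(TransectParams(), noise_sigma=0.0)
        for f in make_transect(40, 40, p0, seed=3):
            # mean over the full row: the field is defined below the sea
            # floor too, the mask only encodes bathymetry
            row_mean = f.values.mean(axis=1)
            assert np.all(np.diff(row_mean) > 0)
        for f in make_transect(40, 40, seed=3):
            row_mean = f.values.mean(axis=1)
            third = len(row_mean) // 3
            assert row_mean[:third].mean() < row_mean[-third:].mean()

    def test_depth_mean_decreases_west_to_east(self):
        p = dataclasses.replace(TransectParams(), noise_sigma=0.0)
        for f in make_transect(40, 40, p, seed=0):
            depth_mean = np.array([f.values[:, j][f.mask[:, j]].mean()
                                   for j in range(f.shape[1])])
            assert np.all(np.diff(depth_mean) < 0)

    def test_deep_east_np_ratio_matches_stated_factor(self):
        """Deep-east N:P over deep-west N:P ~ np_deep_east_factor (10% at
        sigma = 0.1)."""
        p = TransectParams()  # sigma = 0.1 default
        no3, po4, _ = make_transect(50, 50, p, seed=21)
        deep = no3.y_axis > 0.75 * p.z_max_m
        west = no3.x_axis < 0.1 * p.x_max_km
        east = no3.x_axis > 0.9 * p.x_max_km

        def ratio(cols):
            sel = np.ix_(deep, cols)
            m = no3.mask[sel]
            return no3.values[sel][m].mean() / po4.values[sel][m].mean()

        factor = ratio(east) / ratio(west)
        assert factor == pytest.approx(p.np_deep_east_factor, rel=0.10)

    def test_bathymetry_masks_deep_cells_consistently(self):
        fields = make_transect(30, 30, seed=4)
        masks = [f.mask for f in fields]
        assert np.array_equal(masks[0], masks[1]) and np.array_equal(masks[1], masks[2])
        # mask is a water column: once masked, everything below is masked
        for j in range(masks[0].shape[1]):
            col = masks[0][:, j]
            assert np.all(np.diff(col.astype(int)) <= 0)

    def test_all_values_non_negative(self):
        for f in make_transect(25, 25, seed=9):
            assert np.all(f.valid_values() >= 0)

    def test_flat_preset_has_no_horizontal_gradient(self):
        no3, _, _ = make_transect(20, 20, "flat", seed=0)
        assert np.allclose(no3.values, no3.values[:, :1], rtol=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(UsageError):
            make_transect(20, 20, dataclasses.replace(TransectParams(),
                                                      noise_sigma=-1.0), seed=0)
        with pytest.raises(UsageError):
            make_transect(2, 20, seed=0)


class TestMakePlanktonSeries:
    def test_seed_determinism(self):
        a = make_plankton_series(8, 10, seed=5)
        b = make_plankton_series(8, 10, seed=5)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.value, tb.value)
            np.testing.assert_array_equal(ta.z, tb.z)

    def test_zero_noise_peak_depth_increases_with_time(self):
        p = dataclasses.replace(PlanktonParams(), poisson_noise=False,
                                depth_jitter_m=0.0)
        euk, syn, pro = make_plankton_series(10, 40, p, seed=0)
        total = euk.value + syn.value + pro.value
        peak_depths = []
        for t in np.unique(euk.t):
            sel = euk.t == t
            peak_depths.append(euk.z[sel][np.argmax(total[sel])])
        assert np.all(np.diff(peak_depths) >= 0)
        assert peak_depths[0] == pytest.approx(p.dcm_start_m, abs=p.z_max_m / 39)
        assert peak_depths[-1] == pytest.approx(p.dcm_end_m, abs=p.z_max_m / 39)

    def test_pro_share_rises_by_season_end(self):
        euk, syn, pro = make_plankton_series(12, 20, seed=8)
        times = np.unique(euk.t)

        def pro_share(t):
            sel = euk.t == t
            total = euk.value[sel] + syn.value[sel] + pro.value[sel]
            k = np.argmax(total)
            return pro.value[sel][k] / total[k]

        assert pro_share(times[-1]) > pro_share(times[0])

    def test_deep_euk_band_present(self):
        """Euk dominates the community near 200 m."""
        p = dataclasses.replace(PlanktonParams(), poisson_noise=False)
        euk, syn, pro = make_plankton_series(6, 60, p, seed=0)
        near = np.abs(euk.z - p.deep_euk_depth_m) < 10.0
        share = euk.value[near] / (euk.value[near] + syn.value[near] + pro.value[near])
        assert share.mean() > 0.5

    def test_values_non_negative_and_tables_aligned(self):
        tables = make_plankton_series(5, 8, seed=2)
        for tab in tables:
            assert np.all(tab.value >= 0)
            np.testing.assert_array_equal(tab.t, tables[0].t)
            np.testing.assert_array_equal(tab.z, tables[0].z)

    def test_invalid_params_rejected(self):
        with pytest.raises(UsageError):
            make_plankton_series(2, 10, seed=0)


def test_pipeline_recovers_dark_surface_band():
    """End-to-end: composing the synthetic transect yields a dark surface
    layer — mean luminance in the top depth decile below the bottom decile."""
    fields = make_transect(60, 50, seed=17)
    specs = tuple(ChannelSpec(channel=c, gamma=0.5) for c in ("red", "green", "blue"))
    raster, _ = compose_transect(fields, specs)
    lum = (raster.r + raster.g + raster.b) / 3.0
    ny = raster.shape[0]
    top = slice(0, max(1, ny // 10))
    bot = slice(ny - max(1, ny // 10), ny)
    lum_top = lum[top][raster.mask[top]].mean()
    lum_bot = lum[bot][raster.mask[bot]].mean()
    assert lum_top < lum_bot
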