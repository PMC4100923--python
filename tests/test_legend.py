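"""Composite legend: pipeline consistency, axis layout, inverse lookup."""

import numpy as np
import pytest

from trirgb import (
    ChannelSpec,
    GriddedField,
    UsageError,
    build_legend,
    color_to_concentrations,
    compose,
    from_saturation,
    render_legend,
    to_saturation,
)


@pytest.fixture
def specs():
    return (
        ChannelSpec(channel="red", source_name="NO3", gamma=0.5, c_min=0.0,
                    c_max=8.0, units="µmol/L"),
        ChannelSpec(channel="green", source_name="PO4", gamma=0.5, c_min=0.0,
                    c_max=0.4, units="µmol/L"),
        ChannelSpec(channel="blue", source_name="SiOH4", gamma=0.5, c_min=0.0,
                    c_max=12.0, units="µmol/L"),
    )


class TestBuildLegend:
    def test_default_has_five_blue_panels(self, specs):
        panel = build_legend(*specs, resolution=16)
        assert panel.n_blue_levels == 5
        assert panel.blue_levels == (0.0, 0.25, 0.5, 0.75, 1.0)

    def test_corner_colors(self, specs):
        panel = build_legend(*specs, resolution=16)
        p0 = panel.panels[0]   # blue = 0
        assert (p0.r[0, -1], p0.g[0, -1], p0.b[0, -1]) == (1.0, 1.0, 0.0)  # yellow
        p4 = panel.panels[-1]  # blue = 1
        assert (p4.r[-1, 0], p4.g[-1, 0], p4.b[-1, 0]) == (0.0, 0.0, 1.0)  # pure blue

    def test_red_increases_upward_green_rightward(self, specs):
        panel = build_legend(*specs, resolution=8)
        p = panel.panels[0]
        assert np.all(np.diff(p.r[:, 0]) < 0)   # row index down => red down
        assert np.all(np.diff(p.g[0, :]) > 0)

    def test_every_pixel_matches_main_pipeline(self, specs):
        """Legend pixels come from compose(to_saturation(...)), not drawing."""
        res = 12
        panel = build_legend(*specs, resolution=res)
        axis = np.arange(res, dtype=float)
        sat_g = np.tile(axis / (res - 1), (res, 1))
        sat_r = 1.0 - axis[:, None] / (res - 1) * np.ones((1, res))
        for lev, praster in zip(panel.blue_levels, panel.panels):
            conc = [from_saturation(sat_r, specs[0]),
                    from_saturation(sat_g, specs[1]),
                    np.full((res, res), from_saturation(lev, specs[2]))]
            sats = [to_saturation(GriddedField(values=c, x_axis=axis, y_axis=axis), s)
                    for c, s in zip(conc, specs)]
            expected = compose(*sats)
            np.testing.assert_allclose(praster.r, expected.r, atol=1e-12)
            np.testing.assert_allclose(praster.g, expected.g, atol=1e-12)
            np.testing.assert_allclose(praster.b, expected.b, atol=1e-12)

    def test_tick_labels_are_inverse_transform_values(self, specs):
        panel = build_legend(*specs, resolution=16, n_ticks=3)
        np.testing.assert_allclose(panel.tick_values("red"), [0.0, 0.25 * 8.0, 8.0])

    @pytest.mark.parametrize("kw", [dict(n_blue_levels=0), dict(resolution=1)])
    def test_invalid_layout_rejected(self, specs, kw):
        with pytest.raises(UsageError):
            build_legend(*specs, **{"resolution": 16, **kw})

    def test_render_writes_png(self, specs, tmp_path):
        panel = build_legend(*specs, resolution=16)
        out = tmp_path / "legend.png"
        render_legend(panel, out)
        assert out.stat().st_size > 0


class TestColorToConcentrations:
    def test_white_returns_maxima(self, specs):
        assert color_to_concentrations((1, 1, 1), *specs) == (8.0, 0.4, 12.0)

    def test_half_red_sqrt_mode(self):
        spec_r = ChannelSpec(channel="red", gamma=0.5, c_min=0.0, c_max=16.0)
        spec_g = ChannelSpec(channel="green", gamma=0.5, c_min=0.0, c_max=1.0)
        spec_b = ChannelSpec(channel="blue", gamma=0.5, c_min=0.0, c_max=1.0)
        out = color_to_concentrations((0.5, 0.0, 0.0), spec_r, spec_g, spec_b)
        assert out[0] == pytest.approx(4.0)
        assert out[1] == 0.0 and out[2] == 0.0

    def test_round_trip_on_random_triples(self, specs):
        """50 random concentration triples survive color round trip to 1e-12."""
        rng = np.random.default_rng(555)
        for _ in range(50):
            conc = [rng.uniform(0.0, float(s.c_max)) for s in specs]
            color = tuple(
                to_saturation(
                    GriddedField(values=np.array([[c]]), x_axis=[0.0], y_axis=[0.0]),
                    s,
                ).values[0, 0]
                for c, s in zip(conc, specs)
            )
            back = color_to_concentrations(color, *specs)
            np.testing.assert_allclose(back, conc, rtol=1e-12, atol=1e-12)

    def test_component_outside_unit_cube_rejected(self, specs):
        with pytest.raises(UsageError):
            color_to_concentrations((1.2, 0.0, 0.0), *specs)
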