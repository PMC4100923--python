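"""Composite RGB legend and the inverse color -> concentration lookup.

All eight corners of the RGB cube cannot be shown on one 2-D panel, so the
legend displays the continuous red x green plane replicated at a small
number of discrete blue levels (default five): within each panel the red
saturation varies continuously along Y (increasing upward) and green along
X, while blue is constant, with that panel's blue-channel physical value
written beside it.  Axis ticks are labeled in physical units through the
inverse saturation transform, so square-root-mode legends have visibly
non-linear tick spacing — intentional, since equal color steps then
correspond to unequal concentration steps.

Every legend pixel is produced by the same to_saturation/compose pipeline
as the main figure, never drawn independently, so the legend is guaranteed
to be consistent with the raster it explains.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .compose import RGBRaster, compose
from .exceptions import UsageError
from .fields import ChannelSpec, GriddedField
from .transform import from_saturation, to_saturation

DEFAULT_BLUE_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class LegendPanel:
    """The composite legend: red(Y) x green(X) planes at discrete blue levels."""

    red_spec: ChannelSpec
    green_spec: ChannelSpec
    blue_spec: ChannelSpec
    blue_levels: tuple[float, ...] = DEFAULT_BLUE_LEVELS
    resolution: int = 128
    n_ticks: int = 5
    panels: list[RGBRaster] = dc_field(default_factory=list)

    @property
    def n_blue_levels(self) -> int:
        return len(self.blue_levels)

    def tick_saturations(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_ticks)

    def tick_values(self, channel: str) -> np.ndarray:
        """Physical concentrations at the tick saturations for one axis."""
        spec = {"red": self.red_spec, "green": self.green_spec, "blue": self.blue_spec}[channel]
        return np.asarray([from_saturation(s, spec) for s in self.tick_saturations()])

    def tick_labels(self, channel: str, fmt: str = "{:.3g}") -> list[str]:
        return [fmt.format(v) for v in self.tick_values(channel)]

    def blue_values(self) -> np.ndarray:
        """Physical value of the blue channel at each panel's level."""
        return np.asarray([from_saturation(s, self.blue_spec) for s in self.blue_levels])


def build_legend(
    red_spec: ChannelSpec,
    green_spec: ChannelSpec,
    blue_spec: ChannelSpec,
    n_blue_levels: int = 5,
    resolution: int = 128,
    blue_levels: tuple[float, ...] | None = None,
    n_ticks: int = 5,
) -> LegendPanel:
    """Build the legend by running the main pipeline over axis concentrations.

    Panel ``k`` holds constant blue saturation ``blue_levels[k]``; pixel
    ``(i, j)`` has green saturation ``j/(resolution-1)`` and red saturation
    ``1 - i/(resolution-1)`` (red increases upward).  The pixel colors are
    computed by mapping those axis saturations back to concentrations and
    feeding them through ``to_saturation`` + ``compose``, exactly as a data
    figure would be.
    """
    if n_blue_levels < 1:
        raise UsageError(f"n_blue_levels must be >= 1, got {n_blue_levels}")
    if resolution < 2:
        raise UsageError(f"legend resolution must be >= 2, got {resolution}")
    for spec in (red_spec, green_spec, blue_spec):
        if not spec.is_resolved:
            raise UsageError(f"channel '{spec.channel}': spec not resolved")
    if blue_levels is None:
        levels = tuple(np.linspace(0.0, 1.0, n_blue_levels)) if n_blue_levels > 1 else (1.0,)
    else:
        levels = tuple(float(b) for b in blue_levels)
        if list(levels) != sorted(levels) or min(levels) < 0 or max(levels) > 1:
            raise UsageError("blue_levels must be ascending within [0, 1]")

    axis = np.arange(resolution, dtype=float)  # index axes for the unit square
    sat_g = np.tile(axis / (resolution - 1), (resolution, 1))
    sat_r = 1.0 - axis[:, None] / (resolution - 1) * np.ones((1, resolution))

    # concentrations on the legend plane, then back through the full pipeline
    conc_r = from_saturation(sat_r, red_spec)
    conc_g = from_saturation(sat_g, green_spec)
    panels: list[RGBRaster] = []
    for lev in levels:
        conc_b = np.full((resolution, resolution), from_saturation(lev, blue_spec))
        rasters = [
            to_saturation(GriddedField(values=c, x_axis=axis, y_axis=axis, name=s.channel), s)
            for c, s in ((conc_r, red_spec), (conc_g, green_spec), (conc_b, blue_spec))
        ]
        panels.append(compose(*rasters))
    return LegendPanel(
        red_spec=red_spec,
        green_spec=green_spec,
        blue_spec=blue_spec,
        blue_levels=levels,
        resolution=resolution,
        n_ticks=n_ticks,
        panels=panels,
    )


def color_to_concentrations(
    color: tuple[float, float, float],
    red_spec: ChannelSpec,
    green_spec: ChannelSpec,
    blue_spec: ChannelSpec,
) -> tuple[float, float, float]:
    """Read three physical concentrations off an (r, g, b) color in [0, 1]^3."""
    r, g, b = color
    return (
        from_saturation(r, red_spec),
        from_saturation(g, green_spec),
        from_saturation(b, blue_spec),
    )


def render_legend(
    panel: LegendPanel,
    path,
    show_saturation: bool = False,
    dpi: int = 100,
) -> None:
    """Render the legend panels side by side to a PNG.

    Each panel is annotated with its blue level's physical value (and the
    saturation in parentheses when ``show_saturation``); the shared axes
    carry physical-unit tick labels from the inverse transform.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = panel.n_blue_levels
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 2.8), squeeze=False)
    ticks = panel.tick_saturations() * (panel.resolution - 1)
    blue_vals = panel.blue_values()
    for k, ax in enumerate(axes[0]):
        from .compose import quantize

        ax.imshow(quantize(panel.panels[k]), origin="upper", interpolation="nearest")
        label = f"{blue_vals[k]:.3g} {panel.blue_spec.units}".strip()
        if show_saturation:
            label += f" (s={panel.blue_levels[k]:.2f})"
        ax.set_title(label, fontsize=8)
        ax.set_xticks(ticks)
        ax.set_xticklabels(panel.tick_labels("green"), fontsize=6, rotation=45)
        if k == 0:
            # red increases upward: row 0 is saturation 1
            ax.set_yticks(ticks)
            ax.set_yticklabels(panel.tick_labels("red")[::-1], fontsize=6)
            ax.set_ylabel(f"{panel.red_spec.source_name} [{panel.red_spec.units}]", fontsize=7)
        else:
            ax.set_yticks([])
        ax.set_xlabel(f"{panel.green_spec.source_name} [{panel.green_spec.units}]", fontsize=7)
    fig.suptitle(
        f"blue: {panel.blue_spec.source_name} [{panel.blue_spec.units}]", fontsize=8
    )
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
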