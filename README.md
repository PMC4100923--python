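# trirgb

Tri-variate RGB composite visualization of 2-D scalar fields, built for
oceanographic sections and depth–time series: three co-registered fields
(e.g. NO₃, PO₄ and SiOH₄ concentrations along a Mediterranean transect, or
picoeukaryote / *Synechococcus* / *Prochlorococcus* cell counts through a
season) are normalized, gamma-transformed and mapped to the red, green and
blue channels of a single raster. A pixel's hue then encodes the *ratio* of
the three variables and its brightness their overall magnitude — nutrient
limitation patterns or community composition shifts become visible in one
figure instead of three side-by-side contour plots.

## Method

Each channel's saturation is

```
s(x, z) = ((c(x, z) − c_min) / (c_max − c_min)) ^ γ
```

with two stock regimes:

* **nutrient mode** — `c_min = 0`, `c_max` the field maximum, `γ = 0.5`
  (square root). The root stretches the low-concentration end, giving a
  more detailed view of the nutrient-depleted photic zone.
* **count mode** — `[c_min, c_max]` the observed range, `γ = 1` (linear).

Scattered samples (time, depth, value) are first normalized, then linearly
interpolated onto a regular Cartesian grid via a Delaunay triangulation;
nodes outside the sample convex hull are masked. The three saturation
fields are stacked per pixel into the raster, quantized to 8-bit
(round-half-away-from-zero) and written as PNG.

The composite legend shows the continuous red × green plane replicated at
five discrete blue levels, with axis ticks in physical units through the
exact inverse transform `c = c_min + (c_max − c_min) · s^(1/γ)` — which
also powers `lookup`, reading three concentrations back off any pixel
color. Legend pixels are produced by the same pipeline as the figure, so
legend and figure can never disagree.

## Worked example

```python
import trirgb

fields = trirgb.make_transect(200, 100, "mediterranean_like", seed=42)
specs = tuple(
    trirgb.ChannelSpec(channel=c, source_name=f.name, gamma=0.5, units=f.units)
    for c, f in zip(("red", "green", "blue"), fields)
)
raster, resolved = trirgb.compose_transect(fields, specs)
for s in resolved:
    print(f"{s.channel:5s} {s.source_name:6s} c_min={s.c_min:g} c_max={s.c_max:.4g} {s.units}")

conc = trirgb.color_to_concentrations((0.5, 0.25, 0.0), *resolved)
print("color (0.5, 0.25, 0.0) ->", tuple(round(c, 4) for c in conc))
```

prints

```
red   NO3    c_min=0 c_max=7.906 µmol/L
green PO4    c_min=0 c_max=0.3455 µmol/L
blue  SiOH4  c_min=0 c_max=13.58 µmol/L
color (0.5, 0.25, 0.0) -> (1.9766, 0.0216, 0.0)
```

The derived `c_max` values are the field maxima of the synthetic transect;
a half-saturated red pixel corresponds to `0.5² × 7.906 ≈ 1.98 µmol/L` of
NO₃ (the square root is inverted by squaring), while green saturation 0.25
maps to only 6 % of the PO₄ range — the low end of a √-scaled channel is
deliberately spread out.

The same flow from the shell:

```
trirgb synth transect --out-dir fx --seed 42
trirgb transect fx/no3.csv fx/po4.csv fx/sioh4.csv \
    --out transect.png --legend-out legend.png --log-specs specs.json
trirgb synth plankton --out-dir fx --seed 42
trirgb timeseries fx/plankton.csv --out timeseries.png
trirgb lookup 0.5 0.25 0 --red-max 7.906 --green-max 0.3455 --blue-max 13.58
```

Every figure-producing run logs the resolved per-channel bounds; re-running
with those bounds stated (`--red-min/--red-max`, …) reproduces the PNG
bit-exactly, so published figures are replayable from their logs.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the synthetic transect and plankton series from the given seed,
composes both RGB figures with their legends into `results/`, exercises the
quantize/lookup round trip, and writes the results JSON.
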