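# Methods

## The composition model

The tool renders three dependent variables over two shared independent axes
as one image. Each variable `c_k(x, z)` (k ∈ {red, green, blue}) is mapped
to a per-channel saturation

    s_k = clip((c_k − c_min,k) / (c_max,k − c_min,k), 0, 1) ^ γ_k ,

and the three saturations form the pixel. Additive color mixing does the
interpretive work: equal saturations are gray (balanced ratios), a dominant
channel tints the pixel toward that variable, and total brightness tracks
overall magnitude. The assumptions are mild but real: the three fields must
be co-registered on one grid, non-negative, and on scales where a per-field
range normalization is meaningful. Nothing perceptual is attempted — the
raster is raw linear RGB, not a perceptually uniform space, so equal
saturation differences are not guaranteed to look equally different.

### Normalization regimes and γ

* `zero_to_max` (nutrient mode): `c_min = 0` regardless of the data, `c_max`
  = field maximum over valid cells; default `γ = 0.5`. Oceanic nutrient
  profiles are depleted at the surface and saturate at depth; a linear map
  would render the entire productive photic zone nearly black. The square
  root reallocates dynamic range to the low end (for any 0 < c < c_max the
  √ saturation strictly exceeds the linear one).
* `min_to_max` (count mode): bounds are the observed range; default `γ = 1`.
  Cell-count ranges rarely include zero, and the range map guarantees each
  taxon uses the full channel. `x/max` normalization is available by
  setting `norm_policy="zero_to_max"` where a zero-anchored scale is
  preferred.

γ is a single knob in (0, 1] covering both regimes. Stated (user-supplied)
bounds clip out-of-range values to 0/1 rather than erroring, so one scale
can be shared across several figures; derived bounds can never clip.

The inverse `c = c_min + (c_max − c_min) s^(1/γ)` is exact on the range, and
is the only route by which physical numbers appear on legend axes or in the
`lookup` command — there is no second, independently maintained mapping.

## Gridding of scattered samples

Depth profiles sampled at irregular times and depths are interpolated with
piecewise-linear (barycentric) interpolation on a Delaunay triangulation of
the (t, z) sample positions (scipy/Qhull). Consequences worth knowing:

* exact on affine functions of (t, z); sample-coincident nodes reproduce
  the sample value;
* interpolated values are convex combinations of sample values — the grid
  never overshoots the sample range, so normalized-first saturations stay
  in [0, 1];
* nodes outside the convex hull are masked, not extrapolated (an optional
  nearest-sample fill exists but fabricates structure and is off by
  default);
* sample points are sorted by (t, z) before triangulation so cocircular
  tie-breaks are deterministic run-to-run.

Default order normalizes sample values first and interpolates saturations,
with `order="interpolate_first"` as the alternative. For γ = 1 with global
bounds the orders commute exactly; for γ < 1 they differ because the root
is nonlinear, and the normalize-first result equals root-transforming the
data before interpolation. Default grid resolution is 200×200 — arbitrary,
chosen to oversample typical profile counts, and configurable.

ISO-8601 sample times are converted to fractional days since the earliest
sample; the origin date is kept for axis labeling.

## Composition, masking, quantization

The output mask is the AND of the three channel masks: a pixel missing any
channel is invalid (a lenient OR mode exists behind a flag; it treats the
missing channel as zero, i.e. invents "none of that variable", and is
therefore not default). Invalid pixels render in a configurable fill color,
default light gray (0.85, 0.85, 0.85) — distinguishable from both black
(all-depleted) and white (all-saturated) data pixels; the choice is purely
cosmetic.

Quantization to 8-bit uses round-half-away-from-zero, `floor(255 s + 0.5)`,
fixed so golden-image comparisons are bit-exact across platforms (banker's
rounding in `np.round` would map 127.5 to 128 but 126.5 to 126). The
quantization error is ≤ 0.5/255 per channel; propagated through the inverse
transform this bounds how precisely concentrations can be read back off a
quantized pixel (the bound is widest at the low-saturation end of √-scaled
channels, where the inverse is flattest... squared, the 0.5/255 color error
is negligible near s=1 but relatively larger near s=0).

## The legend

A 2-D panel cannot show the RGB cube, so the legend replicates the
continuous red(Y, increasing upward) × green(X) plane at discrete blue
saturations, default {0, 0.25, 0.5, 0.75, 1} — five levels; each panel is
annotated with the blue channel's physical value at that level (saturation
shown in parentheses via a flag). Legend pixels are generated by mapping
axis saturations to concentrations and running them through the same
to_saturation/compose pipeline as the data; the tick labels come through
the same inverse. On √-scaled channels the physical tick spacing is
therefore visibly non-linear — intended, and a faithful statement of what
the color scale does.

## Synthetic data generator

The generator exists so every pipeline stage is testable with no external
data set. It emulates the qualitative structure of eastern-Mediterranean
observations, not their numbers.

**Transect preset `mediterranean_like`** (4000 km × 2000 m): each nutrient
is `deep_value × p(z) × h(x) × noise`, with `p(z)` a sigmoid rising from 2 %
of the deep value at the surface through a nutricline at 150 ± 80 m, and
`h(x) = 1 − g·x/x_max` a linear west→east reduction (g = 0.4 for NO₃ and
SiOH₄). PO₄ declines more steeply, `g_P = 1 − (1 − g)/f` with the deep-east
N:P enhancement factor f = 1.6, which makes deep-east N:P exceed deep-west
by exactly f in the noise-free limit while every nutrient's depth mean
still falls monotonically eastward. Deep concentrations (6 µmol/L NO₃,
0.25 µmol/L PO₄, 9 µmol/L SiOH₄) sit near the oligotrophic
eastern-Mediterranean picture with deep N:P above Redfield 16. Noise is
multiplicative log-normal (σ = 0.1, mean-preserving); a smooth random sea
floor at 0.85·z_max ± 10 % masks the bathymetry. The `flat` preset removes
all gradients for null tests.

**Plankton preset** (150 days × 250 m, 12 profiles × 15 depths): Gaussian
biomass peak whose center deepens linearly 50 m → 100 m over the season
(the deep chlorophyll maximum drift), a *Prochlorococcus* amplitude rising
from 3×10⁴ to 1.2×10⁵ cells/mL so its community share grows toward summer,
a secondary picoeukaryote band fixed at 200 m, and Poisson count noise.
Magnitudes follow the usual oligotrophic ordering Pro ≫ Syn > Euk.

Both generators consume a single `numpy.random.default_rng(seed)` stream in
a fixed draw order, so identical seeds give bitwise-identical output and a
parameter change upstream of a component does not silently reshuffle its
draws.

What a green end-to-end test establishes: the pipeline *recovers structures
the generator planted* — dark surface band, west→east darkening, redder
deep-east, deepening biomass maximum, late blue shift. It does not
establish anything about real climatology or flow cytometry data: the
generator has separable structure (profile × gradient), no advection, no
instrument artifacts, and its noise is uncorrelated cell-to-cell.

## Numerical and interface choices

* Depth is stored increasing (positive downward); raster row 0 is the
  shallowest depth, so PNGs come out surface-at-top without flipping.
* Grid coordinates are cell centers.
* Negative input values are rejected at load (concentrations are
  non-negative); small negative interpolation artifacts can be clamped by
  stating `c_min = 0` explicitly.
* Duplicate (t, z) sample positions are an error by default,
  `on_duplicate="mean"` averages them.
* NetCDF IO uses the classic (NetCDF-3) format through xarray's scipy
  backend; CSV grids carry coordinates in the header row/column; sample
  CSVs are tidy `time,depth,<taxon>…`.
* CLI exit codes: 0 success, 1 usage error, 2 data error. Resolved channel
  bounds are logged on every figure run and can be written to JSON
  (`--log-specs`); replaying them as stated bounds reproduces the PNG
  bit-exactly.

## Known limitations

* No perceptual-uniformity or color-blindness accommodation; red–green
  encodes the two continuous legend axes.
* Only three variables; the method does not extend past the three channels.
* Linear interpolation smears sharp fronts between sparse profiles and the
  hull mask can hide near-surface/near-bottom corners of the sampling
  window.
* The legend discretizes blue: intermediate blue levels must be read by
  interpolating between panels or via `lookup`.
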