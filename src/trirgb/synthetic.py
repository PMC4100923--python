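"""Synthetic oceanographic inputs with the qualitative structure of the
eastern Mediterranean, so the full pipeline is testable without any
external data set.

Two generators:

* :func:`make_transect` — three nutrient fields (NO3, PO4, SiOH4) on a
  distance x depth grid: nutrient-depleted surface water over a sigmoid
  nutricline, a linear west-to-east depth-mean reduction, a deep-east N:P
  ratio elevated by a stated factor, multiplicative log-normal noise, and a
  randomly rough sea-floor (bathymetry) mask.
* :func:`make_plankton_series` — scattered flow-cytometry-like depth
  profiles of picoeukaryote, Synechococcus and Prochlorococcus cell
  concentrations: a Gaussian deep-biomass maximum whose center deepens
  linearly from 50 m to 100 m over the season, a Prochlorococcus share
  that rises late in the series, a secondary picoeukaryote band fixed at
  200 m, and Poisson count noise.

Both consume a single ``numpy.random.default_rng(seed)`` stream with a
fixed draw order, so a repeated seed reproduces the output bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UsageError
from .fields import GriddedField, SampleTable


@dataclass(frozen=True)
class TransectParams:
    """Shape parameters for the synthetic nutrient transect.

    Concentrations are µmol/L; the defaults give deep-water values and an
    N:P near the canonical Mediterranean picture (deep N:P above Redfield
    16, rising eastward).
    """

    x_max_km: float = 4000.0          # transect length, west -> east
    z_max_m: float = 2000.0
    nutricline_depth_m: float = 150.0
    nutricline_width_m: float = 80.0
    surface_frac: float = 0.02        # surface concentration / deep concentration
    deep_no3: float = 6.0             # deep-west concentrations, µmol/L
    deep_po4: float = 0.25
    deep_si: float = 9.0
    west_east_reduction: float = 0.4  # fractional depth-mean loss west -> east
    np_deep_east_factor: float = 1.6  # deep-east N:P / deep-west N:P
    noise_sigma: float = 0.1          # log-normal sigma; 0 = deterministic
    floor_mean_frac: float = 0.85     # mean sea-floor depth / z_max
    floor_rough_frac: float = 0.1     # roughness amplitude / z_max

    def validate(self) -> None:
        if not (0 <= self.surface_frac < 1):
            raise UsageError("surface_frac must be in [0, 1)")
        if not (0 <= self.west_east_reduction < 1):
            raise UsageError("west_east_reduction must be in [0, 1)")
        if self.np_deep_east_factor <= 0:
            raise UsageError("np_deep_east_factor must be positive")
        if (1 - self.west_east_reduction) / self.np_deep_east_factor >= 1:
            raise UsageError("np_deep_east_factor too small for the stated reduction")
        if self.noise_sigma < 0:
            raise UsageError("noise_sigma must be non-negative")
        if min(self.deep_no3, self.deep_po4, self.deep_si) <= 0:
            raise UsageError("deep concentrations must be positive")


@dataclass(frozen=True)
class PlanktonParams:
    """Shape parameters for the synthetic depth-time plankton series.

    Cell concentrations are cells/mL; magnitudes follow the usual ordering
    of oligotrophic surface waters (Pro >> Syn > Euk).
    """

    season_days: float = 150.0        # first half of the year
    z_max_m: float = 250.0
    dcm_start_m: float = 50.0         # deep biomass maximum, early season
    dcm_end_m: float = 100.0          # ... late season
    dcm_width_m: float = 25.0
    euk_peak: float = 2.0e3
    syn_peak: float = 2.0e4
    pro_peak_start: float = 3.0e4
    pro_peak_end: float = 1.2e5       # Pro amplitude rises toward summer
    deep_euk_depth_m: float = 200.0   # secondary picoeukaryote band
    deep_euk_width_m: float = 20.0
    deep_euk_peak: float = 1.5e3
    background: float = 50.0
    poisson_noise: bool = True
    depth_jitter_m: float = 3.0

    def validate(self) -> None:
        if self.season_days <= 0 or self.z_max_m <= 0:
            raise UsageError("season_days and z_max_m must be positive")
        if not (0 < self.dcm_start_m < self.dcm_end_m < self.z_max_m):
            raise UsageError("need 0 < dcm_start_m < dcm_end_m < z_max_m")
        if min(self.euk_peak, self.syn_peak, self.pro_peak_start, self.pro_peak_end) <= 0:
            raise UsageError("peak concentrations must be positive")


#: Named presets.  "mediterranean_like" is the default structured world;
#: "flat" removes every gradient (for null tests: the pipeline should then
#: produce a uniform image up to noise).
TRANSECT_PRESETS: dict[str, TransectParams] = {
    "mediterranean_like": TransectParams(),
    "flat": TransectParams(
        surface_frac=1.0 - 1e-9,  # no vertical gradient (frac<1 required)
        west_east_reduction=0.0,
        np_deep_east_factor=1.0 + 1e-9,
        noise_sigma=0.0,
        floor_rough_frac=0.0,
    ),
}

PLANKTON_PRESETS: dict[str, PlanktonParams] = {
    "mediterranean_like": PlanktonParams(),
}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _smooth_noise(rng: np.random.Generator, n: int, n_modes: int = 6) -> np.ndarray:
    """Smooth 1-D random profile in [-1, 1]: a few random Fourier modes."""
    u = np.linspace(0.0, 1.0, n)
    amp = rng.standard_normal(n_modes)
    phase = rng.uniform(0, 2 * np.pi, n_modes)
    prof = np.zeros(n)
    for k in range(n_modes):
        prof += amp[k] / (k + 1) * np.sin(2 * np.pi * (k + 1) * u + phase[k])
    m = np.abs(prof).max()
    return prof / m if m > 0 else prof


def make_transect(
    nx: int,
    nz: int,
    params: TransectParams | str = "mediterranean_like",
    seed: int = 0,
) -> tuple[GriddedField, GriddedField, GriddedField]:
    """Generate co-registered NO3, PO4 and SiOH4 fields on an nx x nz grid.

    Construction, per nutrient ``i`` with deep-west concentration ``D_i``::

        c_i(x, z) = D_i * p(z) * h_i(x) * exp(sigma*eta - sigma^2/2)

    where ``p(z)`` is a sigmoid rising from ``surface_frac`` at the surface
    to 1 below the nutricline, and ``h_i(x) = 1 - g_i * x/x_max`` is the
    linear west-to-east reduction.  NO3 and SiOH4 share
    ``g = west_east_reduction``; PO4 declines more steeply,
    ``g_P = 1 - (1 - g)/f`` with ``f = np_deep_east_factor``, which makes
    the deep-east N:P exceed the deep-west N:P by exactly ``f`` in the
    noise-free limit while every nutrient's depth mean still decreases
    monotonically eastward.

    Cells below a randomly rough sea floor are masked in all three fields.
    Returns ``(no3, po4, sioh4)``.
    """
    if isinstance(params, str):
        params = TRANSECT_PRESETS[params]
    params.validate()
    if nx < 4 or nz < 4:
        raise UsageError(f"grid must be at least 4x4, got {nx}x{nz}")
    rng = np.random.default_rng(seed)

    x = np.linspace(0.0, params.x_max_km, nx)
    z = np.linspace(0.0, params.z_max_m, nz)
    u = x / params.x_max_km                       # 0 west -> 1 east

    prof = params.surface_frac + (1.0 - params.surface_frac) * _sigmoid(
        (z - params.nutricline_depth_m) / params.nutricline_width_m
    )                                             # (nz,)
    g_n = params.west_east_reduction
    g_p = 1.0 - (1.0 - g_n) / params.np_deep_east_factor
    h = {"no3": 1.0 - g_n * u, "po4": 1.0 - g_p * u, "si": 1.0 - g_n * u}
    deep = {"no3": params.deep_no3, "po4": params.deep_po4, "si": params.deep_si}
    units = {"no3": "µmol/L", "po4": "µmol/L", "si": "µmol/L"}
    names = {"no3": "NO3", "po4": "PO4", "si": "SiOH4"}

    # bathymetry first, from its own fixed position in the stream
    floor = params.floor_mean_frac * params.z_max_m + (
        params.floor_rough_frac * params.z_max_m * _smooth_noise(rng, nx)
    )
    mask = z[:, None] <= floor[None, :]

    fields = []
    for key in ("no3", "po4", "si"):              # fixed draw order
        base = deep[key] * prof[:, None] * h[key][None, :]
        if params.noise_sigma > 0:
            eta = rng.standard_normal((nz, nx))
            base = base * np.exp(params.noise_sigma * eta - params.noise_sigma**2 / 2)
        fields.append(
            GriddedField(
                values=base, x_axis=x, y_axis=z,
                units=units[key], name=names[key], mask=mask.copy(),
            )
        )
    return tuple(fields)


def make_plankton_series(
    n_profiles: int = 12,
    depths_per_profile: int = 15,
    params: PlanktonParams | str = "mediterranean_like",
    seed: int = 0,
) -> tuple[SampleTable, SampleTable, SampleTable]:
    """Generate scattered (t, z) samples of Euk, Syn and Pro concentrations.

    Profiles are evenly spaced over the season; depths are evenly spaced
    over [0, z_max] with a small seeded jitter (endpoints pinned so the
    sample hull covers the plotting window).  Expected concentrations:

    * Euk and Syn: Gaussian around the drifting deep maximum (50 m early to
      100 m late), Euk with an extra fixed Gaussian band at 200 m;
    * Pro: same Gaussian, amplitude interpolated from ``pro_peak_start`` to
      ``pro_peak_end`` so its share of the community rises late.

    Poisson sampling of the expected values provides count noise.
    Returns ``(euk, syn, pro)``.
    """
    if isinstance(params, str):
        params = PLANKTON_PRESETS[params]
    params.validate()
    if n_profiles < 3:
        raise UsageError(f"need at least 3 profiles, got {n_profiles}")
    if depths_per_profile < 3:
        raise UsageError(f"need at least 3 depths per profile, got {depths_per_profile}")
    rng = np.random.default_rng(seed)

    times = np.linspace(0.0, params.season_days, n_profiles)
    base_depths = np.linspace(0.0, params.z_max_m, depths_per_profile)

    t_all, z_all = [], []
    for _ in range(n_profiles):
        jit = rng.uniform(-params.depth_jitter_m, params.depth_jitter_m, depths_per_profile)
        jit[0] = jit[-1] = 0.0                    # pin endpoints
        z_prof = np.clip(base_depths + jit, 0.0, params.z_max_m)
        z_all.append(np.sort(z_prof))
    for i, t in enumerate(times):
        t_all.append(np.full(depths_per_profile, t))
    t_flat = np.concatenate(t_all)
    z_flat = np.concatenate(z_all)

    frac = t_flat / params.season_days
    dcm = params.dcm_start_m + (params.dcm_end_m - params.dcm_start_m) * frac
    gauss = np.exp(-0.5 * ((z_flat - dcm) / params.dcm_width_m) ** 2)
    deep_band = np.exp(-0.5 * ((z_flat - params.deep_euk_depth_m) / params.deep_euk_width_m) ** 2)

    expected = {
        "Euk": params.euk_peak * gauss + params.deep_euk_peak * deep_band + params.background,
        "Syn": params.syn_peak * gauss + params.background,
        "Pro": (params.pro_peak_start + (params.pro_peak_end - params.pro_peak_start) * frac)
        * gauss + params.background,
    }
    tables = []
    for taxon in ("Euk", "Syn", "Pro"):           # fixed draw order
        vals = expected[taxon]
        if params.poisson_noise:
            vals = rng.poisson(vals).astype(float)
        tables.append(
            SampleTable(t=t_flat, z=z_flat, value=vals, taxon=taxon, units="cells/mL")
        )
    return tuple(tables)
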