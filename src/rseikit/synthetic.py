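"""Synthetic corridor landscapes with planted statistical structure.

Generates a corridor geometry (centerline, 5-km buffer, 500-m distance
belts, two sections), spatially autocorrelated driver rasters, and
reflectance scenes constructed so the derived component indices are
monotone in a known latent quality field.  The latent field carries a
configurable north-south mean gap, section-specific driver effects
(one "natural-factor" regime, one "human-activity" regime), and planted
per-decade trends, all recorded in a truth object that downstream tests
use as an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString
import shapely

from rseikit.indices import (
    BAND_NAMES,
    WETNESS_COEFFS,
    AnnualScene,
    growing_season_composite,
)
from rseikit.raster import Grid

DRIVER_NAMES = (
    "dem",
    "slope",
    "aspect",
    "precipitation",
    "temperature",
    "land_use",
    "gdp",
    "population",
    "nighttime_light",
)
STATIC_DRIVERS = ("dem", "slope", "aspect")

SECTIONS = ("north", "south")
NORTH, SOUTH = 0, 1

LAND_USE_CODES = {1: "cropland", 2: "forest", 3: "grassland", 4: "water", 5: "builtup"}
#: Ordinal urbanisation intensity per land-use code, used in the latent model.
LAND_USE_INTENSITY = {1: 0.5, 2: 0.0, 3: 0.25, 4: 0.25, 5: 1.0}


class ConfigurationError(ValueError):
    pass


class GridTooSmallError(ValueError):
    pass


def _default_north_effects() -> dict[str, float]:
    # natural-factor-dominated regime: precipitation is the lead driver
    return {
        "precipitation": 0.65,
        "temperature": 0.30,
        "dem": 0.15,
        "slope": 0.10,
        "gdp": 0.05,
        "nighttime_light": -0.05,
        "population": -0.05,
    }


def _default_south_effects() -> dict[str, float]:
    # human-activity-dominated regime: nighttime light suppresses quality
    return {
        "nighttime_light": -0.70,
        "temperature": 0.30,
        "land_use": -0.20,
        "slope": 0.10,
        "gdp": -0.10,
        "precipitation": 0.05,
    }


def _default_driver_params() -> dict[str, tuple[float, float, float]]:
    # driver -> (north mean, south mean, sd); land_use is derived, not sampled
    return {
        "dem": (40.0, 20.0, 15.0),
        "slope": (4.0, 6.0, 1.5),
        "aspect": (180.0, 180.0, 60.0),
        "precipitation": (600.0, 1200.0, 120.0),
        "temperature": (12.0, 17.0, 1.5),
        "gdp": (300.0, 800.0, 200.0),
        "population": (400.0, 700.0, 150.0),
        "nighttime_light": (8.0, 25.0, 8.0),
    }


@dataclass
class SyntheticConfig:
    """Knobs for the synthetic corridor generator."""

    grid_shape: tuple[int, int] = (60, 200)
    pixel_size: float = 500.0
    years: tuple[int, ...] = tuple(range(2000, 2021))
    epoch_years: tuple[int, ...] = (2000, 2005, 2010, 2015, 2020)
    seed: int = 0
    section_gap: float = 0.08
    north_effects: dict[str, float] = field(default_factory=_default_north_effects)
    south_effects: dict[str, float] = field(default_factory=_default_south_effects)
    noise_sd: float = 0.02
    trend_slopes: dict[str, float] = field(
        default_factory=lambda: {"north": 0.015, "south": -0.045}
    )  # latent-quality units per decade
    smoothing_scale: float = 6.0  # pixels
    effect_amplitude: float = 0.12  # latent units per 1-sd driver anomaly per unit effect
    epoch_drift_sd: float = 0.0  # extra per-epoch field variation for non-static drivers
    #: smooth per-index disagreement (latent units); keeps the four indices
    #: from collapsing onto one factor so PC1 explains a realistic share
    index_disagreement_sd: float = 0.07
    monthly_noise_sd: float = 0.01
    n_months: int = 5
    buffer_km: float = 5.0
    belt_m: float = 500.0
    mask_water: bool = False
    driver_params: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_driver_params
    )

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        for name, mapping in (("north_effects", self.north_effects), ("south_effects", self.south_effects)):
            unknown = set(mapping) - set(DRIVER_NAMES)
            if unknown:
                raise ConfigurationError(f"{name} references unknown drivers: {sorted(unknown)}")

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_shape, self.pixel_size)

    def effects(self, section: str) -> dict[str, float]:
        return {"north": self.north_effects, "south": self.south_effects}[section]

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass
class CorridorScene:
    """Corridor geometry rasterised onto the grid."""

    grid: Grid
    centerline: LineString
    distance: np.ndarray  # metres to centerline, full grid
    buffer_mask: np.ndarray  # within buffer_km of the centerline
    belt_id: np.ndarray  # 1..n_belts inside the buffer, 0 outside
    section_code: np.ndarray  # NORTH/SOUTH on the full grid
    water_mask: np.ndarray  # canal strip (pixels straddling the centerline)
    n_belts: int

    def section_mask(self, section: str, buffered: bool = True) -> np.ndarray:
        code = SECTIONS.index(section)
        mask = self.section_code == code
        return mask & self.buffer_mask if buffered else mask

    def analysis_mask(self, mask_water: bool = False) -> np.ndarray:
        mask = self.buffer_mask.copy()
        if mask_water:
            mask &= ~self.water_mask
        return mask


@dataclass
class DriverStack:
    """Per-epoch driver layers on the corridor grid."""

    grid: Grid
    layers: dict[int, dict[str, np.ndarray]]  # epoch year -> driver -> layer
    epoch_years: tuple[int, ...]

    def nearest_epoch(self, year: int) -> int:
        return min(self.epoch_years, key=lambda e: (abs(e - year), e))

    def for_year(self, year: int) -> dict[str, np.ndarray]:
        return self.layers[self.nearest_epoch(year)]


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    latent_quality: dict[int, np.ndarray]  # year -> layer in [0, 1]
    dominant_driver: dict[str, str]  # section -> driver name
    effect_signs: dict[str, dict[str, int]]  # section -> driver -> sign
    planted_slope: dict[str, float]  # section -> latent units per decade
    seed: int


def make_corridor(config: SyntheticConfig) -> CorridorScene:
    """Build corridor geometry: centerline along the grid's long axis,
    a bilateral buffer, contiguous distance belts, and a two-section
    split at the centerline's arc-length midpoint (first half = north).
    """
    grid = config.grid
    buffer_m = config.buffer_km * 1000.0
    need = int(np.ceil(2 * buffer_m / config.pixel_size)) + 1
    cross = min(grid.shape)
    if cross < need:
        raise GridTooSmallError(
            f"grid cross-section of {cross} pixels cannot contain a "
            f"{config.buffer_km} km bilateral buffer; need >= {need} pixels"
        )

    nrows, ncols = grid.shape
    ps = grid.pixel_size
    if ncols >= nrows:  # centerline runs left-to-right through the middle
        y_mid = nrows * ps / 2.0
        centerline = LineString([(0.0, y_mid), (ncols * ps, y_mid)])
    else:  # runs top-to-bottom
        x_mid = ncols * ps / 2.0
        centerline = LineString([(x_mid, 0.0), (x_mid, nrows * ps)])

    x, y = grid.pixel_centers()
    points = shapely.points(x.ravel(), y.ravel())
    distance = shapely.distance(points, centerline).reshape(grid.shape)
    along = shapely.line_locate_point(centerline, points).reshape(grid.shape)

    buffer_mask = distance <= buffer_m
    n_belts = int(np.ceil(buffer_m / config.belt_m))
    belt = np.ceil(distance / config.belt_m).astype(np.int32)
    belt = np.clip(belt, 1, n_belts)
    belt[~buffer_mask] = 0

    section_code = np.where(along < centerline.length / 2.0, NORTH, SOUTH).astype(np.int8)
    water_mask = distance < ps / 2.0
    return CorridorScene(
        grid=grid,
        centerline=centerline,
        distance=distance,
        buffer_mask=buffer_mask,
        belt_id=belt,
        section_code=section_code,
        water_mask=water_mask,
        n_belts=n_belts,
    )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Unit-variance Gaussian random field (white noise if scale == 0)."""
    noise = rng.standard_normal(shape)
    if scale <= 0:
        return noise
    smoothed = gaussian_filter(noise, sigma=scale, mode="reflect")
    sd = smoothed.std()
    return smoothed / sd if sd > 0 else smoothed


def _section_centered(field_layer: np.ndarray, section_code: np.ndarray) -> np.ndarray:
    """Remove the per-section sample mean so section means are exact."""
    out = field_layer.copy()
    for code in (NORTH, SOUTH):
        mask = section_code == code
        if mask.any():
            out[mask] -= out[mask].mean()
    return out


def simulate_drivers(config: SyntheticConfig, corridor: CorridorScene) -> DriverStack:
    """Spatially autocorrelated driver fields with section-specific means.

    Topographic layers are static (identical across epochs); other
    drivers get per-epoch perturbations only when ``epoch_drift_sd`` is
    positive.  Land use is derived categorically: a canal water strip,
    built-up clustered where nighttime light is high, and
    forest/grassland/cropland from a vegetation field.
    """
    rng_root = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    shape = config.grid.shape
    section = corridor.section_code
    params = config.driver_params

    base_fields = {
        name: _section_centered(_smooth_field(rng_root, shape, config.smoothing_scale), section)
        for name in DRIVER_NAMES
        if name != "land_use"
    }
    veg_field = _section_centered(_smooth_field(rng_root, shape, config.smoothing_scale), section)

    nonneg = {"slope", "precipitation", "nighttime_light", "gdp", "population"}
    layers: dict[int, dict[str, np.ndarray]] = {}
    for epoch in config.epoch_years:
        epoch_layers: dict[str, np.ndarray] = {}
        for name in DRIVER_NAMES:
            if name == "land_use":
                continue
            g = base_fields[name]
            if name not in STATIC_DRIVERS and config.epoch_drift_sd > 0:
                drift = _section_centered(
                    _smooth_field(rng_root, shape, config.smoothing_scale), section
                )
                g = g + config.epoch_drift_sd * drift
            north_mean, south_mean, sd = params[name]
            mean = np.where(section == NORTH, north_mean, south_mean)
            layer = mean + sd * g
            if name == "aspect":
                layer = np.mod(layer, 360.0)
            elif name in nonneg:
                layer = np.clip(layer, 0.0, None)
            epoch_layers[name] = layer

        ntl = epoch_layers["nighttime_light"]
        land = np.full(shape, 1, dtype=np.int32)  # cropland default
        land[veg_field > 1.0] = 2  # forest
        land[(veg_field > 0.3) & (veg_field <= 1.0)] = 3  # grassland
        for code in (NORTH, SOUTH):  # built-up where NTL is locally high
            mask = section == code
            land[mask & (ntl >= np.quantile(ntl[mask], 0.85))] = 5
        land[corridor.water_mask] = 4  # the canal itself
        epoch_layers["land_use"] = land
        layers[epoch] = epoch_layers

    return DriverStack(grid=config.grid, layers=layers, epoch_years=tuple(config.epoch_years))


def _driver_numeric(name: str, layer: np.ndarray) -> np.ndarray:
    if name == "land_use":
        out = np.zeros(layer.shape)
        for code, intensity in LAND_USE_INTENSITY.items():
            out[layer == code] = intensity
        return out
    return np.asarray(layer, dtype=float)


def latent_quality(
    config: SyntheticConfig,
    corridor: CorridorScene,
    drivers: DriverStack,
    rng: np.random.Generator | None = None,
) -> dict[int, np.ndarray]:
    """Per-year latent quality q in [0, 1].

    q = section base (0.5 -/+ gap/2 for north/south)
        + amplitude * sum over drivers of effect * section-z-scored driver
        + planted slope * (decades since 2000, centred over the year span)
        + iid noise, clipped to [0, 1].

    Centring the trend term over the configured years keeps the
    long-term mean section gap equal to ``section_gap`` even with
    unequal planted slopes.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    section = corridor.section_code
    decades = {y: (y - 2000) / 10.0 for y in config.years}
    mean_decade = float(np.mean(list(decades.values())))

    if all(e == 0 for e in list(config.north_effects.values()) + list(config.south_effects.values())):
        warnings.warn("all driver effect sizes are zero; attribution recovery is untestable", stacklevel=2)

    out: dict[int, np.ndarray] = {}
    for year in config.years:
        year_drivers = drivers.for_year(year)
        q = np.empty(config.grid.shape)
        for sec_name, code, sign in (("north", NORTH, -1), ("south", SOUTH, +1)):
            mask = section == code
            # standardise against the buffered part of the section so the
            # planted gap is exact over the analysis domain
            ref = mask & corridor.buffer_mask
            if not ref.any():
                ref = mask
            base = 0.5 + sign * config.section_gap / 2.0
            contrib = np.zeros(mask.sum())
            for driver, effect in config.effects(sec_name).items():
                numeric = _driver_numeric(driver, year_drivers[driver])
                sd = numeric[ref].std()
                if sd > 0:
                    contrib += (
                        config.effect_amplitude * effect * (numeric[mask] - numeric[ref].mean()) / sd
                    )
            trend = config.trend_slopes.get(sec_name, 0.0) * (decades[year] - mean_decade)
            q[mask] = base + contrib + trend
        if config.noise_sd > 0:
            q = q + rng.normal(0.0, config.noise_sd, size=q.shape)
        out[year] = np.clip(q, 0.0, 1.0)
    return out


def bands_from_quality(
    q: np.ndarray,
    q_wet: np.ndarray | None = None,
    q_lst: np.ndarray | None = None,
    q_dry: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Construct reflectance bands and LST digital numbers from latent quality.

    The construction makes NDVI (driven by ``q``) and tasseled-cap
    wetness (driven by ``q_wet``) exactly affine increasing, LST (from
    ``q_lst``) exactly affine decreasing, and the dryness indices (SI,
    IBI, from ``q_dry``) monotone decreasing.  The per-index quality
    variants default to ``q`` itself, giving a perfectly rank-1 scene.
    """
    q_wet = q if q_wet is None else q_wet
    q_lst = q if q_lst is None else q_lst
    q_dry = q if q_dry is None else q_dry
    ndvi_t = 0.1 + 0.8 * q
    wet_t = -0.15 + 0.25 * q_wet
    b2 = 0.35 + 0.10 * q
    b1 = b2 * (1.0 - ndvi_t) / (1.0 + ndvi_t)
    b3 = 0.5 * b1
    b5 = np.full(q.shape, 0.30)
    b6 = 0.30 - 0.18 * q_dry
    b7 = 0.25 - 0.15 * q_dry
    c = WETNESS_COEFFS
    b4 = (wet_t - (c[0] * b1 + c[1] * b2 + c[2] * b3 + c[4] * b5 + c[5] * b6 + c[6] * b7)) / c[3]
    lst_c = 35.0 - 20.0 * q_lst
    lst_dn = (lst_c + 273.15) / 0.02
    bands = {"B1": b1, "B2": b2, "B3": b3, "B4": b4, "B5": b5, "B6": b6, "B7": b7}
    return bands, lst_dn


def simulate_monthly_scenes(
    config: SyntheticConfig, quality: dict[int, np.ndarray]
) -> dict[int, list[AnnualScene]]:
    """Growing-season monthly scenes per year (annual bands + monthly noise)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    if config.index_disagreement_sd > 0:
        field_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 304]))
        a = config.index_disagreement_sd
        disagreement = [
            a * _smooth_field(field_rng, config.grid.shape, config.smoothing_scale)
            for _ in range(3)
        ]
    else:
        disagreement = [0.0, 0.0, 0.0]
    out: dict[int, list[AnnualScene]] = {}
    for year in config.years:
        q = quality[year]
        bands, lst_dn = bands_from_quality(
            q,
            q_wet=np.clip(q + disagreement[0], 0.0, 1.0),
            q_lst=np.clip(q + disagreement[1], 0.0, 1.0),
            q_dry=np.clip(q + disagreement[2], 0.0, 1.0),
        )
        months = []
        for _ in range(config.n_months):
            if config.monthly_noise_sd > 0:
                mb = {
                    name: np.clip(
                        layer + rng.normal(0.0, config.monthly_noise_sd, layer.shape), 0.0, 1.0
                    )
                    for name, layer in bands.items()
                }
                mdn = lst_dn + rng.normal(0.0, config.monthly_noise_sd * 50.0, lst_dn.shape)
            else:
                mb = {name: layer.copy() for name, layer in bands.items()}
                mdn = lst_dn.copy()
            months.append(AnnualScene(bands=mb, lst_dn=mdn, year=year))
        out[year] = months
    return out


def simulate_scenes(
    config: SyntheticConfig, corridor: CorridorScene, drivers: DriverStack
) -> tuple[list[AnnualScene], SyntheticTruth]:
    """Composited annual scenes plus the planted-truth oracle."""
    quality = latent_quality(config, corridor, drivers)
    monthly = simulate_monthly_scenes(config, quality)
    scenes = [growing_season_composite(monthly[year]) for year in config.years]
    dominant = {
        sec: max(config.effects(sec), key=lambda d: abs(config.effects(sec)[d]))
        for sec in SECTIONS
        if config.effects(sec)
    }
    truth = SyntheticTruth(
        latent_quality=quality,
        dominant_driver=dominant,
        effect_signs={
            sec: {d: int(np.sign(e)) for d, e in config.effects(sec).items()} for sec in SECTIONS
        },
        planted_slope=dict(config.trend_slopes),
        seed=config.seed,
    )
    return scenes, truth


def simulate(config: SyntheticConfig):
    """One-call generator: corridor, drivers, scenes, truth."""
    corridor = make_corridor(config)
    drivers = simulate_drivers(config, corridor)
    scenes, truth = simulate_scenes(config, corridor, drivers)
    return corridor, drivers, scenes, truth
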