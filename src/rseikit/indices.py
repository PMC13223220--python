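"""The four RSEI component indices and their normalisation.

Band roles follow a fixed registry: B1 red, B2 near-infrared, B3 blue,
B4 green, B5 near-infrared 2, B6 shortwave-infrared 1, B7
shortwave-infrared 2.  Reflectance layers are expected on a 0-1 scale;
readers apply product scale factors before these operators see data.

All operators are pixelwise and mask-preserving: the output nodata set
is the union of the input nodata sets plus any pixel where the formula
is undefined (zero denominators).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from rseikit.raster import check_congruent

BAND_ROLES = {
    "B1": "red",
    "B2": "nir",
    "B3": "blue",
    "B4": "green",
    "B5": "nir2",
    "B6": "swir1",
    "B7": "swir2",
}
BAND_NAMES = tuple(BAND_ROLES)

#: Tasseled-cap wetness coefficients for bands B1..B7.
WETNESS_COEFFS = (0.1147, 0.2489, 0.2408, 0.3132, -0.3122, -0.6416, -0.5087)

LST_SCALE = 0.02
LST_OFFSET = -273.15


class DegenerateLayerError(ValueError):
    """Raised when a layer has no spread (or too few valid pixels)."""


@dataclass
class AnnualScene:
    """One year's composited reflectance bands plus LST digital numbers."""

    bands: dict[str, np.ndarray]
    lst_dn: np.ndarray
    year: int

    def __post_init__(self) -> None:
        missing = set(BAND_NAMES) - set(self.bands)
        if missing:
            raise ValueError(f"scene missing bands: {sorted(missing)}")
        check_congruent(*self.bands.values(), self.lst_dn)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands["B1"].shape

    def band(self, name: str) -> np.ndarray:
        return self.bands[name]


@dataclass
class IndexLayers:
    """Raw component indices for one year."""

    ndvi: np.ndarray
    wet: np.ndarray
    lst: np.ndarray  # degrees Celsius
    si: np.ndarray
    ibi: np.ndarray
    ndbsi: np.ndarray
    year: int


@dataclass
class NormalizedIndices:
    """Min-max scaled components, with the statistics that were used."""

    ndvi: np.ndarray
    wet: np.ndarray
    lst: np.ndarray
    ndbsi: np.ndarray
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    year: int = 0

    def stack(self) -> np.ndarray:
        """(4, rows, cols) array in the fixed order NDVI, WET, LST, NDBSI."""
        return np.stack([self.ndvi, self.wet, self.lst, self.ndbsi])


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = np.isfinite(num) & np.isfinite(den) & (den != 0)
    out[ok] = num[ok] / den[ok]
    return out


def ndvi(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """Normalized difference vegetation index (NIR - red) / (NIR + red)."""
    check_congruent(red, nir)
    return _safe_ratio(nir - red, nir + red)


def lst_celsius(dn: np.ndarray) -> np.ndarray:
    """Decode LST digital numbers to degrees Celsius (DN * 0.02 - 273.15)."""
    dn = np.asarray(dn, dtype=float)
    out = dn * LST_SCALE + LST_OFFSET
    out[dn < 0] = np.nan
    return out


def soil_index(b1: np.ndarray, b6: np.ndarray, b2: np.ndarray, b3: np.ndarray) -> np.ndarray:
    """Bare-soil index SI = ((B1+B6) - (B2+B3)) / ((B1+B6) + (B2+B3))."""
    check_congruent(b1, b6, b2, b3)
    a = b1 + b6
    b = b2 + b3
    return _safe_ratio(a - b, a + b)


def ibi(b1: np.ndarray, b2: np.ndarray, b4: np.ndarray, b6: np.ndarray) -> np.ndarray:
    """Index-based built-up index.

    IBI = (A - B) / (A + B) with A = 2*B6/(B2+B6) and
    B = B2/(B1+B2) + B4/(B4+B6); nodata wherever an inner or outer
    denominator vanishes.
    """
    check_congruent(b1, b2, b4, b6)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = 2.0 * b6 / (b2 + b6)
        b = b2 / (b1 + b2) + b4 / (b4 + b6)
    bad = (b2 + b6 == 0) | (b1 + b2 == 0) | (b4 + b6 == 0)
    out = _safe_ratio(a - b, a + b)
    out[bad] = np.nan
    return out


def ndbsi(si_layer: np.ndarray, ibi_layer: np.ndarray) -> np.ndarray:
    """Dryness component: elementwise mean of SI and IBI."""
    check_congruent(si_layer, ibi_layer)
    return (si_layer + ibi_layer) / 2.0


def wetness(*bands: np.ndarray) -> np.ndarray:
    """Tasseled-cap wetness: fixed linear combination of bands B1..B7."""
    if len(bands) != 7:
        raise ValueError(f"wetness needs 7 bands, got {len(bands)}")
    check_congruent(*bands)
    out = np.zeros(np.asarray(bands[0]).shape)
    for coeff, band in zip(WETNESS_COEFFS, bands):
        out = out + coeff * np.asarray(band, dtype=float)
    return out


def growing_season_composite(monthly_scenes: list[AnnualScene]) -> AnnualScene:
    """Per-pixel mean over monthly scenes, ignoring nodata months.

    A pixel with zero valid months is nodata in the composite.
    """
    if not monthly_scenes:
        raise ValueError("need at least one monthly scene")
    years = {s.year for s in monthly_scenes}
    if len(years) != 1:
        raise ValueError(f"scenes span multiple years: {sorted(years)}")
    check_congruent(*(s.bands["B1"] for s in monthly_scenes))

    def nanmean(stack: list[np.ndarray]) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels
            return np.nanmean(np.stack(stack), axis=0)

    bands = {name: nanmean([s.bands[name] for s in monthly_scenes]) for name in BAND_NAMES}
    lst_dn = nanmean([np.where(s.lst_dn < 0, np.nan, s.lst_dn) for s in monthly_scenes])
    return AnnualScene(bands=bands, lst_dn=lst_dn, year=years.pop())


def minmax_normalize(layer: np.ndarray, mask: np.ndarray | None = None):
    """Scale a layer to [0, 1] by its min/max over valid (masked) pixels.

    Returns ``(scaled_layer, (lo, hi))``.  Pixels outside ``mask`` are
    nodata in the output.  A constant layer is a degenerate input.
    """
    layer = np.asarray(layer, dtype=float)
    if mask is None:
        mask = np.ones(layer.shape, dtype=bool)
    valid = mask & np.isfinite(layer)
    if valid.sum() < 2:
        raise DegenerateLayerError("fewer than 2 valid pixels to normalize")
    lo = float(layer[valid].min())
    hi = float(layer[valid].max())
    if hi == lo:
        raise DegenerateLayerError("constant layer has zero range")
    out = np.full(layer.shape, np.nan)
    out[valid] = (layer[valid] - lo) / (hi - lo)
    return out, (lo, hi)


def compute_indices(scene: AnnualScene) -> IndexLayers:
    """All component indices for one composited scene."""
    b = scene.bands
    si_layer = soil_index(b["B1"], b["B6"], b["B2"], b["B3"])
    ibi_layer = ibi(b["B1"], b["B2"], b["B4"], b["B6"])
    return IndexLayers(
        ndvi=ndvi(b["B1"], b["B2"]),
        wet=wetness(*(b[name] for name in BAND_NAMES)),
        lst=lst_celsius(scene.lst_dn),
        si=si_layer,
        ibi=ibi_layer,
        ndbsi=ndbsi(si_layer, ibi_layer),
        year=scene.year,
    )


def normalize_indices(idx: IndexLayers, mask: np.ndarray | None = None) -> NormalizedIndices:
    """Min-max scale the four PCA inputs within the analysis mask."""
    layers = {"ndvi": idx.ndvi, "wet": idx.wet, "lst": idx.lst, "ndbsi": idx.ndbsi}
    scaled, stats = {}, {}
    for name, layer in layers.items():
        scaled[name], stats[name] = minmax_normalize(layer, mask)
    return NormalizedIndices(year=idx.year, stats=stats, **scaled)
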