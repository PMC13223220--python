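"""Distribution and temporal-trend statistics.

Gaussian kernel density estimation with Silverman's default bandwidth,
Theil-Sen slopes, Mann-Kendall with tie and continuity corrections,
the Pettitt change-point test, OLS trends, per-pixel trend maps, and
year-over-year differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from rseikit.raster import check_congruent
from rseikit.synthetic import SECTIONS, CorridorScene


@dataclass
class KdeResult:
    x: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int
    kernel: str = "gaussian"

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.x))


@dataclass
class TrendStats:
    sen_slope: float  # units per year
    mk_S: int
    mk_tau: float
    mk_p: float
    ols_slope: float  # units per year
    ols_p: float
    ols_r2: float
    pettitt_K: int
    pettitt_year: int | float
    pettitt_p: float
    delta_series: np.ndarray

    @property
    def sen_slope_decade(self) -> float:
        return 10.0 * self.sen_slope

    @property
    def ols_slope_decade(self) -> float:
        return 10.0 * self.ols_slope


@dataclass
class PixelTrendMap:
    slope_decade: np.ndarray  # per-pixel Sen slope, units per decade
    trend_class: np.ndarray  # -1 degrading, 0 stable, +1 improving, nodata = -128
    improving_percent: float
    stable_percent: float
    degrading_percent: float


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def kde(
    values: np.ndarray,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
    grid_size: int = 512,
) -> KdeResult:
    """Gaussian kernel density estimate f(x) = (nh)^-1 sum K((x - x_i)/h)."""
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    n = values.size
    if n < 2:
        raise ValueError("kde needs at least 2 finite values")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(values)
        if bandwidth <= 0:
            raise ValueError("zero-variance sample: supply an explicit bandwidth")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        lo = values.min() - 5.0 * bandwidth
        hi = values.max() + 5.0 * bandwidth
        grid = np.linspace(lo, hi, grid_size)
    grid = np.asarray(grid, dtype=float)
    density = np.zeros(grid.size)
    # chunk the sample axis to bound memory on large rasters
    for start in range(0, n, 65536):
        chunk = values[start : start + 65536]
        u = (grid[:, None] - chunk[None, :]) / bandwidth
        density += np.exp(-0.5 * u * u).sum(axis=1)
    density /= n * bandwidth * np.sqrt(2.0 * np.pi)
    return KdeResult(x=grid, density=density, bandwidth=float(bandwidth), n=n)


def _as_series(series) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        years, values = arr[:, 0], arr[:, 1]
    elif arr.ndim == 1:
        years, values = np.arange(arr.size, dtype=float), arr
    else:
        raise ValueError("series must be 1-D values or (year, value) pairs")
    order = np.argsort(years, kind="stable")
    return years[order], values[order]


def sens_slope(series) -> float:
    """Theil-Sen estimator: median of all pairwise slopes, units per year."""
    years, values = _as_series(series)
    if np.unique(years).size < 2:
        raise ValueError("sens_slope needs >= 2 distinct years")
    i, j = np.triu_indices(years.size, k=1)
    dy = values[j] - values[i]
    dx = years[j] - years[i]
    ok = dx != 0
    return float(np.median(dy[ok] / dx[ok]))


def mann_kendall(series) -> tuple[int, float, float]:
    """Mann-Kendall trend test.

    Returns (S, tau, p).  tau uses the tie-corrected denominator; the
    p-value uses the normal approximation with tie-corrected variance
    and a continuity correction.
    """
    years, values = _as_series(series)
    n = values.size
    if n < 4:
        raise ValueError("mann_kendall needs n >= 4")
    i, j = np.triu_indices(n, k=1)
    s = int(np.sign(values[j] - values[i]).sum())

    _, tie_counts = np.unique(values, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    n_pairs = n * (n - 1) / 2.0
    tie_pairs = (ties * (ties - 1) / 2.0).sum()
    denom = np.sqrt((n_pairs - tie_pairs) * n_pairs)
    tau = s / denom if denom > 0 else 0.0

    var_s = (n * (n - 1) * (2 * n + 5) - (ties * (ties - 1) * (2 * ties + 5)).sum()) / 18.0
    if var_s <= 0:
        return s, float(tau), 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, float(tau), float(p)


def pettitt(series) -> tuple[int, float, float]:
    """Pettitt single change-point test.

    U_t = sum_{i<=t} sum_{j>t} sign(x_j - x_i); K = max_t |U_t|.  The
    change point is reported as the year at the argmax t, i.e. the last
    year of the first regime.  p ~= 2 exp(-6 K^2 / (n^3 + n^2)),
    clipped to 1.
    """
    years, values = _as_series(series)
    n = values.size
    if n < 4:
        raise ValueError("pettitt needs n >= 4")
    # U_t via the cumulative rank identity: U_t = 2 * sum_{i<=t} r_i - t*(n+1),
    # where r_i are midranks of the full sample.
    ranks = stats.rankdata(values)
    u = 2.0 * np.cumsum(ranks[:-1]) - (np.arange(1, n) * (n + 1))
    t_idx = int(np.argmax(np.abs(u)))
    k = int(round(abs(u[t_idx])))
    p = min(1.0, 2.0 * np.exp(-6.0 * k * k / (n**3 + n**2)))
    return k, float(years[t_idx]), float(p)


def ols_trend(series) -> tuple[float, float, float]:
    """Least-squares slope vs year; returns (slope per year, p, R^2)."""
    years, values = _as_series(series)
    if values.size < 3:
        raise ValueError("ols_trend needs n >= 3")
    res = stats.linregress(years, values)
    return float(res.slope), float(res.pvalue), float(res.rvalue**2)


def delta_series(series) -> np.ndarray:
    """Year-over-year differences (length n - 1)."""
    _, values = _as_series(series)
    if values.size < 2:
        raise ValueError("delta_series needs n >= 2")
    return np.diff(values)


def trend_stats(series) -> TrendStats:
    """The full trend suite on one time series."""
    years, values = _as_series(series)
    s, tau, mk_p = mann_kendall(np.column_stack([years, values]))
    slope, ols_p, r2 = ols_trend(np.column_stack([years, values]))
    k, change_year, pet_p = pettitt(np.column_stack([years, values]))
    return TrendStats(
        sen_slope=sens_slope(np.column_stack([years, values])),
        mk_S=s,
        mk_tau=tau,
        mk_p=mk_p,
        ols_slope=slope,
        ols_p=ols_p,
        ols_r2=r2,
        pettitt_K=k,
        pettitt_year=change_year,
        pettitt_p=pet_p,
        delta_series=delta_series(np.column_stack([years, values])),
    )


def subperiod_trends(series, split_year: int = 2010) -> tuple[TrendStats, TrendStats]:
    """Trend suite on [first..split_year] and [split_year+1..last]."""
    years, values = _as_series(series)
    first = years <= split_year
    second = ~first
    if first.sum() < 4 or second.sum() < 4:
        raise ValueError(
            f"split at {split_year} leaves sub-periods of {int(first.sum())} and "
            f"{int(second.sum())} years; need >= 4 each"
        )
    return (
        trend_stats(np.column_stack([years[first], values[first]])),
        trend_stats(np.column_stack([years[second], values[second]])),
    )


def _pixel_sen_slopes(stack: np.ndarray, years: np.ndarray) -> np.ndarray:
    """Vectorised per-pixel Theil-Sen slope; stack is (T, n_pixels)."""
    t = years.size
    i, j = np.triu_indices(t, k=1)
    dx = (years[j] - years[i])[:, None]
    dy = stack[j, :] - stack[i, :]
    return np.median(dy / dx, axis=0)


def pixel_trends(
    rsei_by_year: dict[int, np.ndarray],
    corridor: CorridorScene | None = None,
    stable_band: float = 0.005,
    section: str | None = None,
) -> PixelTrendMap:
    """Per-pixel Sen-slope map with improving/stable/degrading classes.

    ``stable_band`` is in RSEI per decade: pixels with |slope| <= band
    are stable.  Percentages are over valid (optionally section-masked)
    pixels.
    """
    if len(rsei_by_year) < 3:
        raise ValueError("pixel_trends needs >= 3 years")
    years = np.array(sorted(rsei_by_year), dtype=float)
    layers = [rsei_by_year[int(y)] for y in years]
    check_congruent(*layers)
    shape = layers[0].shape

    mask = np.isfinite(np.stack(layers)).all(axis=0)
    if corridor is not None:
        mask &= corridor.buffer_mask
        if section is not None:
            mask &= corridor.section_mask(section)
    if not mask.any():
        raise ValueError("no valid pixels for trend mapping")

    stack = np.stack([layer[mask] for layer in layers])
    slopes_decade = 10.0 * _pixel_sen_slopes(stack, years)

    slope_layer = np.full(shape, np.nan)
    slope_layer[mask] = slopes_decade
    classes = np.full(shape, -128, dtype=np.int8)
    classes[mask] = np.where(
        slopes_decade > stable_band, 1, np.where(slopes_decade < -stable_band, -1, 0)
    )
    n = mask.sum()
    return PixelTrendMap(
        slope_decade=slope_layer,
        trend_class=classes,
        improving_percent=100.0 * float((classes == 1).sum()) / n,
        stable_percent=100.0 * float((classes == 0).sum()) / n,
        degrading_percent=100.0 * float((classes == -1).sum()) / n,
    )


def section_trend_report(
    rsei_by_year: dict[int, np.ndarray], corridor: CorridorScene, split_year: int = 2010
):
    """TrendStats per section on annual section means, plus sub-periods."""
    from rseikit.corridor import annual_section_means

    annual = annual_section_means(rsei_by_year, corridor)
    report = {}
    for sec in SECTIONS:
        sub = annual[annual["section"] == sec]
        series = np.column_stack([sub["year"].to_numpy(float), sub["mean"].to_numpy()])
        entry = {"full": trend_stats(series)}
        try:
            entry["early"], entry["late"] = subperiod_trends(series, split_year)
        except ValueError:
            pass
        report[sec] = entry
    return report
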