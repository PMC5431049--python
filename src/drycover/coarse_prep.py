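"""Preparation of coarse-resolution (MODIS-like) composite time series.

The raw inputs are two 16-day composite streams (Terra-like and Aqua-like,
offset by 8 days) of six signals (NDVI, EVI, blue, red, NIR, SWIR) with a
per-observation reliability flag and a per-pixel compositing day of year.
The pipeline is:

    merge_terra_aqua -> screen_reliability -> stl_outlier_removal
        -> savitzky_golay_smooth -> seasonal_statistics

yielding 90 per-pixel predictors: 6 signals x 3 seasons (spring, summer,
autumn) x 5 statistics (mean, min, max, range, sd).

Outlier screening decomposes each gridded series with a seasonal-trend
decomposition based on loess (STL) and removes observations whose remainder
exceeds ``k_sd`` robust standard deviations. The non-robust STL is an
exactly linear map of the input series, so it is applied to whole rasters
through a cached remainder operator built from decompositions of identity
columns; a per-series robust variant is available via ``robust=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from statsmodels.tsa.seasonal import STL

log = logging.getLogger(__name__)

COARSE_SIGNALS: tuple[str, ...] = ("ndvi", "evi", "blue", "red", "nir", "swir")

# reliability flags
REL_GOOD = 0
REL_MARGINAL = 1
REL_SNOW = 2
REL_CLOUD = 3
REL_NODATA = 4
REL_REMOVED = 255  # excluded by screening / outlier removal

SRC_TERRA = 0
SRC_AQUA = 1
SRC_SMOOTHED = 2

SEASONS: tuple[tuple[str, int, int], ...] = (
    ("spring", 60, 151),   # March-May, non-leap DOY
    ("summer", 152, 243),  # June-August
    ("autumn", 244, 334),  # September-November
)
STAT_NAMES: tuple[str, ...] = ("mean", "min", "max", "range", "sd")


@dataclass
class CoarseSeries:
    """Per-pixel multi-signal time series with reliability flags and DOY.

    Arrays: ``values`` (n_obs, n_signals, rows, cols), ``doy`` and ``flags``
    and ``source`` (n_obs, rows, cols). Excluded observations keep their
    slot but carry flag ``REL_REMOVED`` and NaN values; ``valid_mask``
    reflects the good/marginal observations that downstream steps may read.
    """

    values: np.ndarray
    doy: np.ndarray
    flags: np.ndarray
    source: np.ndarray
    signal_names: tuple[str, ...] = COARSE_SIGNALS

    def __post_init__(self) -> None:
        n_obs = self.values.shape[0]
        if self.values.ndim != 4 or self.values.shape[1] != len(self.signal_names):
            raise ValueError("values must be (n_obs, n_signals, rows, cols)")
        expect = (n_obs, *self.values.shape[2:])
        for name in ("doy", "flags", "source"):
            if getattr(self, name).shape != expect:
                raise ValueError(f"{name} not aligned with values")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[2:]

    def valid_mask(self) -> np.ndarray:
        return self.flags <= REL_MARGINAL

    def n_valid(self) -> np.ndarray:
        return self.valid_mask().sum(axis=0)

    @classmethod
    def single_pixel(
        cls,
        values: np.ndarray,
        doy: np.ndarray,
        flags: np.ndarray | None = None,
        source: np.ndarray | None = None,
        signal_names: tuple[str, ...] | None = None,
    ) -> "CoarseSeries":
        """Wrap 1-D/2-D per-observation arrays as a 1x1-pixel series."""
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        n_obs, n_sig = values.shape
        if signal_names is None:
            signal_names = COARSE_SIGNALS[:n_sig]
        doy = np.asarray(doy, dtype=float).reshape(n_obs, 1, 1)
        if flags is None:
            flags = np.zeros(n_obs, dtype=np.uint8)
        flags = np.asarray(flags, dtype=np.uint8).reshape(n_obs, 1, 1)
        if source is None:
            source = np.full(n_obs, SRC_TERRA, dtype=np.uint8)
        source = np.asarray(source, dtype=np.uint8).reshape(n_obs, 1, 1)
        return cls(values.reshape(n_obs, n_sig, 1, 1), doy, flags, source, signal_names)


def _sort_by_doy(series: CoarseSeries) -> CoarseSeries:
    order = np.argsort(series.doy, axis=0, kind="stable")
    take = lambda a: np.take_along_axis(a, order, axis=0)
    values = np.take_along_axis(series.values, order[:, None], axis=0)
    return CoarseSeries(
        values, take(series.doy), take(series.flags), take(series.source),
        series.signal_names,
    )


def merge_terra_aqua(terra: CoarseSeries, aqua: CoarseSeries) -> CoarseSeries:
    """Union of the two streams, per-pixel sorted by DOY.

    Observations from both sensors falling on the same DOY at the same pixel
    are averaged into one observation (the duplicate slot is marked
    ``REL_REMOVED``). Duplicates are merged pairwise, which is exact for the
    two-sensor case.
    """
    if terra.shape != aqua.shape or terra.signal_names != aqua.signal_names:
        raise ValueError("terra and aqua series are not on the same grid")
    if aqua.n_obs == 0:
        return terra
    merged = CoarseSeries(
        np.concatenate([terra.values, aqua.values], axis=0),
        np.concatenate([terra.doy, aqua.doy], axis=0),
        np.concatenate([terra.flags, aqua.flags], axis=0),
        np.concatenate([terra.source, aqua.source], axis=0),
        terra.signal_names,
    )
    merged = _sort_by_doy(merged)
    valid = merged.valid_mask()
    dup = (merged.doy[1:] == merged.doy[:-1]) & valid[1:] & valid[:-1]
    if dup.any():
        pair = (merged.values[:-1] + merged.values[1:]) / 2.0
        mask = dup[:, None]
        merged.values[:-1] = np.where(mask, pair, merged.values[:-1])
        merged.values[1:] = np.where(mask, np.nan, merged.values[1:])
        merged.flags[1:] = np.where(dup, REL_REMOVED, merged.flags[1:])
    return merged


def screen_reliability(series: CoarseSeries) -> CoarseSeries:
    """Exclude observations flagged no-data, snow/ice, or cloud.

    Good and marginal observations are retained; excluded slots are marked
    ``REL_REMOVED`` with NaN values.
    """
    bad = (series.flags >= REL_SNOW) & (series.flags != REL_REMOVED)
    values = series.values.copy()
    values[np.broadcast_to(bad[:, None], values.shape)] = np.nan
    flags = np.where(bad, REL_REMOVED, series.flags).astype(np.uint8)
    return CoarseSeries(values, series.doy.copy(), flags, series.source.copy(),
                        series.signal_names)


def _slot_index(doy: np.ndarray, step_days: int) -> np.ndarray:
    return np.rint((doy - 1.0) / step_days).astype(np.int64)


def _grid_series(
    series: CoarseSeries, step_days: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Place observations on a regular ``step_days`` grid.

    Returns (grid (n_slots, n_signals, rows, cols) with NaN for empty slots,
    slot index per observation, grid DOY (n_slots,), observed-slot mask).
    Multiple valid observations in one slot are averaged.
    """
    valid = series.valid_mask() & np.isfinite(series.values).all(axis=1)
    slot = _slot_index(series.doy, step_days)
    n_slots = int(slot.max()) + 1 if slot.size else 0
    n_sig = len(series.signal_names)
    rows, cols = series.shape
    grid_sum = np.zeros((n_slots, n_sig, rows, cols))
    grid_cnt = np.zeros((n_slots, rows, cols))
    r_ix, c_ix = np.indices((rows, cols))
    for o in range(series.n_obs):
        v = valid[o]
        s = slot[o][v]
        np.add.at(grid_cnt, (s, r_ix[v], c_ix[v]), 1.0)
        for g in range(n_sig):
            np.add.at(grid_sum, (s, g, r_ix[v], c_ix[v]), series.values[o, g][v])
    observed = grid_cnt > 0
    with np.errstate(invalid="ignore"):
        grid = grid_sum / grid_cnt[:, None]
    grid[np.broadcast_to(~observed[:, None], grid.shape)] = np.nan
    grid_doy = 1.0 + step_days * np.arange(n_slots)
    return grid, slot, grid_doy, observed


def _fill_gaps(grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of NaN slots along axis 0; edges nearest-filled.

    Columns that are entirely NaN remain NaN.
    """
    n = grid.shape[0]
    flat = grid.reshape(n, -1)
    out = flat.copy()
    x = np.arange(n, dtype=float)
    bad_any = np.isnan(flat).any(axis=0)
    for j in np.flatnonzero(bad_any):
        col = flat[:, j]
        ok = np.isfinite(col)
        if not ok.any():
            continue
        out[:, j] = np.interp(x, x[ok], col[ok])  # np.interp clamps edges
    return out.reshape(grid.shape)


@lru_cache(maxsize=8)
def _stl_remainder_operator(n: int, period: int, seasonal: int) -> np.ndarray:
    """Matrix R with R @ y = STL(y).resid for the non-robust decomposition.

    Valid because every step of the non-robust STL (moving averages and
    loess with fixed weights) is linear in the series.
    """
    R = np.empty((n, n))
    e = np.zeros(n)
    for j in range(n):
        e[:] = 0.0
        e[j] = 1.0
        R[:, j] = STL(e, period=period, seasonal=seasonal).fit().resid
    return R


@lru_cache(maxsize=8)
def _loess_remainder_operator(n: int, window: int) -> np.ndarray:
    """Matrix R with R @ y = y - loess(y) for a fixed-x, non-robust loess."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.arange(n, dtype=float)
    frac = min(1.0, window / n)
    R = np.eye(n)
    e = np.zeros(n)
    for j in range(n):
        e[:] = 0.0
        e[j] = 1.0
        R[:, j] -= lowess(e, x, frac=frac, it=0, return_sorted=False)
    return R


def _stl_remainders(
    y: np.ndarray, period: int, seasonal: int, robust: bool
) -> np.ndarray:
    """Remainder component per series; ``y`` is (n_slots, n_series).

    Series spanning at least two full periods get the genuine STL remainder.
    Shorter series (the common single-year case) cannot support a seasonal
    decomposition — replicating the year would make every one-year feature,
    spikes included, exactly periodic and hence invisible to screening — so
    their remainder is taken against a loess trend fit instead (the one-year
    trajectory *is* the seasonal signal); the thresholding rule is
    unchanged.
    """
    n = y.shape[0]
    if n < 2 * period:
        log.info("series spans < 2 periods (%d slots); STL screening falls "
                 "back to a loess-trend remainder", n)
        window = max(5, min(n, int(round(period / 5))) | 1)
        if robust:
            from statsmodels.nonparametric.smoothers_lowess import lowess

            x = np.arange(n, dtype=float)
            rem = np.empty_like(y)
            for j in range(y.shape[1]):
                rem[:, j] = y[:, j] - lowess(y[:, j], x, frac=window / n,
                                             it=3, return_sorted=False)
            return rem
        return _loess_remainder_operator(n, window) @ y
    if robust:
        rem = np.empty_like(y)
        for j in range(y.shape[1]):
            rem[:, j] = STL(y[:, j], period=period, seasonal=seasonal,
                            robust=True).fit().resid
        return rem
    return _stl_remainder_operator(n, period, seasonal) @ y


def stl_outlier_removal(
    series: CoarseSeries,
    period: int | None = None,
    k_sd: float = 3.0,
    step_days: int = 8,
    seasonal: int = 7,
    robust: bool = False,
    min_sd: float = 1e-3,
) -> CoarseSeries:
    """Remove observations with large STL remainders, per signal.

    Each signal's series is placed on the regular ``step_days`` grid (gaps
    linearly interpolated for the decomposition only) and decomposed with
    STL at ``period`` slots per cycle (default: one year). Observations in
    slots whose |remainder| exceeds ``k_sd`` times the robust (MAD-based)
    standard deviation of the pixel's remainders are excluded. ``min_sd``
    floors that standard deviation so that pure decomposition lack-of-fit
    (well below sensor noise) is never flagged.
    """
    if period is None:
        period = int(round(365.0 / step_days))
    grid, slot, _, observed = _grid_series(series, step_days)
    n_slots = grid.shape[0]
    if n_slots < period:
        log.warning("series too short for STL screening (%d < %d slots); skipped",
                    n_slots, period)
        return series
    filled = _fill_gaps(grid)
    rows, cols = series.shape
    n_sig = len(series.signal_names)
    out_flags = series.flags.copy()
    out_values = series.values.copy()
    flat = filled.reshape(n_slots, n_sig * rows * cols)
    all_nan = np.isnan(flat).all(axis=0)
    flat = np.where(np.isnan(flat), 0.0, flat)
    rem = _stl_remainders(flat, period, seasonal, robust)
    rem = rem.reshape(n_slots, n_sig, rows, cols)
    rem[:, all_nan.reshape(n_sig, rows, cols)] = 0.0
    mad = np.median(np.abs(rem - np.median(rem, axis=0)), axis=0)
    sd = np.maximum(1.4826 * mad, min_sd)
    # slot is outlying if flagged for any signal; threshold per signal
    with np.errstate(invalid="ignore"):
        outlier_slot = (np.abs(rem) > (k_sd * sd)[None]).any(axis=1) & observed
    # map outlying slots back to the contributing observations
    obs_outlier = np.take_along_axis(
        outlier_slot, np.clip(slot, 0, n_slots - 1), axis=0
    ) & series.valid_mask()
    if obs_outlier.any():
        out_flags[obs_outlier] = REL_REMOVED
        out_values[np.broadcast_to(obs_outlier[:, None], out_values.shape)] = np.nan
    return CoarseSeries(out_values, series.doy.copy(), out_flags,
                        series.source.copy(), series.signal_names)


@lru_cache(maxsize=8)
def _sg_matrix(n: int, half_window: int, poly_order: int) -> np.ndarray:
    """Savitzky-Golay smoothing matrix on a regular grid of length n.

    Interior rows are the classical symmetric least-squares coefficients;
    near the edges the window shrinks asymmetrically to the available
    points (still a full-rank polynomial fit).
    """
    S = np.zeros((n, n))
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n - 1, i + half_window)
        t = np.arange(lo, hi + 1, dtype=float) - i
        order = min(poly_order, t.size - 1)
        A = np.vander(t, order + 1, increasing=True)
        S[i, lo : hi + 1] = np.linalg.pinv(A)[0]
    return S


def savitzky_golay_smooth(
    series: CoarseSeries,
    half_window: int = 4,
    poly_order: int = 2,
    step_days: int = 8,
) -> CoarseSeries:
    """Gap-fill to the regular grid and smooth with a Savitzky-Golay filter.

    The series is linearly interpolated to the ``step_days`` grid, then each
    grid value is replaced by the local least-squares polynomial (order
    ``poly_order``, window ``2*half_window+1``) evaluated at that point.
    Pixels with fewer than ``poly_order + 1`` valid observations are marked
    missing (all-NaN, flags ``REL_NODATA``).
    """
    if poly_order >= 2 * half_window + 1:
        raise ValueError("poly_order must be < window length")
    grid, _, grid_doy, _ = _grid_series(series, step_days)
    filled = _fill_gaps(grid)
    n_slots = filled.shape[0]
    S = _sg_matrix(n_slots, half_window, poly_order)
    smooth = np.tensordot(S, filled, axes=(1, 0))
    too_few = series.n_valid() < (poly_order + 1)
    smooth[:, :, too_few] = np.nan
    rows, cols = series.shape
    doy = np.broadcast_to(grid_doy[:, None, None], (n_slots, rows, cols)).copy()
    flags = np.where(too_few[None], REL_NODATA, REL_GOOD).astype(np.uint8)
    flags = np.broadcast_to(flags, (n_slots, rows, cols)).copy()
    source = np.full((n_slots, rows, cols), SRC_SMOOTHED, dtype=np.uint8)
    return CoarseSeries(smooth, doy, flags, source, series.signal_names)


@dataclass
class SeasonalFeatureTable:
    """90 per-pixel predictors: 6 signals x 3 seasons x 5 statistics."""

    features: np.ndarray
    names: tuple[str, ...]
    missing: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.names)

    def matrix(self) -> np.ndarray:
        return self.features.reshape(self.n_features, -1).T


def seasonal_statistics(smoothed: CoarseSeries) -> SeasonalFeatureTable:
    """Seasonal summary statistics of the smoothed regular series.

    Per signal and season (spring: Mar-May, summer: Jun-Aug, autumn:
    Sep-Nov, non-leap DOY ranges), the mean, minimum, maximum, range and
    sample standard deviation over the grid points falling in the season.
    A season with no grid points renders the pixel missing.
    """
    grid_doy = smoothed.doy[:, 0, 0]
    mod_doy = 1.0 + (grid_doy - 1.0) % 365.0
    rows, cols = smoothed.shape
    names: list[str] = []
    feats: list[np.ndarray] = []
    missing = np.isnan(smoothed.values).any(axis=(0, 1))
    for g, sig in enumerate(smoothed.signal_names):
        for season, d0, d1 in SEASONS:
            inside = (mod_doy >= d0) & (mod_doy <= d1)
            if not inside.any():
                block = np.full((5, rows, cols), np.nan)
                missing[:] = True
            else:
                v = smoothed.values[inside, g]
                vmin, vmax = v.min(axis=0), v.max(axis=0)
                sd = v.std(axis=0, ddof=1) if v.shape[0] > 1 else np.zeros_like(vmin)
                block = np.stack([v.mean(axis=0), vmin, vmax, vmax - vmin, sd])
            feats.append(block)
            names += [f"{sig}_{season}_{s}" for s in STAT_NAMES]
    features = np.concatenate(feats, axis=0)
    features[:, missing] = np.nan
    return SeasonalFeatureTable(features, tuple(names), missing)


def prepare_seasonal_features(
    terra: CoarseSeries,
    aqua: CoarseSeries,
    half_window: int = 4,
    poly_order: int = 2,
    k_sd: float = 3.0,
    step_days: int = 8,
    robust: bool = False,
) -> SeasonalFeatureTable:
    """Full coarse-preparation pipeline from raw sensor streams to features."""
    series = merge_terra_aqua(terra, aqua)
    series = screen_reliability(series)
    series = stl_outlier_removal(series, k_sd=k_sd, step_days=step_days, robust=robust)
    smoothed = savitzky_golay_smooth(series, half_window, poly_order, step_days)
    return seasonal_statistics(smoothed)
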