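"""Temporal compositing of fine-resolution reflectance stacks.

Three predictor sets are built from a stack of per-date 6-band surface
reflectance images with per-date clear-sky masks:

* ``single_date``: per band, the clear observation closest to a mid-summer
  target day of year (default DOY 210) within one year (6 features);
* ``metrics_1yr``: per band, five spectral-temporal metrics (mean, median,
  standard deviation, 25th and 75th percentile) over all clear observations
  of one year (30 features);
* ``metrics_epoch``: the same five metrics over a multi-year epoch
  (default three years, 30 features).

Metrics summarise the distribution of clear observations and are therefore
insensitive to acquisition order and to values at masked positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FINE_BANDS: tuple[str, ...] = ("blue", "green", "red", "nir", "swir1", "swir2")

# QA codes for the per-acquisition mask
QA_CLEAR = 0
QA_CLOUD = 1
QA_SHADOW = 2
QA_SNOW = 3
QA_FILL = 4  # sensor gaps (e.g. SLC-off stripes)

METRIC_NAMES: tuple[str, ...] = ("mean", "median", "sd", "p25", "p75")


@dataclass
class FineSeriesStack:
    """Per-acquisition 6-band reflectance rasters with QA masks.

    ``bands`` has shape (n_acq, 6, n_rows, n_cols); not-clear positions hold
    NaN sentinels so that any computation that ignores the QA mask poisons
    its output. ``table`` carries one row per acquisition with columns
    date, year, doy, sensor, slc_off, cloud_fraction.
    """

    bands: np.ndarray
    qa: np.ndarray
    table: pd.DataFrame
    band_names: tuple[str, ...] = FINE_BANDS

    def __post_init__(self) -> None:
        if self.bands.ndim != 4 or self.bands.shape[1] != len(self.band_names):
            raise ValueError("bands must have shape (n_acq, n_bands, rows, cols)")
        if self.qa.shape != (self.bands.shape[0], *self.bands.shape[2:]):
            raise ValueError("QA mask not aligned with bands")
        if len(self.table) != self.bands.shape[0]:
            raise ValueError("acquisition table not aligned with bands")

    @property
    def n_acq(self) -> int:
        return self.bands.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[2:]

    def clear_mask(self) -> np.ndarray:
        """Boolean (n_acq, rows, cols): True where the observation is clear."""
        return self.qa == QA_CLEAR

    def subset(self, index: np.ndarray) -> "FineSeriesStack":
        return FineSeriesStack(
            self.bands[index],
            self.qa[index],
            self.table.iloc[index].reset_index(drop=True),
            self.band_names,
        )


@dataclass
class CompositeFeatureTable:
    """Per-pixel predictor rasters with a fixed, documented feature order.

    ``features`` has shape (n_features, rows, cols); ``missing`` flags pixels
    for which the composite could not be formed (no clear observation, or
    fewer than ``min_obs`` for the metric composites).
    """

    features: np.ndarray
    names: tuple[str, ...]
    kind: str  # single_date | metrics_1yr | metrics_epoch
    missing: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.features.shape[0] != len(self.names):
            raise ValueError("feature count does not match names")
        if self.missing.shape != self.features.shape[1:]:
            raise ValueError("missing mask not aligned")

    @property
    def n_features(self) -> int:
        return len(self.names)

    def matrix(self) -> np.ndarray:
        """(n_pixels, n_features) view in row-major pixel order."""
        return self.features.reshape(self.n_features, -1).T


def _year_index(table: pd.DataFrame, years: set[int]) -> np.ndarray:
    return np.flatnonzero(table["year"].isin(sorted(years)).to_numpy())


def single_date_composite(
    stack: FineSeriesStack, target_doy: int = 210, year: int = 2010
) -> CompositeFeatureTable:
    """Best-available-pixel composite around a target day of year.

    Per pixel and band the value of the clear observation whose DOY is
    closest to ``target_doy`` is selected; on equidistant ties the earlier
    acquisition wins. Pixels with no clear observation in ``year`` are
    flagged missing.
    """
    idx = _year_index(stack.table, {year})
    if idx.size == 0:
        raise ValueError(f"no acquisitions in year {year}")
    sub = stack.subset(idx)
    doy = sub.table["doy"].to_numpy()
    # stable sort on distance keeps the earlier acquisition first on ties
    order = np.argsort(np.abs(doy - target_doy), kind="stable")
    clear = sub.clear_mask()[order]  # (n_acq, r, c)
    any_clear = clear.any(axis=0)
    # first clear acquisition in preference order, per pixel
    first = np.argmax(clear, axis=0)  # 0 if none clear; guarded by any_clear
    picked = order[first]
    rows, cols = np.indices(sub.shape)
    out = np.empty((len(FINE_BANDS), *sub.shape), dtype=np.float32)
    for b in range(len(FINE_BANDS)):
        out[b] = sub.bands[picked, b, rows, cols]
    out[:, ~any_clear] = np.nan
    names = tuple(f"{b}_doy{target_doy}" for b in sub.band_names)
    return CompositeFeatureTable(out, names, "single_date", ~any_clear)


def _sorted_stats(values: np.ndarray, n_valid: np.ndarray) -> np.ndarray:
    """Five metrics from NaN-padded, ascending-sorted samples.

    ``values``: (n_obs, n_pix) with each column's valid entries sorted first
    and NaNs at the end; ``n_valid``: (n_pix,) valid counts. Percentiles use
    linear interpolation between closest ranks; sd is the sample (n-1) form.
    Columns with n_valid == 0 yield NaN.
    """

    n_pix = values.shape[1]
    cols = np.arange(n_pix)
    with np.errstate(invalid="ignore", divide="ignore"):
        total = np.nansum(values, axis=0)
        mean = total / n_valid
        dev = values - mean  # NaN rows stay NaN
        ss = np.nansum(dev * dev, axis=0)
        sd = np.sqrt(ss / np.maximum(n_valid - 1, 1))
        sd = np.where(n_valid >= 2, sd, 0.0)
        sd = np.where(n_valid >= 1, sd, np.nan)

    def quantile(q: float) -> np.ndarray:
        h = q * (n_valid - 1)
        lo = np.floor(h).astype(np.int64)
        hi = np.ceil(h).astype(np.int64)
        lo = np.clip(lo, 0, None)
        hi = np.clip(hi, 0, None)
        vlo = values[np.clip(lo, 0, values.shape[0] - 1), cols]
        vhi = values[np.clip(hi, 0, values.shape[0] - 1), cols]
        return vlo + (h - lo) * (vhi - vlo)

    out = np.stack([mean, quantile(0.50), sd, quantile(0.25), quantile(0.75)])
    out[:, n_valid == 0] = np.nan
    return out


def temporal_metrics(
    stack: FineSeriesStack, years: set[int], min_obs: int = 3
) -> CompositeFeatureTable:
    """Spectral-temporal metrics over all clear observations in ``years``.

    Per pixel and band: mean, median, sample sd, 25th and 75th percentile
    (linear interpolation). Pixels with fewer than ``min_obs`` clear
    observations are flagged missing.
    """
    if not years:
        raise ValueError("years must be non-empty")
    present = set(stack.table["year"].unique().tolist())
    if not set(years) <= present:
        raise ValueError(f"years {set(years) - present} not present in stack")
    sub = stack.subset(_year_index(stack.table, set(years)))
    clear = sub.clear_mask()
    n_valid = clear.sum(axis=0).reshape(-1)
    kind = "metrics_1yr" if len(years) == 1 else "metrics_epoch"
    shape = sub.shape
    n_pix = shape[0] * shape[1]
    feats = np.empty((5 * len(FINE_BANDS), n_pix), dtype=np.float32)
    for b, band in enumerate(sub.band_names):
        vals = np.where(clear, sub.bands[:, b], np.nan).reshape(sub.n_acq, n_pix)
        vals = np.sort(vals, axis=0)  # NaNs sort last
        feats[5 * b : 5 * b + 5] = _sorted_stats(vals, n_valid)
    missing = (n_valid < min_obs).reshape(shape)
    feats = feats.reshape(-1, *shape)
    feats[:, missing] = np.nan
    names = tuple(f"{band}_{m}" for band in sub.band_names for m in METRIC_NAMES)
    return CompositeFeatureTable(feats, names, kind, missing)
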