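"""Multi-scale agreement analysis between continuous tree-cover maps.

Harmonizes tree-cover-percent products (a GFC-style 2000 map updated with
loss/gain layers to 2010, a 30%-threshold forest/non-forest translation),
degrades them by block-mean aggregation (e.g. 250 m -> 1 km -> 5 km), and
quantifies agreement per scale with Pearson's r and an ordinary
least-squares slope over pixels where either map reports cover > 0.
Per-zone (country-style) forest percentages complete the comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class TreeCoverMap:
    """Per-pixel tree-cover percent in [0, 100]; NaN marks nodata."""

    cover: np.ndarray
    resolution: str = "native"

    def __post_init__(self) -> None:
        v = self.cover[np.isfinite(self.cover)]
        if v.size and ((v < 0) | (v > 100)).any():
            raise ValueError("tree cover percent outside [0, 100]")


def update_tree_cover(
    tc2000: TreeCoverMap, loss_mask: np.ndarray, gain_mask: np.ndarray
) -> TreeCoverMap:
    """Update a year-2000 tree-cover map with loss and gain layers.

    Pixels labelled as loss are set to 0% cover, pixels labelled as gain to
    100%; where both are set, loss wins (applied last). The share of area
    with >25% cover that was relabelled is reported as a log statistic.
    """
    if loss_mask.shape != tc2000.cover.shape or gain_mask.shape != tc2000.cover.shape:
        raise ValueError("masks are not aligned with the cover map")
    out = tc2000.cover.astype(float).copy()
    out[np.asarray(gain_mask, dtype=bool)] = 100.0
    out[np.asarray(loss_mask, dtype=bool)] = 0.0
    dense = tc2000.cover > 25.0
    if dense.any():
        relabelled = float((dense & (loss_mask | gain_mask)).sum() / dense.sum())
        log.info("update_tree_cover: %.1f%% of the >25%% cover area relabelled",
                 100.0 * relabelled)
    return TreeCoverMap(out, tc2000.resolution)


def threshold_forest(cover: TreeCoverMap, threshold_pct: float = 30.0) -> np.ndarray:
    """Binary forest map: forest iff cover strictly exceeds the threshold.

    Returns a float array with 1.0 (forest), 0.0 (non-forest) and NaN where
    the cover map has nodata.
    """
    if not 0.0 <= threshold_pct <= 100.0:
        raise ValueError("threshold must be in [0, 100]")
    out = np.where(cover.cover > threshold_pct, 1.0, 0.0)
    out[~np.isfinite(cover.cover)] = np.nan
    return out


def aggregate_mean(raster: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean aggregation by an integer factor, nodata-aware.

    Each factor x factor window is replaced by the mean of its valid cells;
    all-nodata windows stay nodata. Trailing rows/columns that do not fill a
    whole window are dropped.
    """
    if factor < 2:
        raise ValueError("factor must be >= 2")
    rows, cols = raster.shape
    if factor > rows or factor > cols:
        raise ValueError("factor exceeds raster size")
    rr, cc = rows // factor, cols // factor
    trimmed = raster[: rr * factor, : cc * factor].astype(float)
    blocks = trimmed.reshape(rr, factor, cc, factor)
    valid = np.isfinite(blocks)
    n = valid.sum(axis=(1, 3))
    total = np.where(valid, blocks, 0.0).sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        out = total / n
    out[n == 0] = np.nan
    return out


@dataclass
class AgreementReport:
    """Pearson r and OLS slope per aggregation scale."""

    table: pd.DataFrame  # index: factor; columns: pearson_r, slope, intercept, n

    def metric(self, factor: int, name: str) -> float:
        return float(self.table.loc[factor, name])


def _pearson_and_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    mx, my = x.mean(), y.mean()
    dx, dy = x - mx, y - my
    sxx = float((dx * dx).sum())
    sxy = float((dx * dy).sum())
    syy = float((dy * dy).sum())
    if sxx == 0 or syy == 0:
        return float("nan"), float("nan"), float("nan")
    slope = sxy / sxx
    return sxy / np.sqrt(sxx * syy), slope, my - slope * mx


def agreement(
    map_a: np.ndarray,
    map_b: np.ndarray,
    factors: tuple[int, ...] = (1, 4, 20),
    direction: str = "b_on_a",
) -> AgreementReport:
    """Agreement between two cover maps across aggregation scales.

    At each scale the comparison pools pixels where either map reports
    cover > 0 (union mask) and both are valid, and reports Pearson's r and
    the OLS slope. ``direction='b_on_a'`` (default) regresses map B on map
    A (A in the reference role); ``'a_on_b'`` swaps the roles.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps are not aligned")
    if direction not in ("b_on_a", "a_on_b"):
        raise ValueError("direction must be 'b_on_a' or 'a_on_b'")
    rows = {}
    for factor in factors:
        if factor == 1:
            a, b = map_a.astype(float), map_b.astype(float)
        else:
            a, b = aggregate_mean(map_a, factor), aggregate_mean(map_b, factor)
        ok = np.isfinite(a) & np.isfinite(b) & ((a > 0) | (b > 0))
        n = int(ok.sum())
        if n <= 2:
            raise ValueError(f"fewer than 3 comparable pixels at factor {factor}")
        x, y = (a[ok], b[ok]) if direction == "b_on_a" else (b[ok], a[ok])
        r, slope, intercept = _pearson_and_slope(x, y)
        rows[factor] = {"pearson_r": r, "slope": slope,
                        "intercept": intercept, "n": n}
    table = pd.DataFrame(rows).T
    table.index.name = "factor"
    return AgreementReport(table)


def zonal_forest_percent(forest: np.ndarray, zones: np.ndarray) -> pd.DataFrame:
    """Per-zone forest percentage.

    ``forest`` may be binary (0/1) or fractional in [0, 1]; the zonal value
    is 100 x the mean over valid cells of the zone. Zones are any integer
    raster; NaN forest cells are excluded from the zone area.
    """
    if forest.shape != zones.shape:
        raise ValueError("zone raster not aligned")
    df = pd.DataFrame({
        "zone": zones.reshape(-1),
        "forest": forest.reshape(-1),
    }).dropna()
    if df.empty:
        raise ValueError("no valid cells in any zone")
    out = df.groupby("zone")["forest"].agg(["mean", "count"])
    out["forest_percent"] = 100.0 * out["mean"]
    return out[["forest_percent", "count"]].rename(columns={"count": "n_pixels"})
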