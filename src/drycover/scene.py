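"""Synthetic landscapes and multi-resolution observation streams.

The generator emulates the study system: a patchy dryland mosaic of seven
land-cover classes observed by (a) a fine-resolution (Landsat-like) sensor
delivering per-date 6-band reflectance with cloud/snow masks and periodic
SLC-off stripe gaps, and (b) a coarse-resolution (MODIS-like) pair of
sensors delivering 16-day composites of six signals with reliability flags
and per-pixel compositing DOY, offset by 8 days.

Class signatures follow a double-logistic phenology: each class interpolates
between a dormant-season and a peak-season endmember spectrum according to a
greenness curve g(d) = logistic(k (d - d_up)) - logistic(k (d - d_down)).
The default parameters are chosen so that deciduous forest and herbaceous
vegetation are nearly indistinguishable in mid-summer reflectance but differ
in green-season timing and length, and mixed forest lies spectrally between
deciduous and evergreen forest — the separability structure that makes
multi-temporal metrics outperform single-date composites.

Every generator is a pure function of (spec, phenology, calendar): the same
seed yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from . import legend
from .compositing import (FINE_BANDS, QA_CLEAR, QA_CLOUD, QA_FILL, QA_SNOW,
                          FineSeriesStack)
from .coarse_prep import (COARSE_SIGNALS, REL_CLOUD, REL_MARGINAL,
                          REL_NODATA, REL_SNOW, SRC_AQUA, SRC_TERRA,
                          CoarseSeries)
from .fractions import FractionMap

DEFAULT_CLASS_WEIGHTS: dict[int, float] = {
    legend.DECIDUOUS_FOREST: 0.10,
    legend.EVERGREEN_FOREST: 0.10,
    legend.MIXED_FOREST: 0.08,
    legend.WETLAND: 0.10,
    legend.HERBACEOUS: 0.27,
    legend.BARREN: 0.25,
    legend.WATER: 0.10,
}


@dataclass(frozen=True)
class LandscapeSpec:
    n_rows: int = 512
    n_cols: int = 512
    fine_pixel_size: float = 30.0
    coarse_factor: int = 8
    class_list: tuple[int, ...] = legend.LEGEND
    patch_scale: float = 12.0
    class_weights: tuple[float, ...] = tuple(
        DEFAULT_CLASS_WEIGHTS[c] for c in legend.LEGEND
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coarse_factor < 2:
            raise ValueError("coarse_factor must be >= 2")
        if self.n_rows % self.coarse_factor or self.n_cols % self.coarse_factor:
            raise ValueError("grid dimensions must be divisible by coarse_factor")
        w = np.asarray(self.class_weights, dtype=float)
        if len(w) != len(self.class_list):
            raise ValueError("one weight per class required")
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("class_weights must be non-negative with positive sum")
        if not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise ValueError("class_weights must sum to 1")

    @property
    def coarse_shape(self) -> tuple[int, int]:
        return (self.n_rows // self.coarse_factor, self.n_cols // self.coarse_factor)

    @property
    def coarse_pixel_size(self) -> float:
        return self.fine_pixel_size * self.coarse_factor


@dataclass(frozen=True)
class SignalCurve:
    """Double-logistic seasonal trajectory of one signal for one class."""

    base: float
    amplitude: float
    greenup_doy: float
    senescence_doy: float
    steepness: float = 0.10

    def __call__(self, doy: np.ndarray | float) -> np.ndarray:
        d = np.asarray(doy, dtype=float)
        k = self.steepness
        g = expit(k * (d - self.greenup_doy)) - expit(k * (d - self.senescence_doy))
        return self.base + self.amplitude * g


# dormant- and peak-season endmember spectra (blue, green, red, nir, swir1, swir2)
_SPEC_GREEN = np.array([0.04, 0.08, 0.05, 0.45, 0.22, 0.12])
_SPEC_DORMANT_FOREST = np.array([0.06, 0.09, 0.10, 0.25, 0.28, 0.20])
_SPEC_EVERGREEN = np.array([0.03, 0.06, 0.04, 0.38, 0.15, 0.08])
_SPEC_EVERGREEN_WINTER = np.array([0.04, 0.07, 0.05, 0.30, 0.18, 0.10])
_SPEC_DRY_SOIL = np.array([0.10, 0.14, 0.20, 0.28, 0.38, 0.30])
_SPEC_BRIGHT_SOIL = np.array([0.12, 0.16, 0.24, 0.30, 0.42, 0.34])
_SPEC_WATER = np.array([0.06, 0.05, 0.04, 0.02, 0.01, 0.01])

# greenness timing per class: (greenup, senescence, steepness)
_TIMING: dict[int, tuple[float, float, float]] = {
    legend.DECIDUOUS_FOREST: (130.0, 285.0, 0.10),
    legend.EVERGREEN_FOREST: (100.0, 305.0, 0.04),
    legend.MIXED_FOREST: (125.0, 292.0, 0.08),
    legend.WETLAND: (135.0, 268.0, 0.09),
    legend.HERBACEOUS: (100.0, 232.0, 0.08),
    legend.BARREN: (120.0, 260.0, 0.05),
    legend.WATER: (120.0, 260.0, 0.05),
}

_ENDMEMBERS: dict[int, tuple[np.ndarray, np.ndarray]] = {
    legend.DECIDUOUS_FOREST: (_SPEC_DORMANT_FOREST, _SPEC_GREEN),
    legend.EVERGREEN_FOREST: (_SPEC_EVERGREEN_WINTER, _SPEC_EVERGREEN),
    legend.MIXED_FOREST: (
        0.5 * (_SPEC_DORMANT_FOREST + _SPEC_EVERGREEN_WINTER),
        0.5 * (_SPEC_GREEN + _SPEC_EVERGREEN),
    ),
    legend.WETLAND: (
        0.55 * _SPEC_DRY_SOIL + 0.45 * _SPEC_WATER,
        0.70 * _SPEC_GREEN + 0.30 * _SPEC_WATER,
    ),
    legend.HERBACEOUS: (_SPEC_DRY_SOIL, _SPEC_GREEN),
    legend.BARREN: (_SPEC_BRIGHT_SOIL, 0.95 * _SPEC_BRIGHT_SOIL + 0.05 * _SPEC_GREEN),
    legend.WATER: (_SPEC_WATER, _SPEC_WATER),
}

# coarse vegetation-index curves per class: (base, amplitude)
_NDVI_PARAMS: dict[int, tuple[float, float]] = {
    legend.DECIDUOUS_FOREST: (0.22, 0.52),
    legend.EVERGREEN_FOREST: (0.55, 0.15),
    legend.MIXED_FOREST: (0.38, 0.34),
    legend.WETLAND: (0.24, 0.32),
    legend.HERBACEOUS: (0.20, 0.46),
    legend.BARREN: (0.11, 0.04),
    legend.WATER: (-0.12, 0.02),
}


def _default_fine_curves() -> dict[int, dict[str, SignalCurve]]:
    curves: dict[int, dict[str, SignalCurve]] = {}
    for code in legend.LEGEND:
        dormant, peak = _ENDMEMBERS[code]
        up, down, k = _TIMING[code]
        curves[code] = {
            band: SignalCurve(dormant[b], peak[b] - dormant[b], up, down, k)
            for b, band in enumerate(FINE_BANDS)
        }
    return curves


def _default_coarse_curves() -> dict[int, dict[str, SignalCurve]]:
    fine = _default_fine_curves()
    curves: dict[int, dict[str, SignalCurve]] = {}
    for code in legend.LEGEND:
        base, amp = _NDVI_PARAMS[code]
        up, down, k = _TIMING[code]
        curves[code] = {
            "ndvi": SignalCurve(base, amp, up, down, k),
            "evi": SignalCurve(0.6 * base, 0.62 * amp, up, down, k),
            "blue": fine[code]["blue"],
            "red": fine[code]["red"],
            "nir": fine[code]["nir"],
            "swir": fine[code]["swir1"],
        }
    return curves


@dataclass(frozen=True)
class PhenologyModel:
    """Per-class, per-signal seasonal curves plus observation noise levels."""

    fine_curves: dict[int, dict[str, SignalCurve]] = field(
        default_factory=_default_fine_curves
    )
    coarse_curves: dict[int, dict[str, SignalCurve]] = field(
        default_factory=_default_coarse_curves
    )
    fine_noise_sd: float = 0.04
    coarse_noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "ndvi": 0.015, "evi": 0.012, "blue": 0.008,
            "red": 0.008, "nir": 0.010, "swir": 0.010,
        }
    )

    def fine_lut(self, doy: float) -> np.ndarray:
        """(n_classes+1, 6) band values at ``doy`` indexed by class code."""
        lut = np.zeros((max(legend.LEGEND) + 1, len(FINE_BANDS)))
        for code in legend.LEGEND:
            for b, band in enumerate(FINE_BANDS):
                lut[code, b] = self.fine_curves[code][band](doy)
        return np.clip(lut, 0.0, 1.0)

    def coarse_class_values(self, signal: str, doy: np.ndarray) -> np.ndarray:
        """(n_classes, ...) signal values at per-pixel ``doy`` per class."""
        out = np.stack([self.coarse_curves[c][signal](doy) for c in legend.LEGEND])
        lo = -1.0 if signal in ("ndvi", "evi") else 0.0
        return np.clip(out, lo, 1.0)


@dataclass
class GroundTruthLandscape:
    class_raster: np.ndarray
    phenology: PhenologyModel
    spec: LandscapeSpec

    def __post_init__(self) -> None:
        values = set(np.unique(self.class_raster).tolist())
        if not values <= set(self.spec.class_list):
            raise ValueError("class raster contains codes outside the legend")

    def block_fractions(self) -> np.ndarray:
        """(n_classes, coarse_rows, coarse_cols) per-block class fractions."""
        f = self.spec.coarse_factor
        cr, cc = self.spec.coarse_shape
        blocks = self.class_raster.reshape(cr, f, cc, f)
        out = np.empty((len(legend.LEGEND), cr, cc))
        for i, code in enumerate(legend.LEGEND):
            out[i] = (blocks == code).sum(axis=(1, 3)) / (f * f)
        return out


@dataclass(frozen=True)
class AcquisitionCalendar:
    """Fine-sensor acquisition list with per-date cloud cover and SLC state."""

    table: pd.DataFrame  # date, year, doy, sensor, slc_off, cloud_fraction

    def __post_init__(self) -> None:
        t = self.table
        if ((t["doy"] < 1) | (t["doy"] > 366)).any():
            raise ValueError("DOY out of range 1..366")
        if not t["date"].is_monotonic_increasing or t["date"].duplicated().any():
            raise ValueError("dates must be strictly increasing")
        if ((t["cloud_fraction"] < 0) | (t["cloud_fraction"] > 1)).any():
            raise ValueError("cloud fraction out of [0, 1]")

    def __len__(self) -> int:
        return len(self.table)


def make_calendar(
    years: tuple[int, ...] = (2009, 2010, 2011),
    revisit_days: int = 16,
    start_doy: int = 6,
    mean_cloud_fraction: float = 0.35,
    cloud_sd: float = 0.15,
    seed: int = 0,
) -> AcquisitionCalendar:
    """Alternating TM / ETM+ acquisitions; ETM+ dates carry SLC-off gaps."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    rows = []
    i = 0
    for year in years:
        for doy in range(start_doy, 366, revisit_days):
            sensor = "TM" if i % 2 == 0 else "ETM+"
            cloud = float(np.clip(
                rng.normal(mean_cloud_fraction, cloud_sd), 0.0, 0.95))
            date = np.datetime64(f"{year}-01-01") + np.timedelta64(doy - 1, "D")
            rows.append((date, year, doy, sensor, sensor == "ETM+", cloud))
            i += 1
    table = pd.DataFrame(
        rows, columns=["date", "year", "doy", "sensor", "slc_off", "cloud_fraction"]
    )
    return AcquisitionCalendar(table)


def generate_landscape(
    spec: LandscapeSpec, phenology: PhenologyModel | None = None
) -> GroundTruthLandscape:
    """Patchy class mosaic from a quantile-sliced smoothed Gaussian field.

    White noise is smoothed with a Gaussian kernel of sigma ``patch_scale``
    and ranked; rank quantiles are cut at the cumulative class weights, so
    realized class proportions match the targets up to integer rounding.
    """
    phenology = phenology or PhenologyModel()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    field_ = gaussian_filter(
        rng.standard_normal((spec.n_rows, spec.n_cols)), sigma=spec.patch_scale
    )
    flat = field_.reshape(-1)
    order = np.argsort(flat, kind="stable")
    n = flat.size
    weights = np.asarray(spec.class_weights, dtype=float)
    bounds = np.rint(np.cumsum(weights) * n).astype(np.int64)
    classes = np.empty(n, dtype=np.int16)
    start = 0
    for code, stop in zip(spec.class_list, bounds):
        classes[order[start:stop]] = code
        start = stop
    classes[order[start:]] = spec.class_list[-1]
    raster = classes.reshape(spec.n_rows, spec.n_cols)
    block = spec.coarse_factor**2
    for code, w in zip(spec.class_list, weights):
        if w > 0 and (raster == code).sum() < block:
            raise ValueError(
                f"class {code} realizes fewer than one coarse block of pixels; "
                "increase its weight or the grid size"
            )
    return GroundTruthLandscape(raster, phenology, spec)


def _blob_mask(shape: tuple[int, int], fraction: float, sigma: float,
               rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated boolean mask covering ~``fraction`` of the grid."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    if fraction >= 1:
        return np.ones(shape, dtype=bool)
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    thr = np.quantile(f, 1.0 - fraction)
    return f > thr


def _slc_stripes(shape: tuple[int, int], period: int = 14, width: int = 4) -> np.ndarray:
    rows, cols = np.indices(shape)
    return ((rows + cols) % period) < width


def simulate_fine_series(
    truth: GroundTruthLandscape,
    calendar: AcquisitionCalendar,
    snow_doy_range: tuple[int, int] = (330, 60),
    snow_fraction: float = 0.5,
) -> FineSeriesStack:
    """Fine-resolution 6-band stack with cloud/snow blobs and SLC-off gaps.

    Per acquisition, each pixel's reflectance is its class's phenology curve
    at the acquisition DOY plus Gaussian noise, clipped to [0, 1]. QA marks
    spatially correlated cloud blobs, winter snow blobs and (for SLC-off
    dates) periodic diagonal stripes; not-clear positions hold NaN.
    """
    if len(calendar) == 0:
        raise ValueError("calendar must be non-empty")
    spec = truth.spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
    shape = (spec.n_rows, spec.n_cols)
    n_acq = len(calendar)
    bands = np.empty((n_acq, len(FINE_BANDS), *shape), dtype=np.float32)
    qa = np.zeros((n_acq, *shape), dtype=np.uint8)
    noise_sd = truth.phenology.fine_noise_sd
    for a, row in calendar.table.iterrows():
        lut = truth.phenology.fine_lut(float(row["doy"]))
        values = lut[truth.class_raster].transpose(2, 0, 1)  # (6, rows, cols)
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=values.shape)
        bands[a] = np.clip(values, 0.0, 1.0)
        mask = np.zeros(shape, dtype=np.uint8)
        cloud = _blob_mask(shape, float(row["cloud_fraction"]), sigma=20.0, rng=rng)
        mask[cloud] = QA_CLOUD
        doy = int(row["doy"])
        if doy >= snow_doy_range[0] or doy <= snow_doy_range[1]:
            snow = _blob_mask(shape, snow_fraction, sigma=30.0, rng=rng)
            mask[snow & (mask == 0)] = QA_SNOW
        if bool(row["slc_off"]):
            stripes = _slc_stripes(shape)
            mask[stripes] = np.where(mask[stripes] == 0, QA_FILL, mask[stripes])
        qa[a] = mask
        bands[a][:, mask != QA_CLEAR] = np.nan
    return FineSeriesStack(bands, qa, calendar.table.copy())


def simulate_coarse_series(
    truth: GroundTruthLandscape,
    year: int = 2010,
    step_days: int = 16,
    flag_probs: dict[int, float] | None = None,
) -> tuple[CoarseSeries, CoarseSeries]:
    """Terra-like and Aqua-like 16-day composite streams, offset by 8 days.

    Per coarse pixel and composite period the signal is the area-weighted
    mean over constituent fine pixels of the class phenology evaluated at a
    per-pixel random DOY within the period, plus Gaussian noise. Reliability
    flags are drawn independently per observation; flagged values are NaN.
    """
    if step_days <= 0:
        raise ValueError("step_days must be positive")
    if flag_probs is None:
        flag_probs = {REL_MARGINAL: 0.10, REL_SNOW: 0.04, REL_CLOUD: 0.08,
                      REL_NODATA: 0.02}
    spec = truth.spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 37, year]))
    fractions = truth.block_fractions()  # (n_classes, cr, cc)
    cr, cc = spec.coarse_shape
    out = []
    for offset, src in ((0, SRC_TERRA), (8, SRC_AQUA)):
        starts = np.arange(1 + offset, 366, step_days)
        n_obs = len(starts)
        values = np.empty((n_obs, len(COARSE_SIGNALS), cr, cc))
        doy = np.empty((n_obs, cr, cc))
        flags = np.zeros((n_obs, cr, cc), dtype=np.uint8)
        for o, start in enumerate(starts):
            d = start + rng.integers(0, step_days, size=(cr, cc))
            d = np.minimum(d, 365)
            doy[o] = d
            for g, sig in enumerate(COARSE_SIGNALS):
                per_class = truth.phenology.coarse_class_values(sig, d)
                v = np.einsum("kij,kij->ij", fractions, per_class)
                sd = truth.phenology.coarse_noise_sd[sig]
                if sd > 0:
                    v = v + rng.normal(0.0, sd, size=v.shape)
                values[o, g] = v
            u = rng.random((cr, cc))
            cum = 0.0
            for flag, p in flag_probs.items():
                flags[o][(u >= cum) & (u < cum + p)] = flag
                cum += p
        bad = flags >= REL_SNOW
        values[np.broadcast_to(bad[:, None], values.shape)] = np.nan
        source = np.full((n_obs, cr, cc), src, dtype=np.uint8)
        out.append(CoarseSeries(values, doy, flags, source))
    return out[0], out[1]


def true_fractions(truth: GroundTruthLandscape) -> FractionMap:
    """Ground-truth per-coarse-block forest-type fractions."""
    frac = truth.block_fractions()
    idx = {code: i for i, code in enumerate(legend.LEGEND)}
    dec = frac[idx[legend.DECIDUOUS_FOREST]]
    eve = frac[idx[legend.EVERGREEN_FOREST]]
    mix = frac[idx[legend.MIXED_FOREST]]
    overall = np.clip(dec + eve + mix, 0.0, 1.0)
    return FractionMap(dec, eve, mix, overall,
                       missing=np.zeros(dec.shape, dtype=bool))
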