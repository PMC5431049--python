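"""Raster and table I/O.

Rasters are written as plain multi-band TIFF (band-major axis first) with a
JSON sidecar (``<name>.json``) carrying band names, pixel size and an
optional class legend. Tables are CSV. No coordinate reference system is
attached; grids are assumed aligned by construction.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def write_raster(
    path: str | Path,
    array: np.ndarray,
    band_names: tuple[str, ...] | None = None,
    pixel_size: float | None = None,
    legend: dict | None = None,
) -> None:
    path = Path(path)
    array = np.asarray(array)
    if array.ndim == 3:
        tifffile.imwrite(path, array, photometric="minisblack")
    else:
        tifffile.imwrite(path, array)
    meta: dict = {"shape": list(array.shape)}
    if band_names is not None:
        meta["band_names"] = list(band_names)
    if pixel_size is not None:
        meta["pixel_size_m"] = pixel_size
    if legend is not None:
        meta["legend"] = {str(k): v for k, v in legend.items()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    array = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return np.asarray(array), meta


def write_fine_stack(out_dir: str | Path, stack) -> None:
    """One 6-band reflectance TIFF + one QA TIFF per acquisition, plus the
    acquisition table CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for a in range(stack.n_acq):
        write_raster(out_dir / f"fine_{a:03d}.tif", stack.bands[a],
                     band_names=stack.band_names)
        write_raster(out_dir / f"fine_{a:03d}_qa.tif", stack.qa[a])
    stack.table.to_csv(out_dir / "acquisitions.csv", index=False)


def read_fine_stack(in_dir: str | Path):
    from .compositing import FineSeriesStack

    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "acquisitions.csv", parse_dates=["date"])
    bands, qa = [], []
    for a in range(len(table)):
        bands.append(read_raster(in_dir / f"fine_{a:03d}.tif")[0])
        qa.append(read_raster(in_dir / f"fine_{a:03d}_qa.tif")[0])
    return FineSeriesStack(np.stack(bands), np.stack(qa), table)


def write_coarse_series(out_dir: str | Path, series, tag: str) -> None:
    """Per-signal multi-band raster (one band per composite observation),
    plus reliability, DOY and source rasters."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for g, sig in enumerate(series.signal_names):
        write_raster(out_dir / f"{tag}_{sig}.tif", series.values[:, g])
    write_raster(out_dir / f"{tag}_reliability.tif", series.flags)
    write_raster(out_dir / f"{tag}_doy.tif", series.doy.astype(np.int16))
    write_raster(out_dir / f"{tag}_source.tif", series.source)


def read_coarse_series(in_dir: str | Path, tag: str):
    from .coarse_prep import COARSE_SIGNALS, CoarseSeries

    in_dir = Path(in_dir)
    values = np.stack(
        [read_raster(in_dir / f"{tag}_{sig}.tif")[0] for sig in COARSE_SIGNALS],
        axis=1,
    ).astype(float)
    flags = read_raster(in_dir / f"{tag}_reliability.tif")[0].astype(np.uint8)
    doy = read_raster(in_dir / f"{tag}_doy.tif")[0].astype(float)
    source = read_raster(in_dir / f"{tag}_source.tif")[0].astype(np.uint8)
    return CoarseSeries(values, doy, flags, source)


def write_fraction_map(path: str | Path, fmap, pixel_size: float | None = None) -> None:
    stack = np.stack([fmap.deciduous, fmap.evergreen, fmap.mixed, fmap.overall])
    stack = np.where(fmap.missing[None], np.nan, stack).astype(np.float32)
    write_raster(path, stack,
                 band_names=("deciduous", "evergreen", "mixed", "overall"),
                 pixel_size=pixel_size)


def read_fraction_map(path: str | Path):
    from .fractions import FractionMap

    stack, _ = read_raster(path)
    missing = np.isnan(stack).any(axis=0)
    stack = np.where(missing[None], 0.0, stack)
    return FractionMap(stack[0], stack[1], stack[2], stack[3], missing)
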