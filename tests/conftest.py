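from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from drycover.compositing import FINE_BANDS, QA_CLEAR, FineSeriesStack
from drycover.scene import (GroundTruthLandscape, LandscapeSpec, PhenologyModel,
                            generate_landscape)


def make_stack(
    values: np.ndarray,
    doys: list[int],
    years: list[int],
    qa: np.ndarray | None = None,
) -> FineSeriesStack:
    """Assemble a FineSeriesStack from explicit per-acquisition values.

    ``values``: (n_acq, 6, rows, cols); ``qa`` defaults to all clear.
    """
    values = np.asarray(values, dtype=np.float32)
    n_acq = values.shape[0]
    if qa is None:
        qa = np.full((n_acq, *values.shape[2:]), QA_CLEAR, dtype=np.uint8)
    dates = [np.datetime64(f"{y}-01-01") + np.timedelta64(d - 1, "D")
             for y, d in zip(years, doys)]
    table = pd.DataFrame({
        "date": dates, "year": years, "doy": doys,
        "sensor": ["TM"] * n_acq, "slc_off": [False] * n_acq,
        "cloud_fraction": [0.0] * n_acq,
    })
    vals = values.copy()
    vals[:, :, :, :][np.broadcast_to((qa != QA_CLEAR)[:, None], vals.shape)] = np.nan
    return FineSeriesStack(vals, qa, table)


def constant_stack(
    levels: list[float], doys: list[int], years: list[int],
    shape: tuple[int, int] = (2, 2), qa: np.ndarray | None = None,
) -> FineSeriesStack:
    """Stack whose every band/pixel takes the per-acquisition level."""
    n = len(levels)
    values = np.empty((n, len(FINE_BANDS), *shape), dtype=np.float32)
    for i, v in enumerate(levels):
        values[i] = v
    return make_stack(values, doys, years, qa)


def noiseless_phenology() -> PhenologyModel:
    return PhenologyModel(
        fine_noise_sd=0.0,
        coarse_noise_sd={s: 0.0 for s in
                         ("ndvi", "evi", "blue", "red", "nir", "swir")},
    )


@pytest.fixture(scope="session")
def tiny_spec() -> LandscapeSpec:
    return LandscapeSpec(n_rows=64, n_cols=64, coarse_factor=8,
                         patch_scale=4.0, seed=5)


@pytest.fixture(scope="session")
def tiny_truth(tiny_spec) -> GroundTruthLandscape:
    return generate_landscape(tiny_spec, noiseless_phenology())
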