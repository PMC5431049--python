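"""Sub-pixel forest-cover fraction modelling and validation.

The fine-resolution land-cover map supplies per-coarse-pixel reference
fractions of the three forest types. Training locations are drawn with a
minimum-distance constraint (default 1000 m) against spatial
autocorrelation; one regression forest per forest type is fitted on the 90
seasonal features; overall forest cover is the (clipped) sum of the three
type predictions. Accuracy is assessed on a stratified sample (forest /
non-forest strata from the predicted map) with the normalized RMSE

    NRMSE = sqrt( sum_i (P_i - R_i)^2 / n ) / Rbar

where P_i and R_i are predicted and reference fractions and Rbar is the
mean reference, together with Pearson's r.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from . import legend
from .coarse_prep import SeasonalFeatureTable
from .landcover import LandCoverMap, RFParams

log = logging.getLogger(__name__)

FOREST_TYPES = ("deciduous", "evergreen", "mixed")


@dataclass
class FractionMap:
    """Per-coarse-pixel cover fraction for each forest type plus overall."""

    deciduous: np.ndarray
    evergreen: np.ndarray
    mixed: np.ndarray
    overall: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        for name in FOREST_TYPES + ("overall",):
            a = getattr(self, name)[~self.missing]
            if a.size and ((a < -1e-9) | (a > 1 + 1e-9)).any():
                raise ValueError(f"{name} fractions outside [0, 1]")

    def target(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def shape(self) -> tuple[int, int]:
        return self.overall.shape


@dataclass
class FractionTrainingSet:
    rows: np.ndarray
    cols: np.ndarray
    features: np.ndarray  # (n, 90)
    fractions: np.ndarray  # (n, 3): deciduous, evergreen, mixed
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        f = self.fractions
        if ((f < 0) | (f > 1)).any():
            raise ValueError("fractions outside [0, 1]")
        if (f.sum(axis=1) > 1 + 1e-9).any():
            raise ValueError("type fractions sum above 1")


def sample_training_pixels(
    shape: tuple[int, int],
    pixel_size: float,
    n_target: int,
    min_dist: float = 1000.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy random thinning of coarse-pixel centres.

    Candidates are visited in random order and accepted if at least
    ``min_dist`` metres from every previously accepted centre, until
    ``n_target`` accepted or candidates are exhausted. Returns (rows, cols).
    """
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 131]))
    n_pix = shape[0] * shape[1]
    order = rng.permutation(n_pix)
    if min_dist == 0:
        chosen = order[:n_target]
        return np.unravel_index(chosen, shape)
    radius = min_dist / pixel_size
    cell = max(1.0, radius)
    buckets: dict[tuple[int, int], list[tuple[float, float]]] = {}
    acc_r: list[int] = []
    acc_c: list[int] = []
    for flat in order:
        if len(acc_r) >= n_target:
            break
        r, c = divmod(int(flat), shape[1])
        br, bc = int(r // cell), int(c // cell)
        ok = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for rr, cc in buckets.get((br + dr, bc + dc), ()):
                    if (r - rr) ** 2 + (c - cc) ** 2 < radius**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            acc_r.append(r)
            acc_c.append(c)
            buckets.setdefault((br, bc), []).append((r, c))
    if len(acc_r) < n_target:
        log.info("minimum-distance sampler accepted %d of %d requested",
                 len(acc_r), n_target)
    return np.asarray(acc_r), np.asarray(acc_c)


def compute_reference_fractions(
    cover: LandCoverMap,
    coarse_factor: int,
    max_missing: float = 0.5,
) -> FractionMap:
    """Per-coarse-block forest-type proportions from the land-cover map.

    Fine pixels flagged missing are excluded from the denominator; blocks
    with more than ``max_missing`` missing fine pixels are dropped.
    """
    rows, cols = cover.classes.shape
    if rows % coarse_factor or cols % coarse_factor:
        raise ValueError("fine grid does not nest in the coarse grid")
    cr, cc = rows // coarse_factor, cols // coarse_factor
    blocks = cover.classes.reshape(cr, coarse_factor, cc, coarse_factor)
    miss = cover.missing.reshape(cr, coarse_factor, cc, coarse_factor)
    n_ok = (~miss).sum(axis=(1, 3)).astype(float)
    dropped = n_ok < (1.0 - max_missing) * coarse_factor**2
    denom = np.maximum(n_ok, 1.0)
    out = {}
    for name, code in zip(FOREST_TYPES, legend.FOREST_CODES):
        cnt = ((blocks == code) & ~miss).sum(axis=(1, 3))
        frac = cnt / denom
        frac[dropped] = np.nan
        out[name] = frac
    overall = np.clip(out["deciduous"] + out["evergreen"] + out["mixed"], 0, 1)
    return FractionMap(out["deciduous"], out["evergreen"], out["mixed"],
                       overall, dropped)


@dataclass
class FittedFractionModels:
    models: dict[str, RandomForestRegressor]
    feature_names: tuple[str, ...]


def train_fraction_models(
    train: FractionTrainingSet, params: RFParams | None = None
) -> FittedFractionModels:
    """One regression forest per forest type, trained independently."""
    if len(train.features) == 0:
        raise ValueError("empty training set")
    params = params or RFParams()
    models = {}
    for i, name in enumerate(FOREST_TYPES):
        rf = RandomForestRegressor(
            n_estimators=params.n_trees,
            min_samples_leaf=params.min_node_size,
            max_features=RFParams.mtry(train.features.shape[1]),
            random_state=params.seed,
            n_jobs=1,
        )
        rf.fit(train.features, train.fractions[:, i])
        models[name] = rf
    return FittedFractionModels(models, train.feature_names)


def predict_fractions(
    models: FittedFractionModels, features: SeasonalFeatureTable
) -> FractionMap:
    """Wall-to-wall type fractions, clipped to [0, 1]; overall is the
    clipped sum. Missing-feature pixels stay missing."""
    if features.names != models.feature_names:
        raise ValueError("feature schema does not match training")
    X = features.matrix()
    ok = ~features.missing.reshape(-1)
    shape = features.missing.shape
    preds = {}
    for name in FOREST_TYPES:
        p = np.full(X.shape[0], np.nan)
        if ok.any():
            p[ok] = models.models[name].predict(X[ok])
        preds[name] = np.clip(p, 0.0, 1.0).reshape(shape)
    overall = np.clip(preds["deciduous"] + preds["evergreen"] + preds["mixed"],
                      0.0, 1.0)
    return FractionMap(preds["deciduous"], preds["evergreen"], preds["mixed"],
                       overall, ~ok.reshape(shape))


def nrmse(predicted: np.ndarray, reference: np.ndarray) -> float:
    """Root-mean-square error normalized by the mean reference.

    Undefined (NaN) when the mean reference is zero.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    rbar = reference.mean()
    if rbar == 0:
        return float("nan")
    rmse = np.sqrt(np.mean((predicted - reference) ** 2))
    return float(rmse / rbar)


@dataclass
class ValidationReport:
    """Per-target NRMSE and Pearson r over the pooled stratified sample."""

    table: pd.DataFrame  # index: target; columns: nrmse, pearson_r, n
    n_forest: int
    n_nonforest: int

    def metric(self, target: str, name: str) -> float:
        return float(self.table.loc[target, name])


def validate_fractions(
    predicted: FractionMap,
    reference: FractionMap,
    n_per_stratum: int = 1000,
    seed: int = 0,
) -> ValidationReport:
    """Stratified validation of the fraction map.

    Strata are defined on the predicted map: overall fraction > 0 (forest)
    and == 0 (non-forest). min(n_per_stratum, stratum size) pixels are drawn
    from each stratum without replacement; NRMSE and Pearson r are computed
    per target over the pooled sample.
    """
    if predicted.shape != reference.shape:
        raise ValueError("maps are not aligned")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 149]))
    ok = ~(predicted.missing | reference.missing
           | np.isnan(predicted.overall) | np.isnan(reference.overall))
    flat_ok = ok.reshape(-1)
    pred_overall = predicted.overall.reshape(-1)
    strata = {
        "forest": np.flatnonzero(flat_ok & (pred_overall > 0)),
        "nonforest": np.flatnonzero(flat_ok & (pred_overall == 0)),
    }
    chosen = []
    sizes = {}
    for name, pool in strata.items():
        take = min(n_per_stratum, pool.size)
        sizes[name] = take
        if take:
            chosen.append(rng.choice(pool, size=take, replace=False))
    if not chosen:
        raise ValueError("no valid pixels to validate")
    sample = np.concatenate(chosen)
    rows = {}
    for target in FOREST_TYPES + ("overall",):
        p = predicted.target(target).reshape(-1)[sample]
        r = reference.target(target).reshape(-1)[sample]
        err = nrmse(p, r)
        if np.unique(p).size < 2 or np.unique(r).size < 2:
            pearson = float("nan")  # correlation undefined for constant input
        else:
            pearson = float(stats.pearsonr(p, r).statistic)
        rows[target] = {"nrmse": err, "pearson_r": pearson, "n": len(sample)}
    table = pd.DataFrame(rows).T
    return ValidationReport(table, sizes["forest"], sizes["nonforest"])
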