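"""Random-forest land-cover classification and map accuracy assessment.

A random forest is trained on composite features (single-date or
spectral-temporal metrics) against the 7-class legend, predicted wall to
wall, and assessed by disproportionate stratified sampling (equal samples
per mapped class) and an error matrix with overall accuracy and per-class
commission/omission errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from . import legend
from .compositing import CompositeFeatureTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFParams:
    """Forest settings: 1000 trees, terminal nodes of at least 10 samples,
    and mtry = floor(sqrt(p)) candidate features per split."""

    n_trees: int = 1000
    min_node_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_node_size < 1:
            raise ValueError("n_trees and min_node_size must be >= 1")

    @staticmethod
    def mtry(n_features: int) -> int:
        return max(1, math.floor(math.sqrt(n_features)))


@dataclass
class TrainingSet:
    features: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray  # legend codes
    polygon_id: np.ndarray  # source-polygon identifier per pixel
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels differ in length")
        if not set(np.unique(self.labels)) <= set(legend.LEGEND):
            raise ValueError("labels outside the legend")
        if np.isnan(self.features).any():
            raise ValueError("training features contain missing values")


@dataclass
class LandCoverMap:
    """Categorical raster over the legend; 0 marks missing pixels."""

    classes: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        ok = set(legend.LEGEND) | {legend.MISSING}
        if not set(np.unique(self.classes)) <= ok:
            raise ValueError("map contains values outside legend + missing")


@dataclass
class FittedClassifier:
    model: RandomForestClassifier
    feature_names: tuple[str, ...]


def build_training_set(
    truth_classes: np.ndarray,
    features: CompositeFeatureTable,
    n_per_class: int = 500,
    seed: int = 0,
) -> TrainingSet:
    """Sample labelled training pixels from a reference class raster.

    Pixels with any missing feature are excluded. The polygon identifier is
    the connected-component label of the class patch the pixel belongs to
    (4-connectivity), standing in for digitised training polygons.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 71]))
    polygons, _ = ndimage.label(truth_classes)
    X = features.matrix()
    ok = ~features.missing.reshape(-1)
    rows_X, rows_y, rows_p = [], [], []
    flat_classes = truth_classes.reshape(-1)
    flat_poly = polygons.reshape(-1)
    for code in legend.LEGEND:
        pool = np.flatnonzero((flat_classes == code) & ok)
        if pool.size == 0:
            continue
        take = min(n_per_class, pool.size)
        chosen = rng.choice(pool, size=take, replace=False)
        rows_X.append(X[chosen])
        rows_y.append(np.full(take, code, dtype=np.int16))
        rows_p.append(flat_poly[chosen])
    return TrainingSet(
        np.concatenate(rows_X).astype(np.float32),
        np.concatenate(rows_y),
        np.concatenate(rows_p),
        features.names,
    )


def train_classifier(train: TrainingSet, params: RFParams) -> FittedClassifier:
    """Fit the random forest; per-pixel prediction averages per-tree class
    probabilities, with ties resolved to the lowest legend code."""
    if len(train.features) == 0:
        raise ValueError("empty training set")
    model = RandomForestClassifier(
        n_estimators=params.n_trees,
        min_samples_leaf=params.min_node_size,
        max_features=RFParams.mtry(train.features.shape[1]),
        random_state=params.seed,
        n_jobs=1,
    )
    model.fit(train.features, train.labels)
    return FittedClassifier(model, train.feature_names)


def classify(
    model: FittedClassifier, features: CompositeFeatureTable, chunk: int = 200_000
) -> LandCoverMap:
    """Wall-to-wall prediction; missing-feature pixels map to missing."""
    if features.names != model.feature_names:
        raise ValueError("feature schema does not match training")
    X = features.matrix()
    ok = ~features.missing.reshape(-1)
    out = np.zeros(X.shape[0], dtype=np.int16)
    idx = np.flatnonzero(ok)
    for lo in range(0, idx.size, chunk):
        part = idx[lo : lo + chunk]
        out[part] = model.model.predict(X[part]).astype(np.int16)
    shape = features.missing.shape
    return LandCoverMap(out.reshape(shape), ~ok.reshape(shape))


def stratified_reference_sample(
    cover: LandCoverMap, n_per_class: int = 300, seed: int = 0
) -> pd.DataFrame:
    """Disproportionate stratified sample of map pixels, per mapped class.

    Returns a table with row, col and mapped_class; exactly
    min(n_per_class, class pixel count) samples per class, drawn without
    replacement. A class absent from the map contributes zero samples (with
    a warning).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 83]))
    flat = cover.classes.reshape(-1)
    rows = []
    for code in legend.LEGEND:
        pool = np.flatnonzero(flat == code)
        if pool.size == 0:
            log.warning("class %s absent from map; zero samples", code)
            continue
        chosen = np.sort(rng.choice(pool, size=min(n_per_class, pool.size),
                                    replace=False))
        r, c = np.unravel_index(chosen, cover.classes.shape)
        rows.append(pd.DataFrame({"row": r, "col": c, "mapped_class": code}))
    if not rows:
        return pd.DataFrame(columns=["row", "col", "mapped_class"])
    return pd.concat(rows, ignore_index=True)


@dataclass
class ErrorMatrix:
    """Map class x reference class count table with accuracy summaries."""

    counts: pd.DataFrame  # rows: mapped class, cols: reference class
    overall_accuracy: float
    commission: pd.Series  # per mapped class
    omission: pd.Series  # per reference class
    n: int
    oa_se: float = field(default=float("nan"))
    area_weighted_oa: float = field(default=float("nan"))
    area_weighted_oa_se: float = field(default=float("nan"))


def error_matrix(
    predicted: np.ndarray,
    reference: np.ndarray,
    class_areas: dict | None = None,
    labels: list | None = None,
) -> ErrorMatrix:
    """Error matrix with overall accuracy, commission and omission errors.

    ``labels`` fixes the class order (default: sorted union of observed
    labels). ``class_areas`` (mapped-class area proportions) additionally
    yields an area-weighted overall accuracy correcting for the
    disproportionate per-class sampling, with a stratified standard error;
    the raw OA and its simple-random-sampling standard error are always
    reported.
    """
    predicted = np.asarray(predicted)
    reference = np.asarray(reference)
    if predicted.size == 0 or predicted.shape != reference.shape:
        raise ValueError("predicted and reference must be equal-length, non-empty")
    if labels is None:
        labels = sorted(set(predicted.tolist()) | set(reference.tolist()))
    cross = pd.crosstab(pd.Series(predicted), pd.Series(reference))
    counts = cross.reindex(index=labels, columns=labels, fill_value=0).astype(int)
    counts.index.name = "mapped"
    counts.columns.name = "reference"
    total = counts.to_numpy().sum()
    diag = np.diag(counts.to_numpy())
    row_tot = counts.sum(axis=1).to_numpy()
    col_tot = counts.sum(axis=0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        commission = pd.Series(
            np.where(row_tot > 0, 1.0 - diag / np.maximum(row_tot, 1), np.nan),
            index=labels,
        )
        omission = pd.Series(
            np.where(col_tot > 0, 1.0 - diag / np.maximum(col_tot, 1), np.nan),
            index=labels,
        )
    oa = float(diag.sum() / total)
    oa_se = float(np.sqrt(oa * (1.0 - oa) / total))
    aw_oa = float("nan")
    aw_se = float("nan")
    if class_areas is not None:
        w = np.array([class_areas.get(c, 0.0) for c in labels], dtype=float)
        w = w / w.sum()
        users = np.where(row_tot > 0, diag / np.maximum(row_tot, 1), 0.0)
        aw_oa = float((w * users).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            var = np.where(row_tot > 0,
                           users * (1.0 - users) / np.maximum(row_tot, 1), 0.0)
        aw_se = float(np.sqrt((w**2 * var).sum()))
    return ErrorMatrix(counts, oa, commission, omission, int(total),
                       oa_se, aw_oa, aw_se)
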