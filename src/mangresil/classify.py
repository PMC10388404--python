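"""Supervised land-cover classification of a layer stack.

A random-forest ensemble (default 100 trees, 5 candidate predictors per
split) is trained on labelled sample pixels and applied per pixel to a
multi-layer feature stack (SAR backscatter, NDVI, optical bands — the
composition is caller-defined but must match between training and
prediction).  Each tree votes and the majority class wins; ties break to
the lowest class code so predictions are deterministic under a fixed
seed.  Pixels with nodata in any layer propagate to nodata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .grids import NODATA_CODE, ClassMap, Grid


@dataclass
class ClassifierConfig:
    n_trees: int = 100
    n_predictors_per_split: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.n_predictors_per_split < 1:
            raise ValueError("n_trees and n_predictors_per_split must be >= 1")


@dataclass
class FittedClassifier:
    model: RandomForestClassifier
    config: ClassifierConfig
    n_layers: int
    legend: dict[int, str]

    @property
    def metadata(self) -> dict:
        return {
            "n_trees": self.config.n_trees,
            "n_predictors_per_split": self.config.n_predictors_per_split,
            "seed": self.config.seed,
            "n_layers": self.n_layers,
            "classes": {c: self.legend[c] for c in sorted(self.legend)},
        }


def _stack_array(stack: Grid) -> np.ndarray:
    values = stack.values
    return values[np.newaxis] if values.ndim == 2 else values


def extract_features(stack: Grid, rows, cols) -> np.ndarray:
    """Per-pixel feature vectors (n_samples x n_layers) at the given pixels."""
    arr = _stack_array(stack)
    return arr[:, rows, cols].T


def train_classifier(
    stack: Grid,
    train_samples: pd.DataFrame,
    cfg: ClassifierConfig | None = None,
    legend: dict[int, str] | None = None,
) -> FittedClassifier:
    """Fit the ensemble on sample pixels.

    ``train_samples`` needs columns ``row``, ``col``, ``class_code``.
    Samples that fall on nodata pixels are dropped with a warning; a
    single-class training set is an error.
    """
    cfg = cfg or ClassifierConfig()
    rows = train_samples["row"].to_numpy()
    cols = train_samples["col"].to_numpy()
    labels = train_samples["class_code"].to_numpy()
    X = extract_features(stack, rows, cols)
    finite = np.isfinite(X).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} training samples on nodata pixels", stacklevel=2)
        X, labels = X[finite], labels[finite]
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training set must contain at least 2 classes")
    n_layers = X.shape[1]
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=min(cfg.n_predictors_per_split, n_layers),
        random_state=cfg.seed,
    )
    model.fit(X, labels)
    legend = legend or {int(c): str(c) for c in classes}
    return FittedClassifier(model=model, config=cfg, n_layers=n_layers, legend=legend)


def predict_map(clf: FittedClassifier, stack: Grid) -> ClassMap:
    """Per-pixel majority-vote classification of a stack.

    The stack must have the same layer count (and order) as the training
    stack; nodata in any layer yields a nodata pixel.
    """
    arr = _stack_array(stack)
    if arr.shape[0] != clf.n_layers:
        raise ValueError(f"stack has {arr.shape[0]} layers but model was trained on {clf.n_layers}")
    rows, cols = arr.shape[1], arr.shape[2]
    X = arr.reshape(clf.n_layers, -1).T
    finite = np.isfinite(X).all(axis=1)
    codes = np.full(rows * cols, NODATA_CODE, dtype=np.int32)
    if finite.any():
        codes[finite] = clf.model.predict(X[finite])
    return ClassMap(
        codes=codes.reshape(rows, cols),
        legend=dict(clf.legend),
        pixel_size=stack.pixel_size,
        origin=stack.origin,
    )
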