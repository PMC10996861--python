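"""SMOTE-style oversampling of the minority class in training folds.

New minority rows are drawn along the segments joining a minority row to one
of its k nearest minority neighbors (Euclidean distance on the CPP features
only): ``synthetic = seed + lambda * (neighbor - seed)`` with ``lambda``
uniform on [0, 1]. Seed rows are cycled in order so every minority row
contributes; neighbor search uses sklearn's ``NearestNeighbors``.

Balancing is applied to training folds only — synthetic rows carry a flag so
the evaluation protocol can assert they are never scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .exceptions import ConfigError, ValidationError

SYNTHETIC_FLAG = "synthetic"


@dataclass(frozen=True)
class SmoteConfig:
    """k neighbors, target minority/majority ratio, and the RNG seed."""

    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors must be >= 1")
        if not (0 < self.target_ratio <= 1):
            raise ConfigError("target_ratio must be in (0, 1]")


def smote_augment(
    minority_rows: np.ndarray, n_new: int, cfg: SmoteConfig = SmoteConfig()
) -> np.ndarray:
    """Generate ``n_new`` synthetic rows by uniform segment interpolation.

    Returns an array of shape ``(n_new, n_features)`` together with nothing
    else; use :func:`balance_training_fold` for labelled tables.
    """
    X = np.asarray(minority_rows, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError(
            "SMOTE needs at least 2 minority rows to form an interpolation segment"
        )
    if n_new <= 0:
        return np.empty((0, X.shape[1]))
    n_min = X.shape[0]
    k = min(cfg.k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    # first neighbor is the point itself; drop it
    neighbor_idx = nn.kneighbors(X, return_distance=False)[:, 1:]
    rng = np.random.default_rng(cfg.seed)
    out = np.empty((n_new, X.shape[1]))
    for j in range(n_new):
        seed_row = j % n_min
        neighbor = neighbor_idx[seed_row, rng.integers(k)]
        lam = rng.uniform()
        out[j] = X[seed_row] + lam * (X[neighbor] - X[seed_row])
    return out


def balance_training_fold(
    fold: pd.DataFrame, cfg: SmoteConfig = SmoteConfig()
) -> pd.DataFrame:
    """Augment the minority class of a training fold up to
    ``target_ratio * majority_count``.

    ``fold`` is a windowed-table slice (columns Name, CPP1.., Target, Sex,
    Group). Original rows are returned unmodified with ``synthetic=False``;
    synthetic rows copy Name/Sex/Group metadata from their seed row, carry
    the minority target and ``synthetic=True``.
    """
    counts = fold["Target"].value_counts()
    if len(counts) < 2:
        present = counts.index[0] if len(counts) else "none"
        missing = {"SMS", "N"} - set(counts.index)
        raise ValidationError(
            f"training fold contains only class {present!r}; missing class "
            f"{sorted(missing)}"
        )
    minority = counts.idxmin()
    majority = counts.idxmax()
    if counts[minority] == counts[majority]:
        # conventional tie: nothing to balance
        minority_count = majority_count = counts.iloc[0]
        n_new = 0
    else:
        minority_count = int(counts[minority])
        majority_count = int(counts[majority])
        n_new = int(round(cfg.target_ratio * majority_count)) - minority_count
    base = fold.copy()
    base[SYNTHETIC_FLAG] = False
    if n_new <= 0:
        return base.reset_index(drop=True)
    feature_cols = [c for c in fold.columns if c.startswith("CPP")]
    minority_frame = fold[fold["Target"] == minority]
    synthetic_features = smote_augment(
        minority_frame[feature_cols].to_numpy(dtype=float), n_new, cfg
    )
    seed_rows = minority_frame.iloc[np.arange(n_new) % len(minority_frame)]
    synthetic = seed_rows.copy().reset_index(drop=True)
    synthetic[feature_cols] = synthetic_features
    synthetic["Name"] = [f"synthetic.{minority}.{j + 1}" for j in range(n_new)]
    synthetic[SYNTHETIC_FLAG] = True
    return pd.concat([base, synthetic], ignore_index=True)


class SMOTEBalancer(BaseEstimator):
    """Array-level balancer with the imblearn ``fit_resample`` contract.

    ``fit_resample(X, y)`` returns ``(X_res, y_res)`` where the minority
    class has been topped up to ``target_ratio`` times the majority count;
    original rows come first, synthetic rows after.
    """

    def __init__(self, k_neighbors: int = 5, target_ratio: float = 1.0, seed: int = 0):
        self.k_neighbors = k_neighbors
        self.target_ratio = target_ratio
        self.seed = seed

    def fit_resample(self, X, y):
        cfg = SmoteConfig(self.k_neighbors, self.target_ratio, self.seed)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValidationError("fit_resample needs at least two classes")
        minority = classes[np.argmin(counts)]
        n_new = int(round(cfg.target_ratio * counts.max())) - int(counts.min())
        if n_new <= 0 or counts.min() == counts.max():
            return X.copy(), y.copy()
        synthetic = smote_augment(X[y == minority], n_new, cfg)
        return (
            np.vstack([X, synthetic]),
            np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)]),
        )
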