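"""Data conditioning between featurization and model fitting.

Stages, in pipeline order: Tukey-IQR outlier removal with a row-fraction
trigger, point-biserial (Pearson) feature scoring and greedy redundancy-aware
selection, class-wise jittered replication ("numerical replicas") for
augmentation, and a seeded stratified train/test split.  Every stochastic
stage is a pure function of (input, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Knobs for the conditioning stages.

    ``outlier_method`` 'iqr' flags values outside [Q1 - k*IQR, Q3 + k*IQR]
    per feature and drops a row when more than ``outlier_row_fraction`` of
    its features are flagged.  ``select_min_abs_r`` keeps features whose
    point-biserial |r| against the label reaches the threshold (0 keeps all);
    ``redundancy_r`` then prunes pairwise-correlated survivors.
    ``augment_factor`` replicates each training row with Gaussian jitter of
    sd ``jitter_eps`` times the feature's class-wise sd.
    """

    outlier_method: str = "iqr"
    iqr_k: float = 1.5
    outlier_row_fraction: float = 0.10
    select_min_abs_r: float = 0.0
    redundancy_r: float = 0.95
    augment_factor: int = 1
    jitter_eps: float = 0.01
    test_fraction: float = 0.25
    augment_before_split: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outlier_method not in ("none", "iqr"):
            raise ValueError("outlier_method must be 'none' or 'iqr'")
        if self.iqr_k <= 0:
            raise ValueError("iqr_k must be positive")
        if not 0 <= self.outlier_row_fraction <= 1:
            raise ValueError("outlier_row_fraction must be in [0, 1]")
        if not 0 <= self.select_min_abs_r <= 1:
            raise ValueError("select_min_abs_r must be in [0, 1]")
        if not 0 <= self.redundancy_r <= 1:
            raise ValueError("redundancy_r must be in [0, 1]")
        if self.augment_factor < 1:
            raise ValueError("augment_factor must be >= 1")
        if self.jitter_eps < 0:
            raise ValueError("jitter_eps must be non-negative")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def iqr_outlier_mask(
    fm: FeatureMatrix, k: float = 1.5, row_fraction: float = 0.10
) -> np.ndarray:
    """Boolean keep-mask over rows (True = keep).

    A value is flagged when it lies outside the per-feature Tukey fence
    [Q1 - k*IQR, Q3 + k*IQR]; a row is dropped iff the fraction of its
    flagged features strictly exceeds ``row_fraction``.  Constant features
    have a zero-width fence at their value and flag nothing.
    """
    if fm.n < 4:
        raise ValueError("IQR outlier detection needs at least 4 rows")
    q1, q3 = np.percentile(fm.values, [25, 75], axis=0)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flagged = (fm.values < lo) | (fm.values > hi)
    frac = flagged.mean(axis=1)
    keep = frac <= row_fraction
    if (~keep).any():
        logger.info("IQR outlier filter: dropping %d of %d rows", int((~keep).sum()), fm.n)
    return keep


def pearson_feature_scores(fm: FeatureMatrix) -> np.ndarray:
    """Per-feature |Pearson r| against the binary label (point-biserial).

    Zero-variance features score 0 by convention.
    """
    if fm.labels is None:
        raise ValueError("labels are required for feature scoring")
    y = fm.labels.astype(float)
    if fm.n < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    if len(np.unique(fm.labels)) < 2:
        raise ValueError("both classes must be present to score features")
    X = fm.values
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[sx == 0] = 0.0
    return np.abs(r)


def select_features(
    fm: FeatureMatrix, min_abs_r: float = 0.0, redundancy_r: float = 0.95
) -> tuple[FeatureMatrix, dict]:
    """Correlation-based feature selection with greedy redundancy pruning.

    Features scoring |r| < ``min_abs_r`` are dropped; the survivors are then
    scanned in descending |r| (ties: original column order) and any feature
    whose pairwise |Pearson r| with an already-kept feature exceeds
    ``redundancy_r`` is dropped.  Returns the reduced matrix and a report
    recording kept/dropped names, scores and rules.
    """
    scores = pearson_feature_scores(fm)
    names = list(fm.feature_names)
    by_threshold = [names[i] for i in range(len(names)) if scores[i] < min_abs_r]
    surviving = [i for i in range(len(names)) if scores[i] >= min_abs_r]

    order = sorted(surviving, key=lambda i: (-scores[i], i))
    kept: list[int] = []
    by_redundancy: list[str] = []
    X = fm.values
    for i in order:
        redundant = False
        for j in kept:
            xi, xj = X[:, i], X[:, j]
            si, sj = xi.std(), xj.std()
            if si == 0 or sj == 0:
                rij = 0.0
            else:
                rij = abs(float(np.corrcoef(xi, xj)[0, 1]))
            if rij > redundancy_r:
                redundant = True
                break
        if redundant:
            by_redundancy.append(names[i])
        else:
            kept.append(i)
    kept.sort()  # preserve original column order in the output
    if not kept:
        raise ValueError("feature selection removed every feature; lower the thresholds")
    kept_names = [names[i] for i in kept]
    report = {
        "kept": kept_names,
        "scores": {names[i]: float(scores[i]) for i in range(len(names))},
        "dropped_by_threshold": by_threshold,
        "dropped_by_redundancy": by_redundancy,
        "min_abs_r": min_abs_r,
        "redundancy_r": redundancy_r,
    }
    logger.info(
        "feature selection: kept %d of %d (%d below |r| threshold, %d redundant)",
        len(kept_names), len(names), len(by_threshold), len(by_redundancy),
    )
    return fm.subset_columns(kept_names), report


def augment_dataset(
    fm: FeatureMatrix, factor: int, eps: float = 0.01, seed: int = 0
) -> FeatureMatrix:
    """Class-wise jittered replication of every row.

    Each original row yields ``factor - 1`` replicas whose features are
    perturbed by Gaussian noise with sd = ``eps`` times that feature's
    class-wise population sd (``eps = 0`` gives exact duplicates).  Output
    preserves the class ratio exactly: row count = factor * n.  Replica ids
    carry an ``_aug<k>`` suffix.
    """
    if factor < 1:
        raise ValueError("augmentation factor must be >= 1")
    if fm.labels is None:
        raise ValueError("labels are required for class-wise augmentation")
    if factor == 1:
        return fm
    rng = np.random.default_rng(seed)
    class_sd = np.zeros_like(fm.values)
    for label in np.unique(fm.labels):
        rows = fm.labels == label
        class_sd[rows] = fm.values[rows].std(axis=0)
    ids = list(fm.ids)
    blocks = [fm.values]
    labels = [fm.labels]
    for k in range(1, factor):
        noise = rng.standard_normal(fm.values.shape) * (eps * class_sd)
        blocks.append(fm.values + noise)
        labels.append(fm.labels)
        ids.extend(f"{i}_aug{k}" for i in fm.ids)
    return FeatureMatrix(
        ids, np.vstack(blocks), fm.scheme, np.concatenate(labels), list(fm.feature_names)
    )


def stratified_split(
    fm: FeatureMatrix, test_fraction: float = 0.25, seed: int = 0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded per-class random partition into train and test matrices.

    Test size per class is floor(n_class * test_fraction); the remainder
    stays in train.  The partition is disjoint and exhaustive, and rows keep
    their original relative order.
    """
    if fm.labels is None:
        raise ValueError("labels are required for a stratified split")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for label in np.unique(fm.labels):
        rows = np.flatnonzero(fm.labels == label)
        if rows.size < 2:
            raise ValueError(f"class {label} has fewer than 2 rows; cannot split")
        n_test = int(np.floor(rows.size * test_fraction))
        chosen = rng.permutation(rows)[:n_test]
        test_idx.extend(chosen.tolist())
    test_set = set(test_idx)
    train_rows = [i for i in range(fm.n) if i not in test_set]
    test_rows = [i for i in range(fm.n) if i in test_set]
    return fm.subset_rows(train_rows), fm.subset_rows(test_rows)
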