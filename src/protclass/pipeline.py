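"""End-to-end training pipeline: condition, split, fit, evaluate.

Default order: outlier removal -> feature selection -> stratified split ->
augmentation of the *training* partition only -> fit -> held-out
evaluation.  Setting ``augment_before_split`` replicates the whole matrix
before splitting instead; this reproduces the protocol the reference study
appears to have used (its test-set sizes far exceed its sequence count) but
leaks jittered replicas of training rows into the test partition, so it is
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models
from .evaluation import MetricsReport, evaluate_model
from .features import FeatureMatrix, PropertyTable
from .models import ModelConfig, TrainedModel
from .preprocess import (
    PreprocessConfig,
    augment_dataset,
    iqr_outlier_mask,
    select_features,
    stratified_split,
)


@dataclass
class PipelineResult:
    model: TrainedModel
    report: MetricsReport
    report_json: dict
    train: FeatureMatrix
    test: FeatureMatrix
    selection_report: dict


def run_training(
    fm: FeatureMatrix,
    algo: str,
    config: PreprocessConfig | None = None,
    model_config: ModelConfig | None = None,
    props: PropertyTable | None = None,
) -> PipelineResult:
    """Run the full pipeline on a labeled feature matrix."""
    if fm.labels is None:
        raise ValueError("the training pipeline requires labels")
    if config is None:
        config = PreprocessConfig()
    if config.outlier_method == "iqr":
        fm = fm.subset_rows(
            np.flatnonzero(iqr_outlier_mask(fm, config.iqr_k, config.outlier_row_fraction))
        )
    fm, selection_report = select_features(
        fm, config.select_min_abs_r, config.redundancy_r
    )
    if config.augment_before_split and config.augment_factor > 1:
        fm = augment_dataset(fm, config.augment_factor, config.jitter_eps, config.seed)
    train_fm, test_fm = stratified_split(fm, config.test_fraction, config.seed)
    if not config.augment_before_split and config.augment_factor > 1:
        train_fm = augment_dataset(
            train_fm, config.augment_factor, config.jitter_eps, config.seed
        )
    if model_config is None:
        model_config = models.default_config(algo, fm.scheme, seed=config.seed)
    model = models.train(train_fm, model_config, config.to_dict(), props)
    report, report_json = evaluate_model(
        model,
        test_fm,
        extra={
            "n_train_rows": int(train_fm.n),
            "n_test_rows": int(test_fm.n),
            "selected_features": len(selection_report["kept"]),
            "preprocess": config.to_dict(),
        },
    )
    return PipelineResult(model, report, report_json, train_fm, test_fm, selection_report)
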