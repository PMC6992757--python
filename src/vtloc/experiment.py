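"""End-to-end experiment orchestration.

``run_experiment`` drives the full pipeline from a single configuration:
synthesize (or load) a corpus of originals -> augment x11 -> build the
split plan (CV10 or LoSo) -> train fresh localizers per fold -> predict on
the fold's test items -> assemble one pooled evaluation report.  All
randomness derives from the single ``seed``, and the report carries the
split manifest, so re-running the data stages with the same configuration
reproduces byte-identical inputs.

``compare_methods`` lines up several reports produced on the *same* split
manifest and runs pairwise paired t-tests on their matched distance
records.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .augment import augment_corpus
from .evaluation import (DegenerateInputError, EvaluationReport, SplitPlan,
                         build_report, make_cv_splits, make_loso_splits,
                         paired_ttest)
from .flatnet import (FlatNetConfig, TrainConfig, partition_landmarks,
                      predict_landmarks, train_localizer)
from .heatmap import CodecConfig
from .io import read_corpus
from .phantom import PhantomConfig, generate_corpus
from .schema import load_schema

logger = logging.getLogger("vtloc")

__all__ = ["ExperimentConfig", "run_experiment", "compare_methods"]


@dataclass
class ExperimentConfig:
    """One experiment: input source + sub-configs + scheme + output dir.

    Exactly one input source must be set: either ``phantom`` (synthetic
    corpus) or ``annotations_path`` + ``images_dir`` (external corpus).
    """

    scheme: str = "LoSo"                   # "LoSo" or "CV10"
    seed: int = 0
    output_dir: str | None = None
    phantom: PhantomConfig | None = None
    annotations_path: str | None = None
    images_dir: str | None = None
    codec: CodecConfig = field(default_factory=CodecConfig)
    flatnet: FlatNetConfig = field(default_factory=FlatNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    max_per_network: int = 5
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if self.scheme not in ("LoSo", "CV10"):
            raise ValueError("scheme must be 'LoSo' or 'CV10'")
        have_phantom = self.phantom is not None
        have_external = self.annotations_path is not None
        if have_phantom == have_external:
            raise ValueError("exactly one input source (phantom or external "
                             "corpus paths) must be configured")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        if "phantom" in kwargs and kwargs["phantom"] is not None:
            ph = dict(kwargs["phantom"])
            if "image_size" in ph:
                ph["image_size"] = tuple(ph["image_size"])
            kwargs["phantom"] = PhantomConfig(**ph)
        if "codec" in kwargs:
            kwargs["codec"] = CodecConfig(**kwargs["codec"])
        if "flatnet" in kwargs:
            fn = dict(kwargs["flatnet"])
            for key in ("branch_dilation_rates", "target_range"):
                if key in fn:
                    fn[key] = tuple(fn[key])
            kwargs["flatnet"] = FlatNetConfig(**fn)
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        cfg = cls(**kwargs)
        if seed is not None:
            cfg.seed = seed
        return cfg


def _load_originals(config: ExperimentConfig):
    if config.phantom is not None:
        return generate_corpus(config.phantom)
    return read_corpus(config.annotations_path, config.images_dir)


def run_experiment(config: ExperimentConfig) -> EvaluationReport:
    """Execute the configured pipeline and return the pooled report.

    Models are retrained from scratch for every fold.  Under LoSo a
    runtime assertion verifies that no fold's training data contains the
    fold's test subject.  When ``output_dir`` is set, the report (JSON +
    CSV matrices), the split manifest and per-fold model directories are
    written there.
    """
    originals = _load_originals(config)
    augmented = augment_corpus(originals, seed=config.seed)
    logger.info("corpus: %d originals -> %d augmented items",
                len(originals), len(augmented))
    if config.scheme == "LoSo":
        plan = make_loso_splits(augmented, originals)
    else:
        plan = make_cv_splits(augmented, k=config.cv_folds, seed=config.seed)
    by_key = {it.key: it for it in augmented.items}
    partition = partition_landmarks(load_schema(), config.max_per_network)
    resolution = originals[0].resolution_mm_per_px

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "split_manifest.json").write_text(
            json.dumps(plan.manifest(), indent=1))

    all_test_items, predictions = [], {}
    for f, (train_keys, test_keys) in enumerate(plan.folds):
        train_items = [by_key[k] for k in train_keys]
        test_items = [by_key[k] for k in test_keys]
        if config.scheme == "LoSo":
            test_subjects = {it.subject_id for it in test_items}
            leaked = [it.key for it in train_items
                      if it.subject_id in test_subjects]
            assert not leaked, f"LoSo fold {f}: test subject leaked into training"
        logger.info("fold %d/%d: %d train / %d test items",
                    f + 1, len(plan.folds), len(train_items), len(test_items))
        fold_train = TrainConfig(**{**asdict(config.train),
                                    "rng_seed": config.train.rng_seed + f})
        localizer = train_localizer(train_items, partition, config.flatnet,
                                    fold_train, codec=config.codec)
        if out_dir:
            localizer.save(out_dir / f"fold{f}_model")
        for it in test_items:
            predictions[it.key] = predict_landmarks(localizer, it.image)
        all_test_items.extend(test_items)

    report = build_report(all_test_items, predictions, plan,
                          resolution_mm_per_px=resolution)
    if out_dir:
        report.to_json(out_dir / "report.json")
        report.to_csv(out_dir / "per_landmark.csv", out_dir / "per_subject.csv")
    return report


def compare_methods(reports: list[EvaluationReport],
                    names: list[str] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Side-by-side metrics and pairwise p-values for matched reports.

    All reports must share the same split manifest (same folds over the
    same items); distance records are matched per (image, landmark).
    Returns ``(summary, pvalues)`` DataFrames, ordered as the input.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    names = names or [f"method{i}" for i in range(len(reports))]
    manifests = [r.split_manifest for r in reports]
    if any(m != manifests[0] for m in manifests[1:]):
        raise ValueError("reports do not share the same split manifest")
    keysets = [tuple((r.image_id, r.landmark) for r in rep.records)
               for rep in reports]
    if any(k != keysets[0] for k in keysets[1:]):
        raise ValueError("reports do not cover identical (image, landmark) records")
    summary = pd.DataFrame({
        "method": names,
        "rmse_px": [r.overall_rmse_px for r in reports],
        "rmse_cm": [r.overall_rmse_cm for r in reports],
        "outlier_pct": [r.overall_outlier_pct for r in reports],
        "mean_distance_px": [float(r.distances().mean()) for r in reports],
    })
    pv = np.full((len(reports), len(reports)), np.nan)
    for i in range(len(reports)):
        for j in range(len(reports)):
            if i == j:
                continue
            _, p = paired_ttest(reports[i].distances(), reports[j].distances())
            pv[i, j] = p
    pvalues = pd.DataFrame(pv, index=names, columns=names)
    return summary, pvalues
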