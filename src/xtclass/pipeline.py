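"""End-to-end orchestration: cluster → extract → split → select → fit
→ calibrate → evaluate → predict, as a single reproducible run.

Every stochastic stage receives its seed from the run's global seed,
all effective settings (including defaults) are written to the run
manifest, and repeating a run with the same config and seed reproduces
the predictions file byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import learn, seqio
from .descriptors import DescriptorConfig, extract_all
from .imbalance import ResampleConfig
from .learn import (
    ModelBundle,
    MetricsReport,
    SplitConfig,
    XyloseTransportModel,
    deserialize,
)
from .profiles import build_profile_features
from .redundancy import greedy_cluster
from .seqio import XtclassError
from .synthetic import SyntheticFixture

logger = logging.getLogger("xtclass")


@dataclass
class RunConfig:
    """All knobs of one pipeline run (defaults land in the manifest)."""

    fasta: str | None = None
    labels: str | None = None
    msa: str | None = None
    regions: str | None = None
    out_dir: str = "xtclass_run"
    descriptors: DescriptorConfig = field(default_factory=DescriptorConfig.compact)
    resample: ResampleConfig = field(default_factory=ResampleConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    learner_params: dict = field(default_factory=dict)
    rfecv_step: float | int | None = 0.25
    rfecv_folds: int = 5
    rfecv_metric: str = "average_precision"
    rfecv_min_features: int = learn.IMPORTANCE_REPORT_ROWS
    threshold_mode: str = "fixed"
    threshold: float = learn.STRICT_THRESHOLD
    cluster: bool = True
    cluster_threshold: float = 0.8
    prosite_patterns: tuple[str, ...] = ()
    hmm_alpha: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        doc = {
            "fasta": self.fasta,
            "labels": self.labels,
            "msa": self.msa,
            "regions": self.regions,
            "out_dir": self.out_dir,
            "descriptors": self.descriptors.to_dict(),
            "resample": self.resample.to_dict(),
            "split": {
                "train_fraction": self.split.train_fraction,
                "stratified": self.split.stratified,
                "seed": self.split.seed,
            },
            "learner_params": self.learner_params,
            "rfecv_step": self.rfecv_step,
            "rfecv_folds": self.rfecv_folds,
            "rfecv_metric": self.rfecv_metric,
            "rfecv_min_features": self.rfecv_min_features,
            "threshold_mode": self.threshold_mode,
            "threshold": self.threshold,
            "cluster": self.cluster,
            "cluster_threshold": self.cluster_threshold,
            "prosite_patterns": list(self.prosite_patterns),
            "hmm_alpha": self.hmm_alpha,
            "seed": self.seed,
        }
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        if "descriptors" in doc:
            doc["descriptors"] = DescriptorConfig.from_dict(doc["descriptors"])
        if "resample" in doc:
            doc["resample"] = ResampleConfig.from_dict(doc["resample"])
        if "split" in doc:
            doc["split"] = SplitConfig(**doc["split"])
        if "prosite_patterns" in doc:
            doc["prosite_patterns"] = tuple(doc["prosite_patterns"])
        return cls(**doc)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def with_seed(self, seed: int) -> "RunConfig":
        """Propagate one global seed into every stochastic stage."""
        doc = self.to_dict()
        doc["seed"] = seed
        doc["split"]["seed"] = seed
        doc["resample"]["seed"] = seed
        return RunConfig.from_dict(doc)


@dataclass
class RunResult:
    out_dir: Path
    bundle: ModelBundle
    metrics_default: MetricsReport
    metrics_strict: MetricsReport
    predictions: pd.DataFrame
    manifest: dict


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run(
    config: RunConfig,
    fixture: SyntheticFixture | None = None,
) -> RunResult:
    """Execute the full pipeline; artifacts land in config.out_dir.

    *fixture* supplies in-memory inputs (dataset, alignment, regions)
    instead of the configured paths — used for synthetic-data runs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out_dir)
    manifest: dict = {
        "config": config.with_seed(config.seed).to_dict(),
        "stages": [],
    }
    config = config.with_seed(config.seed)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            logger.info("[%s] start", name)
            try:
                out = fn()
            except Exception as exc:
                manifest["stages"].append(
                    {"name": name, "error": str(exc)}
                )
                with open(out_dir / "manifest.json", "w") as fh:
                    json.dump(manifest, fh, indent=1, default=str)
                logger.error("[%s] failed: %s", name, exc)
                raise
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3)}
            )
            logger.info("[%s] done", name)
            return out
        return wrap

    try:
        def _load():
            if fixture is not None:
                return fixture.dataset, fixture.msa, fixture.annotation
            if not all((config.fasta, config.labels, config.msa, config.regions)):
                raise XtclassError(
                    "run needs fasta, labels, msa and regions paths"
                )
            records = seqio.read_fasta(config.fasta)
            dataset = seqio.load_labels(config.labels, records, logger=logger)
            msa = seqio.read_fasta(config.msa, gapped=True)
            ann = seqio.read_regions_json(config.regions)
            msa.reference_id = ann.reference_id
            if ann.reference_id not in [i for i, _ in msa.rows]:
                raise XtclassError(
                    f"annotation reference {ann.reference_id!r} missing "
                    "from the alignment"
                )
            return dataset, msa, ann

        dataset, msa, ann = stage("load")(_load)
        manifest["input_count"] = len(dataset.records)
        pos, neg = dataset.class_counts()
        manifest["input_class_counts"] = {"positive": pos, "negative": neg}

        def _cluster():
            if not config.cluster:
                return dataset
            protected = {i for i, l in dataset.labels.items() if l == 1}
            result = greedy_cluster(
                dataset, threshold=config.cluster_threshold,
                protected=protected,
            )
            kept = dataset.subset(result.output_ids)
            logger.info(
                "clustering kept %d / %d sequences",
                len(kept.records), len(dataset.records),
            )
            return kept

        dataset = stage("cluster")(_cluster)
        manifest["post_cluster_count"] = len(dataset.records)

        def _profiles():
            return build_profile_features(
                msa, annotation=ann,
                patterns=list(config.prosite_patterns),
                alpha=config.hmm_alpha,
            )

        profile_set = stage("profiles")(_profiles)

        def _extract():
            prof = profile_set.features(dataset.records)
            return extract_all(dataset, config.descriptors, prof)

        features = stage("extract")(_extract)
        manifest["n_features"] = int(features.shape[1])
        seqio.write_features(features, out_dir / "features.tsv")

        y = pd.Series(
            [dataset.labels[i] for i in features.index], index=features.index
        )

        def _split():
            return learn.split(features, y, config.split)

        X_train, y_train, X_test, y_test = stage("split")(_split)
        manifest["train_class_counts"] = (
            y_train.value_counts().to_dict()
        )
        manifest["test_class_counts"] = y_test.value_counts().to_dict()

        def _fit():
            model = XyloseTransportModel(
                X_train, y_train,
                resample_cfg=config.resample,
                rfecv_step=config.rfecv_step,
                rfecv_folds=config.rfecv_folds,
                rfecv_metric=config.rfecv_metric,
                rfecv_min_features=config.rfecv_min_features,
                learner=learn.GradientBoostingLearner(
                    config.seed, **config.learner_params
                ),
                seed=config.seed,
            )
            return model.fit()

        results = stage("select+fit")(_fit)
        manifest["selected_features"] = results.selected_features
        results.bundle.metadata["descriptors"] = config.descriptors.to_dict()
        results.bundle.metadata["prosite_patterns"] = list(
            config.prosite_patterns
        )

        def _calibrate():
            if config.threshold_mode == "fixed":
                return results.calibrate(mode="fixed", value=config.threshold)
            return results.calibrate(
                mode="precision_floor", value=config.threshold,
                X_val=X_train, y_val=y_train,
            )

        strict = stage("calibrate")(_calibrate)

        def _evaluate():
            m1 = results.evaluate(X_test, y_test)
            m2 = strict.evaluate(X_test, y_test)
            return m1, m2

        metrics_default, metrics_strict = stage("evaluate")(_evaluate)
        manifest["metrics"] = {
            "model1_default_threshold": metrics_default.to_dict(),
            "model2_strict_threshold": metrics_strict.to_dict(),
        }

        def _predict():
            preds = strict.predict(X_test)
            preds.to_csv(
                out_dir / "predictions.tsv", sep="\t", float_format="%.17g"
            )
            return preds

        predictions = stage("predict")(_predict)

        strict.save(out_dir / "model.json")
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(manifest["metrics"], fh, indent=1)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return RunResult(
            out_dir=out_dir,
            bundle=strict.bundle,
            metrics_default=metrics_default,
            metrics_strict=metrics_strict,
            predictions=predictions,
            manifest=manifest,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


def screen(
    model_path,
    candidate_fasta,
    msa_path,
    regions_path,
    out_path=None,
) -> pd.DataFrame:
    """Score candidate sequences against a trained model.

    Features are extracted exactly as during training (descriptor
    config and PROSITE patterns are read from the model metadata; the
    profile models are rebuilt from the supplied alignment and region
    annotation) and the ranked table is sorted by descending
    probability.
    """
    bundle = deserialize(model_path)
    meta = bundle.metadata
    if "descriptors" not in meta:
        raise XtclassError(
            "model metadata lacks the descriptor config; cannot guarantee "
            "a matching feature schema"
        )
    config = DescriptorConfig.from_dict(meta["descriptors"])
    try:
        records = seqio.read_fasta(candidate_fasta)
    except XtclassError as exc:
        if "no FASTA records" in str(exc):
            logger.warning("empty candidate file %s", candidate_fasta)
            empty = pd.DataFrame(
                columns=["probability", "predicted", "near_miss"]
            )
            empty.index.name = "id"
            if out_path:
                empty.to_csv(out_path, sep="\t")
            return empty
        raise
    msa = seqio.read_fasta(msa_path, gapped=True)
    ann = seqio.read_regions_json(regions_path)
    msa.reference_id = ann.reference_id
    profile_set = build_profile_features(
        msa, annotation=ann, patterns=meta.get("prosite_patterns", [])
    )
    prof = profile_set.features(records)
    features = extract_all(records, config, prof)
    missing = [f for f in bundle.selected_features if f not in features.columns]
    if missing:
        raise XtclassError(
            "feature-schema mismatch between model and extraction: "
            f"missing {missing[:5]}"
        )
    table = learn.predict(bundle, features)
    table = table.sort_values("probability", ascending=False, kind="stable")
    if out_path:
        table.to_csv(out_path, sep="\t", float_format="%.17g")
    return table
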