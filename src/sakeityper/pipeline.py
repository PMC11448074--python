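"""End-to-end orchestration: simulate -> preprocess -> peaks -> classify -> evaluate.

A :class:`RunConfig` fully determines a run: one master seed is split into
per-stage seeds (profile sampling, spectrum noise, train/test split, model
fitting), so a config plus seed reproduces a run bit-for-bit.  Every output
file records the hash of the config that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify, evaluate, peaks, preprocess, simulate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration of a full pipeline run."""

    design: simulate.CohortDesign = field(default_factory=simulate.default_design)
    noise: simulate.NoiseParams = field(default_factory=simulate.NoiseParams)
    preprocess: preprocess.PreprocessParams = field(
        default_factory=preprocess.PreprocessParams
    )
    split: classify.SplitSpec = field(default_factory=classify.SplitSpec)
    models: tuple[str, ...] = ("plsda", "pcaknn", "svm", "rf")
    association_classes: tuple[str, str] = (simulate.SAKEI, simulate.CARNOSUS)
    alpha: float = 0.01
    top_k: int = 10
    aggregation: str = "macro"
    importance_top_fraction: float = 0.10
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        def enc(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return enc(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        if "design" in raw:
            d = dict(raw["design"])
            for key in ("class_names", "strains_per_class", "methods", "mz_range"):
                if key in d:
                    d[key] = tuple(d[key])
            kwargs["design"] = simulate.CohortDesign(**d)
        if "noise" in raw:
            kwargs["noise"] = simulate.NoiseParams(**raw["noise"])
        if "preprocess" in raw:
            kwargs["preprocess"] = preprocess.PreprocessParams(**raw["preprocess"])
        if "split" in raw:
            kwargs["split"] = classify.SplitSpec(**raw["split"])
        for key in (
            "models",
            "association_classes",
            "alpha",
            "top_k",
            "aggregation",
            "importance_top_fraction",
            "seed",
        ):
            if key in raw:
                val = raw[key]
                kwargs[key] = tuple(val) if isinstance(val, list) else val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def stage_seeds(master: int) -> dict[str, int]:
    """Derive independent per-stage seeds (< 2**31) from one master seed."""
    names = ("cohort", "split", "models")
    children = np.random.SeedSequence(master).spawn(len(names))
    return {
        n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)
    }


@dataclass
class RunResult:
    """In-memory results of one pipeline run."""

    config: RunConfig
    manifest: pd.DataFrame
    features: preprocess.FeatureMatrix
    presence: peaks.PresenceMatrix
    associations: list[peaks.PeakAssociation]
    models: dict[str, classify.TrainedModel]
    reports: dict[str, dict[str, Any]]
    importance: classify.ImportanceRanking | None


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full pipeline; optionally write all artifacts to ``out_dir``."""
    chash = config.config_hash()
    seeds = stage_seeds(config.seed)
    timings: dict[str, float] = {}

    def _stage(name: str):
        logger.info("stage %s ...", name)
        timings[name] = time.perf_counter()

    def _done(name: str):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s done in %.1fs", name, timings[name])

    try:
        _stage("simulate")
        spectra, manifest = simulate.generate_cohort(
            config.design, noise=config.noise, seed=seeds["cohort"]
        )
        _done("simulate")
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        _stage("preprocess")
        labels = pd.Series(
            manifest["class_label"].to_numpy(), index=manifest["spectrum_id"]
        )
        features, _, _ = preprocess.preprocess_cohort(
            [ls.spectrum for ls in spectra], config.preprocess, labels=labels
        )
        _done("preprocess")
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    try:
        _stage("peaks")
        presence = peaks.strain_presence(features, manifest)
        cls_a, cls_b = config.association_classes
        associations = peaks.discriminative_peaks(
            presence, cls_a, cls_b, alpha=config.alpha, k=config.top_k
        )
        _done("peaks")
    except Exception as exc:
        raise RuntimeError(f"stage 'peaks' failed: {exc}") from exc

    try:
        _stage("classify")
        split = dataclasses.replace(config.split, seed=seeds["split"])
        train, test = classify.split_data(features, split, manifest=manifest)
        trained: dict[str, classify.TrainedModel] = {}
        reports: dict[str, dict[str, Any]] = {}
        for name in config.models:
            model = classify.train_model(train, name, seed=seeds["models"])
            trained[name] = model
            reports[name] = _evaluate_model(model, train, test, config.aggregation)
        importance = (
            classify.rf_importance(trained["rf"], config.importance_top_fraction)
            if "rf" in trained
            else None
        )
        _done("classify")
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    result = RunResult(
        config=config,
        manifest=manifest,
        features=features,
        presence=presence,
        associations=associations,
        models=trained,
        reports=reports,
        importance=importance,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir), chash, timings)
    return result


def _evaluate_model(
    model: classify.TrainedModel,
    train: preprocess.FeatureMatrix,
    test: preprocess.FeatureMatrix,
    aggregation: str,
) -> dict[str, Any]:
    """Train/test accuracies, the five metrics (test), and test AUROC."""
    class_order = list(model.classes)
    pred_train, _ = classify.predict(model, train)
    pred_test, scores_test = classify.predict(model, test)
    cm_train = evaluate.confusion(train.labels.to_numpy(), pred_train, class_order)
    cm_test = evaluate.confusion(test.labels.to_numpy(), pred_test, class_order)
    rep = evaluate.metrics(cm_test, aggregation=aggregation)
    roc = evaluate.roc_auc(test.labels.to_numpy(), scores_test, class_order)
    return {
        "model": model.spec.name,
        "train_accuracy": evaluate.metrics(cm_train).overall_accuracy,
        "test_accuracy": rep.overall_accuracy,
        "n_misclassified_test": int(cm_test.total - np.trace(cm_test.counts)),
        "aggregate": rep.aggregate,
        "per_class": rep.per_class,
        "confusion_test": cm_test.to_frame().to_dict(),
        "auroc_per_class": roc.auroc,
        "macro_auroc": roc.macro_auroc,
        "roc": roc,
        "predictions_test": pd.DataFrame(
            {
                "spectrum_id": test.intensities.index,
                "true": test.labels.to_numpy(),
                "predicted": pred_test,
            }
        ).join(scores_test.reset_index(drop=True)),
    }


def _json_safe(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, (pd.DataFrame, evaluate.ROCResult)):
        return None
    return obj


def _write_outputs(
    result: RunResult, out_dir: Path, chash: str, timings: dict[str, float]
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    result.features.to_tsv(out_dir / "feature_matrix.tsv", config_hash=chash)
    result.presence.to_tsv(out_dir / "presence_matrix.tsv", config_hash=chash)
    assoc = peaks.associations_table(result.associations)
    with open(out_dir / "associations.tsv", "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        assoc.to_csv(fh, sep="\t", index=False)
    for name, rep in result.reports.items():
        rep["predictions_test"].to_csv(
            out_dir / f"predictions_{name}.tsv", sep="\t", index=False
        )
        roc: evaluate.ROCResult = rep["roc"]
        roc.points_frame().to_csv(out_dir / f"roc_points_{name}.csv", index=False)
        safe = {k: _json_safe(v) for k, v in rep.items() if k not in ("roc", "predictions_test")}
        safe["config_hash"] = chash
        with open(out_dir / f"report_{name}.json", "w") as fh:
            json.dump(safe, fh, indent=2)
    if result.importance is not None:
        pd.DataFrame(result.importance.ranking, columns=["bin_mz", "importance"]).to_csv(
            out_dir / "rf_importance.tsv", sep="\t", index=False
        )
    provenance = {
        "config_hash": chash,
        "config": result.config.to_dict(),
        "stage_seeds": stage_seeds(result.config.seed),
        "stage_seconds": {k: round(v, 2) for k, v in timings.items()},
        "n_spectra": int(len(result.manifest)),
        "n_peak_bins": int(result.features.bin_mz.size),
    }
    with open(out_dir / "run.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(result.config.to_dict(), fh, sort_keys=False)
    logger.info("wrote run artifacts to %s (config %s)", out_dir, chash)
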