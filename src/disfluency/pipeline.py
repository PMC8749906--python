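"""Configuration-driven end-to-end runs.

``run_pipeline`` chains synthesize -> front-end -> features (PCA residual
distances or SOM winner indices) -> stratified split -> MLP training ->
evaluation, optionally writing every artifact (feature table, split
manifest, model JSON, report JSON, resolved config) to a run directory.
``compare`` runs both feature arms on the identical dataset and lays the
recognition rates out side by side.  The whole chain is a pure function of
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import (MLPDisfluencyClassifier, ClassificationReport,
                         SplitPlan, TABLE_SPLIT_PLAN, evaluate,
                         split_indices)
from .frontend import ThirdOctaveFrontend
from .pca import ResidualDistanceExtractor
from .som import SOMFeatureExtractor
from .synth import CLASSES, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "compare", "plot_distance_trace",
           "TABLE_CLASS_COUNTS"]

log = logging.getLogger("disfluency")

#: Reference corpus composition (per-class utterance totals).
TABLE_CLASS_COUNTS = {"block": 55, "repetition": 46, "prolongation": 59,
                      "fluent": 38}


@dataclass
class RunConfig:
    seed: int = 0
    class_counts: dict = field(
        default_factory=lambda: dict(TABLE_CLASS_COUNTS))
    difficulty: str = "easy"
    feature_method: str = "pca"
    l_override: int | None = 4
    a_weighting: bool = True
    som_epochs: int = 100
    som_lr: float = 0.1
    som_nb_start: int = 3
    som_grid: tuple = (5, 5)
    mlp_hidden: int = 8
    mlp_iters: int = 100
    out_dir: str | None = None

    def __post_init__(self):
        if self.feature_method not in ("pca", "som"):
            raise ValueError("feature_method must be 'pca' or 'som'")
        for label, n in self.class_counts.items():
            if label not in CLASSES:
                raise ValueError(f"unknown class {label!r}")
            if n < 0:
                raise ValueError("class counts must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        if "som_grid" in obj:
            obj["som_grid"] = tuple(obj["som_grid"])
        return cls(**obj)

    def to_yaml(self) -> str:
        obj = dataclasses.asdict(self)
        obj["som_grid"] = list(obj["som_grid"])
        return yaml.safe_dump(obj, sort_keys=True)


def _split_plan(class_counts: dict) -> SplitPlan:
    if class_counts == TABLE_CLASS_COUNTS:
        return TABLE_SPLIT_PLAN
    return SplitPlan.proportional(class_counts)


def _features(config: RunConfig, matrices):
    if config.feature_method == "pca":
        ext = ResidualDistanceExtractor(n_components=config.l_override)
    else:
        ext = SOMFeatureExtractor(grid_shape=tuple(config.som_grid),
                                  epochs=config.som_epochs,
                                  lr=config.som_lr,
                                  nb_start=config.som_nb_start,
                                  random_state=config.seed)
    return ext.fit(matrices).transform(matrices)


def run_pipeline(config: RunConfig) -> ClassificationReport:
    """Execute every stage; write artifacts when ``config.out_dir`` is set."""
    t0 = time.perf_counter()
    stage = "synthesize"
    try:
        dataset = generate_dataset(config.class_counts, seed=config.seed,
                                   difficulty=config.difficulty)
        labels = dataset.labels
        log.info("synthesized %d utterances (%.1fs)", len(dataset),
                 time.perf_counter() - t0)

        stage = "extract"
        frontend = ThirdOctaveFrontend(a_weighting=config.a_weighting).fit()
        matrices = frontend.transform(dataset)

        stage = "features"
        F = _features(config, matrices)

        stage = "split"
        plan = _split_plan(config.class_counts)
        tr, va, te = split_indices(labels, plan, seed=config.seed)

        stage = "train"
        est = MLPDisfluencyClassifier(hidden_units=config.mlp_hidden,
                                      max_iter=config.mlp_iters,
                                      random_state=config.seed)
        est.fit(F[tr], labels[tr], validation=(F[va], labels[va]))

        stage = "evaluate"
        report = evaluate(est, F[te], labels[te])
        log.info("pipeline (%s arm) done in %.1fs: acc=%.4f",
                 config.feature_method, time.perf_counter() - t0,
                 report.accuracy)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") \
            from exc

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        feat = pd.DataFrame(F)
        feat.insert(0, "label", labels)
        feat.insert(0, "id", [u.id for u in dataset])
        feat.to_csv(out / "features.csv", index=False)
        (out / "split.json").write_text(json.dumps(
            {"train": tr.tolist(), "validation": va.tolist(),
             "test": te.tolist()}, sort_keys=True))
        (out / "model.json").write_text(est.to_json())
        (out / "report.json").write_text(report.to_json())
        (out / "config_resolved.yaml").write_text(config.to_yaml())
        (out / "manifest.json").write_text(json.dumps({
            "artifacts": ["features.csv", "split.json", "model.json",
                          "report.json", "config_resolved.yaml"],
            "feature_method": config.feature_method,
            "n_samples": len(dataset), "seed": config.seed},
            sort_keys=True))
    return report


def compare(config: RunConfig) -> dict:
    """Run the PCA and SOM arms on the same synthetic dataset and summarise
    recognition rates in a side-by-side table."""
    rows = {}
    reports = {}
    for method in ("pca", "som"):
        cfg = dataclasses.replace(
            config, feature_method=method,
            out_dir=(str(Path(config.out_dir) / method)
                     if config.out_dir else None))
        rep = run_pipeline(cfg)
        reports[method] = rep
        row = {"acc": round(rep.accuracy, 4),
               "eps": round(rep.error_rate, 4)}
        for lab in rep.labels:
            row[lab] = round(rep.per_class_accuracy[lab], 4)
        rows[method.upper()] = row
    table = pd.DataFrame(rows).T
    out = {"table": table, "reports": reports}
    if config.out_dir:
        table.to_csv(Path(config.out_dir) / "comparison.csv")
    return out


def plot_distance_trace(sample, features, out_path) -> None:
    """Distance-vs-time curve for one utterance (silence sits near the
    model, bursts stand far from it)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = np.asarray(features.d if hasattr(features, "d") else features,
                   dtype=np.float64)
    times = sample.frame_times()
    if len(times) != len(d):
        raise ValueError("distance vector length does not match frame count")
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(times, d, lw=1.0, color="tab:blue")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("distance from PCA model")
    ax.set_title(sample.sample_id or "distance trace")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
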