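"""End-to-end experiment orchestration and evaluation reporting.

``run_experiment`` wires the stages together — synthesize (or ingest) a
panel dataset, compute USMs, optionally train the multi-task residual
network, select the C most informative images, compute each held-out
target person's similarity profile from those images alone, predict their
attention maps on test images, and score the predictions — under one
seeded configuration, producing an :class:`EvaluationReport` whose means
are exact averages of the per-person entries.

Two sources of panel predictions are supported: ``psm_source="network"``
runs the trained multi-task CNN (the full method), while
``psm_source="ground_truth"`` substitutes the panel's measured maps —
useful for isolating the selection/similarity machinery from network
capacity, and the default for fast synthetic studies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import attention_maps as am
from . import adaptive_selection as sel
from . import few_shot_prediction as fsp
from . import psm_network as net
from . import synthetic_gaze as syn

logger = logging.getLogger("persalmap")

METRIC_FUNCS = {
    "cc": am.metric_cc,
    "sim": am.metric_sim,
    "kldiv": am.metric_kldiv,
}


@dataclass(frozen=True)
class SyntheticDataConfig:
    P: int = 12
    N: int = 60
    M: int = 6
    height: int = 64
    width: int = 64
    n_clusters: int = 3
    jitter: float = 0.05
    active_categories: tuple[int, ...] | None = None
    base_weight: float = 0.15
    idiosyncrasy_noise: float = 0.03


@dataclass(frozen=True)
class SplitConfig:
    """Seeded random train/test and panel/target splits.

    Defaults mirror the 1100/500 image and 20/10 person proportions of a
    full-scale panel study.
    """

    train_image_fraction: float = 0.6875
    panel_person_fraction: float = 2.0 / 3.0


@dataclass(frozen=True)
class SelectionConfig:
    strategy: str = "ais"  # ais | ispsm | isvf | random
    C: int = 10
    normalize: str | None = "unit_sum"


@dataclass(frozen=True)
class FewShotConfig:
    tau: float = fsp.DEFAULT_TAU
    corr_mode: str = "pearson"
    psm_source: str = "ground_truth"  # ground_truth | network


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    data: SyntheticDataConfig = field(default_factory=SyntheticDataConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    fpsp: FewShotConfig = field(default_factory=FewShotConfig)
    metrics: tuple[str, ...] = ("cc", "sim", "kldiv")
    network: net.NetworkConfig | None = None
    training: net.TrainConfig | None = None

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        def build(cls, key):
            sub = dict(d.get(key) or {})
            if key == "data" and isinstance(sub.get("active_categories"), list):
                sub["active_categories"] = tuple(sub["active_categories"])
            return cls(**sub)

        cfg = PipelineConfig(
            seed=int(d.get("seed", 0)),
            data=build(SyntheticDataConfig, "data"),
            split=build(SplitConfig, "split"),
            selection=build(SelectionConfig, "selection"),
            fpsp=build(FewShotConfig, "fpsp"),
            metrics=tuple(d.get("metrics", ("cc", "sim", "kldiv"))),
        )
        if d.get("network"):
            nd = dict(d["network"])
            for k in ("encoder_channels", "decoder_channels"):
                if k in nd:
                    nd[k] = tuple(nd[k])
            cfg = dataclasses.replace(cfg, network=net.NetworkConfig(**nd))
        if d.get("training"):
            cfg = dataclasses.replace(cfg, training=net.TrainConfig(**d["training"]))
        return cfg

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


@dataclass
class EvaluationReport:
    """Per-person and mean metric values for one experiment."""

    strategy: str
    C: int
    seed: int
    per_person: dict[str, dict[str, float]]
    means: dict[str, float]

    def __post_init__(self) -> None:
        for metric, mean in self.means.items():
            vals = [v[metric] for v in self.per_person.values()]
            if vals and abs(mean - float(np.mean(vals))) > 1e-9:
                raise ValueError(f"mean of {metric} is not the average of per-person values")

    def to_json(self, path=None) -> str:
        doc = json.dumps(dataclasses.asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    def to_csv(self, path) -> None:
        rows = [
            {"person_id": pid, **vals} for pid, vals in self.per_person.items()
        ]
        rows.append({"person_id": "mean", **self.means})
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(
    predictions: dict[str, list[am.SaliencyMap]],
    ground_truth: dict[str, list[am.SaliencyMap]],
    metrics: Sequence[str] = ("cc", "sim", "kldiv"),
    strategy: str = "",
    C: int = 0,
    seed: int = 0,
) -> EvaluationReport:
    """Score per-person predictions against ground truth.

    ``predictions[pid]`` and ``ground_truth[pid]`` are aligned lists of
    maps; persons missing from the ground truth are excluded with a
    warning.  Each person's entry is the mean of each metric over their
    images; report means average the per-person entries.
    """
    unknown = [m for m in metrics if m not in METRIC_FUNCS]
    if unknown:
        raise ValueError(f"unknown metrics: {unknown}")
    per_person: dict[str, dict[str, float]] = {}
    for pid, preds in predictions.items():
        if pid not in ground_truth:
            logger.warning("no ground truth for person %s; excluded from report", pid)
            continue
        gts = ground_truth[pid]
        if len(gts) != len(preds):
            raise ValueError(f"person {pid}: {len(preds)} predictions vs {len(gts)} ground truths")
        per_person[pid] = {
            m: float(np.mean([METRIC_FUNCS[m](pr, gt) for pr, gt in zip(preds, gts)]))
            for m in metrics
        }
    means = {
        m: float(np.mean([v[m] for v in per_person.values()])) for m in metrics
    } if per_person else {m: float("nan") for m in metrics}
    return EvaluationReport(strategy=strategy, C=C, seed=seed, per_person=per_person, means=means)


# ---------------------------------------------------------------------------
# Experiment
# ---------------------------------------------------------------------------

def _split_indices(n: int, fraction: float, rng: np.random.Generator) -> tuple[list[int], list[int]]:
    perm = rng.permutation(n)
    k = max(1, min(n - 1, int(round(n * fraction))))
    return sorted(int(i) for i in perm[:k]), sorted(int(i) for i in perm[k:])


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-10s done in %.2fs", name, t1 - t0)
    return t1


def run_experiment(config: PipelineConfig, dataset: syn.SyntheticDataset | None = None) -> EvaluationReport:
    """Run the full few-shot prediction experiment on (synthetic) panel data.

    Stages: simulate → (train) → select → similarity/predict → evaluate.
    Any stage failure is re-raised with the stage name.  Fully seeded:
    identical configs give identical reports.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    t0 = time.perf_counter()
    stage = "simulate"
    try:
        d = config.data
        if dataset is None:
            dataset = syn.generate_dataset(
                P=d.P, N=d.N, M=d.M,
                cluster_spec=syn.ClusterSpec(
                    n_clusters=d.n_clusters, jitter=d.jitter,
                    active_categories=d.active_categories,
                ),
                seed=config.seed, height=d.height, width=d.width,
                base_weight=d.base_weight, idiosyncrasy_noise=d.idiosyncrasy_noise,
            )
        t0 = _stage(stage, t0)

        stage = "split"
        train_idx, test_idx = _split_indices(
            dataset.num_images, config.split.train_image_fraction, rng
        )
        panel_idx, target_idx = _split_indices(
            dataset.num_persons, config.split.panel_person_fraction, rng
        )
        if config.selection.C > len(train_idx):
            raise ValueError(
                f"C={config.selection.C} exceeds the {len(train_idx)} training images"
            )
        usms = {
            n: am.compute_usm([dataset.psms[p][n] for p in panel_idx])
            for n in range(dataset.num_images)
        }
        t0 = _stage(stage, t0)

        stage = "train"
        model = None
        if config.fpsp.psm_source == "network":
            ncfg = config.network or net.NetworkConfig(
                num_persons=len(panel_idx),
                input_height=dataset.images[0].height,
                input_width=dataset.images[0].width,
                in_channels=dataset.images[0].pixels.shape[2] + 1,
            )
            tcfg = config.training or net.TrainConfig(seed=config.seed)
            model = net.build_model(ncfg, seed=config.seed)
            targets = [
                [
                    am.difference_map(dataset.psms[p][n], usms[n]).values
                    for n in train_idx
                ]
                for p in panel_idx
            ]
            net.train(
                model,
                [dataset.images[n] for n in train_idx],
                [usms[n] for n in train_idx],
                targets,
                tcfg,
            )
        elif config.fpsp.psm_source != "ground_truth":
            raise ValueError(f"unknown psm_source {config.fpsp.psm_source!r}")
        t0 = _stage(stage, t0)

        stage = "select"
        strategy = config.selection.strategy.lower()
        C = config.selection.C
        maps_by_train_image = [
            [dataset.psms[p][n] for p in panel_idx] for n in train_idx
        ]
        if strategy == "ais":
            boxes_by_train_image = [dataset.boxes[dataset.images[n].image_id] for n in train_idx]
            table = sel.compute_variance_table(
                boxes_by_train_image, maps_by_train_image,
                dataset.num_categories, normalize=config.selection.normalize,
            )
            selection = sel.select_images(table, C)
        elif strategy == "ispsm":
            selection = sel.select_images_ispsm(
                maps_by_train_image, C, normalize=config.selection.normalize
            )
        elif strategy == "isvf":
            selection = sel.select_images_isvf([dataset.images[n] for n in train_idx], C)
        elif strategy == "random":
            selection = sel.select_images_random(len(train_idx), C, seed=config.seed)
        else:
            raise ValueError(f"unknown selection strategy {strategy!r}")
        selected = [train_idx[i] for i in selection.indices]
        t0 = _stage(stage, t0)

        stage = "predict"

        def panel_prediction(p: int, n: int) -> am.SaliencyMap:
            if model is not None:
                return net.predict_psm(
                    model, dataset.images[n], usms[n], panel_idx.index(p)
                )
            return dataset.psms[p][n]

        predictions: dict[str, list[am.SaliencyMap]] = {}
        ground_truth: dict[str, list[am.SaliencyMap]] = {}
        for tp in target_idx:
            pid = dataset.profiles[tp].person_id
            target_maps = [dataset.psms[tp][n] for n in selected]
            panel_predictions = [
                [panel_prediction(p, n) for n in selected] for p in panel_idx
            ]
            profile = fsp.build_similarity_profile(
                pid, target_maps, panel_predictions,
                tau=config.fpsp.tau, corr_mode=config.fpsp.corr_mode,
            )
            predictions[pid] = [
                fsp.predict_for_person(
                    profile,
                    [panel_prediction(p, n) for p in panel_idx],
                    usms[n],
                )
                for n in test_idx
            ]
            ground_truth[pid] = [dataset.psms[tp][n] for n in test_idx]
        t0 = _stage(stage, t0)

        stage = "evaluate"
        report = evaluate(
            predictions, ground_truth, config.metrics,
            strategy=selection.strategy, C=C, seed=config.seed,
        )
        _stage(stage, t0)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
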