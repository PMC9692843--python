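"""End-to-end pipeline: generate/ingest → preprocess → select k → battery →
consensus → report.

The pipeline is a pure function of its configuration: every stochastic stage
draws its seed from ``master_seed`` by stable hashing of the stage name, so
two runs with the same configuration produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._seeds import derive_seed
from .clustering import (BatteryConfig, ClusteringRun, PROPOSED_CODES,
                         run_battery)
from .consensus import (AgreementPartition, OverlapConfig, Thread,
                        agreement_grouping, all_pairwise_relations,
                        combination_count, compare_to_human, find_threads,
                        relations_frame)
from .errors import ConfigurationError
from .model_selection import DEFAULT_K_GRID, KSelectionResult, choose_k
from .preprocess import (AugmentConfig, PreprocessConfig,
                         compute_representations, feature_matrix,
                         shuffle_split)
from .synthetic import (SeedImage, generate_dataset, load_dataset,
                        well_separated_triple)

logger = logging.getLogger("testaclust")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report",
           "planted_study_config"]


@dataclasses.dataclass
class PipelineConfig:
    """Full pipeline configuration; exactly one dataset source must be set."""

    class_spec: list | None = None
    dataset_dir: str | None = None
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    augment: AugmentConfig = dataclasses.field(default_factory=AugmentConfig)
    battery: BatteryConfig = dataclasses.field(default_factory=BatteryConfig)
    overlap: OverlapConfig = dataclasses.field(default_factory=OverlapConfig)
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    train_fraction: float = 0.8
    master_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if (self.class_spec is None) == (self.dataset_dir is None):
            raise ConfigurationError(
                "exactly one of class_spec / dataset_dir must be given"
            )


@dataclasses.dataclass
class RunReport:
    """Everything the pipeline computed, ready for serialization."""

    selection: dict[str, KSelectionResult]
    runs: list[ClusteringRun]
    relations: pd.DataFrame
    threads: list[Thread]
    agreement: AgreementPartition
    n_tables: int
    human_table: pd.DataFrame | None
    train_ids: list[str]
    test_ids: list[str]
    config_echo: dict
    version: str = __version__


def _config_echo(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, np.integer):
            return int(obj)
        return obj

    echo = {
        "class_spec": None,
        "dataset_dir": config.dataset_dir,
        "preprocess": enc(config.preprocess),
        "augment": enc(config.augment),
        "battery": enc(config.battery),
        "overlap": enc(config.overlap),
        "k_grid": list(config.k_grid),
        "train_fraction": config.train_fraction,
        "master_seed": config.master_seed,
    }
    if config.class_spec is not None:
        spec = []
        for entry in config.class_spec:
            wc, count = entry[0], entry[1]
            overrides = dict(entry[2]) if len(entry) > 2 else {}
            spec.append({
                "anticlinal": wc.anticlinal.value if hasattr(wc, "anticlinal") else wc[0],
                "periclinal": wc.periclinal.value if hasattr(wc, "periclinal") else wc[1],
                "count": int(count),
                "overrides": overrides,
            })
        echo["class_spec"] = spec
    return echo


def planted_study_config(n_per_class: int = 20, master_seed: int = 0,
                         output_dir: str | None = None) -> PipelineConfig:
    """Pipeline configuration for the three-class planted-partition study.

    The dataset is the well-separated class triple with ``n_per_class``
    images per class.  Pixel representations use an 8 × 8 feature grid:
    each feature then pools a ~31 px neighbourhood, about half a cell, so
    the features measure local wall density and brightness rather than
    exact wall positions, which makes them tolerant to the mesh jitter
    that individual images of a class legitimately carry.  The overlap
    report floor is scaled to the dataset (5 images).
    """
    spec = [(wc, n_per_class, ov) for wc, _, ov in well_separated_triple()]
    return PipelineConfig(
        class_spec=spec,
        preprocess=PreprocessConfig(downsample_side=8),
        overlap=OverlapConfig(report_floor=5),
        master_seed=master_seed,
        output_dir=output_dir,
    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage; raise with the stage name on failure."""
    stage = "ingest"
    try:
        if config.class_spec is not None:
            images = generate_dataset(config.class_spec,
                                      seed=derive_seed(config.master_seed, "generate"))
        else:
            images = load_dataset(config.dataset_dir)
        ids = [img.id for img in images]
        logger.info("stage=%s n_images=%d", stage, len(images))

        stage = "split"
        train, test = shuffle_split(images, config.train_fraction,
                                    seed=derive_seed(config.master_seed, "split"))
        # The split is recorded for training-style workflows; consensus runs
        # on the full original set so agreement is per-original-image.
        train_ids = [img.id for img in train]
        test_ids = [img.id for img in test]

        stage = "preprocess"
        t0 = time.perf_counter()
        reps = [compute_representations(img, config.preprocess,
                                        color_seed=derive_seed(config.master_seed,
                                                               "colorize"))
                for img in images]
        features = {rep: feature_matrix(reps, rep, config.preprocess)
                    for rep in config.battery.representations}
        logger.info("stage=%s dt=%.2fs", stage, time.perf_counter() - t0)

        stage = "select-k"
        selection = {}
        for rep in config.battery.representations:
            selection[rep] = choose_k(
                features[rep], k_grid=config.k_grid,
                restarts=config.battery.restarts,
                seed=derive_seed(config.master_seed, "select", rep),
                representation=rep,
            )
            logger.info("stage=select-k rep=%s k_elbow=%d k_silhouette=%d",
                        rep, selection[rep].k_elbow, selection[rep].k_silhouette)

        stage = "battery"
        battery_cfg = dataclasses.replace(config.battery,
                                          master_seed=config.master_seed)
        runs = run_battery(ids, features, battery_cfg, selection)

        stage = "consensus"
        proposed = [r for r in runs if r.code in PROPOSED_CODES.values()]
        relations, n_tables = all_pairwise_relations(proposed, config.overlap)
        threads = find_threads(relations)
        agreement = agreement_grouping(proposed)

        human_table = None
        truth = {img.id: img.truth for img in images if img.truth is not None}
        if len(truth) == len(images):
            method_runs = [r for r in runs if r.code.startswith("M")]
            _, _, human_table = compare_to_human(method_runs, truth,
                                                 config.overlap)

        stage = "report"
        report = RunReport(
            selection=selection, runs=runs,
            relations=relations_frame(relations), threads=threads,
            agreement=agreement, n_tables=n_tables, human_table=human_table,
            train_ids=train_ids, test_ids=test_ids,
            config_echo=_config_echo(config),
        )
        expected = combination_count(len(proposed), 2)
        if n_tables != expected:
            raise ConfigurationError(
                f"emitted {n_tables} pairwise tables, expected C({len(proposed)},2)={expected}"
            )
        if config.output_dir:
            write_report(report, config.output_dir)
        return report
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc


def write_report(report: RunReport, output_dir) -> list[Path]:
    """Write the machine-readable report: JSON summary, CSV tables, log.

    Idempotent: re-writing the same report produces byte-identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    curves = []
    for rep, sel in sorted(report.selection.items()):
        for k, sse, sil in zip(sel.k_grid, sel.sse, sel.silhouette):
            curves.append({"representation": rep, "k": k,
                           "sse": float(sse), "silhouette": float(sil)})
    _write_csv(pd.DataFrame(curves), out / "k_curves.csv", written)

    manifest = pd.DataFrame([{
        "code": r.code, "method": r.method, "representation": r.representation,
        "criterion": r.criterion or "", "k": r.k, "seed": r.seed,
    } for r in report.runs])
    _write_csv(manifest, out / "runs.csv", written)

    labels = []
    for r in report.runs:
        for img, lab in zip(r.image_ids, r.labels):
            labels.append({"image_id": img, "code": r.code, "label": int(lab)})
    _write_csv(pd.DataFrame(labels), out / "labels.csv", written)

    _write_csv(report.relations, out / "relations.csv", written)

    threads_payload = [[list(node) for node in t.nodes] for t in report.threads]
    _write_json(threads_payload, out / "threads.json", written)

    agreement_rows = [{"image_id": img,
                       "level": report.agreement.level[img],
                       "group": grp}
                      for img, grp in sorted(report.agreement.assignment.items())]
    _write_csv(pd.DataFrame(agreement_rows), out / "agreement.csv", written)

    if report.human_table is not None:
        _write_csv(report.human_table, out / "human_comparison.csv", written)

    summary = {
        "version": report.version,
        "n_images": report.agreement.n,
        "agreement_counts": {g: report.agreement.counts[g]
                             for g in ("SI", "SS", "SM", "NS", "PS", "PD")},
        "n_pairwise_tables": report.n_tables,
        "n_threads": len(report.threads),
        "run_manifest": manifest.to_dict(orient="records"),
        "chosen_k": {rep: {"elbow": sel.k_elbow, "silhouette": sel.k_silhouette}
                     for rep, sel in sorted(report.selection.items())},
        "train_size": len(report.train_ids),
        "test_size": len(report.test_ids),
        "config": report.config_echo,
    }
    _write_json(summary, out / "summary.json", written)
    return written


def _write_csv(df: pd.DataFrame, path: Path, written: list[Path]):
    df.to_csv(path, index=False)
    written.append(path)


def _write_json(payload, path: Path, written: list[Path]):
    # insertion order is deterministic and keeps the counts block in the
    # SI..PD reading order
    path.write_text(json.dumps(payload, indent=2) + "\n")
    written.append(path)
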