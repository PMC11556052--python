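"""End-to-end orchestration: cohort → phantoms → features/grades → ROI
localisation → age regression → statistical report.

One global seed deterministically derives a per-stage seed (keyed by stage
name), so any stage can be re-run reproducibly in isolation.  Every file a
run writes is listed in a JSON manifest with its SHA-256 content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as coh
from . import phantom as ph
from . import roi as roi_mod
from . import regression as reg
from . import stats as st
from .involution import grade_geometry
from .morphometry import FEATURE_NAMES, extract_features

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, keyed by stage name."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Desk-scale end-to-end configuration.

    The defaults run the full chain on a reduced cohort with small volumes
    so a complete pass stays in the minutes range on one CPU; every knob
    scales up to the full protocol (223 subjects, 512-voxel volumes, 64³
    cubes) by configuration alone.
    """

    cohort: coh.CohortConfig = field(default_factory=lambda: coh.CohortConfig(n=40))
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    scanogram_shape: tuple[int, int] = (256, 256)
    roi_half_width: int = 13
    classifier: roi_mod.SliceClassifierConfig = field(
        default_factory=roi_mod.SliceClassifierConfig.desk_profile)
    regressor: reg.RegressorConfig = field(
        default_factory=reg.RegressorConfig.desk_profile)
    #: Fraction of volumes whose slice datasets train the classifier.
    classifier_train_fraction: float = 0.8
    seed: int = 2024
    out_dir: Path = Path("craniage_run")

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}

    def record(stage: str, path: Path) -> None:
        manifest["artifacts"][str(path.relative_to(out))] = _sha256(path)
        manifest["stages"].setdefault(stage, {"seed": config.stage_seed(stage)})

    try:
        # -- stage: simulate -------------------------------------------------
        stage = "simulate"
        cohort_cfg = coh.CohortConfig(**{**asdict(config.cohort),
                                         "calibration": config.cohort.calibration,
                                         "seed": config.stage_seed(stage)})
        subjects = coh.sample_cohort(cohort_cfg)
        cohort_csv = out / "cohort.csv"
        coh.write_cohort(subjects, cohort_cfg, cohort_csv)
        record(stage, cohort_csv)
        record(stage, out / "cohort.config.json")

        # -- stage: render ---------------------------------------------------
        stage = "render"
        rng = np.random.default_rng(config.stage_seed(stage))
        volumes, annotations, scanograms = [], [], []
        for s in subjects:
            v, ann = ph.render_volume(s, shape=config.volume_shape,
                                      spacing=cohort_cfg.voxel_spacing, rng=rng)
            volumes.append(v)
            annotations.append(ann)
            scanograms.append(ph.render_scanogram(s, shape=config.scanogram_shape,
                                                  rng=rng))
        ann_path = out / "annotations.json"
        ann_path.write_text(json.dumps([a.to_dict() for a in annotations], indent=1))
        record(stage, ann_path)

        # -- stage: features + involution grading ---------------------------
        stage = "features"
        grades = [grade_geometry(s.geometry) for s in subjects]
        fvs = [extract_features(sc, g) for sc, g in zip(scanograms, grades)]
        fdf = pd.DataFrame([fv.values for fv in fvs])[list(FEATURE_NAMES)]
        fdf.insert(0, "id", [s.id for s in subjects])
        fdf.insert(1, "age_years", [s.age_years for s in subjects])
        features_csv = out / "features.csv"
        fdf.to_csv(features_csv, index=False)
        record(stage, features_csv)

        # -- stage: roi ------------------------------------------------------
        stage = "roi"
        truth_boxes = [roi_mod.landmark_roi(a, v.shape, config.roi_half_width)
                       for a, v in zip(annotations, volumes)]
        datasets = [roi_mod.make_slice_dataset(v, b)
                    for v, b in zip(volumes, truth_boxes)]
        n_train = max(int(round(len(datasets) * config.classifier_train_fraction)), 1)
        clf_cfg = roi_mod.SliceClassifierConfig(
            **{**asdict(config.classifier), "seed": config.stage_seed(stage)})
        clf = roi_mod.train_slice_classifier(
            [s for d in datasets[:n_train] for s in d], clf_cfg)
        held = [s for d in datasets[n_train:] for s in d]
        cm = roi_mod.confusion(clf.predict([s.image for s in held]),
                               [s.label for s in held])
        p1, r1 = roi_mod.precision_recall(cm, 1)
        p0, r0 = roi_mod.precision_recall(cm, 0)
        cm_csv = out / "confusion.csv"
        pd.DataFrame([{"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                       "precision_class1": p1, "recall_class1": r1,
                       "precision_class0": p0, "recall_class0": r0}]
                     ).to_csv(cm_csv, index=False)
        record(stage, cm_csv)

        # predicted ROI boxes (fallback to landmarks when aggregation fails)
        boxes = []
        for v, d, a in zip(volumes, datasets, annotations):
            labels = clf.predict([s.image for s in d])
            triples = [(s.projection, s.index, int(l)) for s, l in zip(d, labels)]
            try:
                _, box = roi_mod.aggregate_roi(triples, v.shape,
                                               config.roi_half_width)
            except roi_mod.AggregationError:
                box = roi_mod.landmark_roi(a, v.shape, config.roi_half_width)
            boxes.append(box)
        roi_json = out / "roi_boxes.json"
        roi_json.write_text(json.dumps([b.to_dict() for b in boxes], indent=1))
        record(stage, roi_json)

        # -- stage: age regression ------------------------------------------
        stage = "age"
        reg_cfg = reg.RegressorConfig(
            **{**asdict(config.regressor), "seed": config.stage_seed(stage)})
        items = [
            (s.id, reg.standardize_roi(v, b, reg_cfg.input_edge), s.age_years)
            for s, v, b in zip(subjects, volumes, boxes)
        ]
        train, test = reg.split_dataset(items, reg_cfg.split_ratio,
                                        seed=config.stage_seed("split"))
        model = reg.train_regressor([c for _, c, _ in train],
                                    [a for _, _, a in train], reg_cfg)
        report = reg.evaluate(model, train, test)
        scatter_csv = out / "age_scatter.csv"
        report.write_scatter_csv(scatter_csv)
        record(stage, scatter_csv)
        summary_json = out / "age_summary.json"
        summary_json.write_text(json.dumps(report.summary(), indent=1))
        record(stage, summary_json)
        model_path = out / "age_model.npz"
        model.save(model_path)
        record(stage, model_path)

        # -- stage: report ---------------------------------------------------
        stage = "report"
        ages = [s.age_years for s in subjects]
        table = st.correlation_table(fvs, ages)
        table1_csv = out / "table1_replica.csv"
        table.to_csv(table1_csv)
        record(stage, table1_csv)
        heat_csv = out / "heatmap_matrix.csv"
        st.heatmap_matrix(fvs).to_csv(heat_csv)
        record(stage, heat_csv)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d artifacts", len(manifest["artifacts"]))
    return manifest


# ---------------------------------------------------------------------------


@dataclass
class FixtureSet:
    """A small in-memory end-to-end fixture for tests and examples."""

    subjects: list
    volumes: list
    annotations: list
    scanograms: list
    grades: list
    features: list
    boxes: list


def fixture_suite(seed: int = 0, n: int = 10,
                  volume_shape: tuple[int, int, int] = (48, 48, 48)) -> FixtureSet:
    """Build a 10-subject mini-cohort with 48³ volumes and derived products."""
    cfg = coh.CohortConfig(n=n, seed=derive_seed(seed, "fixture"))
    subjects = coh.sample_cohort(cfg)
    rng = np.random.default_rng(derive_seed(seed, "fixture-render"))
    volumes, annotations, scanograms = [], [], []
    for s in subjects:
        v, ann = ph.render_volume(s, shape=volume_shape,
                                  spacing=cfg.voxel_spacing, rng=rng)
        volumes.append(v)
        annotations.append(ann)
        scanograms.append(ph.render_scanogram(s, rng=rng))
    grades = [grade_geometry(s.geometry) for s in subjects]
    features = [extract_features(sc, g) for sc, g in zip(scanograms, grades)]
    boxes = [roi_mod.landmark_roi(a, v.shape, half_width=13)
             for a, v in zip(annotations, volumes)]
    return FixtureSet(subjects, volumes, annotations, scanograms, grades,
                      features, boxes)
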