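"""Reproducible evaluation protocols at the desk scale.

These bind the package's stages into the standard measurement runs: the
cohort-level correlation summaries, the held-out slice-classifier recall
protocol and the held-out 3D age-regression protocol.  Problem sizes are
the package's desk profile (48³ phantom volumes, 32³ regression cubes,
short cosine-annealed schedules); every run is fully determined by one
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import regression as reg
from . import roi as roi_mod
from .cohort import CohortConfig, sample_cohort
from .involution import grade_geometry
from .morphometry import extract_features
from .phantom import render_scanogram, render_volume
from .pipeline import derive_seed
from .stats import pearson

#: Desk-scale phantom canvas and the ROI half-width matched to the
#: phantom's constant arch outer radius (14 voxels at 0.5 mm spacing).
DESK_VOLUME_SHAPE = (48, 48, 48)
DESK_ROI_HALF_WIDTH = 13


@dataclass
class CohortSummary:
    n: int
    mean_age: float
    r_grade_age: float
    r_brightness_sd_age: float
    mean_gap_max_grade_mm: float
    n_max_grade: int


def cohort_correlation_summary(seed: int = CohortConfig.seed) -> CohortSummary:
    """Grade/texture age correlations on the default-condition cohort.

    Grades come from the rule-based scorer on each subject's latent
    geometry; the brightness-SD feature is extracted from the rendered
    scanogram (feature 20 of the scheme), not read from the latent.
    """
    cfg = CohortConfig(seed=seed)
    subjects = sample_cohort(cfg)
    ages = np.array([s.age_years for s in subjects])
    grades = np.array([grade_geometry(s.geometry).points for s in subjects])

    rng = np.random.default_rng(derive_seed(seed, "scanograms"))
    f20 = []
    for s in subjects:
        fv = extract_features(render_scanogram(s, rng=rng),
                              grade_geometry(s.geometry))
        f20.append(fv["clivus_brightness_sd"])
    r_grade, _ = pearson(grades, ages)
    r_sd, _ = pearson(np.array(f20), ages)

    max_grade = int(grades.max())
    sel = [s.geometry.gap_mm for s, g in zip(subjects, grades) if g == max_grade]
    return CohortSummary(
        n=cfg.n,
        mean_age=float(ages.mean()),
        r_grade_age=float(r_grade),
        r_brightness_sd_age=float(r_sd),
        mean_gap_max_grade_mm=float(np.mean(sel)),
        n_max_grade=len(sel),
    )


@dataclass
class SliceRecallResult:
    recall_class1: float
    precision_class1: float
    precision_class0: float
    n_test_slices: int
    confusion: roi_mod.ConfusionMatrix


def slice_classifier_protocol(seed: int = 0, n_volumes: int = 50,
                              train_fraction: float = 0.8) -> SliceRecallResult:
    """Held-out recall of the positive slice class at the desk profile.

    Renders ``n_volumes`` phantoms, labels every slice against the
    landmark-derived ground-truth box, trains the compact classifier on
    the first 80% of volumes and scores slices of the held-out volumes.
    """
    subjects = sample_cohort(CohortConfig(n=n_volumes,
                                          seed=derive_seed(seed, "recall-cohort")))
    rng = np.random.default_rng(derive_seed(seed, "recall-render"))
    datasets = []
    for s in subjects:
        vol, ann = render_volume(s, shape=DESK_VOLUME_SHAPE, rng=rng)
        box = roi_mod.landmark_roi(ann, vol.shape, DESK_ROI_HALF_WIDTH)
        datasets.append(roi_mod.make_slice_dataset(vol, box))
    n_train = max(int(round(n_volumes * train_fraction)), 1)
    cfg = roi_mod.SliceClassifierConfig.desk_profile(
        seed=derive_seed(seed, "recall-train"))
    clf = roi_mod.train_slice_classifier(
        [s for d in datasets[:n_train] for s in d], cfg)
    held = [s for d in datasets[n_train:] for s in d]
    cm = roi_mod.confusion(clf.predict([s.image for s in held]),
                           [s.label for s in held])
    p1, r1 = roi_mod.precision_recall(cm, 1)
    p0, _ = roi_mod.precision_recall(cm, 0)
    return SliceRecallResult(recall_class1=r1, precision_class1=p1,
                             precision_class0=p0, n_test_slices=len(held),
                             confusion=cm)


@dataclass
class RegressionResult:
    rmse_train_years: float
    rmse_test_years: float
    mae_test_years: float
    n_train: int
    n_test: int


def age_regression_protocol(seed: int = 0, n_volumes: int = 200) -> RegressionResult:
    """Held-out age-prediction error at the desk profile.

    Renders ``n_volumes`` phantoms, crops ground-truth ROIs, standardizes
    to 32³ cubes, splits 4:1 and trains the compact 3D regressor.
    """
    subjects = sample_cohort(CohortConfig(n=n_volumes,
                                          seed=derive_seed(seed, "age-cohort")))
    rng = np.random.default_rng(derive_seed(seed, "age-render"))
    cfg = reg.RegressorConfig.desk_profile(seed=derive_seed(seed, "age-train"))
    items = []
    for s in subjects:
        vol, ann = render_volume(s, shape=DESK_VOLUME_SHAPE, rng=rng)
        box = roi_mod.landmark_roi(ann, vol.shape, DESK_ROI_HALF_WIDTH)
        items.append((s.id, reg.standardize_roi(vol, box, cfg.input_edge),
                      s.age_years))
    train, test = reg.split_dataset(items, cfg.split_ratio,
                                    seed=derive_seed(seed, "age-split"))
    model = reg.train_regressor([c for _, c, _ in train],
                                [a for _, _, a in train], cfg)
    report = reg.evaluate(model, train, test)
    return RegressionResult(
        rmse_train_years=report.rmse_train,
        rmse_test_years=report.rmse_test,
        mae_test_years=report.mae_test,
        n_train=len(train),
        n_test=len(test),
    )
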