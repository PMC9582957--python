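"""End-to-end scoring pipelines and their ensemble.

Pipeline 1: semantic segmentation of the lower spine -> spine curve ->
aortic ROI -> rule-based calcification detection and Kauppila scoring.

Pipeline 2: per-vertebra box detection -> spine curve -> aortic ROI ->
learned regression of the total score.

The ensemble averages the two pipelines' totals; if one pipeline fails
localization the other's score is reported with a provenance flag, and an
image both pipelines fail on is reported as skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import roi as roi_mod
from . import scoring, spine
from .types import LEVELS, WALLS, DexaImage, LocalizationFailure


@dataclass
class GeometryConfig:
    """ROI geometry shared by both pipelines (and the phantom generator)."""

    offset_factor: float = roi_mod.DEFAULT_OFFSET_FACTOR
    width_factor: float = roi_mod.DEFAULT_WIDTH_FACTOR
    curve_degree: int = 2
    use_pelvis_anchor: bool = False


@dataclass
class PipelineResult:
    image_id: str
    rule_total: float | None = None
    per_wall: dict | None = None
    regression_total: float | None = None
    ensemble_total: float | None = None
    provenance: str = ""
    errors: dict = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return self.ensemble_total is None


def _localize(image: DexaImage, geom: GeometryConfig, method: str):
    """Shared localization tail: boxes -> curve -> ROI."""
    if method == "segmentation":
        seg = spine.segment_spine(image, method="classical")
        boxes = spine.detect_vertebrae(seg)
        anchor = spine.pelvis_centroid(seg) if geom.use_pelvis_anchor else None
    else:  # detection front-end
        boxes = spine.detect_vertebrae(image)
        anchor = None
    curve = roi_mod.fit_spine_curve(boxes, pelvis_centroid=anchor,
                                    degree=geom.curve_degree)
    band = roi_mod.extract_aortic_roi(curve, boxes,
                                      offset_factor=geom.offset_factor,
                                      width_factor=geom.width_factor,
                                      image_shape=image.shape)
    return boxes, curve, band


def run_rule_pipeline(image: DexaImage, geom: GeometryConfig | None = None,
                      detection: scoring.DetectionConfig | None = None):
    """Pipeline 1: segmentation front-end + rule-based Kauppila scoring.

    Returns ``(total, per_wall_scores)``.
    """
    geom = geom or GeometryConfig()
    _, _, band = _localize(image, geom, "segmentation")
    mask = scoring.detect_calcification(image, band, config=detection)
    ks = scoring.kauppila_score(mask)
    return float(ks.total), dict(ks.per_wall)


def run_regression_pipeline(image: DexaImage, model: scoring.RegressionModel,
                            geom: GeometryConfig | None = None) -> float:
    """Pipeline 2: box-detection front-end + learned score regression."""
    geom = geom or GeometryConfig()
    _, _, band = _localize(image, geom, "detection")
    return scoring.regress_score(image, band, model)


def score_image(image: DexaImage, model: scoring.RegressionModel | None = None,
                geom: GeometryConfig | None = None,
                detection: scoring.DetectionConfig | None = None) -> PipelineResult:
    """Run both pipelines on one image and ensemble their totals."""
    geom = geom or GeometryConfig()
    res = PipelineResult(image_id=image.id)
    try:
        res.rule_total, res.per_wall = run_rule_pipeline(image, geom, detection)
    except (LocalizationFailure, ValueError) as exc:
        res.errors["pipeline1"] = str(exc)
    if model is not None:
        try:
            res.regression_total = run_regression_pipeline(image, model, geom)
        except (LocalizationFailure, ValueError) as exc:
            res.errors["pipeline2"] = str(exc)
    try:
        res.ensemble_total, res.provenance = scoring.ensemble_score(
            res.rule_total, res.regression_total)
    except ValueError:
        res.provenance = "failed"
    return res


def train_pipeline_regressor(pairs, seed: int = 0,
                             geom: GeometryConfig | None = None,
                             targets=None) -> scoring.RegressionModel:
    """Train pipeline 2's regressor on (image, ground-truth) pairs.

    ``targets`` overrides the reference totals (e.g. annotator consensus);
    by default the ground-truth totals are used.  Images failing
    localization are skipped.
    """
    geom = geom or GeometryConfig()
    images, rois, totals = [], [], []
    for i, (image, gt) in enumerate(pairs):
        try:
            _, _, band = _localize(image, geom, "detection")
        except (LocalizationFailure, ValueError):
            continue
        images.append(image)
        rois.append(band)
        totals.append(gt.true_score.total if targets is None else targets[i])
    if len(images) < 2:
        raise ValueError("too few localizable training pairs")
    return scoring.train_regressor(images, rois, totals, seed=seed)


def score_image_set(images, model: scoring.RegressionModel | None = None,
                    geom: GeometryConfig | None = None) -> pd.DataFrame:
    """Score a list of images; one row per image (TSV-ready).

    Failed pipelines leave NaNs and set the failure flag; the row order
    follows the input order.
    """
    rows = []
    for image in images:
        r = score_image(image, model=model, geom=geom)
        row = {"image_id": r.image_id,
               "rule_total": np.nan if r.rule_total is None else r.rule_total,
               "regression_total": (np.nan if r.regression_total is None
                                    else r.regression_total),
               "ensemble_total": (np.nan if r.ensemble_total is None
                                  else r.ensemble_total),
               "provenance": r.provenance,
               "failed": r.failed}
        for lv in LEVELS:
            for w in WALLS:
                key = f"score_{lv}_{w}"
                row[key] = (r.per_wall or {}).get((lv, w), np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
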