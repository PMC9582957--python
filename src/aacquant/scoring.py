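"""Kauppila scoring of aortic calcification within the aortic ROI.

The 24-point scheme scores the anterior and posterior aortic wall at each
lumbar level L1-L4 by the fraction of the vertebral height that the
calcification spans in projection:

    0  no calcification (below a small noise floor),
    1  span < 1/3 of the vertebra,
    2  span from 1/3 to 2/3 (both boundaries inclusive),
    3  span > 2/3,

and sums the eight per-wall scores (total 0..24).  Three scorers are
provided: a deterministic rule-based detector + threshold scorer, a learned
regressor on ROI intensity features, and their ensemble (mean of the two
pipelines' totals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.ensemble import GradientBoostingRegressor

from .types import (LEVELS, WALLS, AorticROI, CalcificationMask, DexaImage,
                    KauppilaScore)

#: Minimum coverage fraction (of vertebral height) before a wall scores 1.
NOISE_FLOOR = 0.02

_ONE_THIRD = 1.0 / 3.0
_TWO_THIRDS = 2.0 / 3.0
_TOL = 1e-9  # boundary tolerance: fractions arrive as row-count ratios


def score_wall(f: float, eps: float = NOISE_FLOOR) -> int:
    """Score a single aortic wall from its projected coverage fraction.

    Boundaries: exactly 1/3 and exactly 2/3 both score 2 (the verbal rule
    uses "< 1/3", "from 1/3 to 2/3", "> 2/3", so both cut points belong to
    the middle class).
    """
    f = float(f)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"coverage fraction {f} outside [0, 1]")
    if f <= eps:
        return 0
    if f < _ONE_THIRD - _TOL:
        return 1
    if f <= _TWO_THIRDS + _TOL:
        return 2
    return 3


def kauppila_score(mask: CalcificationMask, eps: float = NOISE_FLOOR) -> KauppilaScore:
    """Apply the per-wall rule to all eight (level, wall) coverages and sum."""
    missing = {(lv, w) for lv in LEVELS for w in WALLS} - set(mask.coverage)
    if missing:
        raise ValueError(f"coverage missing for {sorted(missing)}")
    per_wall = {key: score_wall(mask.coverage[key], eps=eps)
                for key in ((lv, w) for lv in LEVELS for w in WALLS)}
    return KauppilaScore(per_wall=per_wall)


def score_from_coverage(coverage: dict, eps: float = NOISE_FLOOR) -> KauppilaScore:
    """Kauppila score straight from a (level, wall) -> fraction mapping."""
    per_wall = {(lv, w): score_wall(coverage[(lv, w)], eps=eps)
                for lv in LEVELS for w in WALLS}
    return KauppilaScore(per_wall=per_wall)


# ---------------------------------------------------------------------------
# Rule-based detection


@dataclass
class DetectionConfig:
    """Thresholding parameters for rule-based calcification detection.

    ``rel_threshold`` is the position of the cut between the band's local
    background (median) and the image's bright-bone reference (99th
    percentile): pixel > bg + rel_threshold * (bone - bg) marks calcium.
    """

    rel_threshold: float = 0.35
    min_component_px: int = 3


def detect_calcification(image: DexaImage, roi: AorticROI,
                         config: DetectionConfig | None = None) -> CalcificationMask:
    """Detect calcified pixels inside the aortic ROI and project per wall.

    Pixels brighter than an adaptive threshold (relative to the local
    background level of each level's band) are marked, small components are
    removed, and per-(level, wall) coverage is the fraction of the level's
    rows containing at least one calcified pixel in that wall sub-band.
    """
    config = config or DetectionConfig()
    px = image.pixels
    n_rows, n_cols = px.shape
    bone_ref = float(np.percentile(px, 99))

    full_mask = np.zeros_like(px, dtype=bool)
    coverage: dict = {}
    for level in LEVELS:
        rows, post_lo, mid, ant_hi = roi.bands[level]
        if len(rows) == 0:
            raise ValueError(f"empty ROI band for {level}")
        # collect band pixels for the local background estimate
        band_vals = []
        spans = []
        for r, lo, hi in zip(rows, post_lo, ant_hi):
            lo_i = max(0, int(np.floor(lo)))
            hi_i = min(n_cols, int(np.ceil(hi)))
            if hi_i <= lo_i or not 0 <= r < n_rows:
                spans.append((r, lo_i, lo_i))
                continue
            band_vals.append(px[r, lo_i:hi_i])
            spans.append((r, lo_i, hi_i))
        if not band_vals:
            raise ValueError(f"ROI band for {level} fully outside the image")
        # local background, capped by the global soft-tissue level so a
        # band dense with calcium does not raise its own threshold
        bg = min(float(np.median(np.concatenate(band_vals))),
                 float(np.median(px)))
        thr = bg + config.rel_threshold * max(bone_ref - bg, 1e-12)
        for r, lo_i, hi_i in spans:
            if hi_i > lo_i:
                full_mask[r, lo_i:hi_i] = px[r, lo_i:hi_i] > thr

    # drop specks (noise) below the minimum component size
    lab, n_lab = ndimage.label(full_mask)
    if n_lab:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n_lab + 1))
        small = np.flatnonzero(sizes < config.min_component_px) + 1
        if small.size:
            full_mask[np.isin(lab, small)] = False

    coverage = coverage_from_mask(full_mask, roi)
    return CalcificationMask(mask=full_mask, coverage=coverage)


def coverage_from_mask(mask: np.ndarray, roi: AorticROI) -> dict:
    """Project a binary calcification mask onto each wall sub-band.

    Coverage of (level, wall) = fraction of the level's rows containing at
    least one marked pixel in that wall's column span.  The midline pixel
    (``round(mid)``) belongs to the anterior wall, never to both.
    """
    n_rows, n_cols = mask.shape
    coverage: dict = {}
    for level in LEVELS:
        rows, post_lo, mid, ant_hi = roi.bands[level]
        height = len(rows)
        for wall in WALLS:
            hit = 0
            for r, lo, m, hi in zip(rows, post_lo, mid, ant_hi):
                if not 0 <= r < n_rows:
                    continue
                split = int(round(m))
                if wall == "anterior":
                    lo_i, hi_i = max(0, split), min(n_cols, int(np.ceil(hi)))
                else:
                    lo_i, hi_i = max(0, int(np.floor(lo))), min(n_cols, split)
                if hi_i > lo_i and mask[r, lo_i:hi_i].any():
                    hit += 1
            coverage[(level, wall)] = hit / height
    return coverage


# ---------------------------------------------------------------------------
# Learned regression scorer


@dataclass
class RegressionModel:
    """Serializable handle for the learned ROI -> total-score regressor."""

    estimator: GradientBoostingRegressor
    format_version: int = 1


def roi_features(image: DexaImage, roi: AorticROI) -> np.ndarray:
    """Fixed-length feature vector summarizing intensity inside each wall
    sub-band: background-subtracted mean / max / upper-quantile plus the
    fraction of bright rows at two thresholds."""
    px = image.pixels
    n_rows, n_cols = px.shape
    bone_ref = float(np.percentile(px, 99))
    feats: list[float] = []
    for level in LEVELS:
        rows, post_lo, mid, ant_hi = roi.bands[level]
        band_vals = []
        for r, lo, hi in zip(rows, post_lo, ant_hi):
            lo_i, hi_i = max(0, int(np.floor(lo))), min(n_cols, int(np.ceil(hi)))
            if hi_i > lo_i and 0 <= r < n_rows:
                band_vals.append(px[r, lo_i:hi_i])
        bg = float(np.median(np.concatenate(band_vals))) if band_vals else 0.0
        scale = max(bone_ref - bg, 1e-12)
        for wall in WALLS:
            row_max = []
            for r, lo, m, hi in zip(rows, post_lo, mid, ant_hi):
                split = int(round(m))
                if wall == "anterior":
                    lo_i, hi_i = max(0, split), min(n_cols, int(np.ceil(hi)))
                else:
                    lo_i, hi_i = max(0, int(np.floor(lo))), min(n_cols, split)
                if hi_i > lo_i and 0 <= r < n_rows:
                    row_max.append((px[r, lo_i:hi_i].max() - bg) / scale)
                else:
                    row_max.append(0.0)
            rm = np.asarray(row_max)
            feats.extend([
                float(rm.mean()),
                float(rm.max(initial=0.0)),
                float(np.percentile(rm, 90)) if rm.size else 0.0,
                float(np.mean(rm > 0.25)),
                float(np.mean(rm > 0.35)),
                float(np.mean(rm > 0.45)),
            ])
    return np.asarray(feats)


def train_regressor(images, rois, totals, seed: int = 0) -> RegressionModel:
    """Fit the score regressor on paired (image, ROI, reference total)."""
    if not (len(images) == len(rois) == len(totals)):
        raise ValueError("images, rois and totals must have equal length")
    X = np.stack([roi_features(im, roi) for im, roi in zip(images, rois)])
    y = np.asarray(totals, dtype=float)
    est = GradientBoostingRegressor(n_estimators=200, max_depth=3,
                                    learning_rate=0.06, subsample=0.9,
                                    random_state=seed)
    est.fit(X, y)
    return RegressionModel(estimator=est)


def regress_score(image: DexaImage, roi: AorticROI, model: RegressionModel) -> float:
    """Continuous total-score prediction, clipped to [0, 24]."""
    if model is None or getattr(model, "estimator", None) is None:
        raise ValueError("untrained regression model")
    x = roi_features(image, roi)[None, :]
    return float(np.clip(model.estimator.predict(x)[0], 0.0, 24.0))


# ---------------------------------------------------------------------------
# Ensemble


def ensemble_score(s1: float | None, s2: float | None):
    """Average the two pipelines' totals; fall back to the surviving one.

    Returns ``(score, provenance)`` with provenance in
    {"ensemble", "pipeline1_only", "pipeline2_only"}.
    """
    for s in (s1, s2):
        if s is not None and not 0.0 <= float(s) <= 24.0:
            raise ValueError(f"score {s} outside [0, 24]")
    if s1 is None and s2 is None:
        raise ValueError("both pipelines failed; no score available")
    if s1 is None:
        return float(s2), "pipeline2_only"
    if s2 is None:
        return float(s1), "pipeline1_only"
    return (float(s1) + float(s2)) / 2.0, "ensemble"
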