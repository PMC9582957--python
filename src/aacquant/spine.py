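"""Spine localization: semantic segmentation and per-vertebra box detection.

Two interchangeable back-ends stand behind one interface.  The *classical*
back-end (intensity thresholding, morphological opening, connected
components) is fully deterministic and needs no training; the *learned*
back-end is a per-pixel random-forest classifier over multiscale intensity
features.  Vertebra labels are anchored on the pelvis — the largest bright
component at the inferior end — counting L4, L3, L2, L1 upward from it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology
from sklearn.ensemble import RandomForestClassifier

from .types import DexaImage, LocalizationFailure, SpineSegmentation, VertebraBox

log = logging.getLogger(__name__)


@dataclass
class ClassicalConfig:
    """Classical segmentation knobs.

    The bone threshold is Otsu's threshold computed on the upper intensity
    quartile of the image (the bright tail containing bone), which keeps the
    split insensitive to the large soft-tissue background mode.
    """

    upper_quantile: float = 0.75
    opening_radius: int = 1
    min_component_px: int = 20
    #: components above the pelvis smaller than this fraction of the largest
    #: such component are not vertebrae (calcific deposits, ribs, specks)
    vertebra_area_frac: float = 0.4


@dataclass
class SegmenterModel:
    """Serializable learned-segmentation handle."""

    estimator: RandomForestClassifier
    format_version: int = 1


def _pixel_features(px: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack: raw + multiscale smoothed intensity, gradient
    magnitude, local variance, and normalized coordinates."""
    n_rows, n_cols = px.shape
    g1 = ndimage.gaussian_filter(px, 1.0)
    g2 = ndimage.gaussian_filter(px, 2.0)
    g4 = ndimage.gaussian_filter(px, 4.0)
    grad = ndimage.gaussian_gradient_magnitude(px, 1.5)
    var = ndimage.gaussian_filter(px ** 2, 2.0) - g2 ** 2
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    feats = np.stack([px, g1, g2, g4, grad, np.clip(var, 0, None),
                      rr / n_rows, cc / n_cols], axis=-1)
    return feats.reshape(-1, feats.shape[-1])


def _label_components(bright: np.ndarray, cfg: ClassicalConfig) -> SpineSegmentation:
    """Turn a cleaned bright-pixel mask into a pelvis/vertebra label mask."""
    lab = measure.label(bright)
    props = measure.regionprops(lab)
    props = [p for p in props if p.area >= cfg.min_component_px]
    if not props:
        raise LocalizationFailure("no candidate spine component found")
    pelvis = max(props, key=lambda p: p.area)
    above = [p for p in props
             if p is not pelvis and p.centroid[0] < pelvis.centroid[0]]
    max_area = max((p.area for p in above), default=0)
    vertebrae = [p for p in above if p.area >= cfg.vertebra_area_frac * max_area]

    mask = np.zeros(bright.shape, dtype=np.uint8)
    mask[lab == pelvis.label] = SpineSegmentation.PELVIS
    comps = [{"class": "pelvis", "area": int(pelvis.area),
              "centroid": tuple(pelvis.centroid), "bbox": pelvis.bbox}]
    for p in sorted(vertebrae, key=lambda p: p.centroid[0]):
        mask[lab == p.label] = SpineSegmentation.VERTEBRA
        comps.append({"class": "vertebra", "area": int(p.area),
                      "centroid": tuple(p.centroid), "bbox": p.bbox})
    return SpineSegmentation(mask=mask, components=comps)


def segment_spine(image: DexaImage, method: str = "classical",
                  model: SegmenterModel | None = None,
                  config: ClassicalConfig | None = None) -> SpineSegmentation:
    """Segment the lower spine (pelvis + lumbar vertebrae).

    Raises :class:`LocalizationFailure` when no spine candidate is found so
    callers can skip and report the image.
    """
    cfg = config or ClassicalConfig()
    px = image.pixels
    if method == "classical":
        tail = px[px >= np.quantile(px, cfg.upper_quantile)]
        if tail.size == 0 or np.ptp(tail) < 1e-9:
            raise LocalizationFailure("flat image; no intensity structure")
        thr = filters.threshold_otsu(tail)
        bright = px > thr
    elif method == "learned":
        if model is None:
            raise ValueError("learned segmentation requires a trained model")
        pred = model.estimator.predict(_pixel_features(px)).reshape(px.shape)
        bright = pred > 0
    else:
        raise ValueError(f"unknown method {method!r}")

    bright = morphology.opening(
        bright, morphology.footprint_rectangle((2 * cfg.opening_radius + 1,) * 2))
    if not bright.any():
        raise LocalizationFailure("nothing above the bone threshold")
    return _label_components(bright, cfg)


def detect_vertebrae(source, config: ClassicalConfig | None = None) -> list[VertebraBox]:
    """Detect exactly four lumbar vertebra boxes, labeled L1..L4.

    ``source`` is either a :class:`SpineSegmentation` or a raw
    :class:`DexaImage` (in which case the classical segmenter runs first —
    this is the box-detection front-end of pipeline 2).  Labels count upward
    from the pelvis: the vertebra nearest the pelvis is L4.
    """
    if isinstance(source, DexaImage):
        seg = segment_spine(source, method="classical", config=config)
    else:
        seg = source
    lab = measure.label(seg.mask == SpineSegmentation.VERTEBRA)
    props = measure.regionprops(lab)
    if len(props) < 4:
        raise LocalizationFailure(
            f"found {len(props)} vertebra candidates; need 4")
    if len(props) > 4:
        log.info("keeping the 4 largest of %d vertebra candidates", len(props))
        props = sorted(props, key=lambda p: p.area, reverse=True)[:4]
    props = sorted(props, key=lambda p: p.centroid[0])  # superior -> inferior
    boxes = []
    for level, p in zip(("L1", "L2", "L3", "L4"), props):
        rmin, cmin, rmax, cmax = p.bbox
        boxes.append(VertebraBox(level=level, row_min=rmin, row_max=rmax,
                                 col_min=cmin, col_max=cmax))
    return boxes


def pelvis_centroid(seg: SpineSegmentation) -> tuple[float, float] | None:
    """Centroid of the pelvis component, if one was labeled."""
    ys, xs = np.nonzero(seg.mask == SpineSegmentation.PELVIS)
    if ys.size == 0:
        return None
    return float(ys.mean()), float(xs.mean())


@dataclass
class TrainConfig:
    """Learned-segmenter training knobs (desk-scale by default)."""

    n_estimators: int = 30
    max_depth: int = 14
    samples_per_class_per_image: int = 300
    seed: int = 0


def train_segmenter(images, masks, config: TrainConfig | None = None) -> SegmenterModel:
    """Fit the per-pixel random-forest segmenter on paired (image, label mask).

    Masks use the segmentation label convention (0 background, 1 pelvis,
    2 vertebra).  Fewer than 50 pairs is allowed but logged as degenerate.
    """
    cfg = config or TrainConfig()
    if len(images) != len(masks):
        raise ValueError("images and masks must pair up")
    if len(images) < 50:
        log.warning("degenerate training set: only %d pairs (< 50)", len(images))
    rng = np.random.default_rng(cfg.seed)
    X_parts, y_parts = [], []
    for im, mk in zip(images, masks):
        px = im.pixels if isinstance(im, DexaImage) else np.asarray(im, float)
        mk = np.asarray(mk)
        if mk.shape != px.shape:
            raise ValueError(f"mask shape {mk.shape} != image shape {px.shape}")
        feats = _pixel_features(px)
        flat = mk.reshape(-1)
        for cls in (0, 1, 2):
            idx = np.flatnonzero(flat == cls)
            if idx.size == 0:
                continue
            take = min(cfg.samples_per_class_per_image, idx.size)
            sel = rng.choice(idx, size=take, replace=False)
            X_parts.append(feats[sel])
            y_parts.append(flat[sel])
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    est = RandomForestClassifier(n_estimators=cfg.n_estimators,
                                 max_depth=cfg.max_depth,
                                 random_state=cfg.seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    # decreasing-loss sanity: out-of-bag style check is skipped at desk scale
    return SegmenterModel(estimator=est)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
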