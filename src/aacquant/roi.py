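"""Spine-curve fitting and aortic ROI extraction.

The abdominal aorta runs roughly parallel to the lumbar spine, a fixed
anatomical distance anterior to it.  A low-degree polynomial (default
quadratic — lumbar lordosis is one gentle bend) is fit through the four
vertebral centroids (optionally anchored by the pelvis centroid), and the
aortic region of interest is a band *centered* on the expected aortic
centerline at ``offset_factor x mean vertebral height`` anterior to the
curve, ``width_factor x mean vertebral height`` wide.  The band midline is
the aortic centerline, so splitting at the midline yields the posterior
(spine-adjacent) and anterior wall sub-bands.  Per-level row ranges come
from the detected boxes, so unequal vertebrae are handled.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import AorticROI, LocalizationFailure, SpineCurve, VertebraBox

#: Geometry defaults shared with the phantom generator.
DEFAULT_OFFSET_FACTOR = 1.2
DEFAULT_WIDTH_FACTOR = 0.8


def fit_spine_curve(boxes: list[VertebraBox], pelvis_centroid=None,
                    degree: int = 2) -> SpineCurve:
    """Least-squares polynomial column = p(row) through vertebral centroids.

    Requires more points than the polynomial degree.  Perfectly collinear
    points with degree > 1 fall back to a straight line with a warning.
    """
    pts = [b.centroid for b in boxes]
    if pelvis_centroid is not None:
        pts.append(tuple(pelvis_centroid))
    if len(pts) <= degree:
        raise ValueError(f"{len(pts)} points cannot constrain degree {degree}")
    rows = np.array([p[0] for p in pts])
    cols = np.array([p[1] for p in pts])

    if degree > 1:
        lin = np.polyfit(rows, cols, 1)
        if np.max(np.abs(np.polyval(lin, rows) - cols)) < 1e-9:
            warnings.warn("collinear centroids; falling back to degree 1")
            coeffs = lin
        else:
            coeffs = np.polyfit(rows, cols, degree)
    else:
        coeffs = np.polyfit(rows, cols, degree)

    curve = SpineCurve(coeffs=coeffs,
                       row_min=float(min(b.row_min for b in boxes)),
                       row_max=float(max(b.row_max for b in boxes)))
    widths = [b.col_max - b.col_min for b in boxes]
    resid = np.abs(curve(np.array([b.centroid[0] for b in boxes]))
                   - np.array([b.centroid[1] for b in boxes]))
    if np.any(resid >= 0.25 * np.asarray(widths)):
        warnings.warn("spine-curve residual exceeds 1/4 vertebral width; "
                      "localization may be unreliable")
    return curve


def extract_aortic_roi(curve: SpineCurve, boxes: list[VertebraBox],
                       offset_factor: float = DEFAULT_OFFSET_FACTOR,
                       width_factor: float = DEFAULT_WIDTH_FACTOR,
                       image_shape: tuple | None = None) -> AorticROI:
    """Extract the per-level aortic band anterior to the spine curve.

    For every row of each vertebra's row range the band spans
    ``curve(row) + offset +/- width/2`` columns, where offset and width are
    the configured multiples of the mean vertebral height.  The midline
    (``curve(row) + offset``) splits the posterior and anterior wall
    sub-bands.  Bands partially outside the image are clipped with a
    warning; a band fully outside raises :class:`LocalizationFailure`.
    """
    if offset_factor == 0:
        warnings.warn("offset factor 0: aortic band abuts the spine")
    if offset_factor < 0 or width_factor <= 0:
        raise ValueError("offset factor must be >= 0 and width factor > 0")
    mean_h = float(np.mean([b.height for b in boxes]))
    offset = offset_factor * mean_h
    width = width_factor * mean_h

    bands = {}
    clipped = False
    for box in boxes:
        if box.row_min < curve.row_min - 1e-9 or box.row_max > curve.row_max + 1e-9:
            raise ValueError(
                f"curve domain [{curve.row_min}, {curve.row_max}] does not "
                f"cover {box.level} rows [{box.row_min}, {box.row_max}]")
        rows = np.arange(box.row_min, box.row_max)
        mid = curve(rows) + offset
        post_lo = mid - width / 2.0
        ant_hi = mid + width / 2.0
        if image_shape is not None:
            n_cols = image_shape[1]
            if np.all(post_lo >= n_cols) or np.all(ant_hi <= 0):
                raise LocalizationFailure(
                    f"aortic band for {box.level} fully outside the image")
            if np.any(ant_hi > n_cols) or np.any(post_lo < 0):
                clipped = True
                warnings.warn(f"aortic band for {box.level} clipped to image")
                post_lo = np.clip(post_lo, 0, n_cols)
                ant_hi = np.clip(ant_hi, 0, n_cols)
                mid = np.clip(mid, 0, n_cols)
        bands[box.level] = (rows, post_lo, mid, ant_hi)
    return AorticROI(bands=bands, offset_factor=offset_factor,
                     width_factor=width_factor, clipped=clipped)
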