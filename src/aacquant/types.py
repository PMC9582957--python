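"""Core domain types shared by every pipeline stage.

Coordinate convention (fixed across the package): images are 2-D arrays
indexed ``[row, column]`` with row 0 the most superior (cranial) row and
*increasing column = anterior*.  All geometry (boxes, curves, ROI bands)
uses this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Lumbar vertebral levels, ordered superior -> inferior.
LEVELS = ("L1", "L2", "L3", "L4")
#: Aortic walls in lateral projection: posterior = spine-adjacent edge.
WALLS = ("anterior", "posterior")


class LocalizationFailure(RuntimeError):
    """Raised when an image cannot be localized (no spine found, ROI out of
    bounds, ...).  Pipelines catch this and report the image as skipped."""


@dataclass
class DexaImage:
    """A single-channel lateral-spine scan with isotropic pixel spacing."""

    pixels: np.ndarray
    spacing_mm: float = 1.0
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 32:
            raise ValueError(
                f"image too small {self.pixels.shape}; need >= 64 rows x 32 cols"
            )
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise ValueError("intensities must be finite and non-negative")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class VertebraBox:
    """Axis-aligned bounding box of one lumbar vertebra."""

    level: str
    row_min: int
    row_max: int  # exclusive
    col_min: int
    col_max: int  # exclusive

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError("degenerate box")

    @property
    def centroid(self) -> tuple[float, float]:
        return ((self.row_min + self.row_max - 1) / 2.0,
                (self.col_min + self.col_max - 1) / 2.0)

    @property
    def height(self) -> int:
        return self.row_max - self.row_min


@dataclass
class SpineSegmentation:
    """Label mask over the image grid: 0 background, 1 pelvis, 2 vertebra."""

    mask: np.ndarray
    components: list[dict] = field(default_factory=list)

    BACKGROUND = 0
    PELVIS = 1
    VERTEBRA = 2

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        labels = set(np.unique(self.mask).tolist())
        if not labels <= {0, 1, 2}:
            raise ValueError("mask labels must be in {0, 1, 2}")


@dataclass
class SpineCurve:
    """Polynomial column = p(row) describing the anterior spine margin line
    through the vertebral centroids."""

    coeffs: np.ndarray  # numpy polyval order (highest degree first)
    row_min: float
    row_max: float

    def __call__(self, rows) -> np.ndarray:
        return np.polyval(self.coeffs, np.asarray(rows, dtype=float))

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1


@dataclass
class AorticROI:
    """Per-level quadrilateral band anterior to the spine curve.

    ``bands[level]`` holds, for each row of that vertebra's row range, the
    column interval ``[post_lo, mid, ant_hi]``: the posterior-wall sub-band
    is ``[post_lo, mid)`` and the anterior-wall sub-band ``[mid, ant_hi)``.
    """

    bands: dict  # level -> (rows: np.ndarray, post_lo, mid, ant_hi arrays)
    offset_factor: float
    width_factor: float
    clipped: bool = False

    def wall_slices(self, level: str):
        """Yield (row, col_lo, col_hi) integer spans per wall for a level."""
        rows, post_lo, mid, ant_hi = self.bands[level]
        return rows, post_lo, mid, ant_hi


@dataclass
class KauppilaScore:
    """Eight per-(level, wall) integer scores in 0..3 and their 0..24 total."""

    per_wall: dict  # (level, wall) -> int
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {(lv, w) for lv in LEVELS for w in WALLS} - set(self.per_wall)
        if missing:
            raise ValueError(f"missing per-wall scores: {sorted(missing)}")
        for key, s in self.per_wall.items():
            if s not in (0, 1, 2, 3):
                raise ValueError(f"score {s} for {key} outside 0..3")

    @property
    def total(self) -> int:
        return int(sum(self.per_wall.values()))


@dataclass
class CalcificationMask:
    """Binary calcification mask restricted to the ROI plus per-(level, wall)
    projected coverage fractions (rows containing any calcified pixel over
    the level's row extent)."""

    mask: np.ndarray
    coverage: dict  # (level, wall) -> float in [0, 1]

    def __post_init__(self) -> None:
        for key, f in self.coverage.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"coverage {f} for {key} outside [0, 1]")


@dataclass
class GroundTruth:
    """Exact generation record accompanying a phantom image."""

    vertebrae: list        # list[VertebraBox], superior -> inferior
    pelvis_mask: np.ndarray
    aorta_centerline: np.ndarray       # (n, 2) array of (row, col)
    coverage: dict                     # (level, wall) -> realized fraction
    true_score: "KauppilaScore"
    contrast_L12: float
    vertebra_mask: np.ndarray
    calc_mask: np.ndarray
    curve_coeffs: np.ndarray           # generating spine-curve polynomial
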