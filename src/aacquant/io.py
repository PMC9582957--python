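"""Reading and writing the package's on-disk formats.

Images go out as 16-bit PNG or TIFF; ground truth as a JSON sidecar with a
schema version; label masks as 8-bit PNG; annotations and score tables as
TSV; cohorts as CSV; configs as YAML; model handles as single joblib files
with a format version.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .types import DexaImage, GroundTruth, KauppilaScore, VertebraBox

SIDECAR_SCHEMA_VERSION = 1
MODEL_FORMAT_VERSION = 1


def write_image(image: DexaImage, path) -> None:
    """Write as 16-bit grayscale PNG or TIFF (by extension), scaled to the
    full dynamic range; the scale is recorded in the sidecar if needed."""
    path = Path(path)
    px = image.pixels
    hi = float(px.max()) or 1.0
    arr = np.round(px / hi * 65535.0).astype(np.uint16)
    Image.fromarray(arr, mode="I;16").save(path)


def read_image(path, spacing_mm: float = 1.0) -> DexaImage:
    """Load a single-channel image of arbitrary bit depth, normalized to
    [0, 1]."""
    path = Path(path)
    arr = np.asarray(Image.open(path), dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    hi = arr.max() or 1.0
    return DexaImage(pixels=arr / hi, spacing_mm=spacing_mm, id=path.stem)


def write_mask(mask: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)


def write_ground_truth(gt: GroundTruth, path) -> None:
    """JSON sidecar: geometry, coverage, true score; masks are not embedded."""
    payload = {
        "schema_version": SIDECAR_SCHEMA_VERSION,
        "vertebrae": [dataclasses.asdict(b) for b in gt.vertebrae],
        "aorta_centerline": np.asarray(gt.aorta_centerline).tolist(),
        "coverage": {f"{lv}:{w}": f for (lv, w), f in gt.coverage.items()},
        "true_per_wall": {f"{lv}:{w}": s
                          for (lv, w), s in gt.true_score.per_wall.items()},
        "true_total": gt.true_score.total,
        "contrast_L12": gt.contrast_L12,
        "curve_coeffs": np.asarray(gt.curve_coeffs).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth_sidecar(path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SIDECAR_SCHEMA_VERSION:
        raise ValueError("unsupported ground-truth schema version")
    payload["coverage"] = {tuple(k.split(":")): v
                           for k, v in payload["coverage"].items()}
    payload["vertebrae"] = [VertebraBox(**b) for b in payload["vertebrae"]]
    return payload


def write_scores_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"image_id", "annotator_id", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation TSV needs columns {sorted(required)}")
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def save_model(model, path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path):
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    return payload["model"]
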