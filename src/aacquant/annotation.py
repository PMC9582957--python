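"""Annotation consensus and model-vs-reader agreement metrics.

Annotation tables are tidy DataFrames with columns ``image_id``,
``annotator_id`` and ``score`` (total AAC score, 0-24).  Consensus across
readers is the median (even count: mean of the two middle values), which
bounds the influence of any single outlying reader.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def consensus_score(scores) -> float:
    """Median of one image's annotations (even count: mean of middle two)."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("no annotations for image")
    if np.any((arr < 0) | (arr > 24)):
        raise ValueError("annotation outside [0, 24]")
    return float(np.median(arr))


def consensus_table(annotations: pd.DataFrame) -> pd.Series:
    """Per-image median consensus from a tidy annotation table."""
    return annotations.groupby("image_id")["score"].median()


def split_dataset(image_ids, sizes: tuple, seed: int = 0):
    """Seeded disjoint split of image ids into (train_test, validation).

    ``sizes`` gives the two subset sizes; their sum may not exceed the
    number of distinct ids.
    """
    ids = pd.unique(pd.Series(list(image_ids)))
    n_train, n_val = sizes
    if n_train + n_val > len(ids):
        raise ValueError(f"requested {n_train}+{n_val} ids from {len(ids)}")
    perm = np.random.default_rng(seed).permutation(len(ids))
    train = ids[perm[:n_train]]
    val = ids[perm[n_train:n_train + n_val]]
    return list(train), list(val)


@dataclass
class AgreementReport:
    mae: float
    pearson_r: float | None
    n: int


def agreement_stats(predicted, reference) -> AgreementReport:
    """Mean absolute error and Pearson correlation of paired score vectors.

    A constant reference makes the correlation undefined; it is reported as
    ``None`` rather than NaN-propagated.
    """
    pred = np.asarray(list(predicted), dtype=float)
    ref = np.asarray(list(reference), dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference lengths differ")
    if pred.size < 2:
        raise ValueError("need at least 2 pairs")
    mae = float(np.mean(np.abs(pred - ref)))
    if np.ptp(ref) == 0 or np.ptp(pred) == 0:
        r = None
    else:
        r = float(stats.pearsonr(pred, ref).statistic)
    return AgreementReport(mae=mae, pearson_r=r, n=int(pred.size))


def per_annotator_mae(annotations: pd.DataFrame) -> pd.Series:
    """Each annotator's MAE against the per-image median consensus."""
    cons = consensus_table(annotations)
    joined = annotations.join(cons.rename("consensus"), on="image_id")
    return (joined["score"] - joined["consensus"]).abs() \
        .groupby(joined["annotator_id"]).mean()
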