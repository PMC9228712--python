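"""Kennard-Stone calibration/prediction splitting.

Selection runs on per-sample mean preprocessed spectra, never on individual
replicate scans, so all spectra of one sample land on the same side of the
split (no replicate leakage).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import InvalidInputError
from .preprocess import FusedData

__all__ = ["SplitPlan", "kennard_stone", "split_dataset"]


@dataclass(frozen=True)
class SplitPlan:
    """Outcome of a Kennard-Stone split at sample level.

    ``calibration_sample_ids`` keeps the selection order; prediction ids are
    in original dataset order.
    """

    calibration_sample_ids: tuple
    prediction_sample_ids: tuple
    distance_metric: str = "euclidean"

    def __post_init__(self) -> None:
        overlap = set(self.calibration_sample_ids) & set(self.prediction_sample_ids)
        if overlap:
            raise InvalidInputError(f"samples on both sides of split: {overlap}")

    def calibration_mask(self, sample_id: np.ndarray) -> np.ndarray:
        cal = set(self.calibration_sample_ids)
        return np.asarray([s in cal for s in sample_id])

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "calibration_sample_ids": list(self.calibration_sample_ids),
                    "prediction_sample_ids": list(self.prediction_sample_ids),
                    "distance_metric": self.distance_metric,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            calibration_sample_ids=tuple(d["calibration_sample_ids"]),
            prediction_sample_ids=tuple(d["prediction_sample_ids"]),
            distance_metric=d.get("distance_metric", "euclidean"),
        )


def kennard_stone(points: np.ndarray, n_select: int) -> list[int]:
    """Kennard-Stone max-min selection order on Euclidean distances.

    The first two picks are a maximally distant pair; every further pick
    maximizes its minimum distance to everything already selected. Ties are
    broken toward the lowest index, making the selection deterministic.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n_select < 2:
        raise InvalidInputError("n_select must be >= 2")
    if n_select > n:
        raise InvalidInputError(f"n_select={n_select} exceeds n={n}")

    dist = cdist(points, points)
    # np.argmax on the flattened matrix returns the first (lowest (i, j))
    # occurrence of the maximum, giving the deterministic tie rule.
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    selected = [int(min(i, j)), int(max(i, j))]
    min_dist = np.minimum(dist[selected[0]], dist[selected[1]])
    min_dist[selected] = -np.inf

    while len(selected) < n_select:
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
        min_dist[nxt] = -np.inf
    return selected


def sample_means(fused: FusedData) -> tuple[list, np.ndarray]:
    """Per-sample mean spectra in order of first appearance."""
    order: list = []
    seen = set()
    for s in fused.sample_id:
        if s not in seen:
            seen.add(s)
            order.append(s)
    means = np.stack(
        [fused.X[fused.sample_id == s].mean(axis=0) for s in order]
    )
    return order, means


def split_dataset(fused: FusedData, n_calibration: int = 26) -> SplitPlan:
    """Kennard-Stone split of a fused, preprocessed dataset by sample.

    The default 26 calibration / 13 prediction samples reproduces the
    520/260-spectrum design at 20 spectra per sample.
    """
    ids, means = sample_means(fused)
    if n_calibration > len(ids):
        raise InvalidInputError(
            f"requested {n_calibration} calibration samples from {len(ids)}"
        )
    sel = kennard_stone(means, n_calibration)
    cal = tuple(ids[i] for i in sel)
    pred = tuple(s for s in ids if s not in set(cal))
    if not pred:
        warnings.warn("calibration set uses every sample; prediction set is empty")
    return SplitPlan(calibration_sample_ids=cal, prediction_sample_ids=pred)
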