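"""Limit of blank / limit of detection from replicate values.

The classical replicate-based estimators::

    LoB = mean_blank + 1.645 * SD_blank
    LoD = LoB + 1.645 * SD_low

where SD_blank comes from repeated blank measurements (or blank predictions
of a calibration model) and SD_low from a sample known to contain a low
analyte concentration. 1.645 is the one-sided normal 95th percentile;
standard deviations use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InsufficientReplicatesError, InvalidInputError
from .regress import CalibrationModel, predict

__all__ = [
    "Z_95",
    "LodResult",
    "limit_of_blank",
    "limit_of_detection",
    "lod_from_model",
]

#: One-sided 95th percentile of the standard normal distribution.
Z_95 = 1.645


@dataclass(frozen=True)
class LodResult:
    """LoB/LoD estimate with its ingredients (all mg/mL)."""

    mean_blank: float
    sd_blank: float
    sd_low: float
    lob: float
    lod: float
    n_blank: int
    n_low: int
    source: str = "predicted"  # or "measured"

    def __post_init__(self) -> None:
        if not np.isclose(self.lob, self.mean_blank + Z_95 * self.sd_blank):
            raise InvalidInputError("lob inconsistent with mean_blank/sd_blank")
        if not np.isclose(self.lod, self.lob + Z_95 * self.sd_low):
            raise InvalidInputError("lod inconsistent with lob/sd_low")
        if self.source not in ("measured", "predicted"):
            raise InvalidInputError(f"unknown source {self.source!r}")


def _as_replicates(values: Sequence[float], what: str) -> np.ndarray:
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 {what} replicates, got {v.size}"
        )
    return v


def limit_of_blank(blank_values: Sequence[float]) -> tuple[float, float, float]:
    """(mean_blank, sd_blank, LoB) from replicate blank values."""
    v = _as_replicates(blank_values, "blank")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return mean, sd, mean + Z_95 * sd


def limit_of_detection(
    lob: float, low_conc_values: Sequence[float]
) -> tuple[float, float]:
    """(sd_low, LoD) from the LoB and replicate low-concentration values."""
    v = _as_replicates(low_conc_values, "low-concentration")
    sd = float(v.std(ddof=1))
    return sd, lob + Z_95 * sd


def lod_from_model(
    model: CalibrationModel,
    data,
    blank_conc: float = 0.0,
    low_conc: float | None = None,
) -> LodResult:
    """LoB/LoD from model predictions of blank and low-level replicates.

    ``data`` is anything :func:`specfuse.regress.predict` accepts that
    carries a per-row ``concentration`` (raw blocks or FusedData). When
    ``low_conc`` is None the smallest non-zero level above ``blank_conc``
    present in the data is used. Negative predictions are retained: clipping
    them would bias the replicate SDs downward.
    """
    conc = np.asarray(
        data[0].concentration if isinstance(data, (list, tuple)) else data.concentration,
        dtype=float,
    )
    if low_conc is None:
        above = np.unique(conc[conc > blank_conc])
        if above.size == 0:
            raise InvalidInputError("no level above the blank concentration")
        low_conc = float(above[0])

    blank_rows = np.isclose(conc, blank_conc)
    low_rows = np.isclose(conc, low_conc)
    if not blank_rows.any():
        raise InvalidInputError(f"no replicates at blank level {blank_conc}")
    if not low_rows.any():
        raise InvalidInputError(f"no replicates at low level {low_conc}")

    preds = predict(model, data)
    mean_blank, sd_blank, lob = limit_of_blank(preds[blank_rows])
    sd_low, lod = limit_of_detection(lob, preds[low_rows])
    return LodResult(
        mean_blank=mean_blank,
        sd_blank=sd_blank,
        sd_low=sd_low,
        lob=lob,
        lod=lod,
        n_blank=int(blank_rows.sum()),
        n_low=int(low_rows.sum()),
        source="predicted",
    )
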