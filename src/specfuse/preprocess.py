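"""Preprocessing chain and low-level block fusion.

Fixed stage order: Savitzky-Golay 2nd derivative -> SNV, applied per
instrument block, then masking + column-wise fusion, then mean-centering on
the calibration subset. SNV before fusion acts as implicit block scaling, so
neither instrument's raw scale dominates the fused matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .exceptions import (
    AlignmentError,
    DegenerateSpectrumError,
    InvalidInputError,
    PipelineStateError,
)
from .synthetic import SpectralBlock

__all__ = [
    "PreprocessSpec",
    "FusedData",
    "DEFAULT_MASKS",
    "savitzky_golay",
    "snv",
    "mean_center",
    "to_wavelength",
    "fuse_blocks",
    "PreprocessPipeline",
]

#: Fusion windows in each block's native axis unit. The MIR window keeps the
#: fingerprint region 1800-800 cm^-1 (= 5556-12500 nm); the NIR block is
#: used in full. ``None`` means no masking.
DEFAULT_MASKS: dict[str, tuple[float, float] | None] = {
    "MIR": (800.0, 1800.0),
    "NIR": None,
}


@dataclass(frozen=True)
class PreprocessSpec:
    """Savitzky-Golay derivative + SNV + centering configuration."""

    sg_window: int = 15
    sg_polyorder: int = 2
    sg_deriv: int = 2
    apply_snv: bool = True
    center: str = "calibration_mean"  # or "none"

    def __post_init__(self) -> None:
        if self.sg_window % 2 != 1:
            raise InvalidInputError("sg_window must be odd")
        if self.sg_window < self.sg_polyorder + 2:
            raise InvalidInputError("sg_window must be >= sg_polyorder + 2")
        if self.sg_deriv > self.sg_polyorder:
            raise InvalidInputError("sg_deriv must be <= sg_polyorder")
        if self.center not in ("calibration_mean", "none"):
            raise InvalidInputError(f"unknown centering mode {self.center!r}")


def savitzky_golay(
    spectra: np.ndarray, spec: PreprocessSpec, delta: float = 1.0
) -> np.ndarray:
    """Savitzky-Golay derivative along rows.

    Interior points carry the derivative of the local least-squares
    polynomial scaled by ``1/delta**deriv``; the ``window//2`` columns at
    each edge are replaced by the nearest valid interior value so the matrix
    width is preserved without extrapolated edge polynomials.
    """
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    if x.shape[1] < spec.sg_window:
        raise InvalidInputError(
            f"sg_window={spec.sg_window} exceeds row length {x.shape[1]}"
        )
    out = savgol_filter(
        x,
        window_length=spec.sg_window,
        polyorder=spec.sg_polyorder,
        deriv=spec.sg_deriv,
        delta=delta,
        axis=1,
        mode="interp",
    )
    half = spec.sg_window // 2
    if half:
        out[:, :half] = out[:, half : half + 1]
        out[:, -half:] = out[:, -half - 1 : -half]
    return out[0] if np.asarray(spectra).ndim == 1 else out


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row to mean 0, sample SD 1 (ddof=1)."""
    x = np.atleast_2d(np.asarray(spectra, dtype=float))
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd[:, 0] == 0.0)
    if bad.size:
        raise DegenerateSpectrumError(
            f"constant spectrum (zero SD) in row(s) {bad.tolist()}"
        )
    out = (x - mean) / sd
    return out[0] if np.asarray(spectra).ndim == 1 else out


def mean_center(
    train: np.ndarray, apply_to: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Center columns by the training-set mean.

    Returns ``(train_centered, apply_centered, column_means)`` where the
    middle element is ``None`` when no second matrix is given. The centering
    vector always comes from ``train`` only.
    """
    train = np.asarray(train, dtype=float)
    mean = train.mean(axis=0)
    train_c = train - mean
    apply_c = None
    if apply_to is not None:
        apply_to = np.asarray(apply_to, dtype=float)
        if apply_to.shape[1] != train.shape[1]:
            raise InvalidInputError(
                "column count of apply_to does not match train"
            )
        apply_c = apply_to - mean
    return train_c, apply_c, mean


def to_wavelength(axis_cm: np.ndarray) -> np.ndarray:
    """Convert a wavenumber axis (cm^-1) to wavelength (nm), increasing.

    nm = 1e7 / cm^-1; the order is reversed so an increasing wavenumber axis
    maps to an increasing wavelength axis (callers must reorder intensity
    columns the same way).
    """
    axis_cm = np.asarray(axis_cm, dtype=float)
    if np.any(axis_cm <= 0):
        raise InvalidInputError("wavenumbers must be positive")
    return (1e7 / axis_cm)[::-1]


@dataclass
class FusedData:
    """Fused feature matrix with a per-column provenance axis.

    ``provenance`` has one row per column: modality, native axis value and
    unit, and the equivalent wavelength in nm for cross-modality reporting.
    """

    X: np.ndarray
    provenance: pd.DataFrame
    sample_id: np.ndarray
    replicate_id: np.ndarray
    concentration: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def select_rows(self, mask: np.ndarray) -> "FusedData":
        return FusedData(
            X=self.X[mask],
            provenance=self.provenance,
            sample_id=self.sample_id[mask],
            replicate_id=self.replicate_id[mask],
            concentration=self.concentration[mask],
        )


def _mask_columns(
    block: SpectralBlock, window: tuple[float, float] | None
) -> np.ndarray:
    if window is None:
        return np.ones(block.n_points, dtype=bool)
    lo, hi = sorted(window)
    sel = (block.axis >= lo) & (block.axis <= hi)
    if not sel.any():
        raise InvalidInputError(
            f"empty {block.modality} mask window {window}"
        )
    return sel


def fuse_blocks(
    blocks: Sequence[SpectralBlock],
    region_masks: Mapping[str, tuple[float, float] | None] | None = None,
) -> FusedData:
    """Column-wise concatenation of masked blocks (low-level data fusion).

    All blocks must share row metadata in the same order; the provenance
    axis records where each fused column came from.
    """
    if not blocks:
        raise InvalidInputError("no blocks to fuse")
    region_masks = DEFAULT_MASKS if region_masks is None else region_masks
    first = blocks[0]
    for b in blocks[1:]:
        if (
            not np.array_equal(b.sample_id, first.sample_id)
            or not np.array_equal(b.replicate_id, first.replicate_id)
            or not np.array_equal(b.concentration, first.concentration)
        ):
            raise AlignmentError(
                "blocks do not share row metadata in the same order"
            )

    parts, prov = [], []
    for b in blocks:
        sel = _mask_columns(b, region_masks.get(b.modality))
        parts.append(b.intensities[:, sel])
        values = b.axis[sel]
        nm = values if b.axis_unit == "nm" else 1e7 / values
        prov.append(
            pd.DataFrame(
                {
                    "modality": b.modality,
                    "value": values,
                    "unit": b.axis_unit,
                    "wavelength_nm": nm,
                }
            )
        )
    return FusedData(
        X=np.concatenate(parts, axis=1),
        provenance=pd.concat(prov, ignore_index=True),
        sample_id=first.sample_id.copy(),
        replicate_id=first.replicate_id.copy(),
        concentration=first.concentration.copy(),
    )


class PreprocessPipeline:
    """Per-block derivative + SNV with a re-application guard.

    The chain is not idempotent (a second derivative of a derivative is a
    4th derivative), so transforming an already-preprocessed block raises.
    """

    def __init__(self, spec: PreprocessSpec | None = None):
        self.spec = PreprocessSpec() if spec is None else spec

    def transform_block(self, block: SpectralBlock) -> SpectralBlock:
        if block.is_preprocessed:
            raise PipelineStateError(
                f"{block.modality} block was already preprocessed"
            )
        x = savitzky_golay(
            block.intensities, self.spec, delta=abs(block.axis_spacing)
        )
        if self.spec.apply_snv:
            x = snv(x)
        return SpectralBlock(
            modality=block.modality,
            axis_unit=block.axis_unit,
            axis=block.axis.copy(),
            intensities=x,
            sample_id=block.sample_id.copy(),
            replicate_id=block.replicate_id.copy(),
            concentration=block.concentration.copy(),
            is_preprocessed=True,
        )

    def transform(self, blocks: Sequence[SpectralBlock]) -> list[SpectralBlock]:
        return [self.transform_block(b) for b in blocks]
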