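"""Synthetic paired MIR/NIR serum-spiking datasets.

Emulates a spiking study in which a low-molecular-weight analyte (glycine by
default) is added to whole serum over a wide concentration series and each
sample is measured on two instruments:

* a handheld NIR spectrometer producing 141 points over 2500-1350 nm, and
* an ATR-FTIR spectrometer covering 4000-800 cm^-1 at 8 cm^-1 resolution
  (zero-filling factor 2, i.e. ~4 cm^-1 point spacing).

The absorbance model for one spectrum at concentration ``c`` is::

    A(x) = M~(x) * (1 + delta_rep + m_scatter) + c * r * S(x) + b(x) + eps(x)

with ``S`` the analyte unit spectrum, ``r`` the response in AU per (mg/mL),
``delta_rep`` a per-donor amplitude offset, ``m_scatter`` a per-spectrum
multiplicative scatter term, ``b`` a random low-order polynomial baseline,
and ``eps`` iid Gaussian noise. ``M~`` is the serum matrix spectrum with
per-spectrum band heterogeneity: each matrix band's amplitude is perturbed
by an independent relative factor ``1 + eta`` (dried-film deposits are not
compositionally uniform, so band ratios vary between repeated scans; this
structured, concentration-irrelevant variability is what forces
latent-variable models to spend components on the matrix). Absorbance is
clipped at zero after summation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "AxisSpec",
    "BandModel",
    "ComponentLibrary",
    "SimulationConfig",
    "SpectralBlock",
    "NIR_AXIS",
    "MIR_AXIS",
    "DEFAULT_CONCENTRATION_SERIES",
    "evaluate_band",
    "component_spectrum",
    "simulate_dataset",
]

Modality = Literal["MIR", "NIR"]

#: Glycine spiking series in mg/mL (13 levels including the blank).
DEFAULT_CONCENTRATION_SERIES: tuple[float, ...] = (
    0.0, 0.01, 0.05, 0.1, 0.5, 1.0, 2.5, 5.0, 7.5, 10.0, 17.5, 25.0, 50.0,
)

_UNIT_SUFFIX = {"nm": "nm", "inverse_cm": "cm-1"}
_SUFFIX_UNIT = {v: k for k, v in _UNIT_SUFFIX.items()}


@dataclass(frozen=True)
class AxisSpec:
    """A uniformly sampled spectral axis."""

    unit: Literal["nm", "inverse_cm"]
    start: float
    end: float
    n_points: int

    def __post_init__(self) -> None:
        if self.unit not in _UNIT_SUFFIX:
            raise InvalidInputError(f"unknown axis unit {self.unit!r}")
        if self.n_points < 2:
            raise InvalidInputError("an axis needs at least 2 points")
        if self.start == self.end:
            raise InvalidInputError("axis start and end must differ")

    def grid(self) -> np.ndarray:
        """Realize the axis as a strictly monotone grid."""
        return np.linspace(self.start, self.end, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.end - self.start) / (self.n_points - 1)


#: 141-point near-infrared grid, 1350-2500 nm (handheld MEMS spectrometer).
NIR_AXIS = AxisSpec(unit="nm", start=1350.0, end=2500.0, n_points=141)

#: Mid-infrared ATR grid, 800-4000 cm^-1 at 4 cm^-1 point spacing.
MIR_AXIS = AxisSpec(unit="inverse_cm", start=800.0, end=4000.0, n_points=801)


@dataclass(frozen=True)
class BandModel:
    """One parametric absorption band.

    Parameters are in the units of the axis the band lives on (nm for NIR,
    cm^-1 for MIR); amplitude is peak absorbance.
    """

    center: float
    fwhm: float
    amplitude: float
    shape: Literal["gaussian", "lorentzian"] = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise InvalidInputError("band fwhm must be positive")
        if self.amplitude < 0:
            raise InvalidInputError("band amplitude must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise InvalidInputError(f"unknown band shape {self.shape!r}")


def _check_monotone(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise InvalidInputError("grid must be a 1-D vector with >= 2 points")
    d = np.diff(grid)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise InvalidInputError("grid must be strictly monotone")
    return grid


def evaluate_band(band: BandModel, grid: np.ndarray) -> np.ndarray:
    """Evaluate one band on a monotone grid.

    Gaussian bands use ``A * exp(-4 ln2 (x-c)^2 / fwhm^2)``; Lorentzian bands
    ``A / (1 + (2 (x-c)/fwhm)^2)``. Both equal the amplitude at the center
    and half of it at center +/- fwhm/2.
    """
    grid = _check_monotone(grid)
    z = (grid - band.center) / band.fwhm
    if band.shape == "gaussian":
        out = band.amplitude * np.exp(-4.0 * np.log(2.0) * z**2)
    else:
        out = band.amplitude / (1.0 + 4.0 * z**2)
    return out


@dataclass(frozen=True)
class ComponentLibrary:
    """Band library of one chemical component in both modalities."""

    name: str
    mir_bands: tuple[BandModel, ...]
    nir_bands: tuple[BandModel, ...]
    response_per_unit_conc: float = 1.0

    def bands(self, modality: Modality) -> tuple[BandModel, ...]:
        if modality == "MIR":
            return tuple(self.mir_bands)
        if modality == "NIR":
            return tuple(self.nir_bands)
        raise InvalidInputError(f"unknown modality {modality!r}")


def component_spectrum(
    lib: ComponentLibrary, modality: Modality, grid: np.ndarray
) -> np.ndarray:
    """Sum of the library's bands for one modality, evaluated on ``grid``."""
    bands = lib.bands(modality)
    if not bands:
        raise InvalidInputError(
            f"component {lib.name!r} has no {modality} bands"
        )
    grid = _check_monotone(grid)
    out = np.zeros_like(grid)
    for band in bands:
        out += evaluate_band(band, grid)
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of the simulated spiking experiment.

    Defaults mirror the study design: a 13-level glycine series (0-50 mg/mL)
    in 3 biological serum replicates with 20 spectra per sample, i.e. 39
    samples and 780 spectra per instrument.
    """

    concentration_series: tuple[float, ...] = DEFAULT_CONCENTRATION_SERIES
    n_biological_replicates: int = 3
    n_spectra_per_sample: int = 20
    noise_sd: float = 1e-3            # AU, iid per point
    baseline_amplitude: float = 0.02  # AU, bound on the random polynomial baseline
    scatter_sd: float = 0.01          # per-spectrum multiplicative scatter
    replicate_effect_sd: float = 0.01  # per-donor matrix amplitude variation
    matrix_heterogeneity_sd: float = 0.05  # per-spectrum relative band-amplitude jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.concentration_series) == 0:
            raise InvalidInputError("concentration series must be non-empty")
        if any(c < 0 for c in self.concentration_series):
            raise InvalidInputError("concentrations must be non-negative")
        if self.n_biological_replicates < 1 or self.n_spectra_per_sample < 1:
            raise InvalidInputError("replicate and spectra counts must be >= 1")
        for name in ("noise_sd", "baseline_amplitude", "scatter_sd",
                     "replicate_effect_sd", "matrix_heterogeneity_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        object.__setattr__(
            self, "concentration_series", tuple(float(c) for c in self.concentration_series)
        )

    @property
    def n_samples(self) -> int:
        return len(self.concentration_series) * self.n_biological_replicates

    @property
    def n_spectra(self) -> int:
        return self.n_samples * self.n_spectra_per_sample


#: Reduced-noise study conditions used for robustness analyses (e.g. the
#: blind-set inclusion/exclusion comparison), where conclusions should not
#: be driven by measurement noise.
LOW_NOISE_CONFIG = SimulationConfig(
    noise_sd=2e-4,
    scatter_sd=0.005,
    replicate_effect_sd=0.005,
    matrix_heterogeneity_sd=0.01,
)


@dataclass
class SpectralBlock:
    """One instrument's spectra plus per-row sample metadata.

    ``intensities`` is (n_spectra, n_points) absorbance; ``sample_id``,
    ``replicate_id`` and ``concentration`` are per-row arrays shared (in the
    same order) by the paired block of the other modality.
    """

    modality: Modality
    axis_unit: Literal["nm", "inverse_cm"]
    axis: np.ndarray
    intensities: np.ndarray
    sample_id: np.ndarray
    replicate_id: np.ndarray
    concentration: np.ndarray
    is_preprocessed: bool = False

    def __post_init__(self) -> None:
        self.axis = _check_monotone(self.axis)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.replicate_id = np.asarray(self.replicate_id, dtype=int)
        self.concentration = np.asarray(self.concentration, dtype=float)
        n, p = self.intensities.shape
        if p != self.axis.size:
            raise InvalidInputError("intensity width must equal axis length")
        for name in ("sample_id", "replicate_id", "concentration"):
            if getattr(self, name).shape != (n,):
                raise InvalidInputError(f"{name} must have one entry per spectrum")
        if not np.all(np.isfinite(self.intensities)):
            raise InvalidInputError("intensities contain non-finite values")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    @property
    def axis_spacing(self) -> float:
        return float(self.axis[1] - self.axis[0])

    def row_metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "replicate_id": self.replicate_id,
                "concentration_mg_per_ml": self.concentration,
            }
        )

    def select_rows(self, mask: np.ndarray) -> "SpectralBlock":
        """Row-subset copy (boolean mask or index array)."""
        return SpectralBlock(
            modality=self.modality,
            axis_unit=self.axis_unit,
            axis=self.axis.copy(),
            intensities=self.intensities[mask],
            sample_id=self.sample_id[mask],
            replicate_id=self.replicate_id[mask],
            concentration=self.concentration[mask],
            is_preprocessed=self.is_preprocessed,
        )

    # -- wide CSV interchange -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        suffix = _UNIT_SUFFIX[self.axis_unit]
        cols = [f"{v:.10g}{suffix}" for v in self.axis]
        df = self.row_metadata()
        return pd.concat(
            [df, pd.DataFrame(self.intensities, columns=cols)], axis=1
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, modality: Modality) -> "SpectralBlock":
        meta_cols = ["sample_id", "replicate_id", "concentration_mg_per_ml"]
        missing = [c for c in meta_cols if c not in df.columns]
        if missing:
            raise InvalidInputError(f"missing metadata columns: {missing}")
        spec_cols = [c for c in df.columns if c not in meta_cols]
        pat = re.compile(r"^([0-9.eE+-]+)(nm|cm-1)$")
        values, units = [], set()
        for c in spec_cols:
            m = pat.match(c)
            if not m:
                raise InvalidInputError(f"cannot parse axis column label {c!r}")
            values.append(float(m.group(1)))
            units.add(m.group(2))
        if len(units) != 1:
            raise InvalidInputError("mixed axis units in one file")
        return cls(
            modality=modality,
            axis_unit=_SUFFIX_UNIT[units.pop()],
            axis=np.asarray(values),
            intensities=df[spec_cols].to_numpy(dtype=float),
            sample_id=df["sample_id"].to_numpy(dtype=object),
            replicate_id=df["replicate_id"].to_numpy(dtype=int),
            concentration=df["concentration_mg_per_ml"].to_numpy(dtype=float),
        )

    @classmethod
    def read_csv(cls, path, modality: Modality) -> "SpectralBlock":
        return cls.from_frame(pd.read_csv(path), modality)


def _polynomial_baseline(coeffs: np.ndarray, n_points: int) -> np.ndarray:
    """Quadratic baseline per spectrum, bounded by the coefficient scale.

    Basis: 1, t, (3t^2-1)/2 on t in [-1, 1] (Legendre, so terms are
    comparable in magnitude and the quadratic has zero mean).
    """
    t = np.linspace(-1.0, 1.0, n_points)
    basis = np.stack([np.ones_like(t), t, 0.5 * (3.0 * t**2 - 1.0)])
    return coeffs @ basis


def simulate_dataset(
    config: SimulationConfig,
    analyte: ComponentLibrary | None = None,
    matrix: ComponentLibrary | None = None,
) -> tuple[SpectralBlock, SpectralBlock]:
    """Simulate the paired (MIR, NIR) spiking dataset.

    Returns the two blocks with identical row metadata order: replicates are
    outermost, concentration levels inner, ``n_spectra_per_sample`` repeated
    scans innermost. Identical config (including seed) gives bit-identical
    output.
    """
    from . import libraries  # deferred: libraries imports BandModel from here

    analyte = libraries.GLYCINE if analyte is None else analyte
    matrix = libraries.SERUM_MATRIX if matrix is None else matrix
    if analyte.response_per_unit_conc <= 0:
        raise InvalidInputError("analyte response_per_unit_conc must be > 0")

    rng = np.random.default_rng(config.seed)

    # Row metadata: one sample per (donor replicate, concentration level).
    sample_ids, rep_ids, concs = [], [], []
    for rep in range(1, config.n_biological_replicates + 1):
        for lvl, c in enumerate(config.concentration_series):
            sid = f"rep{rep}_lvl{lvl:02d}"
            sample_ids += [sid] * config.n_spectra_per_sample
            rep_ids += [rep] * config.n_spectra_per_sample
            concs += [c] * config.n_spectra_per_sample
    sample_id = np.asarray(sample_ids, dtype=object)
    replicate_id = np.asarray(rep_ids, dtype=int)
    concentration = np.asarray(concs, dtype=float)
    n = concentration.size

    # Per-donor matrix amplitude offsets, shared by both modalities.
    delta = rng.normal(0.0, config.replicate_effect_sd,
                       config.n_biological_replicates)
    delta_row = delta[replicate_id - 1]

    blocks: list[SpectralBlock] = []
    for modality, axis_spec in (("MIR", MIR_AXIS), ("NIR", NIR_AXIS)):
        grid = axis_spec.grid()
        a_spec = component_spectrum(analyte, modality, grid)
        m_bands = np.stack(
            [evaluate_band(b, grid) for b in matrix.bands(modality)]
        )  # (n_bands, n_points)

        scatter = rng.normal(0.0, config.scatter_sd, n)
        # Per-spectrum, per-band matrix heterogeneity (dried-film deposits
        # are compositionally non-uniform between repeated scans).
        eta = rng.normal(
            0.0, config.matrix_heterogeneity_sd, (n, m_bands.shape[0])
        )
        base_coeffs = rng.uniform(-1.0, 1.0, (n, 3)) * config.baseline_amplitude
        noise = rng.normal(0.0, config.noise_sd, (n, grid.size))

        amp = (1.0 + delta_row + scatter)[:, None]
        m_rows = (1.0 + eta) @ m_bands  # per-spectrum matrix spectra
        signal = concentration[:, None] * analyte.response_per_unit_conc * a_spec
        x = amp * m_rows + signal
        x += _polynomial_baseline(base_coeffs, grid.size)
        x += noise
        np.clip(x, 0.0, None, out=x)

        blocks.append(
            SpectralBlock(
                modality=modality,
                axis_unit=axis_spec.unit,
                axis=grid,
                intensities=x,
                sample_id=sample_id.copy(),
                replicate_id=replicate_id.copy(),
                concentration=concentration.copy(),
            )
        )
    return blocks[0], blocks[1]
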