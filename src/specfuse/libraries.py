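"""Default component band libraries.

Glycine band positions follow the dried-deposit assignments used throughout
the analysis: MIR bands at 906 (CH2 rocking), 1036 (C-N stretch), 1111 (NH3
rocking), 1330 (CH2 wagging) and 1414 cm^-1 (O-C=O symmetric stretch), with
1330 and 906 cm^-1 the most intense; NIR combination bands at 2110, 2204 and
2375 nm. Relative amplitudes are not tabulated anywhere, so they are chosen
to respect that intensity ordering.

The serum matrix is a literature-typical dried-serum profile: amide I/II/III
and CH bends plus a broad amide A / O-H envelope in the MIR, protein
combination bands at 2055 and 2180 nm plus C-H overtone structure in the
NIR, and in each modality a very broad envelope that keeps absorbance
positive across the grid. Amplitudes are scaled so the matrix dominates the
analyte throughout the spiking series (~1 AU at amide I vs ~0.25 AU for the
strongest glycine band at the top 50 mg/mL level, and a >100-fold margin at
the physiologically relevant bottom of the series), reproducing the
high-dynamic-range masking problem the fusion approach targets. Glycine's
MIR fundamentals are kept weaker in peak absorbance than its NIR
combination bands appear on this instrument pairing, so the two blocks are
comparably informative, as observed for the single-block detection limits.
"""

from .synthetic import BandModel, ComponentLibrary

__all__ = ["GLYCINE", "SERUM_MATRIX"]


def _b(center: float, fwhm: float, amplitude: float) -> BandModel:
    return BandModel(center=center, fwhm=fwhm, amplitude=amplitude)


GLYCINE = ComponentLibrary(
    name="glycine",
    mir_bands=(
        _b(906.0, 18.0, 0.40),    # CH2 rocking
        _b(1036.0, 16.0, 0.22),   # C-N stretching
        _b(1111.0, 16.0, 0.20),   # NH3 rocking
        _b(1330.0, 18.0, 0.50),   # CH2 wagging (global maximum)
        _b(1414.0, 20.0, 0.28),   # O-C=O symmetric stretching
    ),
    nir_bands=(
        _b(2110.0, 55.0, 0.50),   # N-H + C-H combination
        _b(2204.0, 50.0, 0.45),   # C-H + C-H combination
        _b(2375.0, 60.0, 0.40),   # C-H + C-H combination
    ),
    response_per_unit_conc=0.01,  # AU per mg/mL at unit band amplitude
)


SERUM_MATRIX = ComponentLibrary(
    name="serum_matrix",
    mir_bands=(
        _b(1652.0, 70.0, 1.00),    # amide I
        _b(1545.0, 60.0, 0.65),    # amide II
        _b(1242.0, 70.0, 0.30),    # amide III
        _b(1452.0, 45.0, 0.25),    # CH2/CH3 bending
        _b(1080.0, 80.0, 0.20),    # carbohydrate / phosphate envelope
        _b(2930.0, 70.0, 0.25),    # C-H stretching
        _b(3290.0, 350.0, 0.55),   # amide A with residual O-H
        _b(2200.0, 2600.0, 0.15),  # broad positive envelope
    ),
    nir_bands=(
        _b(2055.0, 70.0, 0.80),    # N-H stretch / amide Ib combination
        _b(2180.0, 70.0, 0.65),    # N-H bend overtone / C=O combinations
        _b(2290.0, 80.0, 0.35),    # C-H combination
        _b(1730.0, 60.0, 0.20),    # C-H first overtone
        _b(1500.0, 110.0, 0.45),   # N-H / O-H first overtone
        _b(1940.0, 700.0, 0.30),   # broad positive envelope
    ),
    response_per_unit_conc=1.0,    # matrix enters at fixed (unit) level
)
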