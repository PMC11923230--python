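"""Deterministic floral phenotype derivations.

Pigment absorbance standardized by corolla mass, capillary column height to
nectar volume, and herkogamy (pistil minus stamen length).
"""

from __future__ import annotations

from dataclasses import dataclass

# Volume of the full 100 mm measurement capillary (internal diameter
# 1.15 mm), in microlitres, as printed on the manufacturer's conversion:
# pi * 0.575^2 * 100 = 103.869...; the printed constant rounds to 103.87.
CAPILLARY_FULL_VOLUME_UL = 103.87
CAPILLARY_LENGTH_MM = 100.0
CAPILLARY_RADIUS_MM = 0.575


@dataclass(frozen=True)
class PigmentMeasurement:
    """One spectrophotometric pigment reading for a line.

    pigment_class is "anthocyanin" (read at 525 nm) or "carotenoid"
    (450 nm). ``dilution_factor`` >= 1 tracks re-dilution of saturated
    samples; ``mean_corolla_mass`` is the line's mean fresh corolla mass in
    grams.
    """

    line: str
    pigment_class: str
    absorbance: float
    dilution_factor: float = 1.0
    mean_corolla_mass: float = 1.0

    def __post_init__(self) -> None:
        if self.pigment_class not in ("anthocyanin", "carotenoid"):
            raise ValueError(f"unknown pigment_class {self.pigment_class!r}")
        if self.absorbance < 0:
            raise ValueError("absorbance must be >= 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if not self.mean_corolla_mass > 0:
            raise ValueError("mean_corolla_mass must be > 0 g")


def standardize_pigment(m: PigmentMeasurement) -> float:
    """Absorbance standardized by corolla mass (AU per gram).

    absorbance * dilution_factor / mean_corolla_mass; linear in absorbance,
    invariant to halving absorbance while doubling dilution.
    """
    return m.absorbance * m.dilution_factor / m.mean_corolla_mass


def nectar_volume(height_mm: float) -> float:
    """Nectar volume (uL) from column height in a 1.15 mm i.d. capillary.

    volume = (h / 100) * 103.87, i.e. the cylinder formula pi r^2 h with
    r = 0.575 mm and the full-capillary constant as printed.
    """
    if not 0.0 <= height_mm <= CAPILLARY_LENGTH_MM:
        raise ValueError(f"height must lie in [0, {CAPILLARY_LENGTH_MM}] mm, got {height_mm!r}")
    return height_mm / CAPILLARY_LENGTH_MM * CAPILLARY_FULL_VOLUME_UL


def herkogamy(pistil_length_mm: float, stamen_length_mm: float) -> float:
    """Anther-stigma separation: pistil length minus stamen length (mm).

    Negative when the stamens overtop the pistil; the sign is preserved.
    """
    if pistil_length_mm < 0 or stamen_length_mm < 0:
        raise ValueError("lengths must be >= 0")
    return pistil_length_mm - stamen_length_mm
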