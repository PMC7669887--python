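"""Blood-panel traits: [Hb] from Drabkin's assay, Hct averaging, MCHC, pH correction.

Haemoglobin is assayed as cyanmethemoglobin: whole blood diluted into
Drabkin's reagent, absorbance read at 540 nm, and concentration recovered
through Beer-Lambert with a millimolar (heme-basis) extinction coefficient
of 11 mmol^-1 L cm^-1.  Haematocrit is spun in duplicate and averaged.
MCHC is the ratio [Hb]/Hct.  Measured blood pH may be passed through a
pluggable affine temperature correction (identity unless configured).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean

import numpy as np

__all__ = [
    "BloodPanel",
    "AffinePhCorrection",
    "hb_from_absorbance",
    "mchc",
    "correct_ph",
]

DEFAULT_EXTINCTION = 11.0  # mmol^-1 L cm^-1, cyanmethemoglobin at 540 nm
DEFAULT_DILUTION = 201.0  # 5 uL blood + 1000 uL reagent
DEFAULT_PATH_LENGTH = 0.56  # cm; 200 uL in a flat-bottom 96-well


@dataclass
class AffinePhCorrection:
    """pH_corrected = ph + slope * (temperature - reference_temperature).

    Stands in for species-specific electrode temperature-correction
    equations; the default (slope 0) is the identity.
    """

    slope: float = 0.0  # pH units per degC
    reference_temperature: float = 25.0

    def __call__(self, ph: float, temperature: float) -> float:
        return ph + self.slope * (temperature - self.reference_temperature)

    def invert(self, ph_corrected: float, temperature: float) -> float:
        return ph_corrected - self.slope * (temperature - self.reference_temperature)


@dataclass
class BloodPanel:
    """One shark's acid-base / haematology panel."""

    shark_id: str
    ph_measured: float
    lactate: float  # mmol L-1
    hct_replicates: tuple[float, ...]  # fractions, duplicate spins
    a540_replicates: tuple[float, ...]  # triplicate absorbances
    dilution: float = DEFAULT_DILUTION
    path_length: float = DEFAULT_PATH_LENGTH
    temperature: float = 25.0
    ph_corrected: float | None = None

    def __post_init__(self) -> None:
        if self.lactate < 0:
            raise ValueError("lactate cannot be negative")
        for h in self.hct_replicates:
            if not 0 < h < 1:
                raise ValueError(f"haematocrit fraction {h} outside (0, 1)")

    @property
    def hct(self) -> float:
        return mean(self.hct_replicates)

    @property
    def hb(self) -> float:
        return hb_from_absorbance(
            self.a540_replicates, self.dilution, self.path_length
        )[0]

    @property
    def mchc(self) -> float:
        return mchc(self.hb, self.hct)


def hb_from_absorbance(
    a540_replicates,
    dilution: float = DEFAULT_DILUTION,
    path_length: float = DEFAULT_PATH_LENGTH,
    extinction: float = DEFAULT_EXTINCTION,
) -> tuple[float, float]:
    """([Hb] mmol L-1, replicate CV %) from A540 replicates.

    [Hb] = mean(A540) / (extinction * path_length) * dilution.
    """
    a = np.asarray(a540_replicates, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one absorbance replicate")
    if np.any(a < 0):
        raise ValueError("negative absorbance")
    if path_length <= 0 or extinction <= 0:
        raise ValueError("path length and extinction must be positive")
    hb = float(a.mean() / (extinction * path_length) * dilution)
    cv = float(a.std(ddof=1) / a.mean() * 100.0) if a.size > 1 and a.mean() > 0 else 0.0
    return hb, cv


def mchc(hb: float, hct: float) -> float:
    """Mean corpuscular haemoglobin concentration, [Hb]/Hct (mmol L-1)."""
    if hct <= 0:
        raise ValueError("haematocrit must be positive to form MCHC")
    if hb < 0:
        raise ValueError("[Hb] cannot be negative")
    return hb / hct


def correct_ph(
    ph_measured: float,
    temperature: float,
    correction: AffinePhCorrection | None = None,
) -> float:
    """Apply the configured affine pH temperature correction (identity if none)."""
    if correction is None:
        return ph_measured
    return correction(ph_measured, temperature)
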