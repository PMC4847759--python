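"""Allometric scaling of shaking frequencies with body mass.

Across species, the frequencies of shivering and of shaking dry follow
negative power laws in body mass.  On log10 axes:

    shivering:    log10(f) = 1.335 - 1.86  * log10(M)
    shaking dry:  log10(f) = 1.063 - 0.215 * log10(M)

with M in kilograms (the convention under which multi-kilogram birds land
in the observed few-Hz band for shaking dry).  Display behaviors can be
classified by where their frequency sits relative to a law's prediction
band at the animal's mass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "ScalingLaw",
    "SHIVERING",
    "SHAKING_DRY",
    "predict_frequency",
    "mass_from_frequency",
    "classify_behavior",
    "correct_train_length",
    "GROWTH_RATE_CM_PER_DAY",
]

GROWTH_RATE_CM_PER_DAY = 0.41


@dataclass(frozen=True)
class ScalingLaw:
    """log10-linear frequency-mass relation with an optional CI band.

    ``ci_band`` is the half-width of the 95% band in log10(frequency)
    units, assumed constant over the plotted mass range (the published
    bands are not parameterized; supply a fitted half-width to enable the
    'within' classification).
    """

    name: str
    intercept: float  # log10 Hz at unit mass
    slope: float  # per log10 mass
    mass_unit: str = "kg"
    ci_band: float | None = None

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("shaking-frequency laws have negative slope")
        if self.ci_band is not None and self.ci_band <= 0:
            raise ValueError("ci_band half-width must be positive")


SHIVERING = ScalingLaw("shivering", intercept=1.335, slope=-1.86)
SHAKING_DRY = ScalingLaw("shaking_dry", intercept=1.063, slope=-0.215)


def predict_frequency(law: ScalingLaw, mass: float) -> float:
    """Predicted shaking frequency (Hz) at ``mass`` (law's declared unit)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return 10.0 ** (law.intercept + law.slope * math.log10(mass))


def mass_from_frequency(law: ScalingLaw, frequency: float) -> float:
    """Inverse of :func:`predict_frequency`."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    return 10.0 ** ((math.log10(frequency) - law.intercept) / law.slope)


def classify_behavior(frequency: float, mass: float, law: ScalingLaw) -> str:
    """Position of an observed behavior relative to a scaling law.

    Returns ``"above"``, ``"within"`` or ``"below"`` the law's 95% band at
    the given mass.  Without a band the comparison degrades to a binary
    above/below against the central prediction (with a warning); a
    frequency exactly on the line classifies as ``"within"``.
    """
    if frequency <= 0 or mass <= 0:
        raise ValueError("frequency and mass must be positive")
    center = law.intercept + law.slope * math.log10(mass)
    logf = math.log10(frequency)
    if law.ci_band is None:
        if logf == center:
            return "within"
        warnings.warn(
            f"scaling law '{law.name}' has no CI band; "
            "classification is binary above/below",
            stacklevel=2,
        )
        return "above" if logf > center else "below"
    if logf > center + law.ci_band:
        return "above"
    if logf < center - law.ci_band:
        return "below"
    return "within"


def correct_train_length(measured_length_cm: float, elapsed_days: float) -> float:
    """Correct a train-length measurement for feather growth.

    Train feathers grow ~0.41 cm/day during the display season; positive
    ``elapsed_days`` projects the measurement forward to the observation
    date, negative backward.
    """
    corrected = measured_length_cm + GROWTH_RATE_CM_PER_DAY * elapsed_days
    if corrected <= 0:
        raise ValueError("corrected train length is non-positive")
    return corrected
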