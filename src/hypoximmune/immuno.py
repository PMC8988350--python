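"""Fc-gamma-receptor immunophenotyping arithmetic.

Implements isotype-corrected geometric MFIs, the activating:inhibitory (A:I)
FcgR ratio (sum of activating geometric MFIs over the inhibitory FcgRIIb
geometric MFI) and Western-blot fold changes normalised to a loading control.
MFIs are treated as abstract positive reals; units cancel in every ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, NamedTuple, Sequence

__all__ = [
    "MarkerMeasurement",
    "FcgrPanel",
    "WesternQuant",
    "CorrectedMFI",
    "UndefinedRatioError",
    "background_correct",
    "ai_ratio",
    "normalized_fold_change",
    "geometric_mean",
]

ACTIVATING_MARKERS = ("FcgRI", "FcgRIIa", "FcgRIIIa")
INHIBITORY_MARKER = "FcgRIIb"


class UndefinedRatioError(ArithmeticError):
    """The inhibitory MFI is non-positive after correction; the A:I ratio is
    undefined (never reported as infinity)."""


@dataclass(frozen=True)
class MarkerMeasurement:
    """One marker's geometric MFI with its isotype-control geometric MFI."""

    marker: str
    geomean: float
    isotype_geomean: float = 0.0

    def __post_init__(self):
        if self.geomean <= 0:
            raise ValueError(f"{self.marker}: geomean must be positive, got {self.geomean}")
        if self.isotype_geomean < 0:
            raise ValueError(
                f"{self.marker}: isotype geomean must be non-negative, got {self.isotype_geomean}"
            )


@dataclass(frozen=True)
class FcgrPanel:
    """Activating-receptor measurements plus the single inhibitory FcgRIIb."""

    activating: Sequence[MarkerMeasurement]
    inhibitory: MarkerMeasurement
    subject_id: str = ""

    def __post_init__(self):
        if not self.activating:
            raise ValueError("activating marker list must be non-empty")
        object.__setattr__(self, "activating", tuple(self.activating))


@dataclass(frozen=True)
class WesternQuant:
    """Densitometry of a target band and its loading-control band."""

    target_signal: float
    loading_signal: float
    condition: str = ""

    def __post_init__(self):
        if self.target_signal <= 0 or self.loading_signal <= 0:
            raise ValueError("densitometry signals must be positive")


class CorrectedMFI(NamedTuple):
    value: float
    clamped: bool


def background_correct(m: MarkerMeasurement, clamp: bool = True) -> CorrectedMFI:
    """geomean minus its isotype-control geomean.

    A negative difference is clamped to 0 (flagged) by default; with
    ``clamp=False`` the raw, possibly negative, difference is returned.
    """
    diff = m.geomean - m.isotype_geomean
    if clamp and diff < 0:
        return CorrectedMFI(0.0, True)
    return CorrectedMFI(diff, False)


def ai_ratio(panel: FcgrPanel, corrected: bool = True) -> float:
    """Sum of activating geometric MFIs divided by the inhibitory geometric MFI.

    With ``corrected=True`` (default) every value is isotype-corrected first
    (negative differences clamp to 0). An inhibitory value <= 0 after
    correction raises :class:`UndefinedRatioError`.
    """
    if corrected:
        numerator = sum(background_correct(m).value for m in panel.activating)
        denominator = background_correct(panel.inhibitory).value
    else:
        numerator = sum(m.geomean for m in panel.activating)
        denominator = panel.inhibitory.geomean
    if denominator <= 0:
        raise UndefinedRatioError(
            f"inhibitory MFI {denominator} is non-positive; A:I ratio undefined"
            + (f" (subject {panel.subject_id})" if panel.subject_id else "")
        )
    return numerator / denominator


def normalized_fold_change(sample: WesternQuant, reference: WesternQuant) -> float:
    """(sample target / sample loading) over (reference target / reference loading)."""
    return (sample.target_signal / sample.loading_signal) / (
        reference.target_signal / reference.loading_signal
    )


def geometric_mean(values: Sequence[float]) -> float:
    """exp(mean(log values)); all values must be positive."""
    vals: List[float] = list(values)
    if not vals:
        raise ValueError("geometric mean of an empty sequence is undefined")
    if any(v <= 0 for v in vals):
        raise ValueError("geometric mean requires strictly positive values")
    return math.exp(sum(math.log(v) for v in vals) / len(vals))
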