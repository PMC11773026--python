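"""FH1-delivery fraction deconvolution from filament fluorescence.

A formin elongating a filament can add subunits by two routes: direct
binding of a monomer to the FH2-bound barbed end, or FH1-mediated delivery
of profilin-bound actin.  Because labeled actin binds profilin ~10x more
weakly than unlabeled actin, FH1-delivered stretches are depleted of label
and appear dim.  Comparing the fluorescence of the formin-assembled
segment with a control segment of the same filament (grown after the
formin dissociated) therefore reports the delivered fraction:

    fh1_black = 1 - F_formin/F_control          (unlabeled subunits)
    fh1_green = fh1_black * [PA_green]/[PA_black]  (labeled subunits)
    fh1_total = fh1_black + fh1_green

Measurement noise can push the normalized fluorescence above 1 or the
total fraction above 1; such values are clamped into [0, 1] with a logged
warning and the raw value is kept for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Iterable, Sequence

__all__ = [
    "FluorescenceMeasurement",
    "FH1Fraction",
    "normalized_fluorescence",
    "fh1_fraction_black",
    "fh1_fraction_total",
    "summarize_fractions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FluorescenceMeasurement:
    """Background-subtracted segment intensities for one filament (a.u.)."""

    formin_segment_intensity: float
    control_segment_intensity: float

    def __post_init__(self) -> None:
        if self.formin_segment_intensity <= 0 or self.control_segment_intensity <= 0:
            raise ValueError("segment intensities must be > 0")


@dataclass(frozen=True)
class FH1Fraction:
    """Fractions of polymerized subunits incorporated via FH1-mediated delivery.

    ``raw_normalized`` preserves the uncorrected fluorescence ratio and
    ``clamped`` flags whether any component was clipped into [0, 1].
    """

    fh1_black: float
    fh1_green: float
    fh1_total: float
    raw_normalized: float
    clamped: bool = False


def normalized_fluorescence(m: FluorescenceMeasurement) -> float:
    """Formin-segment intensity relative to the control segment."""
    return m.formin_segment_intensity / m.control_segment_intensity


def fh1_fraction_black(normalized: float) -> float:
    """Fraction of unlabeled subunits delivered by the FH1 domain, 1 − F.

    Values of ``normalized`` above 1 (brighter than control, i.e. noise)
    clamp the fraction to 0 with a warning.
    """
    if normalized < 0:
        raise ValueError(f"normalized fluorescence must be >= 0, got {normalized}")
    black = 1.0 - normalized
    if black < 0.0:
        logger.warning(
            "normalized fluorescence %.4f > 1; clamping FH1_black to 0", normalized
        )
        return 0.0
    return black


def fh1_fraction_total(normalized: float, pa_label_ratio: float) -> FH1Fraction:
    """Total FH1-delivered fraction from the fluorescence ratio.

    The labeled contribution is the unlabeled one scaled by the
    labeled/unlabeled profilin–actin ratio of the reaction; the total is
    their sum.  If the sum exceeds 1 (noise), both components are rescaled
    proportionally so the sum identity is preserved, with a warning.
    """
    if pa_label_ratio < 0:
        raise ValueError(f"pa_label_ratio must be >= 0, got {pa_label_ratio}")
    black = fh1_fraction_black(normalized)
    clamped = black == 0.0 and normalized > 1.0
    green = black * pa_label_ratio
    total = black + green
    if total > 1.0:
        logger.warning(
            "FH1 total fraction %.4f > 1; rescaling components into [0, 1]", total
        )
        black, green, total, clamped = black / total, green / total, 1.0, True
    return FH1Fraction(
        fh1_black=black,
        fh1_green=green,
        fh1_total=total,
        raw_normalized=normalized,
        clamped=clamped,
    )


def summarize_fractions(fractions: Iterable[FH1Fraction] | Sequence[float]) -> dict:
    """Per-condition mean and SD of the total FH1-delivered fraction."""
    values = [f.fh1_total if isinstance(f, FH1Fraction) else float(f) for f in fractions]
    if not values:
        raise ValueError("no fractions to summarize")
    return {
        "n": len(values),
        "mean_fh1_total": mean(values),
        "sd_fh1_total": stdev(values) if len(values) > 1 else None,
    }
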