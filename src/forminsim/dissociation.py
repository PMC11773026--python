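"""Piecewise-linear dependence of formin dissociation on FH1-delivered fraction.

Measured Bni1p dissociation rates are flat at a basal value while fewer
than two-thirds of polymerized subunits arrive via FH1-mediated delivery,
and rise linearly with the delivered fraction beyond that threshold:

    k_off(f) = k_basal                          f <= threshold
             = k_basal + slope·(f − threshold)  f >  threshold

with published values k_basal ≈ 0.0039 s⁻¹ (FH1FH2-C basal average),
slope 0.02 s⁻¹ per unit fraction, threshold 2/3.  The threshold matches
the point where two consecutive FH1 deliveries (probability f²) become
as likely as not, suggesting that stepping onto a second delivered
subunit is the destabilizing event.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "DissociationModel",
    "predict_koff",
    "fit_piecewise",
    "relative_rate_increase",
    "consecutive_delivery_probability",
]

TWO_THIRDS = float(Fraction(2, 3))


@dataclass(frozen=True)
class DissociationModel:
    """Piecewise k_off(f) model: basal rate, slope, and breakpoint.

    ``threshold`` defaults to the exact rational 2/3; pass 0.67 to replay
    the rounded figure-legend arithmetic.
    """

    k_basal: float = 0.0039
    slope: float = 0.02
    threshold: float = TWO_THIRDS

    def __post_init__(self) -> None:
        if self.k_basal <= 0:
            raise ValueError("k_basal must be > 0")
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    @classmethod
    def bni1_default(cls, literal_threshold: bool = False) -> "DissociationModel":
        """Published Bni1p parameterization (0.0039 s⁻¹ basal, 0.02 slope)."""
        return cls(k_basal=0.0039, slope=0.02, threshold=0.67 if literal_threshold else TWO_THIRDS)


def predict_koff(f_fh1, model: DissociationModel):
    """Dissociation rate (s⁻¹) at FH1-delivered fraction ``f_fh1``.

    Continuous at the threshold by construction; accepts scalars or arrays.
    """
    f = np.asarray(f_fh1, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("FH1 fraction must be within [0, 1]")
    k = model.k_basal + model.slope * np.maximum(f - model.threshold, 0.0)
    return float(k) if np.isscalar(f_fh1) else k


def fit_piecewise(
    points: Sequence[tuple[float, float]], threshold: float = TWO_THIRDS
) -> DissociationModel:
    """Fit the piecewise model with the breakpoint held fixed.

    The slope comes from unconstrained ordinary least squares on the
    points above the threshold (mirroring the linear fit applied to the
    measured rates in the delivery-dominated regime); the basal rate is
    the mean of the points at or below it.  Requires >= 2 points above and
    >= 1 at/below the threshold.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (f_fh1, k_off) pairs")
    f, k = pts[:, 0], pts[:, 1]
    upper = f > threshold
    lower = ~upper
    if upper.sum() < 2:
        raise ValueError(
            f"need >= 2 points above threshold {threshold:.4g} to fit a slope, "
            f"have {int(upper.sum())}"
        )
    if lower.sum() < 1:
        raise ValueError(
            f"need >= 1 point at or below threshold {threshold:.4g} for the basal rate"
        )
    slope, _intercept = np.polyfit(f[upper], k[upper], 1)
    k_basal = float(np.mean(k[lower]))
    return DissociationModel(k_basal=k_basal, slope=float(slope), threshold=threshold)


def relative_rate_increase(model: DissociationModel, f0: float, delta_f: float) -> float:
    """Percent change in k_off when the delivered fraction rises f0 → f0+Δf."""
    k0 = predict_koff(f0, model)
    k1 = predict_koff(f0 + delta_f, model)
    return 100.0 * (k1 - k0) / k0


def consecutive_delivery_probability(f_fh1: float, n_consecutive: int = 2) -> float:
    """Probability that ``n_consecutive`` successive subunits are FH1-delivered.

    Deliveries are independent with per-subunit probability ``f_fh1``, so
    the probability of a run of n is f^n; at f = 0.67 two consecutive
    deliveries occur with probability ≈ 0.449, just under one-half.
    """
    if not 0.0 <= f_fh1 <= 1.0:
        raise ValueError("FH1 fraction must be within [0, 1]")
    if n_consecutive < 1:
        raise ValueError("n_consecutive must be >= 1")
    return f_fh1**n_consecutive
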