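"""Run-length/lifetime survival analysis and hazard–probability conversions.

A processive formin tracks the growing barbed end for an exponentially
distributed number of subunit additions.  The population of measured run
lengths (or run times) is summarized as an empirical survival curve —
the fraction of filaments whose formin remained bound beyond a given
length or time — and fitted with a single exponential A·exp(−k·x).  The
fitted hazard is the dissociation rate: per second in the time domain,
per FH2 step in the length domain.  Rates convert to the per-increment
dissociation probabilities used by the stochastic simulator via
p = 1 − exp(−k·Δ).

Conventions: 370 subunits per micrometre of filament; run time =
run length (subunits) / elongation rate (subunits/s).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SUBUNITS_PER_UM",
    "FilamentRecord",
    "SurvivalCurve",
    "SurvivalFitResult",
    "StepProbability",
    "run_time_from_length",
    "subunits_from_um",
    "um_from_subunits",
    "build_survival_curve",
    "fit_survival_exponential",
    "fit_exponential_mle",
    "p_off_step_from_rate",
    "p_off_time_from_rate",
    "rate_from_p_off",
    "k_step_from_k_time",
    "step_probabilities",
]

logger = logging.getLogger(__name__)

#: subunits per micrometre of actin filament
SUBUNITS_PER_UM = 370.0

Domain = Literal["length", "time"]


@dataclass
class FilamentRecord:
    """One filament's formin run, as measured or simulated.

    ``censored`` marks filaments whose formin was still bound when the
    observation (or simulation) ended, so the run length is a lower bound.
    """

    run_length_subunits: float
    elongation_rate: float
    run_time: Optional[float] = None
    censored: bool = False
    condition_id: str = ""
    run_length_um: Optional[float] = None
    formin_intensity: Optional[float] = None
    control_intensity: Optional[float] = None
    nucleation_time: float = 0.0

    def __post_init__(self) -> None:
        if self.run_length_subunits < 0:
            raise ValueError("run_length_subunits must be >= 0")
        if self.elongation_rate <= 0:
            raise ValueError("elongation_rate must be > 0")
        if self.run_time is None:
            self.run_time = run_time_from_length(self.run_length_subunits, self.elongation_rate)
        if self.run_length_um is None:
            self.run_length_um = um_from_subunits(self.run_length_subunits)


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical survivor function S(x) = fraction of runs >= x."""

    domain: Domain
    values: np.ndarray  # strictly increasing
    fractions: np.ndarray  # non-increasing, starts at 1
    n_observations: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "fractions", np.asarray(self.fractions, dtype=float))


@dataclass(frozen=True)
class SurvivalFitResult:
    """Single-exponential fit A·exp(−rate·x) of a survival curve.

    ``rate`` is the hazard (per subunit for length-domain curves, per
    second for time-domain curves) and ``mean`` = 1/rate is the mean run
    length or lifetime.  ``ci95_rate`` is the large-sample interval
    rate·(1 ± 1.96/√n): the regression covariance of correlated survival
    points badly understates the sampling error, so the information-bound
    interval is reported instead (raw covariance kept in ``covariance``).
    """

    rate: float
    mean: float
    amplitude: float
    ci95_rate: tuple[float, float]
    n_used: int
    omitted_first_point: bool
    domain: Domain
    covariance: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class StepProbability:
    """Per-time and per-step dissociation probabilities for one condition."""

    k_off_time: float
    k_off_step: float
    dt: float
    p_off_time: float
    p_off_step: float


def run_time_from_length(subunits: float, elongation_rate: float) -> float:
    """Run time (s) = number of steps (subunits) / elongation rate (subunits/s)."""
    if elongation_rate <= 0:
        raise ValueError(f"elongation_rate must be > 0, got {elongation_rate}")
    if subunits < 0:
        raise ValueError("subunits must be >= 0")
    return subunits / elongation_rate


def subunits_from_um(length_um: float) -> float:
    """Convert filament length in micrometres to subunit count (x370)."""
    if length_um < 0:
        raise ValueError("length must be >= 0")
    return length_um * SUBUNITS_PER_UM


def um_from_subunits(subunits: float) -> float:
    """Convert subunit count to filament length in micrometres."""
    if subunits < 0:
        raise ValueError("subunits must be >= 0")
    return subunits / SUBUNITS_PER_UM


def _uncensored_values(records: Sequence[FilamentRecord], domain: Domain) -> np.ndarray:
    censored = sum(r.censored for r in records)
    if censored:
        logger.info("excluding %d censored record(s) from survival curve", censored)
    if domain == "length":
        vals = [r.run_length_subunits for r in records if not r.censored]
    elif domain == "time":
        vals = [r.run_time for r in records if not r.censored]
    else:
        raise ValueError(f"domain must be 'length' or 'time', got {domain!r}")
    return np.asarray(vals, dtype=float)


def build_survival_curve(
    records: Sequence[FilamentRecord] | np.ndarray, domain: Domain = "time"
) -> SurvivalCurve:
    """Empirical survival curve from uncensored run measurements.

    Accepts either :class:`FilamentRecord` sequences (censored records are
    excluded with a logged count) or a bare array of values.  At each
    distinct value v the curve reports the fraction of observations >= v,
    so the first point is always (min value, 1.0).
    """
    if len(records) and isinstance(records[0], FilamentRecord):
        vals = _uncensored_values(records, domain)
    else:
        vals = np.asarray(records, dtype=float)
    if vals.size < 2:
        raise ValueError(
            f"need >= 2 uncensored records to build a survival curve, got {vals.size}"
        )
    vals = np.sort(vals)
    uniq, first_idx = np.unique(vals, return_index=True)
    fractions = 1.0 - first_idx / vals.size
    return SurvivalCurve(domain=domain, values=uniq, fractions=fractions, n_observations=vals.size)


def fit_survival_exponential(
    curve: SurvivalCurve, omit_first: Optional[bool] = None
) -> SurvivalFitResult:
    """Fit A·exp(−rate·x) to a survival curve by unweighted least squares.

    The amplitude is free: under-detection of short runs makes the
    empirical curve start below its true origin, which an amplitude-free
    fit absorbs (fitted y-intercepts above 1 are expected in that case).
    ``omit_first`` drops the first curve point before fitting; the default
    is True in the length domain (short dim stretches are systematically
    under-represented in the measurements) and False in the time domain.
    """
    if omit_first is None:
        omit_first = curve.domain == "length"
    x = curve.values[1:] if omit_first else curve.values
    y = curve.fractions[1:] if omit_first else curve.fractions
    if x.size < 4:
        raise ValueError(f"need >= 4 points to fit, have {x.size} after omission")

    # crude rate guess from the mean of the underlying sample
    scale = float(np.sum(x * -np.diff(np.append(y, 0.0))) / y[0])
    k0 = 1.0 / scale if scale > 0 else 1.0

    def model(t, amplitude, rate):
        return amplitude * np.exp(-rate * t)

    try:
        popt, pcov = curve_fit(
            model, x, y, p0=[1.0, k0], bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological curves
        raise RuntimeError(
            f"single-exponential fit failed for {curve.domain}-domain curve "
            f"(n={curve.n_observations}): {exc}"
        ) from exc
    amplitude, rate = popt
    if rate <= 0:
        raise RuntimeError("fit returned non-positive rate; curve is degenerate")
    half_width = 1.96 * rate / math.sqrt(curve.n_observations)
    return SurvivalFitResult(
        rate=rate,
        mean=1.0 / rate,
        amplitude=amplitude,
        ci95_rate=(rate - half_width, rate + half_width),
        n_used=curve.n_observations,
        omitted_first_point=omit_first,
        domain=curve.domain,
        covariance=pcov,
    )


def fit_exponential_mle(
    records: Sequence[FilamentRecord], domain: Domain = "time"
) -> SurvivalFitResult:
    """Censoring-aware maximum-likelihood exponential fit.

    The MLE of a constant hazard with right censoring is
    (number of dissociation events) / (total observed run time or length,
    censored records included).  Unbiased under any censoring schedule, so
    it is the preferred estimator for simulator output with many censored
    filaments; the survival-curve fit remains the default to mirror the
    experimental analysis.
    """
    if domain == "length":
        exposures = np.array([r.run_length_subunits for r in records], dtype=float)
    elif domain == "time":
        exposures = np.array([r.run_time for r in records], dtype=float)
    else:
        raise ValueError(f"domain must be 'length' or 'time', got {domain!r}")
    events = np.array([not r.censored for r in records], dtype=bool)
    n_events = int(events.sum())
    total = float(exposures.sum())
    if n_events < 1 or total <= 0:
        raise ValueError("need at least one dissociation event with positive exposure")
    rate = n_events / total
    half_width = 1.96 * rate / math.sqrt(n_events)
    return SurvivalFitResult(
        rate=rate,
        mean=1.0 / rate,
        amplitude=1.0,
        ci95_rate=(rate - half_width, rate + half_width),
        n_used=len(records),
        omitted_first_point=False,
        domain=domain,
    )


def p_off_step_from_rate(k_off_step: float) -> float:
    """Dissociation probability per FH2 step: 1 − exp(−k_off_step · 1 step)."""
    if k_off_step < 0:
        raise ValueError(f"k_off_step must be >= 0, got {k_off_step}")
    return -math.expm1(-k_off_step)


def p_off_time_from_rate(k_off_time: float, dt: float = 0.01) -> float:
    """Dissociation probability per time increment: 1 − exp(−k_off_time·Δt)."""
    if k_off_time < 0:
        raise ValueError(f"k_off_time must be >= 0, got {k_off_time}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return -math.expm1(-k_off_time * dt)


def rate_from_p_off(p_off: float, delta: float = 1.0) -> float:
    """Inverse of the probability conversions: k = −ln(1 − p)/Δ."""
    if not 0.0 <= p_off < 1.0:
        raise ValueError(f"p_off must be in [0, 1), got {p_off}")
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    return -math.log1p(-p_off) / delta


def k_step_from_k_time(k_off_time: float, elongation_rate: float) -> float:
    """Per-step dissociation rate from the per-second rate and elongation rate."""
    if elongation_rate <= 0:
        raise ValueError(f"elongation_rate must be > 0, got {elongation_rate}")
    if k_off_time < 0:
        raise ValueError(f"k_off_time must be >= 0, got {k_off_time}")
    return k_off_time / elongation_rate


def step_probabilities(
    k_off_time: float, elongation_rate: float, dt: float = 0.01
) -> StepProbability:
    """Bundle the per-time and per-step rates and probabilities for a condition."""
    k_step = k_step_from_k_time(k_off_time, elongation_rate)
    return StepProbability(
        k_off_time=k_off_time,
        k_off_step=k_step,
        dt=dt,
        p_off_time=p_off_time_from_rate(k_off_time, dt),
        p_off_step=p_off_step_from_rate(k_step),
    )
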