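"""Profilin–actin binding equilibria for two-color polymerization reactions.

Polymerization reactions mix unlabeled and fluorescently labeled actin
monomers that compete for a single pool of profilin.  Labeling the monomer
weakens the profilin interaction roughly ten-fold (Kd 2.9 vs 29 uM for
S. cerevisiae profilin; 0.1 vs 1.0 uM for human profilin-1), so the
labeled fraction of the profilin-bound pool differs from the labeled
fraction of total actin.  The functions here compute the per-species
profilin–actin (PA) concentrations either with the simple isotherms used
in the original analysis or by solving the coupled conservation system
for a shared free-profilin pool.

All concentrations are in uM; no unit conversion is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "ReactionCondition",
    "EquilibriumState",
    "pa_weak_binding",
    "pa_quadratic",
    "solve_shared_profilin",
    "solve_independent_species",
    "pa_label_ratio",
    "SC_KD",
    "HS_KD",
    "ACTIN_SPLITS",
    "condition_preset",
]

#: (kd_unlabeled, kd_labeled) in uM for S. cerevisiae profilin binding actin
SC_KD = (2.9, 29.0)
#: (kd_unlabeled, kd_labeled) in uM for human profilin-1 binding actin
HS_KD = (0.1, 1.0)
#: total actin (uM) -> (unlabeled, labeled) split at 33% labeling
ACTIN_SPLITS = {0.75: (0.5, 0.25), 1.0: (0.67, 0.33)}


@dataclass(frozen=True)
class ReactionCondition:
    """Concentrations and affinities defining one polymerization reaction."""

    actin_unlabeled: float
    actin_labeled: float
    profilin_total: float
    kd_unlabeled: float
    kd_labeled: float
    profilin_isoform: str = "Sc"
    formin_construct: str = "FH1FH2"

    def __post_init__(self) -> None:
        for name in ("actin_unlabeled", "actin_labeled", "profilin_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("kd_unlabeled", "kd_labeled"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def actin_total(self) -> float:
        return self.actin_unlabeled + self.actin_labeled


@dataclass(frozen=True)
class EquilibriumState:
    """Profilin–actin complex concentrations at equilibrium (uM)."""

    pa_unlabeled: float
    pa_labeled: float
    pa_total: float
    profilin_free: float


def pa_weak_binding(actin: float, profilin_free: float, kd: float) -> float:
    """Profilin–actin concentration from the hyperbolic binding isotherm.

    PA = [A]·[P_free] / (Kd + [P_free]).  With [A] the *total* actin of the
    species this is the exact single-species mass-action solution at a given
    free-profilin concentration, since free actin = [A] − PA.

    Parameters are uM; returns uM in [0, actin).
    """
    if actin < 0 or profilin_free < 0:
        raise ValueError("concentrations must be non-negative")
    if kd <= 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    if profilin_free == 0.0:
        return 0.0
    return actin * profilin_free / (kd + profilin_free)


def pa_quadratic(actin: float, profilin_total: float, kd: float) -> float:
    """Profilin–actin concentration from the tight-binding quadratic.

    Smaller root of PA^2 − (A + P_total + Kd)·PA + A·P_total = 0, the exact
    solution when ligand depletion matters (Kd comparable to or below the
    reactant concentrations).  Evaluated in the numerically stable form
    2·A·P / (b + sqrt(b^2 − 4·A·P)) to avoid cancellation at weak binding.
    """
    if actin < 0 or profilin_total < 0:
        raise ValueError("concentrations must be non-negative")
    if kd <= 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    if actin == 0.0 or profilin_total == 0.0:
        return 0.0
    b = actin + profilin_total + kd
    disc = b * b - 4.0 * actin * profilin_total
    if disc < 0:  # impossible for valid inputs; guards float pathologies
        raise ArithmeticError("negative discriminant in binding quadratic")
    return 2.0 * actin * profilin_total / (b + math.sqrt(disc))


def solve_shared_profilin(condition: ReactionCondition, tol: float = 1e-10) -> EquilibriumState:
    """Solve the coupled two-species equilibrium for one shared profilin pool.

    Finds the free-profilin concentration P satisfying

        P + A_u·P/(Kd_u + P) + A_l·P/(Kd_l + P) = P_total,

    which conserves profilin and each actin species simultaneously.  The
    residual is strictly increasing in P, so the bracket [0, P_total]
    contains exactly one root (located with Brent's method, ``tol`` uM).
    """
    p_total = condition.profilin_total
    if p_total == 0.0:
        return EquilibriumState(0.0, 0.0, 0.0, 0.0)

    def residual(p_free: float) -> float:
        return (
            p_free
            + pa_weak_binding(condition.actin_unlabeled, p_free, condition.kd_unlabeled)
            + pa_weak_binding(condition.actin_labeled, p_free, condition.kd_labeled)
            - p_total
        )

    p_free = brentq(residual, 0.0, p_total, xtol=tol)
    pa_u = pa_weak_binding(condition.actin_unlabeled, p_free, condition.kd_unlabeled)
    pa_l = pa_weak_binding(condition.actin_labeled, p_free, condition.kd_labeled)
    return EquilibriumState(pa_u, pa_l, pa_u + pa_l, p_free)


def solve_independent_species(
    condition: ReactionCondition, isotherm: str = "weak"
) -> EquilibriumState:
    """Per-species equilibrium as computed in the original analysis.

    Each actin species is treated against the *total* profilin pool
    independently: ``isotherm="weak"`` applies the hyperbolic isotherm with
    P_free approximated by P_total (appropriate when Kd >> concentrations,
    the Sc-profilin regime); ``isotherm="quadratic"`` applies the
    depletion-corrected quadratic per species (the Hs-profilin regime).
    Summing the two species can over-commit profilin when binding is tight
    and actin is abundant; :func:`solve_shared_profilin` is the exact
    alternative and the package default elsewhere.
    """
    if isotherm == "weak":
        pa_u = pa_weak_binding(
            condition.actin_unlabeled, condition.profilin_total, condition.kd_unlabeled
        )
        pa_l = pa_weak_binding(
            condition.actin_labeled, condition.profilin_total, condition.kd_labeled
        )
    elif isotherm == "quadratic":
        pa_u = pa_quadratic(
            condition.actin_unlabeled, condition.profilin_total, condition.kd_unlabeled
        )
        pa_l = pa_quadratic(
            condition.actin_labeled, condition.profilin_total, condition.kd_labeled
        )
    else:
        raise ValueError(f"isotherm must be 'weak' or 'quadratic', got {isotherm!r}")
    pa_tot = pa_u + pa_l
    return EquilibriumState(pa_u, pa_l, pa_tot, max(condition.profilin_total - pa_tot, 0.0))


def pa_label_ratio(state: EquilibriumState) -> float:
    """Ratio of labeled to unlabeled profilin–actin, [PA_green]/[PA_black].

    This is the relative availability of labeled vs unlabeled substrate for
    FH1-mediated delivery, used to convert the unlabeled delivered fraction
    into the total delivered fraction.
    """
    if state.pa_unlabeled == 0.0:
        raise ZeroDivisionError(
            "pa_unlabeled is zero: the labeled/unlabeled PA ratio is undefined "
            "(no unlabeled profilin-actin present)"
        )
    return state.pa_labeled / state.pa_unlabeled


def condition_preset(
    actin_total: float,
    profilin_total: float,
    isoform: str = "Sc",
    construct: str = "FH1FH2",
) -> ReactionCondition:
    """Build a :class:`ReactionCondition` from the published reaction grid.

    ``actin_total`` must be one of the standard mixes (0.75 or 1.0 uM at 33%
    labeling); the Kd pair is selected by profilin isoform (``"Sc"`` or
    ``"Hs"``).
    """
    if actin_total not in ACTIN_SPLITS:
        raise ValueError(
            f"no preset actin split for {actin_total} uM; known: {sorted(ACTIN_SPLITS)}"
        )
    if isoform == "Sc":
        kd_u, kd_l = SC_KD
    elif isoform == "Hs":
        kd_u, kd_l = HS_KD
    else:
        raise ValueError(f"unknown profilin isoform {isoform!r}")
    unlabeled, labeled = ACTIN_SPLITS[actin_total]
    return ReactionCondition(
        actin_unlabeled=unlabeled,
        actin_labeled=labeled,
        profilin_total=profilin_total,
        kd_unlabeled=kd_u,
        kd_labeled=kd_l,
        profilin_isoform=isoform,
        formin_construct=construct,
    )
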