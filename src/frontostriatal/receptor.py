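"""Single-site D2 receptor binding theory.

All dopamine and drug concentrations are carried as ratios to their
respective dissociation constants: ``y`` is the normalized extracellular
dopamine level Y = [DA]/K_DA and ``f_over_k`` is the normalized free
antipsychotic concentration F/K_APD.  Absolute dissociation constants never
enter any computation.

The quantities exposed here are the building blocks for PET/SPECT
depletion-imaging analysis:

* binding potential BP ∝ B_max / (1 + Y) — receptor density times the
  fraction of receptors not occupied by endogenous dopamine;
* the occupancy by dopamine P = Y / (1 + Y);
* the BP increase after acute dopamine depletion (e.g. with the tyrosine
  hydroxylase inhibitor AMPT), which unmasks receptors and lets Y be
  estimated from the fractional BP change;
* competitive occupancies when an antipsychotic drug is co-present.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError, InfeasibleError

#: Default residual dopamine fraction after acute AMPT depletion
#: (70% depletion leaves 30% of the baseline extracellular level).
DEFAULT_ALPHA = 0.3

__all__ = [
    "DEFAULT_ALPHA",
    "ReceptorSystem",
    "DepletionObservation",
    "binding_potential",
    "occupancy_from_da",
    "da_from_occupancy",
    "bp_depletion_ratio",
    "estimate_da_from_bp_increase",
    "occupancies_with_drug",
    "bp_ratio_sz_hc",
]


@dataclass(frozen=True)
class ReceptorSystem:
    """Striatal D2 receptor pool of one cohort.

    Parameters
    ----------
    b_max
        Relative D2 receptor density, dimensionless; the healthy-control
        reference is 1.0.
    y
        Normalized extracellular dopamine concentration Y = [DA]/K_DA, ≥ 0.
    cohort_label
        Free-text label, conventionally ``"HC"`` or ``"SZ"``.
    """

    b_max: float
    y: float
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if not self.b_max > 0:
            raise DomainError(f"b_max must be > 0, got {self.b_max}")
        if self.y < 0:
            raise DomainError(f"y must be >= 0, got {self.y}")

    @property
    def occupancy(self) -> float:
        """Occupancy of the receptor pool by endogenous dopamine."""
        return occupancy_from_da(self.y)


@dataclass(frozen=True)
class DepletionObservation:
    """One subject's binding potential before and after dopamine depletion.

    ``alpha`` is the residual dopamine fraction [DA]_depleted/[DA] the
    depletion protocol is assumed to achieve (0.3 for 70% depletion).
    """

    bp_baseline: float
    bp_depleted: float
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not self.bp_baseline > 0 or not self.bp_depleted > 0:
            raise DomainError("binding potentials must be > 0")
        if not 0 <= self.alpha < 1:
            raise DomainError(f"alpha must be in [0, 1), got {self.alpha}")

    @property
    def beta(self) -> float:
        """Fractional BP increase after depletion, (BP_dep − BP)/BP."""
        return self.bp_depleted / self.bp_baseline - 1.0


def _check_y(y: float) -> None:
    if y < 0:
        raise DomainError(f"normalized DA level must be >= 0, got {y}")


def binding_potential(system: ReceptorSystem) -> float:
    """Relative binding potential of the receptor pool.

    BP is proportional to the density of receptors available to the
    radiotracer, i.e. those not occupied by endogenous dopamine:
    BP ∝ B_max / (1 + Y).  The proportionality constant (tracer affinity)
    cancels in every ratio used downstream and is set to 1.
    """
    return system.b_max / (1.0 + system.y)


def occupancy_from_da(y: float) -> float:
    """D2 occupancy by endogenous dopamine, P = Y/(1+Y)."""
    _check_y(y)
    return y / (1.0 + y)


def da_from_occupancy(p: float) -> float:
    """Normalized dopamine level from the occupancy, Y = P/(1−P).

    Exact algebraic inverse of :func:`occupancy_from_da`.
    """
    if not 0 <= p < 1:
        raise DomainError(f"occupancy must be in [0, 1), got {p}")
    return p / (1.0 - p)


def bp_depletion_ratio(y: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Ratio BP_depleted / BP_baseline after partial dopamine depletion.

    With the receptor density unchanged by acute depletion, only the
    unoccupied fraction changes: the ratio is (1 + Y) / (1 + α·Y) ≥ 1,
    with equality iff Y = 0 (nothing to unmask).
    """
    _check_y(y)
    if not 0 <= alpha < 1:
        raise DomainError(f"alpha must be in [0, 1), got {alpha}")
    return (1.0 + y) / (1.0 + alpha * y)


def estimate_da_from_bp_increase(beta: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Baseline normalized dopamine level from the fractional BP increase.

    Inverts :func:`bp_depletion_ratio`: with β = BP_dep/BP − 1,

        Y = β / (1 − α·(1 + β)).

    Raises
    ------
    InfeasibleError
        If α·(1+β) ≥ 1, i.e. the observed BP increase is too large to be
        explained by the stated depletion fraction.
    """
    if beta < 0:
        raise DomainError(f"fractional BP increase must be >= 0, got {beta}")
    if not 0 <= alpha < 1:
        raise DomainError(f"alpha must be in [0, 1), got {alpha}")
    denom = 1.0 - alpha * (1.0 + beta)
    if denom <= 0:
        raise InfeasibleError(
            f"BP increase beta={beta} is inconsistent with residual "
            f"fraction alpha={alpha}: alpha*(1+beta) >= 1"
        )
    return beta / denom


def occupancies_with_drug(y: float, f_over_k: float) -> tuple[float, float]:
    """Competitive D2 occupancies by dopamine and an antipsychotic drug.

    Two ligands competing for one site:

        P_DA(APD) = Y / (1 + Y + F/K_APD)
        P_APD     = (F/K_APD) / (1 + Y + F/K_APD)

    Returns ``(p_da_apd, p_apd)``.  The unoccupied fraction
    1/(1+Y+F/K) completes the partition of unity.
    """
    _check_y(y)
    if f_over_k < 0:
        raise DomainError(f"normalized drug concentration must be >= 0, got {f_over_k}")
    denom = 1.0 + y + f_over_k
    return y / denom, f_over_k / denom


def bp_ratio_sz_hc(sz: ReceptorSystem, hc: ReceptorSystem) -> float:
    """Patient-to-control binding-potential ratio.

    (B_max,SZ / B_max,HC) × (1 + Y_HC) / (1 + Y_SZ); identical to the ratio
    of the two :func:`binding_potential` values, and invariant to whether
    both cohorts are imaged before or after depletion (the α factors cancel
    when the same protocol is applied to both).
    """
    return binding_potential(sz) / binding_potential(hc)
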