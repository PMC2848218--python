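"""Antipsychotic dosing and clinical-outcome transformation.

Antipsychotic drugs compete with endogenous dopamine for striatal D2
receptors.  The *net-binding* criterion defines the optimum dose: the
receptor-density-weighted dopamine occupancy in patients, reduced by
competition with the drug, should equal the unmedicated control value,

    B_max,SZ · P_DA(APD),SZ = B_max,HC · P_DA,HC .

Solving under single-site competition gives a closed-form normalized dose

    F_opt/K_APD = Y_SZ · B_max,SZ / (B_max,HC · P_DA,HC) − (1 + Y_SZ)

and the associated drug occupancy P_APD.

The outcome pipeline chains depletion imaging to circuit state: a
patient's pre-treatment fractional BP increase after dopamine depletion
(β) yields the baseline dopamine level, hence D2 occupancy, hence — by
inverting the circuit equilibrium — the PFC activity X_p.  Regressing
symptom change (PANSS positive subscale; negative = improvement) on X_p
tests the prediction that lower PFC activity (stronger hypofrontality)
goes with larger improvement under antipsychotic treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .calibration import CalibratedModel
from .errors import DomainError, InfeasibleError
from .receptor import (
    DEFAULT_ALPHA,
    estimate_da_from_bp_increase,
    occupancies_with_drug,
)

__all__ = [
    "DrugRegimen",
    "PatientOutcomeRecord",
    "RegressionResult",
    "optimum_regimen",
    "pfc_activity_from_beta",
    "fit_outcome_regression",
    "generate_synthetic_outcome_records",
]


@dataclass(frozen=True)
class DrugRegimen:
    """Normalized antipsychotic dose and the occupancies it produces.

    ``f_over_k`` is the free synaptic drug concentration divided by its D2
    dissociation constant; ``p_da_apd`` the residual dopamine occupancy
    under competition; ``p_apd`` the drug occupancy; ``p_total`` their sum.
    """

    f_over_k: float
    p_da_apd: float
    p_apd: float

    def __post_init__(self) -> None:
        if self.f_over_k < 0:
            raise DomainError("f_over_k must be >= 0")
        for v in (self.p_da_apd, self.p_apd):
            if not 0 <= v < 1:
                raise DomainError("occupancies must be in [0, 1)")
        if not self.p_total < 1:
            raise DomainError("total occupancy must be < 1")

    @property
    def p_total(self) -> float:
        return self.p_da_apd + self.p_apd


@dataclass(frozen=True)
class PatientOutcomeRecord:
    """Pre-treatment depletion response and post-treatment symptom change."""

    beta: float
    delta_panss_pos: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise DomainError("fractional BP increase beta must be >= 0")


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares summary of symptom change on PFC activity."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
        }


def optimum_regimen(model: CalibratedModel) -> DrugRegimen:
    """Optimum antipsychotic dose for a calibrated patient/control pair.

    Solves the net-binding criterion in closed form and populates all
    occupancies through the competitive-binding relations.

    Raises
    ------
    InfeasibleError
        If the patient's net dopamine binding is already at or below the
        control level, so the criterion would require a negative dose.
    """
    y_sz = model.sz.y
    target = model.hc.b_max * model.hc.occupancy  # net binding to restore
    if target <= 0:
        raise InfeasibleError("control net binding is zero; criterion undefined")
    f = y_sz * model.sz.b_max / target - (1.0 + y_sz)
    if f < 0:
        raise InfeasibleError(
            f"patient net binding already <= control ({model.label}); "
            "no positive dose satisfies the criterion"
        )
    p_da_apd, p_apd = occupancies_with_drug(y_sz, f)
    return DrugRegimen(f_over_k=f, p_da_apd=p_da_apd, p_apd=p_apd)


def pfc_activity_from_beta(
    beta: float,
    alpha: float = DEFAULT_ALPHA,
    a: float = 0.0,
    b: float = 0.0,
    j_d: float = 1.0,
    b_max: float = 1.0,
    scale_by_density: bool = False,
) -> float:
    """PFC activity implied by a depletion-imaging response.

    Chains β → Y (depletion inversion) → P (occupancy) → X_p (circuit
    equilibrium inversion).  With (a, b) = (0, 0) this reduces to
    X_p = J_d − β/(1 − α(1+β)) and is strictly decreasing in β.

    ``scale_by_density`` applies the cohort's relative receptor density
    ``b_max`` as a multiplier on the D2 coefficients, as in cross-cohort
    comparisons; it is moot at (a, b) = (0, 0), the default setting.
    """
    y = estimate_da_from_bp_increase(beta, alpha)
    p = y / (1.0 + y)
    scale = b_max if scale_by_density else 1.0
    a_eff, b_eff = a * scale, b * scale
    if a_eff * p >= 1 or b_eff * p >= 1:
        raise InfeasibleError("D2 modulation saturates transmission")
    x_p = (j_d - y / (1.0 - a_eff * p)) / (1.0 - b_eff * p)
    if not x_p > 0:
        raise InfeasibleError(
            f"beta={beta} implies dopamine level {y:.3f} >= drive j_d={j_d}; "
            "no positive PFC activity"
        )
    return x_p


def fit_outcome_regression(
    records: Sequence[PatientOutcomeRecord],
    alpha: float = DEFAULT_ALPHA,
    a: float = 0.0,
    b: float = 0.0,
) -> RegressionResult:
    """OLS regression of symptom change on transformed PFC activity.

    Each record's β is transformed through :func:`pfc_activity_from_beta`;
    ΔPANSS-positive is then regressed on X_p by unweighted ordinary least
    squares.  The p-value is the two-sided test on the slope.
    """
    if len(records) < 3:
        raise DomainError("need at least 3 records to fit the regression")
    x = np.array([pfc_activity_from_beta(r.beta, alpha, a, b) for r in records])
    y = np.array([r.delta_panss_pos for r in records])
    if np.ptp(x) < 1e-12:
        raise DomainError("transformed PFC activity is constant; slope undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n=len(records),
    )


def generate_synthetic_outcome_records(
    n: int = 14,
    slope: float = 49.6,
    intercept: float = -61.5,
    noise_sd: float = 0.0,
    alpha: float = DEFAULT_ALPHA,
    beta_range: tuple[float, float] = (0.02, 0.45),
    seed: int | None = None,
) -> list[PatientOutcomeRecord]:
    """Synthetic patient records lying on (or scattered about) a line.

    β values are drawn uniformly over ``beta_range``, transformed to X_p
    at (a, b) = (0, 0), and symptom changes generated as
    slope·X_p + intercept plus Gaussian noise of ``noise_sd`` score
    points.  The default line is a plausible hypofrontality-outcome
    relationship for a 14-patient cohort.  Deterministic given ``seed``.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    betas = rng.uniform(*beta_range, size=n)
    records = []
    for beta in betas:
        x_p = pfc_activity_from_beta(beta, alpha)
        dp = slope * x_p + intercept + rng.normal(0.0, noise_sd)
        records.append(PatientOutcomeRecord(beta=float(beta), delta_panss_pos=float(dp)))
    return records
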