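"""Patient/control calibration from dopamine-depletion imaging.

Receptor-imaging depletion studies (AMPT paradigm) yield estimates of the
striatal D2 occupancy by endogenous dopamine in healthy controls (HC) and
schizophrenia patients (SZ).  Two canonical parameterizations are built
from the published occupancies:

* **Model 1** — the single study reporting both cohorts: occupancies
  12% (HC) and 21% (SZ), relative receptor densities 1.0 and 1.2.
* **Model 2** — the mean HC occupancy across studies (23.6%), with the SZ
  occupancy extrapolated by Model 1's SZ/HC ratio (→ 41.3%), rounded to
  24% and 41%; densities as in Model 1.

Feeding a calibrated model back through the circuit equilibrium gives the
cohort's glutamatergic synaptic efficacy and PFC activity, and hence the
SZ − HC differences (hypofrontality).  Because the patient receptor
density is 1.2× the control one, the presynaptic D2 coefficients acting in
patients are scaled by the same factor in cross-cohort comparisons.

A synthetic depletion-study generator supports parameter-recovery testing
of the imaging-side estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InfeasibleError
from .receptor import (
    DEFAULT_ALPHA,
    DepletionObservation,
    ReceptorSystem,
    da_from_occupancy,
)

__all__ = [
    "OccupancyRecord",
    "CalibratedModel",
    "load_occupancy_table",
    "average_hc_occupancy",
    "extrapolate_sz_occupancy",
    "build_model",
    "model_1",
    "model_2",
    "efficacy_and_pfc_from_model",
    "sz_hc_differences",
    "generate_synthetic_depletion_study",
]

_FIXTURE = "d2_occupancy_studies.csv"


@dataclass(frozen=True)
class OccupancyRecord:
    """One cohort's D2-occupancy estimate from one imaging study.

    ``occupancy`` is a fraction in [0, 1) or ``None`` when the study did
    not report that cohort.
    """

    study_label: str
    cohort: str
    occupancy: float | None

    def __post_init__(self) -> None:
        if self.cohort not in ("HC", "SZ"):
            raise DomainError(f"cohort must be 'HC' or 'SZ', got {self.cohort!r}")
        if self.occupancy is not None and not 0 <= self.occupancy < 1:
            raise DomainError(
                f"occupancy must be in [0, 1), got {self.occupancy} "
                f"({self.study_label}, {self.cohort})"
            )


@dataclass(frozen=True)
class CalibratedModel:
    """Paired HC/SZ receptor systems calibrated from imaging data."""

    label: str
    hc: ReceptorSystem
    sz: ReceptorSystem


def load_occupancy_table(path=None) -> list[OccupancyRecord]:
    """Read occupancy records from a CSV table.

    Without ``path``, loads the packaged table of published striatal D2
    occupancies (columns: study_label, cohort, occupancy_percent; one row
    per study × cohort that was actually reported).
    """
    if path is None:
        src = resources.files("frontostriatal").joinpath("data", _FIXTURE)
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"study_label", "cohort", "occupancy_percent"}
    if not required.issubset(df.columns):
        raise DomainError(f"occupancy table must have columns {sorted(required)}")
    records = []
    for i, row in df.iterrows():
        occ = row["occupancy_percent"]
        occ = None if pd.isna(occ) else float(occ) / 100.0
        try:
            records.append(
                OccupancyRecord(str(row["study_label"]), str(row["cohort"]).strip(), occ)
            )
        except DomainError as e:
            raise DomainError(f"row {i}: {e}") from e
    return records


def average_hc_occupancy(records: Iterable[OccupancyRecord]) -> float:
    """Unweighted mean occupancy over healthy-control records.

    Records from other cohorts or with missing occupancy are ignored.
    """
    vals = [r.occupancy for r in records if r.cohort == "HC" and r.occupancy is not None]
    if not vals:
        raise DomainError("no HC occupancy records to average")
    return float(np.mean(vals))


def extrapolate_sz_occupancy(hc_occupancy: float, ratio_model: CalibratedModel) -> float:
    """Patient occupancy extrapolated by a reference model's SZ/HC ratio."""
    p_hc = ratio_model.hc.occupancy
    p_sz = ratio_model.sz.occupancy
    if p_hc <= 0 or p_sz <= 0:
        raise DomainError("ratio model must have positive occupancies in both cohorts")
    return hc_occupancy * p_sz / p_hc


def build_model(
    p_hc: float,
    p_sz: float,
    b_max_sz: float,
    label: str = "custom",
    b_max_hc: float = 1.0,
) -> CalibratedModel:
    """Calibrated model from per-cohort occupancies and relative density.

    Normalized dopamine levels are computed exactly as Y = P/(1−P); the HC
    density is 1 by normalization.
    """
    return CalibratedModel(
        label=label,
        hc=ReceptorSystem(b_max=b_max_hc, y=da_from_occupancy(p_hc), cohort_label="HC"),
        sz=ReceptorSystem(b_max=b_max_sz, y=da_from_occupancy(p_sz), cohort_label="SZ"),
    )


def model_1() -> CalibratedModel:
    """Canonical Model 1: occupancies 12%/21%, patient density 1.2."""
    return build_model(0.12, 0.21, b_max_sz=1.2, label="Model 1")


def model_2() -> CalibratedModel:
    """Canonical Model 2: occupancies 24%/41%, patient density 1.2."""
    return build_model(0.24, 0.41, b_max_sz=1.2, label="Model 2")


def _efficacy_and_pfc(
    y: float, a_eff: float, b_eff: float, j_d: float
) -> tuple[float, float]:
    p = y / (1.0 + y)
    if a_eff * p >= 1 or b_eff * p >= 1:
        raise InfeasibleError(
            f"D2 modulation saturates transmission (a_eff*P={a_eff * p:.3f}, "
            f"b_eff*P={b_eff * p:.3f})"
        )
    v_ps = 1.0 - b_eff * p
    x_p = (j_d - y / (1.0 - a_eff * p)) / v_ps
    if not x_p > 0:
        raise InfeasibleError(f"implied PFC activity is not positive (x_p={x_p:.3f})")
    return v_ps, x_p


def efficacy_and_pfc_from_model(
    model: CalibratedModel,
    a: float,
    b: float,
    j_d: float = 1.0,
    scale_by_density: bool = True,
) -> dict[str, tuple[float, float]]:
    """Per-cohort (v_ps, x_p): glutamatergic efficacy and PFC activity.

    Inverts the circuit equilibrium at each cohort's dopamine level:
    v_ps = 1 − b_eff·P and x_p = (J_d − Y/(1 − a_eff·P)) / (1 − b_eff·P).
    With ``scale_by_density`` (default) the D2 coefficients acting in each
    cohort are scaled by its relative receptor density, so patients with
    1.2× the density experience 1.2× the presynaptic D2 effect.
    """
    if a < 0 or b < 0:
        raise DomainError("D2 coefficients must be >= 0")
    out = {}
    for name, sys in (("HC", model.hc), ("SZ", model.sz)):
        scale = sys.b_max if scale_by_density else 1.0
        out[name] = _efficacy_and_pfc(sys.y, a * scale, b * scale, j_d)
    return out


def sz_hc_differences(
    model: CalibratedModel,
    a_values: Sequence[float],
    b_grid: Sequence[float],
    j_d: float = 1.0,
) -> pd.DataFrame:
    """SZ − HC differences of synaptic efficacy and PFC activity.

    Tidy frame with columns ``a, b, delta_v_ps, delta_x_p, feasible``.
    The efficacy difference Δv_ps = b·(P_HC − b_max,SZ·P_SZ)·... depends on
    b only, never on the autoreceptor coefficient a; the PFC-activity
    difference depends on both.  Infeasible (a, b) pairs are flagged.
    """
    rows = []
    for a in a_values:
        for b in b_grid:
            row = {"a": float(a), "b": float(b)}
            try:
                res = efficacy_and_pfc_from_model(model, a, b, j_d=j_d)
                row["delta_v_ps"] = res["SZ"][0] - res["HC"][0]
                row["delta_x_p"] = res["SZ"][1] - res["HC"][1]
                row["feasible"] = True
            except InfeasibleError:
                row.update(delta_v_ps=np.nan, delta_x_p=np.nan, feasible=False)
            rows.append(row)
    return pd.DataFrame(rows)


def generate_synthetic_depletion_study(
    true_y: float,
    b_max: float = 1.0,
    alpha: float = DEFAULT_ALPHA,
    n_subjects: int = 1,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> list[DepletionObservation]:
    """Simulate a depletion-imaging study for estimator recovery tests.

    Each subject's baseline and post-depletion binding potentials are the
    noiseless binding-theory values, B_max/(1+Y) and B_max/(1+αY), each
    multiplied by independent lognormal noise with the given coefficient
    of variation.  Multiplicative noise reflects that BP is positive and
    imaging error scales with signal.  Deterministic given ``seed``.
    """
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    if n_subjects < 1:
        raise DomainError("n_subjects must be >= 1")
    if true_y < 0:
        raise DomainError("true_y must be >= 0")
    if not 0 <= alpha < 1:
        raise DomainError("alpha must be in [0, 1)")
    rng = np.random.default_rng(seed)
    bp0 = b_max / (1.0 + true_y)
    bp1 = b_max / (1.0 + alpha * true_y)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    mu = -0.5 * sigma**2  # unit-mean lognormal
    noise = rng.lognormal(mean=mu, sigma=sigma, size=(n_subjects, 2))
    return [
        DepletionObservation(
            bp_baseline=bp0 * noise[i, 0], bp_depleted=bp1 * noise[i, 1], alpha=alpha
        )
        for i in range(n_subjects)
    ]
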