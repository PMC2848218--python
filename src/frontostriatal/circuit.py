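"""Three-region frontostriatal circuit model.

The circuit couples the prefrontal cortex (PFC), the striatum and the
midbrain dopamine (DA) nuclei: a glutamatergic PFC→striatum projection, a
GABAergic striatum→midbrain projection, and dopaminergic feedback into the
striatum.  Two presynaptic D2 effects modulate transmission as functions of
the D2 occupancy P = Y/(1+Y):

* heteroreceptors on the glutamatergic terminals depress cortical input to
  the striatum by a factor (1 − b·P);
* autoreceptors on the dopaminergic terminals suppress DA release by a
  factor (1 − a·P).

In normalized variables (each activity scaled by its downstream gains and
K_DA) the equilibrium of the linearized system is the fixed point

    X_s = X_p (1 − b P)
    X_d = J_d − X_s
    Y   = X_d (1 − a P)
    P   = Y / (1 + Y)

subject to X_s, X_d, Y > 0.  Lower PFC activity disinhibits the DA nuclei
and raises striatal DA release; D2 heteroreceptor activation amplifies that
elevation while autoreceptor activation damps it.

The time-domain system (with optional tanh activation) is integrated only
to verify the algebraic equilibrium dynamically; all parametric results
come from the fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import DomainError, InfeasibleError
from .receptor import occupancy_from_da

__all__ = [
    "CircuitParams",
    "EquilibriumState",
    "Trajectory",
    "dynamics_rhs",
    "simulate",
    "solve_equilibrium",
    "sweep_equilibrium",
    "enhancement_percent",
]


@dataclass(frozen=True)
class CircuitParams:
    """Parameters of the frontostriatal circuit.

    Attributes
    ----------
    a
        D2 autoreceptor coefficient: presynaptic suppression of DA release,
        dimensionless, ≥ 0.
    b
        D2 heteroreceptor coefficient: presynaptic depression of the
        frontostriatal glutamatergic input, dimensionless, ≥ 0.
    j_d
        Normalized tonic drive to the DA nuclei (default 1).
    tau_s, tau_d, tau_y
        Time constants of the striatal population, the DA-nucleus
        population and DA release (arbitrary time units, > 0).
    w_ps, w_sd, w_dy
        Connectivity / releasability coefficients (> 0).  The parametric
        analysis works in normalized variables where these are absorbed;
        they matter only for raw time-domain simulation.
    activation
        ``"linear"`` (f(x) = x; used for all equilibrium analysis) or
        ``"tanh"`` (full saturating model, time-domain only).
    """

    a: float = 0.0
    b: float = 0.0
    j_d: float = 1.0
    tau_s: float = 1.0
    tau_d: float = 1.0
    tau_y: float = 1.0
    w_ps: float = 1.0
    w_sd: float = 1.0
    w_dy: float = 1.0
    activation: Literal["linear", "tanh"] = "linear"

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0:
            raise DomainError("D2 coefficients a, b must be >= 0")
        if self.j_d < 0:
            raise DomainError("tonic drive j_d must be >= 0")
        for name in ("tau_s", "tau_d", "tau_y", "w_ps", "w_sd", "w_dy"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")
        if self.activation not in ("linear", "tanh"):
            raise DomainError(f"unknown activation {self.activation!r}")

    @property
    def f(self) -> Callable[[np.ndarray], np.ndarray]:
        """Activation function."""
        return np.tanh if self.activation == "tanh" else (lambda x: x)

    def with_(self, **kwargs) -> "CircuitParams":
        """Copy with fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EquilibriumState:
    """Self-consistent fixed point of the normalized circuit.

    All activities and the DA release are strictly positive (physiological
    constraint); ``p`` is the D2 occupancy implied by ``y``.
    """

    x_p: float
    x_s: float
    x_d: float
    y: float
    p: float

    def as_dict(self) -> dict[str, float]:
        return {"x_p": self.x_p, "x_s": self.x_s, "x_d": self.x_d, "y": self.y, "p": self.p}


@dataclass(frozen=True)
class Trajectory:
    """Time course of the circuit state from :func:`simulate`."""

    t: np.ndarray
    x_p: np.ndarray
    x_s: np.ndarray
    x_d: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.t) > 0):
            raise DomainError("time grid must be strictly increasing")
        for arr in (self.x_p, self.x_s, self.x_d, self.y):
            if not np.all(np.isfinite(arr)):
                raise DomainError("trajectory contains non-finite values")

    @property
    def terminal(self) -> tuple[float, float, float, float]:
        return (self.x_p[-1], self.x_s[-1], self.x_d[-1], self.y[-1])


def _d2_factor(coeff: float, p: float) -> float:
    # Effective presynaptic gains never go negative.
    return max(0.0, 1.0 - coeff * p)


def dynamics_rhs(
    state: Sequence[float],
    params: CircuitParams,
    pfc_input: float,
) -> np.ndarray:
    """Time derivatives of (x_p, x_s, x_d, y).

    The PFC relaxes toward its external drive; the striatum integrates the
    D2-depressed glutamatergic input; the DA nuclei integrate their tonic
    drive minus the GABAergic striatal input; DA release relaxes toward the
    autoreceptor-suppressed dopaminergic output.  D2 occupancy is evaluated
    from the instantaneous release level.
    """
    x_p, x_s, x_d, y = state
    f = params.f
    p = occupancy_from_da(max(y, 0.0))
    dx_p = (pfc_input - x_p) / params.tau_s
    dx_s = (-x_s + params.w_ps * f(x_p) * _d2_factor(params.b, p)) / params.tau_s
    dx_d = (-x_d + params.j_d - params.w_sd * f(x_s)) / params.tau_d
    dy = (-y + params.w_dy * x_d * _d2_factor(params.a, p)) / params.tau_y
    return np.array([dx_p, dx_s, dx_d, dy])


def simulate(
    params: CircuitParams,
    initial: Sequence[float],
    pfc_input: float,
    t_end: float,
    dt: float | None = None,
    state_bound: float = 1e6,
) -> Trajectory:
    """Integrate the circuit dynamics on a regular output grid.

    Parameters
    ----------
    initial
        Initial (x_p, x_s, x_d, y).
    pfc_input
        Constant external drive to the PFC.
    t_end, dt
        Final time and output-grid spacing; ``dt`` defaults to
        min(τ)/20.

    Raises
    ------
    InfeasibleError
        If the state leaves ``[-state_bound, state_bound]`` (divergence)
        or the integrator fails.
    """
    if t_end <= 0:
        raise DomainError("t_end must be > 0")
    if dt is None:
        dt = min(params.tau_s, params.tau_d, params.tau_y) / 20.0
    if dt <= 0:
        raise DomainError("dt must be > 0")

    t_eval = np.arange(0.0, t_end + 0.5 * dt, dt)

    def rhs(_t, s):
        return dynamics_rhs(s, params, pfc_input)

    def blowup(_t, s):
        return state_bound - np.max(np.abs(s))

    blowup.terminal = True  # type: ignore[attr-defined]

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        np.asarray(initial, dtype=float),
        t_eval=t_eval,
        rtol=1e-10,
        atol=1e-12,
        events=blowup,
        method="RK45",
    )
    if sol.status == 1:
        raise InfeasibleError(f"state diverged beyond {state_bound} at t={sol.t_events[0][0]:.3g}")
    if not sol.success:
        raise InfeasibleError(f"integration failed: {sol.message}")
    return Trajectory(t=sol.t, x_p=sol.y[0], x_s=sol.y[1], x_d=sol.y[2], y=sol.y[3])


def _equilibrium_residual(y: float, params: CircuitParams, x_p: float) -> float:
    """Scalar residual g(Y): self-consistency map minus Y."""
    p = y / (1.0 + y)
    x_s = x_p * _d2_factor(params.b, p)
    x_d = params.j_d - x_s
    return x_d * _d2_factor(params.a, p) - y


def solve_equilibrium(
    params: CircuitParams,
    x_p: float,
    tol: float = 1e-12,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> EquilibriumState:
    """Unique positive fixed point of the normalized linearized circuit.

    Solves the self-consistent system by damped iteration on Y, falling
    back to a bracketed root search on the scalar residual when the
    iteration fails to converge.

    Raises
    ------
    InfeasibleError
        If no solution with X_s, X_d, Y > 0 exists for the given
        parameters (e.g. PFC drive at or above the tonic DA-nucleus drive
        with no heteroreceptor relief).
    """
    if not x_p > 0:
        raise DomainError(f"x_p must be > 0, got {x_p}")
    if not params.j_d > 0:
        raise InfeasibleError("equilibrium analysis requires positive tonic drive j_d")

    y = max(params.j_d - x_p, 1e-3)  # b=0 solution as a starting guess
    converged = False
    for _ in range(max_iter):
        g = _equilibrium_residual(y, params, x_p)
        y_new = max(y + damping * g, 0.0)
        if abs(y_new - y) < tol and abs(g) < tol:
            y = y_new
            converged = True
            break
        y = y_new

    if not converged or not y > 0 or abs(_equilibrium_residual(y, params, x_p)) > 1e-10:
        y = _root_scan(params, x_p)

    p = occupancy_from_da(y)
    x_s = x_p * _d2_factor(params.b, p)
    x_d = params.j_d - x_s
    if not (x_s > 0 and x_d > 0 and y > 0):
        raise InfeasibleError(
            f"no positive equilibrium at x_p={x_p} with a={params.a}, "
            f"b={params.b}, j_d={params.j_d}"
        )
    return EquilibriumState(x_p=x_p, x_s=x_s, x_d=x_d, y=y, p=p)


def _root_scan(params: CircuitParams, x_p: float) -> float:
    """Bracketing fallback: scan the residual for a sign change, then brentq."""
    # Y < J_d always (X_d < J_d and the autoreceptor factor is <= 1).
    y_hi = params.j_d
    grid = np.linspace(0.0, y_hi, 2001)
    g = np.array([_equilibrium_residual(yy, params, x_p) for yy in grid])
    sign_change = np.nonzero(np.diff(np.sign(g)) != 0)[0]
    for i in sign_change:
        lo, hi = grid[i], grid[i + 1]
        root = brentq(_equilibrium_residual, lo, hi, args=(params, x_p), xtol=1e-14)
        if root > 0:
            return float(root)
    raise InfeasibleError(
        f"no positive equilibrium at x_p={x_p} with a={params.a}, "
        f"b={params.b}, j_d={params.j_d}"
    )


def sweep_equilibrium(
    params: CircuitParams,
    x_p_grid: Iterable[float],
    b_values: Iterable[float] | None = None,
    a_values: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Equilibrium curves over a PFC-activity grid for families of D2 coefficients.

    Returns a tidy frame with columns ``x_p, a, b, j_d, x_s, x_d, y, p,
    feasible``.  Grid points with no positive equilibrium are flagged
    (``feasible=False``, NaN state), never silently dropped.
    """
    x_p_grid = np.asarray(list(x_p_grid), dtype=float)
    if x_p_grid.size == 0:
        raise DomainError("x_p grid is empty")
    if np.any(~np.isfinite(x_p_grid)) or np.any(x_p_grid <= 0):
        raise DomainError("x_p grid must be positive and finite")
    b_values = [params.b] if b_values is None else list(b_values)
    a_values = [params.a] if a_values is None else list(a_values)

    rows = []
    for a in a_values:
        for b in b_values:
            pset = params.with_(a=a, b=b)
            for x_p in x_p_grid:
                row = {"x_p": x_p, "a": a, "b": b, "j_d": params.j_d}
                try:
                    eq = solve_equilibrium(pset, x_p)
                    row.update(x_s=eq.x_s, x_d=eq.x_d, y=eq.y, p=eq.p, feasible=True)
                except InfeasibleError:
                    row.update(x_s=np.nan, x_d=np.nan, y=np.nan, p=np.nan, feasible=False)
                rows.append(row)
    return pd.DataFrame(rows)


def enhancement_percent(y_with: float, y_without: float) -> float:
    """Percent change of DA release relative to a reference level."""
    if not y_without > 0:
        raise DomainError(f"reference DA release must be > 0, got {y_without}")
    return 100.0 * (y_with - y_without) / y_without
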