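"""Wild-type steady state: quasi-steady solves, calibration, fixed point.

The stationary signal fields for frozen radii ``(R, r)`` are obtained by
sequential sparse linear solves exactly as the model structure permits:
WUS first (its stationary equation is linear and autonomous), then CLV3
and HEC (each linear given WUS), then CK (linear given WUS and HEC).
Inserting the fields into the radius ODE brackets yields the phase-plane
functions ``F(R, r)`` (OC growth bracket) and ``G(R, r)`` (meristem growth
bracket); the wild-type equilibrium is their common zero.

Calibration follows the published procedure: the OC baseline
differentiation rate ``pdbasic`` and the meristem differentiation
prefactor ``pp`` are estimated from the prescribed steady-state radii so
that ``F = G = 0`` holds there by construction, with the reference radius
``R0`` set to the target meristem radius (the size-dependent
differentiation factor is 1 at equilibrium).  The CLV3 threshold defining
the central zone is frozen at half the central maximum of the calibrated
CLV3 profile and reused unchanged across all perturbation scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinetics
from .grid import RadialGrid
from .params import Parameters
from .scenarios import Scenario, ScenarioKinetics
from .solver import integrate, oc_proliferation_integral
from .state import MeristemState, Trajectory

# Default wild-type target geometry (dimensionless radii).  Chosen once so
# that (a) the central zone holds ~10% of the meristem area at equilibrium
# and (b) the calibrated pdbasic/pp land at the published wild-type values;
# see docs/methods.md.
DEFAULT_R_TARGET = 2.5
DEFAULT_OC_TARGET = 0.95

__all__ = [
    "DEFAULT_R_TARGET",
    "DEFAULT_OC_TARGET",
    "QuasiSteadyPoint",
    "quasi_steady_solve",
    "calibrate",
    "find_steady_state",
    "wildtype_equilibrium",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Raised when the steady-state march does not converge; carries the
    trajectory computed so far for diagnosis."""

    def __init__(self, message: str, trajectory: Trajectory):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class QuasiSteadyPoint:
    """Stationary fields and radius-ODE brackets at frozen radii."""

    R: float
    r: float
    xi: np.ndarray
    u: np.ndarray  # shape (4, n_r + 1)
    F: float
    G: float

    @property
    def state(self) -> MeristemState:
        return MeristemState(0.0, self.R, self.r, self.xi.copy(), self.u.copy())


def quasi_steady_solve(
    R: float,
    r: float,
    p: Parameters,
    scenario: Scenario | None = None,
    n_r: int | None = None,
) -> QuasiSteadyPoint:
    """Solve the four stationary PDEs at frozen radii and evaluate F, G."""
    if not 0 < r <= R:
        raise ValueError("need 0 < r <= R")
    kin = ScenarioKinetics(p, scenario)
    grid = RadialGrid(n_r if n_r is not None else p.numerics.n_r)
    rho = grid.xi * R
    degr = kin.degradation
    D = (p.D0, p.D1, p.D2, p.D3)

    def solve(i: int, prod: np.ndarray) -> np.ndarray:
        return grid.helmholtz_solve(degr[i], D[i] / R**2, prod)

    u0 = solve(0, np.asarray(kin.wus_production(rho, r), dtype=float))
    u1 = solve(1, kin.clv3_production(u0))
    u3 = solve(3, kin.hec_production(u0))
    u2 = solve(2, kin.ck_production(u0, u3))
    u = np.stack([u0, u1, u2, u3])

    state = MeristemState(0.0, R, r, grid.xi, u)
    F = oc_proliferation_integral(kin, grid, state) - p.pdbasic
    I0 = grid.disc_integral(u0, R)
    I2 = grid.disc_integral(u2, R)
    G = p.k21 / (1.0 + p.k23 * kin.wus_integral_for_R(I0)) - p.pp * (
        1.0 + R * R
    ) / (1.0 + p.R0 * p.R0) * kinetics.g_step(I2)
    return QuasiSteadyPoint(R, r, grid.xi, u, float(F), float(G))


def calibrate(
    p: Parameters,
    R_target: float = DEFAULT_R_TARGET,
    r_target: float = DEFAULT_OC_TARGET,
) -> Parameters:
    """Estimate ``pdbasic``, ``pp`` and ``R0`` from the prescribed radii.

    Returns a parameter set for which the quasi-steady point at
    ``(R_target, r_target)`` satisfies ``F = G = 0`` exactly, and with the
    central-zone CLV3 threshold frozen at half the calibrated maximum.
    """
    if not 0 < r_target < R_target:
        raise ValueError("need 0 < r_target < R_target")
    kin = ScenarioKinetics(p)
    qs = quasi_steady_solve(R_target, r_target, p)
    grid = RadialGrid(p.numerics.n_r)
    pdbasic = oc_proliferation_integral(kin, grid, qs.state)
    I0 = grid.disc_integral(qs.u[0], R_target)
    I2 = grid.disc_integral(qs.u[2], R_target)
    pp = (p.k21 / (1.0 + p.k23 * I0)) / kinetics.g_step(I2)
    theta = 0.5 * float(np.max(qs.u[1]))
    return p.replace(pdbasic=float(pdbasic), pp=float(pp), R0=float(R_target),
                     cz_threshold=theta)


def find_steady_state(
    p: Parameters,
    ic: MeristemState,
    scenario: Scenario | None = None,
    *,
    horizon: float = 400.0,
    check_every: float = 2.0,
) -> MeristemState:
    """Time-march the fully coupled system until it stops moving.

    Convergence: the maximum relative change per unit time of the radii
    and of every field (relative to its running maximum) falls below
    ``ss_tol``.  Raises :class:`ConvergenceError` (with the trajectory
    attached) if the horizon is exhausted first.
    """
    tol = p.numerics.ss_tol
    state = ic.copy()
    full = Trajectory()
    t = state.t
    t_stop = t + horizon
    while t < t_stop:
        t_next = min(t + check_every, t_stop)
        traj = integrate(state, scenario, p, t_next, sample_every=check_every)
        new = traj.final
        for st, rec in zip(traj.states, traj.records):
            if not full.states or st.t > full.states[-1].t:
                full.append(st, rec)
        rate = _relative_change_rate(state, new)
        state = new
        t = state.t
        if rate < tol:
            return state
    raise ConvergenceError(
        f"no steady state within horizon {horizon} (last rate {rate:.3e})", full
    )


def _relative_change_rate(a: MeristemState, b: MeristemState) -> float:
    dt = b.t - a.t
    parts = [abs(b.R - a.R) / a.R, abs(b.r - a.r) / a.r]
    for i in range(4):
        scale = max(np.max(np.abs(a.u[i])), np.max(np.abs(b.u[i])), 1e-12)
        parts.append(float(np.max(np.abs(b.u[i] - a.u[i])) / scale))
    return max(parts) / dt


def wildtype_equilibrium(
    p: Parameters | None = None,
    R_target: float = DEFAULT_R_TARGET,
    r_target: float = DEFAULT_OC_TARGET,
) -> tuple[Parameters, MeristemState]:
    """Calibrate at the target geometry and return the equilibrium state.

    By construction the quasi-steady point at the target is a fixed point
    of the fully coupled system, so this also verifies it by a short march.
    """
    p = (p or Parameters()).copy()
    p_cal = calibrate(p, R_target, r_target)
    qs = quasi_steady_solve(R_target, r_target, p_cal)
    state = find_steady_state(p_cal, qs.state, horizon=50.0)
    return p_cal, state
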