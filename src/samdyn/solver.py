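"""Radial method-of-lines solver for the coupled signal/growth system.

The four reaction-diffusion equations are posed on the growing disc
``rho <= R(t)``; mapping to the fixed coordinate ``xi = rho/R(t)`` turns
the deformation-advection term ``-div(u v)`` (with the dilation velocity
``v = rho (Rdot/R)``) plus the grid motion into a pure dilution term, so
each species obeys

    dU/dt = (D/R^2) Lap_xi U - 2 (Rdot/R) U + reaction(U, xi R)

with zero-flux ends.  The two radius ODEs are co-integrated.

Time stepping is a splitting scheme, first order in dt: radii advance by
explicit Euler (with sub-stepping when a radius would change by more than
the configured guard fraction), the dilution factor is applied exactly as
``U <- U (R_old/R_new)^2``, and diffusion plus linear degradation are
advanced implicitly (banded solves) with the nonlinear productions
explicit.  With reactions disabled the scheme conserves the discrete mass
``2 pi R^2 sum V_j U_j`` of every species to machine precision.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0, i1, k0, k1 as bessel_k1

from . import kinetics
from .grid import RadialGrid
from .params import Parameters
from .scenarios import Scenario, ScenarioKinetics
from .state import MeristemState, Trajectory

__all__ = [
    "oc_proliferation_integral",
    "r_rhs",
    "rhs_on_reference",
    "integrate",
    "wus_bessel_oracle",
    "cz_fraction",
]


def cz_fraction(grid: RadialGrid, u1: np.ndarray, theta: float | None) -> float:
    """Fraction of meristem area where CLV3 exceeds the frozen threshold."""
    if theta is None:
        return float("nan")
    mask = u1 > theta
    return float(np.dot(grid.vol, mask) / np.sum(grid.vol))


def oc_proliferation_integral(
    kin: ScenarioKinetics, grid: RadialGrid, state: MeristemState
) -> float:
    """``int_{OC} k77/(1 + k7 u1) f(u2, u3) dx`` over the disc of radius r."""
    p = kin.p
    u1 = np.maximum(kin.u1_for_oc(state.u1), 0.0)
    integrand = p.k77 / (1.0 + p.k7 * u1) * kin.f_gate(
        np.maximum(state.u2, 0.0), np.maximum(state.u3, 0.0)
    )
    return grid.partial_disc_integral(integrand, state.R, state.r / state.R)


def r_rhs(
    r: float,
    R: float,
    u1: np.ndarray,
    u2: np.ndarray,
    u3: np.ndarray,
    p: Parameters,
    grid: RadialGrid | None = None,
) -> float:
    """OC radius growth rate from the nodal fields (wild-type couplings)."""
    if grid is None:
        grid = RadialGrid(len(u1) - 1)
    state = MeristemState(0.0, R, r, grid.xi, np.stack([np.zeros_like(u1), u1, u2, u3]))
    integral = oc_proliferation_integral(ScenarioKinetics(p), grid, state)
    return kinetics.r_rhs_from_integral(r, R, integral, p)


def _productions(
    kin: ScenarioKinetics, grid: RadialGrid, state: MeristemState
) -> np.ndarray:
    """Nonlinear production terms of the four species (no degradation)."""
    u = np.maximum(state.u, 0.0)  # reactions see clipped concentrations
    rho = grid.xi * state.R
    prod = np.empty_like(state.u)
    prod[0] = kin.wus_production(rho, state.r)
    prod[1] = kin.clv3_production(u[0])
    prod[2] = kin.ck_production(u[0], u[3])
    prod[3] = kin.hec_production(u[0])
    return prod


def _radius_rates(
    kin: ScenarioKinetics, grid: RadialGrid, state: MeristemState
) -> tuple[float, float]:
    p = kin.p
    I0 = grid.disc_integral(state.u0, state.R)
    I2 = grid.disc_integral(state.u2, state.R)
    Rdot = kinetics.R_rhs(state.R, kin.wus_integral_for_R(I0), I2, p)
    oc = oc_proliferation_integral(kin, grid, state)
    rdot = kinetics.r_rhs_from_integral(state.r, state.R, oc, p)
    return Rdot, rdot


def rhs_on_reference(
    state: MeristemState,
    scenario: Scenario | None,
    p: Parameters,
    grid: RadialGrid | None = None,
) -> tuple[np.ndarray, float, float]:
    """Instantaneous time derivatives ``(du, Rdot, rdot)`` on the reference grid.

    ``du`` has shape ``(4, n_r + 1)``; each row is diffusion + dilution +
    reaction for one species.  Mainly used for diagnostics and testing --
    :func:`integrate` advances the same physics by operator splitting.
    """
    if not (np.all(np.isfinite(state.u)) and np.isfinite(state.R)):
        raise FloatingPointError("non-finite state passed to rhs_on_reference")
    kin = ScenarioKinetics(p, scenario)
    if grid is None:
        grid = RadialGrid(state.xi.size - 1)
    Rdot, rdot = _radius_rates(kin, grid, state)
    prod = _productions(kin, grid, state)
    degr = kin.degradation
    du = np.empty_like(state.u)
    D = (p.D0, p.D1, p.D2, p.D3)
    for i in range(4):
        du[i] = (
            D[i] / state.R**2 * grid.apply_laplacian(state.u[i])
            - 2.0 * (Rdot / state.R) * state.u[i]
            + prod[i]
            - degr[i] * state.u[i]
        )
    return du, Rdot, rdot


def integrate(
    state0: MeristemState,
    scenario: Scenario | None,
    p: Parameters,
    t_end: float,
    *,
    sample_every: float | None = None,
    snapshot_times: list[float] | None = None,
    radius_drive=None,
    reactions: bool = True,
) -> Trajectory:
    """Advance the fully coupled system from ``state0`` to time ``t_end``.

    Parameters
    ----------
    sample_every : float, optional
        Interval at which states/scalars are recorded (default: 20 base
        steps).  The initial and final states are always recorded.
    snapshot_times : list of float, optional
        Additional times at which a state must be recorded exactly.
    radius_drive : callable, optional
        ``radius_drive(t, state) -> (Rdot, rdot)`` overriding the radius
        ODEs; used to prescribe domain motion in verification runs.
    reactions : bool
        When False, all production and degradation terms are disabled and
        only diffusion + dilution act (mass-conservation checks).
    """
    if t_end <= state0.t:
        raise ValueError("t_end must exceed the initial time")
    kin = ScenarioKinetics(p, scenario)
    grid = RadialGrid(state0.xi.size - 1)
    num = p.numerics
    if sample_every is None:
        sample_every = 20 * num.dt
    marks = {round(state0.t + k * sample_every, 12)
             for k in range(1, int(np.ceil((t_end - state0.t) / sample_every)) + 1)}
    marks |= set(snapshot_times or [])
    marks.add(t_end)
    marks = sorted(m for m in marks if state0.t < m <= t_end + 1e-12)

    D = (p.D0, p.D1, p.D2, p.D3)
    degr = kin.degradation if reactions else (0.0, 0.0, 0.0, 0.0)

    state = state0.copy()
    traj = Trajectory()
    traj.append(state.copy(), _record(kin, grid, state))

    for mark in marks:
        while state.t < mark - 1e-12:
            dt = min(num.dt, mark - state.t)
            if radius_drive is not None:
                Rdot, rdot = radius_drive(state.t, state)
            else:
                Rdot, rdot = _radius_rates(kin, grid, state)
            if not (np.isfinite(Rdot) and np.isfinite(rdot)):
                raise FloatingPointError(f"non-finite radius rate at t={state.t}")
            # sub-step so neither radius moves more than the guard fraction
            scale = max(abs(Rdot) / state.R, abs(rdot) / state.r) * dt
            if scale > num.radius_guard:
                dt = dt * num.radius_guard / scale
                if dt < 1e-12:
                    raise RuntimeError(
                        f"time step underflow at t={state.t} (radii moving too fast)"
                    )
            R_new = state.R + dt * Rdot
            r_new = state.r + dt * rdot
            if R_new <= 0:
                raise RuntimeError(f"meristem radius collapsed at t={state.t}")
            # the smoothstep slowdown keeps rdot -> 0 as r -> R, but R itself
            # may keep shrinking; enforce the physical constraint r <= R
            r_new = min(max(r_new, 1e-12), R_new)
            # exact dilution of concentrations on the dilating disc
            dil = (state.R / R_new) ** 2
            u = state.u * dil
            state.R, state.r = R_new, r_new
            if reactions:
                state.u = u  # productions evaluated after dilution
                prod = _productions(kin, grid, state)
            else:
                prod = 0.0
            # implicit diffusion + degradation, explicit production
            for i in range(4):
                rhs = u[i] + (dt * prod[i] if reactions else 0.0)
                state.u[i] = grid.helmholtz_solve(
                    1.0 + dt * degr[i], dt * D[i] / state.R**2, rhs
                )
            state.t += dt
        state.t = mark
        traj.append(state.copy(), _record(kin, grid, state))
    return traj


def _record(kin: ScenarioKinetics, grid: RadialGrid, state: MeristemState) -> dict:
    I0 = grid.disc_integral(state.u0, state.R)
    I2 = grid.disc_integral(state.u2, state.R)
    return {
        "t": state.t,
        "R": state.R,
        "r": state.r,
        "int_u0": I0,
        "int_u2": I2,
        "cz_fraction": cz_fraction(grid, state.u1, kin.p.numerics.cz_threshold),
        "n_cells": np.pi * state.R**2,
    }


def wus_bessel_oracle(
    R: float, r: float, p: Parameters, n_r: int | None = None
) -> np.ndarray:
    """Closed-form steady WUS profile for a sharp OC source on a fixed disc.

    For ``w = 0`` and frozen radii the stationary WUS equation is linear:
    inside the source ``u = k1/d0 + A I0(lam rho)``, outside
    ``u = B I0(lam rho) + C K0(lam rho)`` with ``lam = sqrt(d0/D0)``; A, B,
    C follow from C1 matching at ``rho = r`` and zero flux at ``rho = R``.
    Serves as the independent oracle for the elliptic grid solver.
    """
    if not 0 < r < R:
        raise ValueError("need 0 < r < R for the two-region closed form")
    if n_r is None:
        n_r = p.numerics.n_r
    lam = np.sqrt(p.d0 / p.D0)
    plateau = p.k1 / p.d0
    x_r, x_R = lam * r, lam * R
    # unknowns (A, B, C)
    M = np.array(
        [
            [i0(x_r), -i0(x_r), -k0(x_r)],
            [i1(x_r), -i1(x_r), bessel_k1(x_r)],
            [0.0, i1(x_R), -bessel_k1(x_R)],
        ]
    )
    rhs = np.array([-plateau, 0.0, 0.0])
    A, B, C = np.linalg.solve(M, rhs)
    xi = np.linspace(0.0, 1.0, n_r + 1)
    rho = xi * R
    x = lam * rho
    inner = plateau + A * i0(x)
    outer = B * i0(x) + C * k0(x)
    # K0 diverges at rho=0 but those nodes are inner anyway
    outer = np.where(rho > 0, outer, inner)
    return np.where(rho <= r, inner, outer)
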