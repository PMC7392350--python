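"""Reaction kinetics, gating functions, geometry map and radius ODE rates.

Pure functions of concentrations and parameters; nothing here knows about
the radial discretization.  All accept scalars or numpy arrays.

Signal roles: WUS (``u0``) is produced inside the organizing center and
induces CLV3 (``u1``) production through a steep sigmoid; cytokinin
(``u2``) production requires WUS and is amplified by HECATE (``u3``);
HEC production is repressed by WUS.  The two gates ``f`` (CK/HEC action on
OC proliferation) and ``g`` (CK-dependent organ outflux) translate signal
levels into growth-rate modifiers.
"""

from __future__ import annotations

import numpy as np

from .params import Parameters

__all__ = [
    "clv3_production",
    "ck_production",
    "hec_production",
    "wus_source",
    "f_gate",
    "g_step",
    "slowdown",
    "R_rhs",
    "r_rhs_from_integral",
    "cap_to_disc_radius",
]


def clv3_production(u0, p: Parameters):
    """CLV3 production rate: sigmoid in WUS, ``k2 / (1 + exp(-(u0-k3) k4))``.

    Half-maximal at ``u0 = k3``; the published steepness ``k4 = 100`` makes
    this effectively a switch at the WUS threshold.
    """
    # clip the exponent: k4=100 overflows exp() for moderate u0 deficits
    z = np.clip(-(np.asarray(u0, dtype=float) - p.k3) * p.k4, -700.0, 700.0)
    return p.k2 / (1.0 + np.exp(z))


def ck_production(u0, u3, p: Parameters):
    """Cytokinin production: ``(1 + k9 u3/(1 + k10 u3)) * k11 u0/(1 + k12 u0)``.

    Vanishes without WUS; saturates at ``(1 + k9/k10) k11/k12``.  The HEC
    factor models amplification of CK signalling by HECATE, with a floor of
    1 so CK is still produced in the HEC loss-of-function mutant.
    """
    u0 = np.asarray(u0, dtype=float)
    u3 = np.asarray(u3, dtype=float)
    return (1.0 + p.k9 * u3 / (1.0 + p.k10 * u3)) * p.k11 * u0 / (1.0 + p.k12 * u0)


def hec_production(u0, p: Parameters):
    """HEC production ``k13 / (1 + k14 u0)``: repressed by WUS."""
    return p.k13 / (1.0 + p.k14 * np.asarray(u0, dtype=float))


def wus_source(rho, r: float, p: Parameters, w: float | None = None):
    """WUS source term ``k1 * chi_{OC}(rho)`` with a piecewise-linear ramp.

    The indicator of the OC disc is smoothed over a total width ``w``
    centered at ``rho = r``: full rate ``k1`` for ``rho <= r - w/2``, zero
    for ``rho >= r + w/2``, linear in between.  ``w = 0`` recovers the
    sharp indicator (value ``k1`` for ``rho <= r``).
    """
    if w is None:
        w = p.numerics.indicator_width
    rho = np.asarray(rho, dtype=float)
    if w == 0.0:
        return np.where(rho <= r, p.k1, 0.0)
    frac = np.clip((r + 0.5 * w - rho) / w, 0.0, 1.0)
    return p.k1 * frac


def f_gate(u2, u3, p: Parameters):
    """OC proliferation gate ``max(min(aa*u2 + ab, k16*u3 + k15), k17)``.

    The CK arm ``aa*u2 + ab`` is capped by the HEC-dependent ceiling
    ``k16*u3 + k15``; the floor ``k17`` keeps OC proliferation positive
    when both signals are absent.  Non-decreasing in both arguments.
    """
    return np.maximum(
        np.minimum(p.aa * np.asarray(u2, dtype=float) + p.ab,
                   p.k16 * np.asarray(u3, dtype=float) + p.k15),
        p.k17,
    )


def g_step(x, p: Parameters | None = None):
    """CK-dependent organ-outflux modifier: piecewise linear, in [0.9, 1.1].

    Branches: 1.1 on [0, 1]; 1.1 - 0.1(x-1) on [1, 2]; 1 on [2, 10];
    1 - (x-10)/20 on [10, 12]; 0.9 on [12, inf).  Low total CK means more
    differentiation (larger g, smaller meristem); high total CK the
    opposite.  Continuous at all breakpoints.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("g_step argument must be non-negative")
    out = np.full_like(x, 1.0)
    out = np.where(x <= 1.0, 1.1, out)
    mid = (x > 1.0) & (x < 2.0)
    out = np.where(mid, 1.1 - 0.1 * (x - 1.0), out)
    hi = (x > 10.0) & (x < 12.0)
    out = np.where(hi, 1.0 - (x - 10.0) / 20.0, out)
    out = np.where(x >= 12.0, 0.9, out)
    return out if out.ndim else float(out)


def slowdown(gap, delta: float):
    """Smoothstep factor s(gap) in [0, 1] with s(0) = 0, s(gap >= delta) = 1.

    Multiplies the OC radius rate so that ``r`` cannot overtake ``R``:
    the OC physically cannot outgrow the meristem.
    """
    y = np.clip(np.asarray(gap, dtype=float) / delta, 0.0, 1.0)
    out = y * y * (3.0 - 2.0 * y)
    return out if out.ndim else float(out)


def R_rhs(R: float, I0: float, I2: float, p: Parameters) -> float:
    """Growth rate of the meristem radius.

    ``[k21/(1 + k23*I0) - pp * (1+R^2)/(1+R0^2) * g(I2)] * R/2`` where
    ``I0 = \\int u0 dx`` (total WUS, which slows cell production) and
    ``I2 = \\int u2 dx`` (total CK, which modulates organ outflux via g).
    The ``R^2`` factor encodes that organ formation scales with meristem
    area.  Strictly decreasing in both ``I0`` and ``R``.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    growth = p.k21 / (1.0 + p.k23 * I0)
    diff = p.pp * (1.0 + R * R) / (1.0 + p.R0 * p.R0) * g_step(I2)
    return (growth - diff) * R / 2.0


def r_rhs_from_integral(r: float, R: float, oc_integral: float, p: Parameters) -> float:
    """Growth rate of the OC radius given the OC proliferation integral.

    ``s(R - r) * [oc_integral - pdbasic] * r/2`` where ``oc_integral`` is
    ``\\int_{OC} k77/(1 + k7 u1) f(u2, u3) dx`` (CLV3 represses, CK/HEC via
    ``f`` promote OC growth) and ``s`` is the smoothstep slowdown with
    width ``slowdown_delta * R``.  Identically zero at ``r = R``.
    """
    if r > R:
        raise ValueError("OC radius r cannot exceed meristem radius R")
    s = slowdown(R - r, p.numerics.slowdown_delta * R)
    return s * (oc_integral - p.pdbasic) * r / 2.0


def cap_to_disc_radius(r_c: float, h_c: float) -> float:
    """Flatten a spherical cap (radius ``r_c``, height ``h_c``) to a disc.

    The SAM surface is a spherical cap; the model works on its flattened
    image, whose radius is the arc length from pole to rim:
    ``R = r_c * arccos((r_c - h_c)/r_c)``.
    """
    if r_c <= 0:
        raise ValueError("cap radius must be positive")
    if not 0.0 <= h_c <= 2.0 * r_c:
        raise ValueError("cap height must lie in [0, 2*r_c]")
    return r_c * float(np.arccos((r_c - h_c) / r_c))
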