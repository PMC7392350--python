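"""Quasi-steady phase-plane analysis of the radius dynamics.

Assuming the signal fields equilibrate instantaneously for given radii,
the growth system reduces to a planar flow ``(Rdot, rdot) propto
(G(R,r) R, F(R,r) r)`` where F and G are the radius-ODE brackets evaluated
on the quasi-steady fields.  Linearizing at a common zero ``(R*, r*)``
gives the Jacobian

    A = [[R* dG/dR, R* dG/dr],
         [r* dF/dR, r* dF/dr]]

and the equilibrium is locally stable iff ``trace A < 0`` and
``det A > 0``.  The partial derivatives are computed by central finite
differences of the quasi-steady solves; this reduction is used for the
analysis only -- all simulations integrate the fully coupled system.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibrium import quasi_steady_solve
from .params import Parameters
from .scenarios import Scenario

DEFAULT_H = 1e-3  # FD step, relative to each radius

__all__ = ["StabilityReport", "fg_map", "classify"]


@dataclass
class StabilityReport:
    """Jacobian entries and trace/determinant classification at (R*, r*)."""

    R_star: float
    r_star: float
    dG_dR: float
    dG_dr: float
    dF_dR: float
    dF_dr: float
    A: tuple[tuple[float, float], tuple[float, float]]
    trace: float
    det: float
    stable: bool
    h: float

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(np.asarray(self.A))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def fg_map(
    R_grid,
    r_grid,
    p: Parameters,
    scenario: Scenario | None = None,
) -> pd.DataFrame:
    """Tabulate F and G over a rectangular (R, r) grid.

    Points with ``r > R`` are reported as NaN (outside the physical
    region).  The output is tidy (columns R, r, F, G), ready for contour
    plotting of the zero level sets.
    """
    R_grid = np.atleast_1d(np.asarray(R_grid, dtype=float))
    r_grid = np.atleast_1d(np.asarray(r_grid, dtype=float))
    if R_grid.size == 0 or r_grid.size == 0:
        raise ValueError("empty radius grid")
    if np.any(R_grid <= 0) or np.any(r_grid <= 0):
        raise ValueError("radii must be positive")
    rows = []
    for R in R_grid:
        for r in r_grid:
            if r > R:
                F = G = float("nan")
            else:
                qs = quasi_steady_solve(R, r, p, scenario)
                F, G = qs.F, qs.G
            rows.append({"R": R, "r": r, "F": F, "G": G})
    return pd.DataFrame(rows)


def classify(
    p: Parameters,
    R_star: float,
    r_star: float,
    h: float = DEFAULT_H,
    *,
    equilibrium_tol: float = 1e-6,
) -> StabilityReport:
    """Finite-difference Jacobian and stability verdict at an equilibrium.

    ``h`` is the central-difference step relative to each radius; steps
    that would move a radius by more than 10% are rejected, as are inputs
    where (R*, r*) is not an F = G = 0 point to ``equilibrium_tol``.
    """
    if not 0 < h <= 0.1:
        raise ValueError("relative FD step h must lie in (0, 0.1]")
    base = quasi_steady_solve(R_star, r_star, p)
    if abs(base.F) > equilibrium_tol or abs(base.G) > equilibrium_tol:
        raise ValueError(
            f"(R*, r*) is not an equilibrium: F={base.F:.3e}, G={base.G:.3e}"
        )
    hR, hr = h * R_star, h * r_star
    Rp = quasi_steady_solve(R_star + hR, r_star, p)
    Rm = quasi_steady_solve(R_star - hR, r_star, p)
    rp = quasi_steady_solve(R_star, r_star + hr, p)
    rm = quasi_steady_solve(R_star, r_star - hr, p)
    dF_dR = (Rp.F - Rm.F) / (2 * hR)
    dG_dR = (Rp.G - Rm.G) / (2 * hR)
    dF_dr = (rp.F - rm.F) / (2 * hr)
    dG_dr = (rp.G - rm.G) / (2 * hr)
    A = (
        (R_star * dG_dR, R_star * dG_dr),
        (r_star * dF_dR, r_star * dF_dr),
    )
    trace = A[0][0] + A[1][1]
    det = A[0][0] * A[1][1] - A[0][1] * A[1][0]
    return StabilityReport(
        R_star=R_star,
        r_star=r_star,
        dG_dR=dG_dR,
        dG_dr=dG_dr,
        dF_dR=dF_dR,
        dF_dr=dF_dr,
        A=A,
        trace=trace,
        det=det,
        stable=bool(trace < 0 and det > 0),
        h=h,
    )
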