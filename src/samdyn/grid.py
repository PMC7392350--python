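"""Finite-volume machinery on the normalized radial coordinate.

The growing disc is mapped to the fixed reference coordinate
``xi = rho / R(t)`` in [0, 1].  Node ``j`` sits at ``xi_j = j/n``; its
control volume is the annulus between the half-integer faces, with exact
radial measure ``V_j = (xi_{j+1/2}^2 - xi_{j-1/2}^2)/2`` (so a disc
integral is ``2 pi R^2 sum_j V_j U_j``).  Diffusive fluxes through the
faces telescope, which makes the discrete total mass of a purely diffusing
species exactly conserved; the symmetry axis and the outer rim carry
zero-flux (homogeneous Neumann) conditions.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded

__all__ = ["RadialGrid"]


class RadialGrid:
    """Uniform node-centered grid on xi in [0, 1] with ``n`` cells."""

    def __init__(self, n: int):
        if n < 4:
            raise ValueError("need at least 4 radial cells")
        self.n = int(n)
        self.xi = np.linspace(0.0, 1.0, self.n + 1)
        self.dxi = 1.0 / self.n
        faces = self.xi[:-1] + 0.5 * self.dxi  # interior faces xi_{j+1/2}
        self.faces = faces
        bounds = np.concatenate(([0.0], faces, [1.0]))
        # exact cell volumes for the measure xi dxi
        self.vol = 0.5 * (bounds[1:] ** 2 - bounds[:-1] ** 2)

    # -- quadrature ---------------------------------------------------
    def disc_integral(self, u: np.ndarray, R: float) -> float:
        """Integral of a radial field over the whole disc of radius R."""
        return float(2.0 * np.pi * R * R * np.dot(self.vol, u))

    def partial_disc_integral(self, u: np.ndarray, R: float, xi_cut: float) -> float:
        """Integral over the concentric disc rho <= xi_cut * R.

        Trapezoid on the sub-grid, with the field linearly interpolated at
        the cut radius (which generally falls between nodes).
        """
        xi_cut = min(max(xi_cut, 0.0), 1.0)
        j = int(np.floor(xi_cut / self.dxi))
        j = min(j, self.n - 1)
        xi_full = self.xi[: j + 1]
        u_full = u[: j + 1]
        acc = np.trapezoid(u_full * xi_full, xi_full) if j > 0 else 0.0
        # partial last interval [xi_j, xi_cut]
        if xi_cut > self.xi[j]:
            frac = (xi_cut - self.xi[j]) / self.dxi
            u_cut = u[j] + frac * (u[j + 1] - u[j])
            acc += 0.5 * (u[j] * self.xi[j] + u_cut * xi_cut) * (xi_cut - self.xi[j])
        return float(2.0 * np.pi * R * R * acc)

    # -- diffusion ----------------------------------------------------
    def laplacian_tridiag(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Tridiagonal radial Laplacian ``(1/xi) d/dxi (xi d/dxi)`` (FV form).

        Returns (lower, main, upper) diagonals such that
        ``(L u)_j = (lower_j u_{j-1} + main_j u_j + upper_j u_{j+1})``,
        with zero-flux closures at both ends.
        """
        n = self.n
        w = self.faces / (self.dxi * self.vol[:-1])  # flux j+1/2 into cell j
        e = self.faces / (self.dxi * self.vol[1:])   # flux j+1/2 into cell j+1
        lower = np.zeros(n + 1)
        main = np.zeros(n + 1)
        upper = np.zeros(n + 1)
        upper[:-1] += w
        main[:-1] -= w
        lower[1:] += e
        main[1:] -= e
        return lower, main, upper

    def apply_laplacian(self, u: np.ndarray) -> np.ndarray:
        lower, main, upper = self.laplacian_tridiag()
        out = main * u
        out[:-1] += upper[:-1] * u[1:]
        out[1:] += lower[1:] * u[:-1]
        return out

    def helmholtz_solve(self, alpha: float, beta: float, rhs: np.ndarray) -> np.ndarray:
        """Solve ``(alpha I - beta L) u = rhs`` (banded direct solve)."""
        lower, main, upper = self.laplacian_tridiag()
        n = self.n + 1
        ab = np.zeros((3, n))
        ab[0, 1:] = -beta * upper[:-1]
        ab[1, :] = alpha - beta * main
        ab[2, :-1] = -beta * lower[1:]
        return solve_banded((1, 1), ab, rhs)
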