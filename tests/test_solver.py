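"""Radial finite-volume solver: conservation, dilution, oracles, convergence."""

import numpy as np
import pytest
from scipy.linalg import solve_banded

from samdyn import Parameters, integrate, rhs_on_reference, wus_bessel_oracle
from samdyn.grid import RadialGrid
from samdyn.equilibrium import quasi_steady_solve
from samdyn.state import MeristemState


def make_state(n=100, R=2.0, r=0.8, profile=None):
    g = RadialGrid(n)
    if profile is None:
        profile = 1.0 + np.cos(np.pi * g.xi)  # smooth, non-uniform
    u = np.stack([profile, 0.5 * profile, 0.2 * profile + 0.1, profile**2])
    return MeristemState(0.0, R, r, g.xi, u)


class TestGrid:
    def test_cell_volumes_tile_the_disc(self):
        g = RadialGrid(64)
        assert g.vol.sum() == pytest.approx(0.5, rel=1e-14)

    def test_disc_integral_of_constant(self):
        g = RadialGrid(64)
        R = 3.0
        assert g.disc_integral(np.ones(65), R) == pytest.approx(np.pi * R * R)

    def test_partial_integral_of_constant(self):
        g = RadialGrid(128)
        R = 2.0
        for xi_cut in (0.17, 0.5, 0.803):
            got = g.partial_disc_integral(np.ones(129), R, xi_cut)
            assert got == pytest.approx(np.pi * (xi_cut * R) ** 2, rel=1e-9)

    def test_laplacian_annihilates_constants(self):
        g = RadialGrid(50)
        # stencil entries are O(n^2), so cancellation leaves O(eps n^2)
        assert np.allclose(g.apply_laplacian(np.ones(51)), 0.0, atol=1e-9)

    def test_laplacian_is_discretely_conservative(self, rng):
        g = RadialGrid(50)
        u = rng.random(51)
        assert g.vol @ g.apply_laplacian(u) == pytest.approx(0.0, abs=1e-12)


class TestRhsOnReference:
    def test_dilution_of_uniform_field(self, fitted):
        # uniform field, reactions cancelled by matching production=0/degr=0
        # -> check the dilution part via prescribed analysis on integrate;
        # here: rhs linearity check instead through the transport identity
        state = make_state()
        du, Rdot, rdot = rhs_on_reference(state, None, fitted.params)
        assert du.shape == state.u.shape
        assert np.all(np.isfinite(du))

    def test_reynolds_transport_identity(self, fitted):
        """With reactions off, total mass rate of each species is zero."""
        p = fitted.params
        state = make_state(n=200)
        g = RadialGrid(200)
        kin_prod_free = state.copy()
        # evaluate only diffusion+dilution: subtract reaction terms explicitly
        du, Rdot, rdot = rhs_on_reference(state, None, p)
        from samdyn.scenarios import ScenarioKinetics
        from samdyn.solver import _productions

        kin = ScenarioKinetics(p)
        prod = _productions(kin, g, state)
        degr = kin.degradation
        for i in range(4):
            du_transport = du[i] - prod[i] + degr[i] * state.u[i]
            # d/dt [2 pi R^2 int U xi dxi] = 2 pi R^2 int dU xi + 2 R Rdot ...
            mass_rate = (
                2 * np.pi * state.R**2 * (g.vol @ du_transport)
                + 4 * np.pi * state.R * Rdot * (g.vol @ state.u[i])
            )
            scale = 2 * np.pi * state.R**2 * (g.vol @ state.u[i])
            assert abs(mass_rate) < 1e-10 * max(scale, 1.0)


class TestIntegrate:
    def test_mass_conserved_on_growing_disc(self, fitted):
        """Reactions off, prescribed growth by 50%: exact mass bookkeeping."""
        p = fitted.params
        state = fitted.state.copy()
        state.t = 0.0
        g = RadialGrid(state.xi.size - 1)
        m0 = [g.disc_integral(state.u[i], state.R) for i in range(4)]
        drive = lambda t, s: (0.05 * s.R, 0.0)
        t_end = np.log(1.5) / 0.05  # exact 50% growth of R
        traj = integrate(state, None, p, t_end, radius_drive=drive,
                         reactions=False)
        fin = traj.final
        assert fin.R / state.R == pytest.approx(1.5, rel=1e-3)
        for i in range(4):
            m1 = g.disc_integral(fin.u[i], fin.R)
            assert abs(m1 - m0[i]) / m0[i] < 1e-9

    def test_dilution_exactness_uniform_field(self, fitted):
        """U R^2 invariant for a uniform profile under pure dilation."""
        p = fitted.params
        g = RadialGrid(100)
        u = np.stack([np.full(101, c) for c in (1.0, 0.5, 0.2, 2.0)])
        state = MeristemState(0.0, 2.0, 0.8, g.xi, u)
        drive = lambda t, s: (0.08 * s.R, 0.0)
        traj = integrate(state, None, p, 5.0, radius_drive=drive,
                         reactions=False)
        fin = traj.final
        for i in range(4):
            np.testing.assert_allclose(
                fin.u[i] * fin.R**2, u[i, 0] * 2.0**2, rtol=1e-12
            )

    def test_positivity(self, fitted):
        state = fitted.state.copy()
        state.t = 0.0
        traj = integrate(state, None, fitted.params, 5.0)
        for s in traj.states:
            assert s.u.min() > -1e-10

    def test_equilibrium_is_fixed_point(self, fitted):
        state = fitted.state.copy()
        state.t = 0.0
        traj = integrate(state, None, fitted.params, 10.0)
        fin = traj.final
        assert fin.R == pytest.approx(fitted.R_star, rel=1e-6)
        assert fin.r == pytest.approx(fitted.r_star, rel=1e-5)
        np.testing.assert_allclose(fin.u, state.u, atol=1e-6)

    def test_rejects_bad_horizon(self, fitted):
        state = fitted.state.copy()
        with pytest.raises(ValueError):
            integrate(state, None, fitted.params, state.t - 1.0)

    def test_temporal_order_one(self, fitted):
        """Step-size refinement of the full nonlinear system converges at
        first order (errors measured against a fine-step reference run)."""
        state0 = fitted.state.copy()
        state0.t = 0.0
        state0.R *= 1.03  # leave the fixed point so the dynamics move

        def final_at(dt):
            p = fitted.params.replace(dt=dt)
            st = state0.copy()
            traj = integrate(st, None, p, 2.0)
            return np.concatenate([[traj.final.R, traj.final.r],
                                   traj.final.u.ravel()])

        ref = final_at(0.00125)
        errs = [np.max(np.abs(final_at(dt) - ref)) for dt in (0.04, 0.02, 0.01)]
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders > 0.8)


class TestBesselOracle:
    def test_matches_quasi_steady_solve(self, params):
        """Grid solve of the stationary WUS equation vs the closed form."""
        p = params.replace(indicator_width=0.0, n_r=400)
        for R, r in [(2.5, 0.95), (2.0, 0.5), (3.5, 1.4)]:
            oracle = wus_bessel_oracle(R, r, p)
            qs = quasi_steady_solve(R, r, p)
            err = np.max(np.abs(qs.u[0] - oracle)) / np.max(oracle)
            assert err < 0.01

    def test_near_full_source_approaches_plateau(self, params):
        p = params.replace(indicator_width=0.0, n_r=200)
        u = wus_bessel_oracle(2.0, 1.999, p)
        assert u[0] == pytest.approx(p.k1 / p.d0, rel=1e-3)
        assert u[-1] == pytest.approx(p.k1 / p.d0, rel=1e-2)

    def test_linear_in_source_rate(self, params):
        p1 = params.replace(indicator_width=0.0)
        p2 = p1.replace(k1=2 * p1.k1)
        np.testing.assert_allclose(
            wus_bessel_oracle(2.0, 0.7, p2), 2 * wus_bessel_oracle(2.0, 0.7, p1),
            rtol=1e-12,
        )

    def test_rejects_degenerate_radii(self, params):
        with pytest.raises(ValueError):
            wus_bessel_oracle(2.0, 2.0, params)

    def test_spatial_order_two_smooth_problem(self):
        """Manufactured smooth elliptic solution: error falls at order 2.

        u = cos(pi xi) satisfies the zero-flux conditions at both ends;
        the forcing for (d - (D/R^2) Lap) u is known in closed form.
        """
        d, D, R = 2.0, 0.5, 1.7
        errs = []
        for n in (50, 100, 200):
            g = RadialGrid(n)
            xi = g.xi
            exact = np.cos(np.pi * xi)
            lap = np.empty_like(xi)
            lap[1:] = (
                -np.pi * np.sin(np.pi * xi[1:]) / xi[1:]
                - np.pi**2 * np.cos(np.pi * xi[1:])
            )
            lap[0] = -2 * np.pi**2
            rhs = d * exact - (D / R**2) * lap
            got = g.helmholtz_solve(d, D / R**2, rhs)
            errs.append(np.max(np.abs(got - exact)))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders > 1.8)


class TestReferencePhysicalEquivalence:
    def test_one_step_matches_physical_ale(self, fitted):
        """One implicit diffusion step on the reference grid equals a
        conservative ALE step assembled directly in physical coordinates."""
        p = fitted.params
        n, R_old, r = 16, 2.0, 0.8
        g = RadialGrid(n)
        rng = np.random.default_rng(7)
        u = rng.random(n + 1)
        dt, Rdot = 0.01, 0.3
        R_new = R_old + dt * Rdot
        D = p.D0

        # reference-coordinate step (as in integrate): exact dilution then
        # implicit diffusion at R_new
        u_ref = g.helmholtz_solve(1.0, dt * D / R_new**2, u * (R_old / R_new) ** 2)

        # physical-coordinate conservative ALE: mesh nodes rho_j = xi_j R(t),
        # cell volumes V_j R^2; moving with the medium, so the update is
        # V^{n+1} u^{n+1} - dt * (diffusive fluxes at R_new) = V^n u^n
        rho_faces = g.faces * R_new
        drho = R_new * g.dxi
        vol_new = g.vol * R_new**2
        vol_old = g.vol * R_old**2
        lower = np.zeros(n + 1)
        main = vol_new.copy()
        upper = np.zeros(n + 1)
        w = dt * D * rho_faces / drho
        main[:-1] += w
        upper[:-1] -= w
        main[1:] += w
        lower[1:] -= w
        ab = np.zeros((3, n + 1))
        ab[0, 1:] = upper[:-1]
        ab[1] = main
        ab[2, :-1] = lower[1:]
        u_phys = solve_banded((1, 1), ab, vol_old * u)

        np.testing.assert_allclose(u_ref, u_phys, rtol=1e-13, atol=1e-14)
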