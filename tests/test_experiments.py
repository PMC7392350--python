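"""Scenario substitutions, phenotype metrics, suite plumbing, sensitivity."""

import numpy as np
import pytest

from samdyn import Scenario, apply_scenario
from samdyn.experiments import (
    SUITE_SCENARIOS,
    phenotype,
    run_scenario,
    sensitivity_sweep,
)
from samdyn.grid import RadialGrid
from samdyn.kinetics import clv3_production, f_gate
from samdyn.solver import cz_fraction
from samdyn.state import Trajectory


@pytest.fixture()
def sample_fields(rng):
    return [rng.uniform(0.0, 1.5, size=8) for _ in range(4)]


class TestApplyScenario:
    def test_wild_type_is_identity(self, params, sample_fields):
        u0, u1, u2, u3 = sample_fields
        wt = apply_scenario(params, Scenario())
        base = apply_scenario(params, None)
        np.testing.assert_allclose(wt.clv3_production(u0), base.clv3_production(u0))
        np.testing.assert_allclose(wt.ck_production(u0, u3), base.ck_production(u0, u3))
        np.testing.assert_allclose(wt.hec_production(u0), base.hec_production(u0))
        np.testing.assert_allclose(wt.f_gate(u2, u3), base.f_gate(u2, u3))
        assert wt.degradation == base.degradation

    def test_wus_oe_adds_constant_source(self, params):
        kin = apply_scenario(params, Scenario("wus_oe", c=2.9))
        # far outside the OC, with no physiological source, the rate is c
        outside = kin.wus_production(np.array([5.0]), 0.5, w=0.0)
        assert outside[0] == pytest.approx(2.9)

    def test_wus_lof_silences_downstream(self, params, sample_fields):
        u0, u1, u2, u3 = sample_fields
        kin = apply_scenario(params, Scenario("wus_lof"))
        np.testing.assert_allclose(
            kin.clv3_production(u0), clv3_production(0.0, params)
        )
        np.testing.assert_allclose(kin.ck_production(u0, u3), 0.0, atol=1e-12)
        np.testing.assert_allclose(kin.hec_production(u0), params.k13)
        assert kin.wus_integral_for_R(7.3) == 0.0

    def test_clv3_oe_scales_production(self, params, sample_fields):
        u0 = sample_fields[0]
        kin = apply_scenario(params, Scenario("clv3_oe", c=3.0))
        np.testing.assert_allclose(
            kin.clv3_production(u0), 3.0 * clv3_production(u0, params)
        )

    def test_clv3_lof_only_affects_oc_coupling(self, params, sample_fields):
        u0, u1, u2, u3 = sample_fields
        kin = apply_scenario(params, Scenario("clv3_lof"))
        np.testing.assert_allclose(kin.u1_for_oc(u1), 0.0, atol=1e-300)
        # production terms untouched
        np.testing.assert_allclose(
            kin.clv3_production(u0), clv3_production(u0, params)
        )

    def test_ck_scenarios(self, params, sample_fields):
        u0, u1, u2, u3 = sample_fields
        lof = apply_scenario(params, Scenario("ck_lof"))
        np.testing.assert_allclose(lof.ck_production(u0, u3), 0.0, atol=1e-300)
        low = apply_scenario(params, Scenario("ck_low_deg", d2_factor=0.65))
        assert low.degradation[2] == pytest.approx(0.65 * params.d2)

    def test_hec_scenarios(self, params, sample_fields):
        u0, u1, u2, u3 = sample_fields
        lof = apply_scenario(params, Scenario("hec_lof"))
        np.testing.assert_allclose(lof.hec_production(u0), 0.0, atol=1e-300)
        oe = apply_scenario(params, Scenario("hec_oe", c=3.0))
        np.testing.assert_allclose(
            oe.hec_production(u0),
            apply_scenario(params, None).hec_production(u0)
            + 3.0 * clv3_production(u0, params),
        )

    def test_no_direct_freezes_f_gate(self, params, sample_fields):
        u2, u3 = sample_fields[2], sample_fields[3]
        kin = apply_scenario(
            params, Scenario("hec_oe_no_direct", c=0.05, u3_frozen=0.17)
        )
        np.testing.assert_allclose(
            kin.f_gate(u2, u3), f_gate(u2, 0.17, params)
        )

    def test_rejects_unknown_kind(self):
        with pytest.raises(ValueError):
            Scenario("wus_overdrive")

    def test_rejects_bad_strengths(self):
        with pytest.raises(ValueError):
            Scenario("wus_oe", c=-1.0)
        with pytest.raises(ValueError):
            Scenario("ck_low_deg", d2_factor=1.5)
        with pytest.raises(ValueError):
            Scenario("wus_oe", d2_factor=0.5)


class TestPhenotype:
    def _traj_with_u1(self, fitted, value):
        s = fitted.state.copy()
        s.u[1] = value
        traj = Trajectory()
        traj.append(s, {"t": s.t})
        return traj

    def test_cz_fraction_extremes(self, fitted):
        theta = fitted.theta
        full = phenotype(self._traj_with_u1(fitted, theta * 2), fitted.params)
        none = phenotype(self._traj_with_u1(fitted, 0.0), fitted.params)
        assert full.cz_fraction == 1.0
        assert none.cz_fraction == 0.0

    def test_cz_fraction_decreasing_in_threshold(self, fitted, grid):
        u1 = fitted.state.u1
        fracs = [
            cz_fraction(grid, u1, th)
            for th in np.linspace(0.05, 0.7, 10)
        ]
        assert np.all(np.diff(fracs) <= 0)

    def test_wildtype_phenotype(self, fitted):
        traj = fitted.simulate("wild_type", t_end=5.0)
        m = fitted.phenotype(traj)
        assert m.cz_fraction == pytest.approx(0.10, abs=0.03)
        assert m.cell_count == pytest.approx(np.pi * m.R_final**2)
        # proliferation decreases where WUS is high (center)
        assert m.alpha_profile[0] < m.alpha_profile[-1]
        assert np.all(m.alpha_profile > 0)

    def test_empty_trajectory_rejected(self, fitted):
        with pytest.raises(ValueError):
            phenotype(Trajectory(), fitted.params)


class TestSuitePlumbing:
    def test_suite_scenarios_cover_all_kinds(self):
        from samdyn.scenarios import KINDS

        assert set(SUITE_SCENARIOS) == set(KINDS)

    def test_run_scenario_fills_frozen_hec(self, fitted):
        traj = run_scenario(
            fitted.params, fitted.state,
            Scenario("hec_oe_no_direct", c=0.05), t_end=0.5,
        )
        assert len(traj) > 1

    def test_wus_oe_levels_reach_distinct_states(self, fitted):
        finals = []
        for c in (0.5, 2.9, 5.0):
            traj = run_scenario(
                fitted.params, fitted.state, Scenario("wus_oe", c=c),
                t_end=30.0,
            )
            finals.append(
                (round(traj.final.r, 3),
                 round(float(traj.final.u1.max()), 3))
            )
        assert len(set(finals)) == 3

    def test_clv3_zone_expands_radially_under_wus_oe(self, fitted):
        """Transient after switching on ubiquitous WUS production: the
        outer boundary of the high-CLV3 zone moves monotonically outward."""
        traj = run_scenario(
            fitted.params, fitted.state, Scenario("wus_oe", c=2.9),
            t_end=1.0, snapshot_times=[0.2, 0.4, 0.6, 0.8, 1.0],
        )
        theta = fitted.theta
        edges = []
        for s in traj.states:
            above = np.flatnonzero(s.u1 > theta)
            edges.append(s.xi[above.max()] * s.R if above.size else 0.0)
        assert np.all(np.diff(edges) > 0)


class TestSensitivitySweep:
    def test_row_shape_and_zero_perturbation(self, fitted):
        df = sensitivity_sweep(
            fitted.params, fitted.state, fractions=(0.0,), parameters=["d0"]
        )
        assert len(df) == 1
        row = df.iloc[0]
        assert row.dR == 0.0 and row.dr == 0.0 and row.converged

    def test_opposite_shifts_for_opposite_perturbations(self, fitted):
        df = sensitivity_sweep(
            fitted.params, fitted.state, fractions=(-0.01, 0.01),
            parameters=["d0"], t_end=120.0,
        )
        dRs = df.sort_values("fraction").dR.to_numpy()
        assert np.sign(dRs[0]) == -np.sign(dRs[1]) != 0
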