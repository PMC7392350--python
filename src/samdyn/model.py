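"""Model/Results facade for the meristem fate-regulation model.

``MeristemModel`` bundles the model constants and the prescribed wild-type
geometry; ``fit()`` performs the calibration (estimating the two
differentiation rates from the prescribed steady radii), verifies the
fixed point by time-marching the fully coupled system, and returns a
:class:`SteadyState` results object carrying the calibrated parameters,
the equilibrium state and derived diagnostics.  Simulation of
perturbation scenarios, the stability classification and the regression
suite hang off the results object.

Example
-------
>>> from samdyn import MeristemModel
>>> res = MeristemModel().fit()
>>> print(res.summary())                       # doctest: +SKIP
>>> rep = res.stability()
>>> traj = res.simulate("hec_lof", t_end=80)
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import equilibrium as eq
from . import experiments as exp
from . import io as io_mod
from . import stability as stab
from .grid import RadialGrid
from .params import Parameters
from .scenarios import Scenario
from .solver import cz_fraction, integrate
from .state import MeristemState, Trajectory

__all__ = ["MeristemModel", "SteadyState"]


class MeristemModel:
    """Growing-disc model of SAM fate regulation by WUS/CLV3/CK/HEC.

    Parameters
    ----------
    params : Parameters, optional
        Model constants; defaults to the published wild-type set.
    R_target, r_target : float
        Prescribed steady-state meristem and organizing-center radii used
        by the calibration.
    """

    def __init__(
        self,
        params: Parameters | None = None,
        R_target: float = eq.DEFAULT_R_TARGET,
        r_target: float = eq.DEFAULT_OC_TARGET,
    ):
        self.params = (params or Parameters()).copy()
        if not 0 < r_target < R_target:
            raise ValueError("need 0 < r_target < R_target")
        self.R_target = R_target
        self.r_target = r_target

    def fit(self, verify_horizon: float = 50.0) -> "SteadyState":
        """Calibrate pdbasic/pp/R0 at the target geometry and return results."""
        p_cal = eq.calibrate(self.params, self.R_target, self.r_target)
        qs = eq.quasi_steady_solve(self.R_target, self.r_target, p_cal)
        state = eq.find_steady_state(p_cal, qs.state, horizon=verify_horizon)
        state.t = 0.0
        return SteadyState(model=self, params=p_cal, state=state)

    @classmethod
    def from_fixture(cls, directory: str | Path | None = None) -> "SteadyState":
        """Results object from a saved fixture (the packaged one if None)."""
        if directory is None:
            p, state, meta = io_mod.load_packaged_fixture()
        else:
            p, state, meta = io_mod.load_fixture(directory)
        model = cls(params=p, R_target=meta["R"], r_target=meta["r"])
        model.params = p
        return SteadyState(model=model, params=p, state=state)


@dataclass
class SteadyState:
    """Calibrated wild-type equilibrium and everything derived from it."""

    model: MeristemModel
    params: Parameters
    state: MeristemState

    # -- basic read-outs ----------------------------------------------
    @property
    def R_star(self) -> float:
        return self.state.R

    @property
    def r_star(self) -> float:
        return self.state.r

    @property
    def theta(self) -> float:
        """Frozen CLV3 threshold defining the central zone."""
        return self.params.numerics.cz_threshold

    @property
    def cz_fraction(self) -> float:
        grid = RadialGrid(self.state.xi.size - 1)
        return cz_fraction(grid, self.state.u1, self.theta)

    @property
    def cell_count(self) -> float:
        return float(np.pi * self.R_star**2)

    # -- diagnostics ----------------------------------------------------
    def stability(self, h: float = stab.DEFAULT_H) -> stab.StabilityReport:
        return stab.classify(self.params, self.R_star, self.r_star, h=h)

    def fg_map(self, R_grid, r_grid):
        return stab.fg_map(R_grid, r_grid, self.params)

    # -- simulation -----------------------------------------------------
    def simulate(
        self,
        scenario: Scenario | str | None = None,
        t_end: float = exp.DEFAULT_T_END,
        **kw,
    ) -> Trajectory:
        if scenario is None:
            scenario = Scenario()
        elif isinstance(scenario, str):
            scenario = exp.SUITE_SCENARIOS.get(scenario, Scenario(scenario))
        return exp.run_scenario(self.params, self.state, scenario, t_end, **kw)

    def phenotype(self, traj: Trajectory) -> exp.PhenotypeMetrics:
        return exp.phenotype(traj, self.params)

    def run_suite(self, t_end: float = exp.DEFAULT_T_END) -> exp.SuiteResult:
        return exp.run_suite(self.params, self.state, t_end)

    def sensitivity_sweep(self, fractions=(-0.01, 0.01), parameters=None):
        return exp.sensitivity_sweep(
            self.params, self.state, fractions, parameters
        )

    # -- persistence ----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        io_mod.save_fixture(directory, self.params, self.state)

    # -- presentation ---------------------------------------------------
    def summary(self) -> str:
        rep = self.stability()
        ev = rep.eigenvalues()
        lines = [
            "            Meristem fate-regulation model: wild-type steady state",
            "=" * 78,
            f"meristem radius R*        {self.R_star:12.6f}    "
            f"cell count pi R*^2      {self.cell_count:12.3f}",
            f"OC radius r*              {self.r_star:12.6f}    "
            f"r*/R*                   {self.r_star / self.R_star:12.4f}",
            f"CZ fraction               {self.cz_fraction:12.4f}    "
            f"CLV3 threshold theta    {self.theta:12.4f}",
            f"calibrated pdbasic        {self.params.pdbasic:12.6f}    "
            f"calibrated pp           {self.params.pp:12.6f}",
            "-" * 78,
            "quasi-steady stability (central differences, "
            f"h = {rep.h:g} x radius)",
            f"dF/dR  {rep.dF_dR:+.4f}    dF/dr  {rep.dF_dr:+.4f}    "
            f"dG/dR  {rep.dG_dR:+.4f}    dG/dr  {rep.dG_dr:+.4f}",
            f"trace A  {rep.trace:+.4f}    det A  {rep.det:+.4f}    "
            f"eigenvalues  {ev[0]:+.4f}, {ev[1]:+.4f}",
            f"classification: {'locally stable' if rep.stable else 'UNSTABLE'}",
            "=" * 78,
        ]
        return "\n".join(lines)
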