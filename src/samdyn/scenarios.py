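"""In-silico genetic perturbations as exact substitutions in the model.

Each scenario modifies the wild-type right-hand sides in one precise way:

``wus_oe``
    Ubiquitous WUS over-expression: a constant source ``c`` is added to
    the WUS equation (on top of the physiological OC source).
``wus_lof``
    Non-functional WUS protein: WUS is still produced but its
    concentration is replaced by zero wherever it acts, i.e. in the CLV3,
    CK and HEC production terms and in the radius ODEs.
``clv3_oe``
    CLV3 induction in its own expression domain: the CLV3 production term
    is multiplied by ``c``.
``clv3_lof``
    CLV3 silencing: CLV3 is replaced by zero in every other right-hand
    side (only the OC radius ODE actually senses it).
``ck_low_deg``
    Reduced CK turnover (ckx mutants): the degradation rate ``d2`` is
    multiplied by ``d2_factor < 1``.
``ck_lof``
    CK receptor loss: the CK production term is set to zero.
``hec_oe``
    HEC over-expression in stem cells: a term ``c * (CLV3 production)``
    is added to the HEC equation (both genes driven by the same promoter).
``hec_lof``
    hec triple mutant: HEC production set to zero.
``hec_oe_no_direct``
    As ``hec_oe``, but the direct HEC arm of the OC gate ``f`` is frozen
    at the wild-type central steady HEC level ``u3_frozen``, so HEC acts
    on the OC only indirectly through CK.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinetics
from .params import Parameters

KINDS = (
    "wild_type",
    "wus_oe",
    "wus_lof",
    "clv3_oe",
    "clv3_lof",
    "ck_low_deg",
    "ck_lof",
    "hec_oe",
    "hec_lof",
    "hec_oe_no_direct",
)

__all__ = ["KINDS", "Scenario", "ScenarioKinetics", "apply_scenario"]


@dataclass(frozen=True)
class Scenario:
    """Which perturbation is active and how strong.

    ``c`` is the over-expression rate/multiplier (ignored by kinds that do
    not use it); ``d2_factor`` scales CK degradation for ``ck_low_deg``;
    ``u3_frozen`` is the reference HEC level for ``hec_oe_no_direct``.
    """

    kind: str = "wild_type"
    c: float = 0.0
    d2_factor: float = 1.0
    u3_frozen: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.c < 0:
            raise ValueError("perturbation strength c must be >= 0")
        if self.kind == "ck_low_deg":
            if not 0.0 < self.d2_factor <= 1.0:
                raise ValueError("d2_factor must lie in (0, 1] for ck_low_deg")
        elif self.d2_factor != 1.0:
            raise ValueError("d2_factor must be 1 except for ck_low_deg")


class ScenarioKinetics:
    """Wild-type kinetics with one scenario's substitutions applied.

    The solver and the quasi-steady elliptic solver evaluate all reaction
    and coupling terms through this object, so a scenario is guaranteed to
    modify every equation it touches and no other.
    """

    def __init__(self, p: Parameters, scenario: Scenario | None = None):
        self.p = p
        self.scenario = scenario or Scenario()
        self.kind = self.scenario.kind
        if self.kind == "hec_oe_no_direct" and self.scenario.u3_frozen is None:
            raise ValueError(
                "hec_oe_no_direct needs the wild-type central HEC level "
                "(Scenario.u3_frozen); run_scenario fills it from the fixture"
            )

    # WUS concentration as seen by the downstream equations
    def _u0_eff(self, u0):
        if self.kind == "wus_lof":
            return np.zeros_like(np.asarray(u0, dtype=float))
        return u0

    # -- production terms --------------------------------------------
    def wus_production(self, rho, r: float, w: float | None = None):
        src = kinetics.wus_source(rho, r, self.p, w=w)
        if self.kind == "wus_oe":
            src = src + self.scenario.c
        return src

    def clv3_production(self, u0):
        rate = kinetics.clv3_production(self._u0_eff(u0), self.p)
        if self.kind == "clv3_oe":
            rate = self.scenario.c * rate
        return rate

    def ck_production(self, u0, u3):
        if self.kind == "ck_lof":
            return np.zeros_like(np.asarray(u0, dtype=float))
        return kinetics.ck_production(self._u0_eff(u0), u3, self.p)

    def hec_production(self, u0):
        rate = kinetics.hec_production(self._u0_eff(u0), self.p)
        if self.kind == "hec_lof":
            return np.zeros_like(rate)
        if self.kind in ("hec_oe", "hec_oe_no_direct"):
            rate = rate + self.scenario.c * kinetics.clv3_production(
                self._u0_eff(u0), self.p
            )
        return rate

    # -- degradation ---------------------------------------------------
    @property
    def degradation(self) -> tuple[float, float, float, float]:
        d2 = self.p.d2 * (
            self.scenario.d2_factor if self.kind == "ck_low_deg" else 1.0
        )
        return (self.p.d0, self.p.d1, d2, self.p.d3)

    # -- couplings into the radius ODEs --------------------------------
    def f_gate(self, u2, u3):
        if self.kind == "hec_oe_no_direct":
            u3 = np.full_like(np.asarray(u2, dtype=float), self.scenario.u3_frozen)
        return kinetics.f_gate(u2, u3, self.p)

    def u1_for_oc(self, u1):
        if self.kind == "clv3_lof":
            return np.zeros_like(np.asarray(u1, dtype=float))
        return u1

    def wus_integral_for_R(self, I0: float) -> float:
        return 0.0 if self.kind == "wus_lof" else I0


def apply_scenario(p: Parameters, scenario: Scenario) -> ScenarioKinetics:
    """Bundle parameters and a scenario into evaluable model functions."""
    return ScenarioKinetics(p, scenario)
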