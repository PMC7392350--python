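"""Model constants and numerical controls.

The shoot apical meristem (SAM) model couples four diffusing signals --
WUSCHEL (``u0``), CLAVATA3 (``u1``), cytokinin (``u2``) and HECATE (``u3``)
-- on a disc of radius ``R`` with a concentric WUS-producing organizing
center (OC) of radius ``r``.  All quantities are dimensionless.  The
default constants are the published wild-type set; ``pp``, ``pdbasic`` and
``R0`` are re-estimated by :func:`samdyn.equilibrium.calibrate` for a
prescribed steady-state geometry.
"""

from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = ["Numerics", "Parameters"]


@dataclass
class Numerics:
    """Discretization and convergence controls.

    Attributes
    ----------
    n_r : int
        Number of radial cells; the grid has ``n_r + 1`` nodes on the
        normalized coordinate xi in [0, 1].
    dt : float
        Base time step of the IMEX integrator (dimensionless time).
    indicator_width : float
        Total physical width ``w`` of the piecewise-linear ramp replacing
        the sharp OC indicator function.  ``w = 0`` gives the sharp
        indicator.  The default corresponds to about two grid cells at the
        default resolution and wild-type geometry.
    slowdown_delta : float
        Width (relative to ``R``) of the smoothstep factor that freezes the
        OC radius ODE as ``r`` approaches ``R``.
    radius_guard : float
        Maximum relative change of either radius allowed per step; the
        integrator sub-steps whenever the explicit update would exceed it.
    ss_tol : float
        Steady-state criterion: maximum relative change per unit time
        below which the march is declared converged.
    cz_threshold : float or None
        Frozen CLV3 threshold defining the central zone.  ``None`` until
        calibration freezes it at half the wild-type CLV3 maximum.
    """

    n_r: int = 200
    dt: float = 0.01
    indicator_width: float = 0.025
    slowdown_delta: float = 0.05
    radius_guard: float = 0.02
    ss_tol: float = 1e-6
    cz_threshold: float | None = None


@dataclass
class Parameters:
    # diffusion constants (WUS, CLV3, CK, HEC)
    D0: float = 1.0
    D1: float = 1.0
    D2: float = 0.2
    D3: float = 0.2
    # degradation rates
    d0: float = 5.0
    d1: float = 64.0
    d2: float = 1.1
    d3: float = 0.6
    # WUS production per unit OC area
    k1: float = 6.0
    # CLV3 sigmoid: amplitude, midpoint, steepness
    k2: float = 50.0
    k3: float = 0.6
    k4: float = 100.0
    # CK production
    k9: float = 4.0
    k10: float = 0.1
    k11: float = 1.4
    k12: float = 1.0
    # HEC production
    k13: float = 2.0
    k14: float = 100.0
    # meristem radius ODE
    k21: float = 1.65
    k23: float = 0.01
    pp: float = 1.622
    R0: float = 2.5
    # OC radius ODE
    k7: float = 500.0
    k77: float = 20.0
    pdbasic: float = 0.83
    # gate f
    aa: float = 2.0
    ab: float = 0.4
    k15: float = 0.4
    k16: float = 5.0
    k17: float = 1.1
    numerics: Numerics = field(default_factory=Numerics)

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        if self.numerics.indicator_width < 0:
            raise ValueError("indicator_width must be >= 0")
        if self.numerics.slowdown_delta <= 0:
            raise ValueError("slowdown_delta must be > 0")

    # -- convenience -------------------------------------------------
    def replace(self, **changes: Any) -> "Parameters":
        """Return a copy with the given scalar fields replaced."""
        num_changes = {
            k: changes.pop(k)
            for k in list(changes)
            if k in {f.name for f in dataclasses.fields(Numerics)}
        }
        numerics = dataclasses.replace(self.numerics, **num_changes)
        return dataclasses.replace(self, numerics=numerics, **changes)

    def copy(self) -> "Parameters":
        return dataclasses.replace(self, numerics=dataclasses.replace(self.numerics))

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "numerics"
        }
        d["numerics"] = dataclasses.asdict(self.numerics)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Parameters":
        d = dict(d)
        numerics = Numerics(**d.pop("numerics", {}))
        return cls(numerics=numerics, **d)

    def to_toml(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            if f.name == "numerics":
                continue
            lines.append(f"{f.name} = {_toml_value(getattr(self, f.name))}")
        lines.append("")
        lines.append("[numerics]")
        for f in dataclasses.fields(Numerics):
            v = getattr(self.numerics, f.name)
            if v is None:
                continue
            lines.append(f"{f.name} = {_toml_value(v)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "Parameters":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Parameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


_RATE_FIELDS = (
    "D0", "D1", "D2", "D3", "d0", "d1", "d2", "d3",
    "k1", "k2", "k4", "k9", "k10", "k11", "k12", "k13", "k14",
    "k21", "k23", "pp", "k7", "k77", "pdbasic", "k17",
)


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, int):
        return str(v)
    if isinstance(v, float):
        if math.isinf(v) or math.isnan(v):
            raise ValueError("non-finite parameter value")
        return repr(v)
    raise TypeError(f"unsupported TOML value {v!r}")
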