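"""State containers: radial fields, full meristem state, trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPECIES = ("u0", "u1", "u2", "u3")  # WUS, CLV3, CK, HEC

__all__ = ["SPECIES", "RadialField", "MeristemState", "Trajectory"]


@dataclass
class RadialField:
    """One signal's concentration sampled on the normalized radial grid."""

    xi: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.xi.shape != self.values.shape:
            raise ValueError("grid and values must have the same shape")
        if self.xi[0] != 0.0 or self.xi[-1] != 1.0:
            raise ValueError("grid must span [0, 1]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    def at(self, xi: float) -> float:
        return float(np.interp(xi, self.xi, self.values))


@dataclass
class MeristemState:
    """Time, radii and the four concentration fields.

    ``u`` has shape ``(4, n_r + 1)`` ordered WUS, CLV3, CK, HEC.
    """

    t: float
    R: float
    r: float
    xi: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.R <= 0:
            raise ValueError("meristem radius R must be positive")
        if not 0 < self.r <= self.R:
            raise ValueError("OC radius must satisfy 0 < r <= R")
        if self.u.shape != (4, self.xi.size):
            raise ValueError("u must have shape (4, n_nodes)")

    @property
    def u0(self) -> np.ndarray:
        return self.u[0]

    @property
    def u1(self) -> np.ndarray:
        return self.u[1]

    @property
    def u2(self) -> np.ndarray:
        return self.u[2]

    @property
    def u3(self) -> np.ndarray:
        return self.u[3]

    def field(self, i: int) -> RadialField:
        return RadialField(self.xi, self.u[i])

    def copy(self) -> "MeristemState":
        return MeristemState(self.t, self.R, self.r, self.xi.copy(), self.u.copy())


@dataclass
class Trajectory:
    """Time-ordered states plus per-time scalar series.

    ``series`` columns: t, R, r, int_u0, int_u2, cz_fraction, n_cells
    (``n_cells = pi R^2`` under the unit-cell-area convention).
    """

    states: list[MeristemState] = field(default_factory=list)
    records: list[dict] = field(default_factory=list)

    def append(self, state: MeristemState, record: dict) -> None:
        if self.states and state.t <= self.states[-1].t:
            raise ValueError("trajectory times must be strictly increasing")
        self.states.append(state)
        self.records.append(record)

    @property
    def series(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.records)

    @property
    def final(self) -> MeristemState:
        return self.states[-1]

    def __len__(self) -> int:
        return len(self.states)
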