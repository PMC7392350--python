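"""Result serialization: trajectory CSVs, profile CSVs, fixtures.

The calibrated wild-type equilibrium is persisted as a small fixture
(parameter TOML + profile CSV + JSON metadata) that serves as the
departure point for all perturbation experiments.  A pre-built fixture at
the default resolution ships with the package and can be regenerated with
``samdyn calibrate``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .params import Parameters
from .state import MeristemState, Trajectory

FLOAT_FMT = "%.12g"  # fixed output precision so regression diffs are meaningful

__all__ = [
    "write_timeseries",
    "write_profiles",
    "write_metadata",
    "save_fixture",
    "load_fixture",
    "load_packaged_fixture",
]


def write_timeseries(traj: Trajectory, path: str | Path) -> None:
    """Time-series CSV: t, R, r, int_u0, int_u2, cz_fraction, n_cells."""
    traj.series.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_profiles(state: MeristemState, path: str | Path) -> None:
    """Per-snapshot profile CSV: xi, rho, u0, u1, u2, u3."""
    df = pd.DataFrame(
        {
            "xi": state.xi,
            "rho": state.xi * state.R,
            "u0": state.u0,
            "u1": state.u1,
            "u2": state.u2,
            "u3": state.u3,
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_metadata(path: str | Path, p: Parameters, **extra) -> None:
    """JSON sidecar with the full resolved parameter set plus extras."""
    meta = {"parameters": p.to_dict(), **extra}
    Path(path).write_text(json.dumps(meta, indent=1))


def save_fixture(directory: str | Path, p: Parameters, state: MeristemState) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    p.to_toml(d / "wildtype.toml")
    write_profiles(state, d / "wildtype_profiles.csv")
    meta = {
        "t": state.t,
        "R": state.R,
        "r": state.r,
        "u3_center": float(state.u3[0]),
        "n_r": state.xi.size - 1,
    }
    (d / "wildtype_meta.json").write_text(json.dumps(meta, indent=1))


def load_fixture(directory: str | Path) -> tuple[Parameters, MeristemState, dict]:
    d = Path(directory)
    p = Parameters.from_toml(d / "wildtype.toml")
    meta = json.loads((d / "wildtype_meta.json").read_text())
    df = pd.read_csv(d / "wildtype_profiles.csv")
    u = np.vstack([df["u0"], df["u1"], df["u2"], df["u3"]])
    state = MeristemState(0.0, meta["R"], meta["r"], df["xi"].to_numpy(), u)
    return p, state, meta


def load_packaged_fixture() -> tuple[Parameters, MeristemState, dict]:
    """Load the wild-type equilibrium fixture shipped with the package."""
    with resources.as_file(resources.files("samdyn") / "data") as d:
        return load_fixture(d)
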