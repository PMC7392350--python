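"""Plots: radial concentration profiles, radius time series, F/G maps."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .state import MeristemState, Trajectory

_STYLES = {
    "u0": dict(color="tab:red", ls="-", label="WUS"),
    "u1": dict(color="tab:blue", ls="--", label="CLV3"),
    "u2": dict(color="tab:green", ls=":", label="CK"),
    "u3": dict(color="tab:purple", ls="-.", label="HEC"),
}


def plot_profiles(state: MeristemState, ax=None, species=("u0", "u1", "u2", "u3")):
    """Concentrations along the meristem diameter (mirrored radial profile)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.concatenate([-state.xi[::-1], state.xi]) * state.R
    for name in species:
        u = getattr(state, name)
        ax.plot(x, np.concatenate([u[::-1], u]), **_STYLES[name])
    ax.set_xlabel("position along diameter")
    ax.set_ylabel("concentration")
    ax.legend(frameon=False)
    return ax


def plot_timeseries(traj: Trajectory, ax=None):
    """Meristem and OC radius versus time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    s = traj.series
    ax.plot(s["t"], s["R"], color="k", label="R (meristem)")
    ax.plot(s["t"], s["r"], color="tab:orange", label="r (OC)")
    ax.set_xlabel("time")
    ax.set_ylabel("radius")
    ax.legend(frameon=False)
    return ax


def plot_fg_map(df: pd.DataFrame, ax=None):
    """Zero level sets of F and G on the (R, r) plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    Rv = np.sort(df["R"].unique())
    rv = np.sort(df["r"].unique())
    F = df.pivot(index="r", columns="R", values="F").to_numpy()
    G = df.pivot(index="r", columns="R", values="G").to_numpy()
    ax.contour(Rv, rv, F, levels=[0.0], colors="tab:red")
    ax.contour(Rv, rv, G, levels=[0.0], colors="tab:blue")
    ax.set_xlabel("R")
    ax.set_ylabel("r")
    ax.set_title("zero level sets: F (red), G (blue)")
    return ax
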