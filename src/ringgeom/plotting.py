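"""Simple 2-D plots for profiles and titrations (matplotlib)."""

from __future__ import annotations

import numpy as np

from .binding import HillResults
from .channel import RadialProfile


def plot_radial_profile(profile: RadialProfile, ax=None):
    """Minimum channel radius vs axial position, with empty bins skipped."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    occ = profile.occupied()
    z = [b[0] for b in occ]
    r = [b[1] for b in occ]
    ax.step(z, r, where="mid")
    ax.set_xlabel("axial position z (Å)")
    ax.set_ylabel("min distance to axis (Å)")
    if profile.selection_label:
        ax.set_title(profile.selection_label)
    return ax


def plot_titration(results: HillResults, ax=None):
    """Data points with the fitted Hill curves overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    s = results.model.series
    ax.plot(s.concentrations, s.frac_free, "o", label="free (data)")
    ax.plot(s.concentrations, s.frac_bound, "s", label="bound (data)")
    pos = s.concentrations[s.concentrations > 0]
    grid = np.geomspace(pos.min() / 3, pos.max() * 3, 200)
    pred = results.predict(grid)
    ax.plot(grid, pred["frac_free"], "-", label="free (fit)")
    ax.plot(grid, pred["frac_bound"], "--", label="bound (fit)")
    ax.set_xscale("log")
    ax.set_xlabel("[protein] (µM)")
    ax.set_ylabel("fraction")
    ax.axvline(results.k_half, color="grey", lw=0.8)
    ax.legend()
    if s.label:
        ax.set_title(s.label)
    return ax
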