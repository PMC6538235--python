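"""Quick-look plots for profiles and depth curves (matplotlib)."""

from __future__ import annotations

import numpy as np

from .beam_model import BeamDataSet
from .profile_metrics import ScanProfile, field_size, penumbra


def plot_profile(profile: ScanProfile, ax=None, annotate: bool = True):
    """Plot a scan profile; optionally annotate field size and penumbrae."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.positions, profile.readings, lw=1.2)
    ax.set_xlabel("position (mm)")
    ax.set_ylabel("relative reading")
    title = f"{profile.coll:g} mm collimator, depth {profile.depth:g} mm"
    if annotate:
        fs = field_size(profile)
        pl, pr = penumbra(profile)
        title += f"\nfield {fs:.2f} mm, penumbra {pl:.2f}/{pr:.2f} mm"
        half = np.max(profile.readings) / 2.0
        ax.axhline(half, color="grey", lw=0.6, ls="--")
    ax.set_title(title, fontsize=9)
    return ax


def plot_depth_curves(data: BeamDataSet, coll: float, ax=None):
    """Plot the PDD (left axis, %) and TMR (right axis) for one collimator."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pdd = data.pdd[coll]
    tmr = data.tmr[coll]
    ax.plot(pdd.x, pdd.y, label="PDD (%)", color="C0")
    ax.set_xlabel("depth (mm)")
    ax.set_ylabel("PDD (%)", color="C0")
    ax2 = ax.twinx()
    ax2.plot(tmr.x, tmr.y, label="TMR", color="C1")
    ax2.set_ylabel("TMR", color="C1")
    ax.set_title(f"depth curves, {coll:g} mm collimator", fontsize=9)
    return ax
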