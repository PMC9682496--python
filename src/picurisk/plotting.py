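"""Plot helpers for heatmaps, risk profiles and time-to-event curves.

matplotlib is imported lazily so headless/pipeline use never pays for
a display backend.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_heatmap(grids: dict, ax=None, panel: str = "pooled"):
    """Render one panel of a bootstrapped relative-risk grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    g = grids[panel]["grid"]
    im = ax.imshow(g, origin="lower", aspect="auto", cmap="coolwarm",
                   vmin=0.0, vmax=max(2.0, float(np.nanmax(g))))
    ax.set_xlabel("age decile")
    ax.set_ylabel(f"{grids.get('feature', 'feature')} decile")
    ax.set_title(panel)
    ax.figure.colorbar(im, ax=ax, label="relative risk")
    return ax


def plot_time_to_event(curve: pd.DataFrame, ax=None, group: str = "all"):
    """Mean relative risk vs hours to event, flagged bins circled."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = curve[curve["group"] == group]
    h = sub["time_to_event_s"] / 3600.0
    ax.plot(-h, sub["mean_relative_risk"], "-", color="tab:red")
    sig = sub[sub["significant"]]
    ax.plot(-sig["time_to_event_s"] / 3600.0, sig["mean_relative_risk"],
            "o", mfc="none", color="black")
    ax.set_xlabel("hours before unplanned intubation")
    ax.set_ylabel("mean relative risk")
    ax.set_title(group)
    return ax


def plot_marginal_profile(profile: pd.DataFrame, ax=None):
    """Log odds of an event as a single feature varies."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    feature = profile.columns[0]
    ax.plot(profile[feature], profile["log_odds"], "-")
    ax.set_xlabel(feature)
    ax.set_ylabel("log odds of unplanned intubation (12 h)")
    return ax
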