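"""Figure exports: ascent velocity traces with landmarks, metric box plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .sticking import StickingEvent


def plot_sticking_trace(
    velocity: np.ndarray,
    sampling_rate_hz: float,
    event: StickingEvent | None = None,
    path: str | Path | None = None,
    title: str = "Ascent vertical velocity",
):
    """Velocity-vs-time plot with V0/Vmax1/Vmin/Vmax2 markers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(len(velocity)) / sampling_rate_hz
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(t, velocity, lw=1.5)
    if event is not None and event.detected:
        for name, idx in (("V0", event.v0_idx), ("Vmax1", event.vmax1_idx),
                          ("Vmin", event.vmin_idx), ("Vmax2", event.vmax2_idx)):
            ax.plot(t[idx], velocity[idx], "o", color="k", ms=4)
            ax.annotate(name, (t[idx], velocity[idx]),
                        textcoords="offset points", xytext=(4, 6), fontsize=8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("vertical velocity (m/s)")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_metric_boxplot(
    table: pd.DataFrame,
    variable: str,
    joint: str = "",
    path: str | Path | None = None,
):
    """Condition x group box plot of one metric from the long-format table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table[table["variable"] == variable]
    if joint:
        sub = sub[sub["joint"] == joint]
    if sub.empty:
        raise ValueError(f"no rows for variable {variable!r} joint {joint!r}")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    labels, data = [], []
    for (cond, grp), cell in sub.groupby(["condition", "group"]):
        labels.append(f"{cond}\n{grp}")
        data.append(cell["value"].to_numpy())
    ax.boxplot(data, tick_labels=labels)
    units = sub["units"].iloc[0] if "units" in sub.columns else ""
    ax.set_ylabel(f"{variable} {joint} ({units})".strip())
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
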