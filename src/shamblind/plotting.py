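"""Basic band plot of the sham-blinding time course."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .blinding import DistinctWindows

__all__ = ["band_plot"]


def band_plot(bands: pd.DataFrame, windows: DistinctWindows | None = None,
              path: str | Path | None = None, ylabel: str = "weighted score"):
    """Median time course with bootstrap CI ribbons per condition.

    Distinct (non-overlapping) probes, if supplied, are marked along the
    x-axis.  Returns the matplotlib figure; saves to ``path`` if given.
    """
    fig, ax = plt.subplots(figsize=(8, 4))
    colors = {"active": "tab:red", "sham": "tab:blue"}
    for condition, grp in bands.groupby("condition"):
        grp = grp.sort_values("time_s")
        color = colors.get(condition, None)
        ax.plot(grp["time_s"], grp["median"], label=condition, color=color)
        ax.fill_between(grp["time_s"], grp["ci_lo"], grp["ci_hi"], alpha=0.25, color=color)
    if windows is not None:
        distinct_t = windows.times[windows.distinct_flags]
        ax.plot(distinct_t, [ax.get_ylim()[0]] * len(distinct_t), "k|", markersize=10,
                label="distinct probes")
    ax.axhline(0.0, color="grey", linewidth=0.8)
    ax.set_xlabel("time since ramp-up onset (s)")
    ax.set_ylabel(ylabel)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
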