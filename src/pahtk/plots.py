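"""Basic concentration-time figure: individual points + median course, log axis."""
from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import DISPLAY_NAMES

_COLORS = {"DHN": "#1f3b73", "NAP1": "#c0392b", "NAP2": "#1e8449", "PYR1": "#5dade2"}


def concentration_time_plot(samples: pd.DataFrame, analytes: Sequence[str],
                            path) -> None:
    inc = samples[samples["included"] == 1]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name in analytes:
        col = f"{name}_ug_per_g"
        color = _COLORS.get(name, "grey")
        ax.scatter(inc["time_h"], inc[col], s=8, alpha=0.35, color=color,
                   label=DISPLAY_NAMES.get(name, name))
        med = inc.groupby("window_index").agg(
            t=("time_h", "median"), c=(col, "median")).sort_values("t")
        ax.plot(med["t"], med["c"], color=color, lw=1.5)
    ax.set_yscale("log")
    ax.set_xlabel("time since exposure onset (h)")
    ax.set_ylabel("concentration (µg/g creatinine)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
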