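"""Tornado and acceptability-curve plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["tornado_plot", "ceac_plot"]


def tornado_plot(table: pd.DataFrame, base_icer: float, ax=None, top: int = 12):
    """Horizontal tornado diagram from a one-way sensitivity table
    (widest ICER span at the top, bars anchored at the base-case ICER)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * min(top, len(table)) + 1.5))
    rows = table.head(top).iloc[::-1]
    y = np.arange(len(rows))
    lo = np.minimum(rows["icer_at_low"], rows["icer_at_high"])
    hi = np.maximum(rows["icer_at_low"], rows["icer_at_high"])
    ax.barh(y, hi - lo, left=lo, color="#4878d0", alpha=0.8)
    ax.axvline(base_icer, color="k", lw=1, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(rows["label"])
    ax.set_xlabel("ICER ($/QALY)")
    return ax


def ceac_plot(ceac: pd.DataFrame, ax=None):
    """Cost-effectiveness acceptability curve of the combination arm."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac["wtp"], ceac["probability_cost_effective"], lw=2)
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    return ax
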