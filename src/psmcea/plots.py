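"""Optional matplotlib views: tornado diagram, PSA scatter, CEAC."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["tornado_plot", "psa_scatter_plot", "ceac_plot"]


def tornado_plot(tornado: pd.DataFrame, base_icer: float, wtp: float,
                 top: int = 12):
    """Horizontal-bar tornado of one-way ICER spans (largest on top)."""
    df = tornado.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.5))
    for i, row in enumerate(df.itertuples()):
        lo, hi = sorted((row.icer_low, row.icer_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878b0")
    ax.axvline(base_icer, color="k", lw=1, label="base-case ICER")
    ax.axvline(wtp, color="r", lw=1, ls="--", label="WTP threshold")
    ax.set_yticks(range(len(df)), df["parameter"])
    ax.set_xlabel("ICER (USD/QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    return fig


def psa_scatter_plot(draws: pd.DataFrame, wtp: float):
    """Incremental cost-effect cloud with the WTP line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(draws["delta_effect"], draws["delta_cost"], s=6, alpha=0.4)
    xlim = np.array(ax.get_xlim())
    ax.plot(xlim, wtp * xlim, "r--", lw=1, label=f"WTP = {wtp:,.0f}/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def ceac_plot(ceac: pd.DataFrame, wtp: float):
    """Cost-effectiveness acceptability curves for both strategies."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac["wtp"], ceac["p_comparator"], label="TC")
    ax.plot(ceac["wtp"], ceac["p_reference"], label="PC")
    ax.axvline(wtp, color="r", ls="--", lw=1)
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    return fig
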