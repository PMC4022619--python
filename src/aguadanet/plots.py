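"""Optional diagnostic figures (never part of the numeric pipeline)."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .scenarios import SweepRecord, sweep_to_dataframe


def plot_sweep(records: Sequence[SweepRecord], path: str) -> None:
    """Link density and waterhole count per scenario, one line per distance."""
    df = sweep_to_dataframe(records)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for d, grp in df.groupby("d_max"):
        ax1.plot(grp["scenario"], grp["link_density"], "o-", label=f"{d / 1000:g} km")
        ax2.plot(grp["scenario"], grp["pc_numerator"], "o-", label=f"{d / 1000:g} km")
    ax1.set_xlabel("drought scenario")
    ax1.set_ylabel("link density L")
    ax2.set_xlabel("drought scenario")
    ax2.set_ylabel("PC numerator (m$^4$)")
    ax2.set_yscale("log")
    ax1.legend(title="distance", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_importance(df, path: str, top: int = 5) -> None:
    """Scatter of waterholes; the highest-aggregate-dPC nodes highlighted."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["area_m2"], df["dPC_aggregate"], s=12, alpha=0.6)
    best = df.nsmallest(top, "rank")
    ax.scatter(best["area_m2"], best["dPC_aggregate"], s=40, color="crimson",
               label=f"top {top}")
    ax.set_xscale("log")
    ax.set_xlabel("waterhole area (m$^2$)")
    ax.set_ylabel("aggregate dPC (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
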