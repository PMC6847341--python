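"""Tables and figures from a calling results table.

The volcano view (mutation-rate difference vs -10*log10 p) is the primary
global summary; the track view plots depth and significance along one
reference. Tables are the authoritative, testable surface; figures are
rendered headlessly and deterministically.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import pandas as pd

from .calling import CallingThresholds

__all__ = ["volcano_table", "plot_volcano", "plot_track"]

_REQUIRED = ["position", "delta", "neg10log10_p", "called"]


def volcano_table(
    results: pd.DataFrame, thresholds: CallingThresholds = CallingThresholds()
) -> pd.DataFrame:
    """Filter-passing positions with delta, capped -10*log10(p) and call flag."""
    for col in _REQUIRED + ["filters"]:
        if col not in results.columns:
            raise KeyError(f"results table lacks required column {col!r}")
    passed = results[results["filters"] == "PASS"]
    cols = ["reference", "position", "delta", "neg10log10_p", "called"]
    cols = [c for c in cols if c in passed.columns]
    return passed[cols].reset_index(drop=True)


def plot_volcano(
    table: pd.DataFrame,
    out: Union[str, Path],
    thresholds: CallingThresholds = CallingThresholds(),
    annotations: Optional[dict[int, str]] = None,
) -> None:
    """Render delta vs -10*log10(p); called sites highlighted."""
    fig, ax = plt.subplots(figsize=(5, 4))
    called = table["called"].astype(bool)
    ax.scatter(
        table.loc[~called, "delta"], table.loc[~called, "neg10log10_p"],
        s=8, c="0.6", label="not called",
    )
    ax.scatter(
        table.loc[called, "delta"], table.loc[called, "neg10log10_p"],
        s=14, c="crimson", label="called",
    )
    ax.axvline(thresholds.min_delta, ls="--", lw=0.8, c="k")
    ax.axhline(-10 * math.log10(thresholds.max_between_p), ls="--", lw=0.8, c="k")
    ax.set_xlabel("mutation rate difference")
    ax.set_ylabel(r"$-10\,\log_{10}(p)$")
    if annotations:
        for pos, label in annotations.items():
            row = table[table["position"] == pos]
            if len(row):
                ax.annotate(label, (row["delta"].iloc[0], row["neg10log10_p"].iloc[0]))
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def plot_track(
    results: pd.DataFrame,
    reference: str,
    out: Union[str, Path],
) -> None:
    """Per-reference coverage and significance track."""
    sub = results[results["reference"] == reference]
    if sub.empty:
        raise ValueError(f"no rows for reference {reference!r}")
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 4))
    ax1.fill_between(
        sub["position"], sub["depth_treated"] + sub["depth_control"], step="mid",
        color="steelblue", alpha=0.7,
    )
    ax1.set_ylabel("combined depth")
    ax2.vlines(sub["position"], 0, sub["neg10log10_p"], color="crimson", lw=1)
    ax2.set_ylabel(r"$-10\,\log_{10}(p)$")
    ax2.set_xlabel(f"position on {reference}")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
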