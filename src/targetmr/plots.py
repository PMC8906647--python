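"""Minimal scatter and forest renderers for the plot-ready tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def scatter_plot(table: pd.DataFrame, path: str, label_a: str = "baseline", label_b: str = "comparator") -> None:
    """Scatter of paired scaled estimates (columns est_a, est_b, subcategory)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for sub, grp in table.groupby(table.get("subcategory", "all")):
        ax.scatter(grp["est_a"], grp["est_b"], s=12, label=str(sub) or None, alpha=0.7)
    lims = [
        min(table["est_a"].min(), table["est_b"].min()),
        max(table["est_a"].max(), table["est_b"].max()),
    ]
    ax.plot(lims, lims, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(label_a)
    ax.set_ylabel(label_b)
    if table.get("subcategory") is not None and table["subcategory"].nunique() <= 12:
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def forest_plot(table: pd.DataFrame, path: str) -> None:
    """Forest of estimates with 95% CIs (columns trait, theta, ci_low, ci_high)."""
    table = table.dropna(subset=["theta"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(5, 0.25 * max(len(table), 4) + 1))
    y = range(len(table))
    ax.errorbar(
        table["theta"], list(y),
        xerr=[table["theta"] - table["ci_low"], table["ci_high"] - table["theta"]],
        fmt="o", ms=3, lw=1, color="black",
    )
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(y), table["trait"], fontsize=6)
    ax.set_xlabel("effect (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
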