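"""Optional figures: coverage distributions and depth profiles of R²."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def coverage_violin(
    table: pd.DataFrame,
    value_col: str = "coverage_0mm",
    out: Optional[str | Path] = None,
):
    """Violin plot of per-sample coverage, one panel per group x primer."""
    keys = table[["primer", "group"]].drop_duplicates().values.tolist()
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(keys)), 4))
    data, labels = [], []
    for primer, group in keys:
        sub = table[(table["primer"] == primer) & (table["group"] == group)]
        vals = sub[value_col].dropna().values
        if len(vals):
            data.append(vals)
            labels.append(f"{primer}\n{group}")
    if data:
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=8)
    ax.set_ylabel(value_col)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def depth_profile(
    results: pd.DataFrame,
    metadata: pd.DataFrame,
    out: Optional[str | Path] = None,
):
    """R² versus depth, depth increasing downward (oceanographic convention)."""
    merged = results.merge(metadata[["sample_id", "depth_m"]], on="sample_id")
    fig, ax = plt.subplots(figsize=(4, 5))
    ax.scatter(merged["r_squared"], merged["depth_m"], s=18)
    ax.invert_yaxis()
    ax.set_xlabel("R² (amplicon vs metagenome)")
    ax.set_ylabel("depth (m)")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
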