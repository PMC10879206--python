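"""Thin matplotlib rendering of the report tables.

Every figure is backed by a serialized data table built in
:mod:`precision_pathways.report`; these functions only draw.  Figures are
written as both SVG and PNG when a path stem is given.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_flowchart", "plot_strata", "plot_bubble", "save_figure"]


def save_figure(fig: plt.Figure, stem: str | Path) -> list[Path]:
    """Write ``<stem>.svg`` and ``<stem>.png``; returns the paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for ext in ("svg", "png"):
        path = stem.with_suffix(f".{ext}")
        fig.savefig(path, bbox_inches="tight")
        paths.append(path)
    plt.close(fig)
    return paths


def plot_flowchart(flow: pd.DataFrame) -> plt.Figure:
    """Stacked per-stage bars: classified per class plus progressed."""
    class_cols = [c for c in flow.columns if c.startswith("classified_")]
    fig, ax = plt.subplots(figsize=(1.8 * len(flow) + 2, 4))
    bottom = np.zeros(len(flow))
    for col in class_cols + ["progressed"]:
        ax.bar(flow["platform"], flow[col], bottom=bottom, label=col)
        bottom += flow[col].to_numpy(dtype=float)
    ax.set_ylabel("patients")
    ax.set_xlabel("stage platform")
    ax.legend(fontsize=8)
    ax.set_title("Patient flow through the pathway")
    return fig


def plot_strata(strata: pd.DataFrame) -> plt.Figure:
    """Patients on the x-axis, classifying stage on the y, accuracy as color."""
    fig, ax = plt.subplots(figsize=(8, 3 + 0.3 * strata["stage"].nunique()))
    sc = ax.scatter(
        np.arange(len(strata)),
        strata["stage"],
        c=strata["accuracy"],
        cmap="RdYlGn",
        vmin=0,
        vmax=1,
        s=14,
        marker="s",
    )
    ax.set_yticks(sorted(strata["stage"].unique()))
    ax.set_xlabel("patients (sorted by stage, true class, accuracy)")
    ax.set_ylabel("classifying stage")
    fig.colorbar(sc, ax=ax, label="patient accuracy")
    return fig


def plot_bubble(bubble: pd.DataFrame) -> plt.Figure:
    """Candidate pathways on cost (x) vs balanced accuracy (y)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    tier1 = next((c for c in bubble.columns if c.startswith("tier1")), None)
    shade = bubble[tier1] if tier1 else 0.5
    sc = ax.scatter(
        bubble["total_cost"], bubble["balanced_accuracy"], c=shade,
        cmap="viridis", vmin=0, vmax=1, s=120, edgecolor="k",
    )
    for _, row in bubble.iterrows():
        ax.annotate(
            row["sequence"], (row["total_cost"], row["balanced_accuracy"]),
            fontsize=6, xytext=(3, 3), textcoords="offset points",
        )
    ax.set_xlabel("total cost")
    ax.set_ylabel("balanced accuracy")
    if tier1:
        fig.colorbar(sc, ax=ax, label="proportion classified at tier 1")
    return fig
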