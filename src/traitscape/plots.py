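"""Static figures: trait-scape biplot, plasticity-index bars, and
factorial interaction plots.  Figures are built without pyplot state so
they render identically in headless batch runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
from matplotlib.figure import Figure

from .scape import TraitScapePCA


def trait_scape_biplot(scape: TraitScapePCA, groups=None, path=None,
                       arrow_scale: float = 3.0) -> Figure:
    """Scores on the first two dimensions with loading arrows."""
    fig = Figure(figsize=(6, 5))
    ax = fig.add_subplot(111)
    scores = np.asarray(scape.scores_)
    ev = scape.explained_variance_ratio_
    if groups is None:
        ax.scatter(scores[:, 0], scores[:, 1], s=18, alpha=0.7)
    else:
        groups = pd.Series(list(groups))
        for g in sorted(groups.unique()):
            m = (groups == g).to_numpy()
            ax.scatter(scores[m, 0], scores[m, 1], s=18, alpha=0.7, label=str(g))
        ax.legend(fontsize=7, ncol=2)
    loadings = np.asarray(scape.loadings_)
    for i, name in enumerate(scape.feature_names_in_):
        ax.annotate("", xy=(arrow_scale * loadings[i, 0],
                            arrow_scale * loadings[i, 1]),
                    xytext=(0, 0), arrowprops=dict(arrowstyle="->", color="0.3"))
        ax.text(arrow_scale * loadings[i, 0] * 1.08,
                arrow_scale * loadings[i, 1] * 1.08, str(name), fontsize=7)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel(f"Dim 1 ({100 * ev[0]:.1f}%)")
    ax.set_ylabel(f"Dim 2 ({100 * ev[1]:.1f}%)")
    ax.set_title("Trait-scape")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


def index_bars(indices: pd.DataFrame, value: str = "mvpi", path=None) -> Figure:
    """Bar chart of plasticity indices per group and contrast with SE
    whiskers (SE of the underlying pairwise distances when available)."""
    fig = Figure(figsize=(7, 4))
    ax = fig.add_subplot(111)
    groups = sorted(indices["group"].unique())
    contrasts = list(pd.unique(indices["contrast"]))
    width = 0.8 / max(len(contrasts), 1)
    x = np.arange(len(groups))
    for k, contrast in enumerate(contrasts):
        sub = indices[indices["contrast"] == contrast].set_index("group")
        vals = [sub[value].get(g, np.nan) for g in groups]
        errs = [sub["se"].get(g, 0.0) if "se" in sub else 0.0 for g in groups]
        ax.bar(x + k * width, vals, width=width, yerr=errs, capsize=2,
               label=str(contrast))
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels([str(g) for g in groups], rotation=0, fontsize=8)
    ax.set_ylabel(value)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig


def interaction_plot(records: pd.DataFrame, response: str, path=None) -> Figure:
    """Cell means +/- SE by cytotype, water and CO2 level."""
    data = records[records["survived"]] if "survived" in records else records
    data = data.dropna(subset=[response])
    fig = Figure(figsize=(7, 4))
    axes = fig.subplots(1, 2, sharey=True)
    for ax, co2 in zip(axes, sorted(data["co2"].unique())):
        for cyto in sorted(data["cytotype"].unique()):
            sub = data[(data["co2"] == co2) & (data["cytotype"] == cyto)]
            stats_ = sub.groupby("water")[response].agg(["mean", "sem"])
            stats_ = stats_.reindex(["well-watered", "drought"]).dropna()
            ax.errorbar(range(len(stats_)), stats_["mean"], yerr=stats_["sem"],
                        marker="o", capsize=3, label=cyto)
        ax.set_xticks(range(2))
        ax.set_xticklabels(["well-watered", "drought"], fontsize=8)
        ax.set_title(f"{co2} CO2", fontsize=9)
    axes[0].set_ylabel(response)
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
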