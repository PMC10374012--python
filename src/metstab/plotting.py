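"""Biplot rendering (SVG/PNG) for the GGE views.

Figures are structural: labelled scatter of genotype and environment
scores with the AEA arrow, plus per-view geometry (hull and sector rays
for which-won-where, concentric circles for the ranking view).  Axis
labels carry the percentage of G+GE variation on each axis.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .gge import (
    GGEResult,
    environment_evaluation,
    ideal_genotype_ranking,
    which_won_where,
)

__all__ = ["render_biplot", "VIEWS"]

VIEWS = ("mean_stability", "environments", "which_won_where", "ranking")

# reproducible SVG output: fixed hash salt, no embedded timestamps
matplotlib.rcParams["svg.hashsalt"] = "metstab"


def _scatter(ax, gge: GGEResult) -> None:
    G = gge.genotype_scores2d
    E = gge.environment_scores2d
    ax.axhline(0.0, color="0.8", lw=0.8)
    ax.axvline(0.0, color="0.8", lw=0.8)
    ax.scatter(G["PC1"], G["PC2"], s=12, color="tab:green", zorder=3)
    for label, row in G.iterrows():
        ax.annotate(label, (row["PC1"], row["PC2"]), fontsize=7, color="tab:green")
    for label, row in E.iterrows():
        ax.annotate(
            label,
            (row["PC1"], row["PC2"]),
            fontsize=8,
            color="tab:purple",
            fontweight="bold",
        )
        ax.plot([0, row["PC1"]], [0, row["PC2"]], color="tab:purple", lw=0.8, alpha=0.6)
    pct = gge.pc_variance_pct
    ax.set_xlabel(f"PC1 ({pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pct[1]:.1f}%)")


def _aea_arrow(ax, gge: GGEResult, scale: float) -> None:
    d = gge.aea_direction * scale
    ax.annotate(
        "",
        xy=d,
        xytext=-d,
        arrowprops={"arrowstyle": "-|>", "color": "tab:red", "lw": 1.2},
    )


def render_biplot(gge: GGEResult, view: str, path) -> None:
    """Write one biplot view to ``path`` (format from the extension)."""
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}")
    fig, ax = plt.subplots(figsize=(6, 6))
    _scatter(ax, gge)
    span = 1.1 * max(
        np.abs(gge.genotype_scores2d.to_numpy()).max(),
        np.abs(gge.environment_scores2d.to_numpy()).max(),
    )
    if view in ("mean_stability", "environments", "ranking"):
        _aea_arrow(ax, gge, span)
    if view == "mean_stability":
        n = gge.aea_normal * span
        ax.plot([-n[0], n[0]], [-n[1], n[1]], color="tab:red", lw=0.8, ls="--")
    if view == "environments":
        ev = environment_evaluation(gge)
        radius = float(ev["vector_length"].max())
        theta = np.linspace(0, 2 * np.pi, 200)
        ax.plot(radius * np.cos(theta), radius * np.sin(theta), color="0.7", lw=0.8)
    if view == "which_won_where":
        part = which_won_where(gge)
        hull = gge.genotype_scores2d.loc[part.hull_vertex_genotypes].to_numpy()
        closed = np.vstack([hull, hull[:1]])
        ax.plot(closed[:, 0], closed[:, 1], color="tab:blue", lw=1.2)
        for ray in part.sector_boundaries:
            ax.plot([0, ray[0] * span], [0, ray[1] * span], color="tab:blue", lw=0.8, ls=":")
    if view == "ranking":
        ranking = ideal_genotype_ranking(gge)
        ideal = (
            gge.genotype_scores2d.to_numpy() @ gge.aea_direction
        )
        best = ideal.min() if gge.trait_direction == "lower_better" else ideal.max()
        center = best * gge.aea_direction
        theta = np.linspace(0, 2 * np.pi, 200)
        for radius in np.quantile(ranking["ideal_distance"], [0.25, 0.5, 0.75, 1.0]):
            ax.plot(
                center[0] + radius * np.cos(theta),
                center[1] + radius * np.sin(theta),
                color="0.7",
                lw=0.8,
            )
    ax.set_title(f"{gge.trait}: {view.replace('_', ' ')}")
    ax.set_aspect("equal", adjustable="datalim")
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
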