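"""GGE biplot analysis: environment-centered SVD and its geometry.

The GGE (genotype + genotype-by-environment) model subtracts the
environment means from a cell-mean matrix and decomposes the remainder
— genotype main effect plus interaction together — by SVD:

    Ybar_ij - Ebar_j = sum_n lambda_n gamma_in delta_jn.

All biplot inference here uses the first two axes, scaled according to
a singular value partition (SVP):

* ``row_metric``  — genotype-focused, scores U * Lambda, environments V;
* ``column_metric`` — environment-focused, U and V * Lambda;
* ``symmetric``   — both sides get sqrt(Lambda).

Derived views:

* mean vs stability — projections on the average environment axis (AEA,
  the direction of the mean environment score vector) proxy mean
  performance; orthogonal distance proxies instability;
* ideal-genotype ranking — distance to the point on the AEA at the best
  observed projection;
* environment evaluation — vector length (discriminativeness) and the
  cosine of the angle to the AEA (representativeness);
* which-won-where — convex hull of genotype scores with perpendicular
  sector boundaries grouping environments into mega-environments;
* bootstrap confidence limits for all 2-D scores, with orthogonal
  Procrustes alignment to undo SVD sign/rotation indeterminacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.spatial import ConvexHull

from .met_data import CellMeanMatrix, METDataset, cell_means

__all__ = [
    "GGEResult",
    "SectorPartition",
    "BootstrapCL",
    "DegenerateGeometryError",
    "gge_decompose",
    "mean_stability",
    "ideal_genotype_ranking",
    "environment_evaluation",
    "which_won_where",
    "environment_desirability",
    "bootstrap_cl",
]

SVP_CONVENTIONS = ("row_metric", "column_metric", "symmetric")


class DegenerateGeometryError(ValueError):
    """The biplot geometry is undefined (zero spread or collinear scores)."""


@dataclass
class GGEResult:
    """Environment-centered SVD of one trait with 2-D biplot scores."""

    centered: np.ndarray
    singular_values: np.ndarray
    genotype_scores2d: pd.DataFrame  # g x 2, SVP-scaled
    environment_scores2d: pd.DataFrame  # e x 2, SVP-scaled
    pc_variance_pct: np.ndarray
    svp: str
    aea_direction: np.ndarray  # unit 2-vector
    trait_direction: str
    trait: str
    genotype_means: pd.Series = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def genotype_labels(self) -> list[str]:
        return list(self.genotype_scores2d.index)

    @property
    def environment_labels(self) -> list[str]:
        return list(self.environment_scores2d.index)

    @property
    def aea_normal(self) -> np.ndarray:
        """Unit vector orthogonal to the AEA (the 'AEC ordinate')."""
        return np.array([-self.aea_direction[1], self.aea_direction[0]])


def gge_decompose(
    matrix: CellMeanMatrix,
    svp: str = "row_metric",
    trait_direction: str | None = None,
) -> GGEResult:
    """Environment-centered SVD (centring=2, no transform, no scaling).

    The AEA is the normalized mean of the environment 2-D score vectors,
    oriented so the highest-mean genotype projects positively.
    """
    matrix.require_biplot_shape()
    if svp not in SVP_CONVENTIONS:
        raise ValueError(f"svp must be one of {SVP_CONVENTIONS}")
    if trait_direction is None:
        trait_direction = "higher_better"
    C = matrix.values - matrix.values.mean(axis=0, keepdims=True)
    U, lam, Vt = np.linalg.svd(C, full_matrices=False)
    V = Vt.T
    if lam[0] <= 1e-12:
        raise DegenerateGeometryError("constant matrix: all singular values are zero")
    for k in range(U.shape[1]):
        nz = np.flatnonzero(np.abs(U[:, k]) > 1e-12)
        if nz.size and U[nz[0], k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    pct = 100.0 * lam**2 / (lam**2).sum()
    if svp == "row_metric":
        G, E = U[:, :2] * lam[:2], V[:, :2]
    elif svp == "column_metric":
        G, E = U[:, :2], V[:, :2] * lam[:2]
    else:
        root = np.sqrt(lam[:2])
        G, E = U[:, :2] * root, V[:, :2] * root
    aea = E.mean(axis=0)
    norm = np.linalg.norm(aea)
    if norm < 1e-12:
        raise DegenerateGeometryError("environment scores are symmetric about the origin")
    aea = aea / norm
    means = matrix.values.mean(axis=1)
    if (G[int(np.argmax(means))] @ aea) < 0:
        aea = -aea
    cols = ["PC1", "PC2"]
    return GGEResult(
        centered=C,
        singular_values=lam,
        genotype_scores2d=pd.DataFrame(G, index=matrix.genotype_labels, columns=cols),
        environment_scores2d=pd.DataFrame(E, index=matrix.environment_labels, columns=cols),
        pc_variance_pct=pct,
        svp=svp,
        aea_direction=aea,
        trait_direction=trait_direction,
        trait=matrix.trait,
        genotype_means=pd.Series(means, index=matrix.genotype_labels, name="mean"),
    )


def mean_stability(gge: GGEResult) -> pd.DataFrame:
    """Per-genotype AEA projection (mean proxy) and AEC distance (instability).

    ``mean_rank`` orders by projection — descending for higher-is-better
    traits, ascending otherwise; ``stability_rank`` orders by distance
    ascending (most stable first).
    """
    G = gge.genotype_scores2d.to_numpy()
    proj = G @ gge.aea_direction
    dist = np.abs(G @ gge.aea_normal)
    out = pd.DataFrame(
        {"aea_projection": proj, "aec_distance": dist},
        index=gge.genotype_scores2d.index,
    )
    ascending = gge.trait_direction == "lower_better"
    out["mean_rank"] = out["aea_projection"].rank(ascending=ascending, method="average")
    out["stability_rank"] = out["aec_distance"].rank(ascending=True, method="average")
    return out


def ideal_genotype_ranking(gge: GGEResult) -> pd.DataFrame:
    """Distance of each genotype to the ideal point on the AEA.

    The ideal point sits at the best observed projection along the AEA —
    the maximum for higher-is-better traits, the minimum for
    lower-is-better ones.  The sorted distances are the radii of the
    concentric circles of the ranking view.
    """
    G = gge.genotype_scores2d.to_numpy()
    proj = G @ gge.aea_direction
    best = proj.min() if gge.trait_direction == "lower_better" else proj.max()
    ideal = best * gge.aea_direction
    dist = np.linalg.norm(G - ideal, axis=1)
    out = pd.DataFrame({"ideal_distance": dist}, index=gge.genotype_scores2d.index)
    out["rank"] = out["ideal_distance"].rank(ascending=True, method="average")
    return out.sort_values("ideal_distance")


def environment_evaluation(gge: GGEResult) -> pd.DataFrame:
    """Discriminativeness (vector length) and representativeness (cos to AEA).

    A longer environment vector separates genotypes more; a smaller
    angle to the AEA marks a more typical environment.  Environments
    with zero-length vectors get NaN representativeness and are flagged.
    """
    E = gge.environment_scores2d.to_numpy()
    length = np.linalg.norm(E, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(length > 1e-12, (E @ gge.aea_direction) / length, np.nan)
    out = pd.DataFrame(
        {
            "vector_length": length,
            "cos_angle_to_aea": cos,
            "zero_length": length <= 1e-12,
        },
        index=gge.environment_scores2d.index,
    )
    out["discriminativeness_rank"] = out["vector_length"].rank(
        ascending=False, method="average"
    )
    out["representativeness_rank"] = out["cos_angle_to_aea"].rank(
        ascending=False, method="average"
    )
    return out


def environment_desirability(gge: GGEResult) -> pd.DataFrame:
    """Composite environment index: normalized length times cos to AEA.

    Vector lengths are min-max normalized to [0, 1] before multiplying
    by the representativeness cosine; ties share the average rank.
    """
    ev = environment_evaluation(gge)
    length = ev["vector_length"]
    span = length.max() - length.min()
    norm_len = (length - length.min()) / span if span > 0 else length * 0 + 1.0
    out = pd.DataFrame(
        {"desirability": norm_len * ev["cos_angle_to_aea"]}, index=ev.index
    )
    out["rank"] = out["desirability"].rank(ascending=False, method="average")
    return out


@dataclass
class SectorPartition:
    """Which-won-where geometry: hull, sector boundaries, winners."""

    hull_vertex_genotypes: list[str]
    sector_boundaries: np.ndarray  # one unit boundary ray per hull edge
    environment_sector: dict[str, int]  # environment -> index into hull vertices
    sector_winner: dict[int, str]
    mega_environments: dict[str, list[str]]  # winner genotype -> environments


def which_won_where(gge: GGEResult) -> SectorPartition:
    """Partition environments by their winning hull-vertex genotype.

    Each environment's winner maximises the projection of genotype
    scores onto the environment vector; because that maximum of a linear
    functional is attained at a vertex of the convex hull, the plane
    splits into angular sectors bounded by lines through the origin
    perpendicular to the hull edges.  Projection ties break
    lexicographically by genotype label.
    """
    G = gge.genotype_scores2d.to_numpy()
    labels = gge.genotype_labels
    if np.linalg.matrix_rank(G - G.mean(axis=0), tol=1e-10) < 2:
        raise DegenerateGeometryError("genotype scores are collinear")
    hull = ConvexHull(G)
    vertex_idx = list(hull.vertices)  # counter-clockwise
    vertices = G[vertex_idx]
    h = len(vertex_idx)

    # Boundary rays: for hull edge (a, b) the tie direction d satisfies
    # d . a = d . b, i.e. d is perpendicular to b - a; keep the sign for
    # which the tied pair attains the hull maximum.
    rays = []
    for i in range(h):
        a, b = vertices[i], vertices[(i + 1) % h]
        d = np.array([-(b - a)[1], (b - a)[0]])
        d = d / np.linalg.norm(d)
        if np.max(vertices @ d) > (a @ d) + 1e-9:
            d = -d
        rays.append(d)
    rays_arr = np.vstack(rays)

    env_sector: dict[str, int] = {}
    sector_winner: dict[int, str] = {}
    for env, vec in gge.environment_scores2d.iterrows():
        v = vec.to_numpy()
        proj = vertices @ v
        best = proj.max()
        tied = [i for i in range(h) if proj[i] >= best - 1e-12]
        win = min(tied, key=lambda i: labels[vertex_idx[i]])
        env_sector[env] = win
        sector_winner.setdefault(win, labels[vertex_idx[win]])
    mega: dict[str, list[str]] = {}
    for env, sector in env_sector.items():
        mega.setdefault(sector_winner[sector], []).append(env)
    return SectorPartition(
        hull_vertex_genotypes=[labels[i] for i in vertex_idx],
        sector_boundaries=rays_arr,
        environment_sector=env_sector,
        sector_winner=sector_winner,
        mega_environments=mega,
    )


@dataclass
class BootstrapCL:
    """Percentile confidence limits for 2-D biplot scores."""

    genotype_lower: pd.DataFrame
    genotype_upper: pd.DataFrame
    environment_lower: pd.DataFrame
    environment_upper: pd.DataFrame
    level: float
    B: int
    point: GGEResult


def bootstrap_cl(
    dataset: METDataset,
    trait: str,
    B: int = 500,
    level: float = 0.95,
    seed: int = 0,
    svp: str = "row_metric",
) -> BootstrapCL:
    """Nonparametric bootstrap CLs for genotype and environment scores.

    Replicates are resampled with replacement within each cell, the
    cell means recomputed and the GGE SVD repeated; each draw's stacked
    2-D scores are aligned to the full-data scores by orthogonal
    Procrustes rotation before taking percentile limits coordinate-wise.
    """
    if dataset.level != "replicate":
        raise ValueError(
            "bootstrap requires replicate-level data: cell means leave no resampling unit"
        )
    if B < 100:
        raise ValueError("B must be at least 100")
    matrix = cell_means(dataset, trait)
    point = gge_decompose(matrix, svp=svp, trait_direction=dataset.trait_direction(trait))
    ref = np.vstack([point.genotype_scores2d.to_numpy(), point.environment_scores2d.to_numpy()])
    g, e, r = matrix.g, matrix.e, matrix.r

    sub = dataset.data[dataset.data["trait"] == trait]
    # replicate cube: g x e x r in label order
    cube = (
        sub.set_index(["genotype", "environment", "replicate"])["value"]
        .unstack("replicate")
        .loc[pd.MultiIndex.from_product([matrix.genotype_labels, matrix.environment_labels])]
        .to_numpy()
        .reshape(g, e, r)
    )
    rng = np.random.default_rng(seed)
    draws = np.empty((B, g + e, 2))
    for b in range(B):
        idx = rng.integers(0, r, size=(g, e, r))
        means = np.take_along_axis(cube, idx, axis=2).mean(axis=2)
        rep = gge_decompose(
            CellMeanMatrix(
                values=means,
                genotype_labels=matrix.genotype_labels,
                environment_labels=matrix.environment_labels,
                r=r,
                trait=trait,
            ),
            svp=svp,
            trait_direction=point.trait_direction,
        )
        S = np.vstack(
            [rep.genotype_scores2d.to_numpy(), rep.environment_scores2d.to_numpy()]
        )
        R, _ = orthogonal_procrustes(S, ref)
        draws[b] = S @ R
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1.0 - alpha, axis=0)
    cols = ["PC1", "PC2"]
    return BootstrapCL(
        genotype_lower=pd.DataFrame(lo[:g], index=matrix.genotype_labels, columns=cols),
        genotype_upper=pd.DataFrame(hi[:g], index=matrix.genotype_labels, columns=cols),
        environment_lower=pd.DataFrame(lo[g:], index=matrix.environment_labels, columns=cols),
        environment_upper=pd.DataFrame(hi[g:], index=matrix.environment_labels, columns=cols),
        level=level,
        B=B,
        point=point,
    )
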