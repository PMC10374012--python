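"""Heritability, rank correlations and hierarchical clustering.

Broad-sense heritability is estimated per location from the
randomized-block ANOVA on an entry-mean basis:

    sigma2_g = max(0, (MS_genotype - MS_error) / r)
    H2       = sigma2_g / (sigma2_g + sigma2_e / r),

where MS_error is the genotype x block residual after removing block
effects, and the error variance is divided by the replicate count
because selection acts on genotype means over r plots.  Block variance
is excluded from the phenotypic denominator (blocks are removed by
design).

Environment-environment and trait-trait association use Spearman rank
correlation; relatedness dendrograms use Ward linkage on Euclidean
distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .met_data import CellMeanMatrix, METDataset, cell_means

__all__ = [
    "HeritabilityEstimate",
    "heritability",
    "heritability_table",
    "spearman_matrix",
    "trait_correlations",
    "ward_cluster",
]


@dataclass
class HeritabilityEstimate:
    """Variance components and broad-sense H2 for one trait at one location."""

    location: str
    trait: str
    ms_genotype: float
    ms_error: float
    r: int
    sigma2_g: float
    sigma2_e: float
    H2: float


def heritability(dataset: METDataset, trait: str, location: str) -> HeritabilityEstimate:
    """Entry-mean broad-sense heritability from a one-location RBD ANOVA."""
    if dataset.level != "replicate":
        raise ValueError("heritability needs replicate-level data")
    if trait not in dataset.traits:
        raise KeyError(f"unknown trait {trait!r}")
    if location not in dataset.environments:
        raise KeyError(f"unknown location {location!r}")
    sub = dataset.data[
        (dataset.data["trait"] == trait) & (dataset.data["environment"] == location)
    ]
    table = sub.pivot(index="genotype", columns="replicate", values="value")
    if table.isna().any().any():
        raise ValueError("unbalanced genotype x block table at this location")
    y = table.to_numpy()
    g, r = y.shape
    if r < 2:
        raise ValueError("heritability needs at least 2 replicates")
    mu = y.mean()
    ss_gen = r * ((y.mean(axis=1) - mu) ** 2).sum()
    ss_block = g * ((y.mean(axis=0) - mu) ** 2).sum()
    ss_tot = ((y - mu) ** 2).sum()
    ss_err = ss_tot - ss_gen - ss_block
    ms_gen = ss_gen / (g - 1)
    ms_err = max(0.0, ss_err) / ((g - 1) * (r - 1))
    sigma2_g = max(0.0, (ms_gen - ms_err) / r)
    sigma2_e = ms_err
    denom = sigma2_g + sigma2_e / r
    H2 = 0.0 if denom == 0 else min(1.0, max(0.0, sigma2_g / denom))
    return HeritabilityEstimate(
        location=location,
        trait=trait,
        ms_genotype=float(ms_gen),
        ms_error=float(ms_err),
        r=r,
        sigma2_g=float(sigma2_g),
        sigma2_e=float(sigma2_e),
        H2=float(H2),
    )


def heritability_table(dataset: METDataset) -> pd.DataFrame:
    """H2 for every (location, trait) pair, one row each."""
    rows = []
    for trait in dataset.traits:
        for location in dataset.environments:
            est = heritability(dataset, trait, location)
            rows.append(vars(est))
    return pd.DataFrame(rows)


def spearman_matrix(matrix: CellMeanMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho between environment columns over genotypes.

    Returns (rho, p) DataFrames; a constant column yields NaN for its
    correlations.  Ties get average ranks; p-values are two-sided.
    """
    if matrix.g < 3:
        raise ValueError("Spearman correlation needs at least 3 genotypes")
    envs = matrix.environment_labels
    e = len(envs)
    rho = np.ones((e, e))
    p = np.zeros((e, e))
    for i in range(e):
        for j in range(i + 1, e):
            xi, xj = matrix.values[:, i], matrix.values[:, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                r_ij = p_ij = np.nan
            else:
                res = stats.spearmanr(xi, xj)
                r_ij, p_ij = float(res.statistic), float(res.pvalue)
            rho[i, j] = rho[j, i] = r_ij
            p[i, j] = p[j, i] = p_ij
    return (
        pd.DataFrame(rho, index=envs, columns=envs),
        pd.DataFrame(p, index=envs, columns=envs),
    )


def trait_correlations(dataset: METDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho between traits over their genotype means."""
    traits = dataset.traits
    if len(traits) < 2:
        raise ValueError("need at least 2 traits")
    means = {}
    for trait in traits:
        m = cell_means(dataset, trait, r=dataset.metadata.get("r", 1))
        means[trait] = pd.Series(m.values.mean(axis=1), index=m.genotype_labels)
    common = set.intersection(*(set(s.index) for s in means.values()))
    if not common:
        raise ValueError("traits share no genotypes")
    order = [g for g in dataset.genotypes if g in common]
    t = len(traits)
    rho = np.ones((t, t))
    p = np.zeros((t, t))
    for i in range(t):
        for j in range(i + 1, t):
            res = stats.spearmanr(
                means[traits[i]].loc[order], means[traits[j]].loc[order]
            )
            rho[i, j] = rho[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    return (
        pd.DataFrame(rho, index=traits, columns=traits),
        pd.DataFrame(p, index=traits, columns=traits),
    )


def ward_cluster(matrix: CellMeanMatrix, axis: str = "genotypes") -> pd.DataFrame:
    """Ward-linkage hierarchical clustering of row or column profiles.

    Returns the merge list: each row gives the two merged cluster ids
    (original items are 0..n-1, merges continue from n), the merge
    height and the new cluster's size.  Heights are non-decreasing.
    """
    if axis == "genotypes":
        X = matrix.values
        labels = matrix.genotype_labels
    elif axis == "environments":
        X = matrix.values.T
        labels = matrix.environment_labels
    else:
        raise ValueError("axis must be 'genotypes' or 'environments'")
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least 2 items")
    Z = hierarchy.linkage(X, method="ward")
    out = pd.DataFrame(Z, columns=["left", "right", "height", "size"])
    out[["left", "right", "size"]] = out[["left", "right", "size"]].astype(int)
    out.attrs["labels"] = labels
    return out
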