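"""Joint two-way ANOVA and the AMMI decomposition.

The additive main effects and multiplicative interaction (AMMI) model
splits a balanced genotype x environment table of cell means into
additive genotype and environment effects plus a singular value
decomposition of the doubly-centered interaction residual

    Z_ij = Ybar_ij - Gbar_i - Ebar_j + mu,     Z = sum_n lambda_n gamma_n delta_n',

whose axes are the interaction principal components (IPCA).  Sums of
squares are on the replicate scale: SS(PCn) = r * lambda_n^2, and
SS(GEN) + SS(ENV) + SS(GENxENV) equals r times the total SS of the cell
means about the grand mean.

IPCA significance uses Gollob degrees of freedom, df_n = g + e - 1 - 2n,
with F ratios against the pooled replicate-level residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .met_data import CellMeanMatrix, METDataset, cell_means

__all__ = [
    "AMMIResult",
    "joint_anova",
    "ammi_decompose",
    "ipca_tests",
    "ammi1_coords",
    "pooled_residual",
    "bartlett_homogeneity",
    "lsd",
    "gollob_df",
]


def gollob_df(g: int, e: int, n: int) -> int:
    """Degrees of freedom of the n-th IPCA axis (Gollob convention)."""
    return g + e - 1 - 2 * n


@dataclass
class AMMIResult:
    """Additive effects plus the interaction SVD of one trait."""

    grand_mean: float
    genotype_effects: pd.Series
    environment_effects: pd.Series
    singular_values: np.ndarray
    genotype_scores: pd.DataFrame  # g x K orthonormal columns (gamma)
    environment_scores: pd.DataFrame  # e x K orthonormal columns (delta)
    r: int
    residual_ms: float | None = None
    residual_df: int | None = None

    @property
    def K(self) -> int:
        return len(self.singular_values)

    @property
    def g(self) -> int:
        return len(self.genotype_effects)

    @property
    def e(self) -> int:
        return len(self.environment_effects)

    @property
    def gollob_df(self) -> np.ndarray:
        return np.array([gollob_df(self.g, self.e, n) for n in range(1, self.K + 1)])

    @property
    def ss_interaction(self) -> float:
        return float(self.r * (self.singular_values**2).sum())

    def interaction_matrix(self) -> np.ndarray:
        """Reconstruct Z from the retained axes."""
        lam = self.singular_values
        return (self.genotype_scores.to_numpy() * lam) @ self.environment_scores.to_numpy().T

    def reconstruct(self) -> np.ndarray:
        """Cell means implied by mu + g_i + e_j + sum lambda gamma delta."""
        return (
            self.grand_mean
            + self.genotype_effects.to_numpy()[:, None]
            + self.environment_effects.to_numpy()[None, :]
            + self.interaction_matrix()
        )


def _double_center(Y: np.ndarray):
    mu = Y.mean()
    gi = Y.mean(axis=1) - mu
    ej = Y.mean(axis=0) - mu
    Z = Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0, keepdims=True) + mu
    return mu, gi, ej, Z


def joint_anova(
    matrix: CellMeanMatrix,
    residual_ms: float | None = None,
    residual_df: int | None = None,
) -> pd.DataFrame:
    """Combined ANOVA across locations from a balanced cell-mean matrix.

    Returns rows ENV, GEN, GEN×ENV (plus Residual if a residual stratum
    is supplied) with df, SS, MS, F, p and each main row's percentage of
    the three-way total.  F and p are only filled when a residual mean
    square is available.
    """
    g, e, r = matrix.g, matrix.e, matrix.r
    if g < 2 or e < 2:
        raise ValueError("joint ANOVA needs at least 2 genotypes and 2 environments")
    mu, gi, ej, Z = _double_center(matrix.values)
    ss_env = r * g * float((ej**2).sum())
    ss_gen = r * e * float((gi**2).sum())
    ss_ge = r * float((Z**2).sum())
    total = ss_env + ss_gen + ss_ge
    rows = [
        ("ENV", e - 1, ss_env),
        ("GEN", g - 1, ss_gen),
        ("GEN×ENV", (g - 1) * (e - 1), ss_ge),
    ]
    out = []
    for source, df, ss in rows:
        ms = ss / df
        if residual_ms is not None and residual_df is not None and residual_ms > 0:
            F = ms / residual_ms
            p = float(stats.f.sf(F, df, residual_df))
        else:
            F = p = np.nan
        out.append(
            {
                "source": source,
                "df": df,
                "SS": ss,
                "MS": ms,
                "F": F,
                "p": p,
                "pct_TSS": 100.0 * ss / total,
            }
        )
    if residual_ms is not None and residual_df is not None:
        out.append(
            {
                "source": "Residual",
                "df": residual_df,
                "SS": residual_ms * residual_df,
                "MS": residual_ms,
                "F": np.nan,
                "p": np.nan,
                "pct_TSS": 0.0,
            }
        )
    return pd.DataFrame(out)


def ammi_decompose(matrix: CellMeanMatrix) -> AMMIResult:
    """SVD of the doubly-centered interaction matrix.

    All min(g, e) axes are retained; the trailing axis of a doubly
    centered matrix has singular value 0 and is reported as the zero
    axis.  Sign policy: the first nonzero entry of each genotype-score
    column is positive.
    """
    if min(matrix.g, matrix.e) < 2:
        raise ValueError("AMMI needs at least a 2 x 2 table")
    mu, gi, ej, Z = _double_center(matrix.values)
    U, lam, Vt = np.linalg.svd(Z, full_matrices=False)
    V = Vt.T
    for k in range(U.shape[1]):
        nz = np.flatnonzero(np.abs(U[:, k]) > 1e-12)
        if nz.size and U[nz[0], k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    axes = [f"IPC{n}" for n in range(1, len(lam) + 1)]
    return AMMIResult(
        grand_mean=float(mu),
        genotype_effects=pd.Series(gi, index=matrix.genotype_labels, name="effect"),
        environment_effects=pd.Series(ej, index=matrix.environment_labels, name="effect"),
        singular_values=lam,
        genotype_scores=pd.DataFrame(U, index=matrix.genotype_labels, columns=axes),
        environment_scores=pd.DataFrame(V, index=matrix.environment_labels, columns=axes),
        r=matrix.r,
    )


def ipca_tests(
    result: AMMIResult,
    residual_ms: float | None = None,
    residual_df: int | None = None,
) -> pd.DataFrame:
    """IPCA ANOVA rows: PCn with Gollob df, F against the residual stratum.

    Percentages are of the interaction SS, reported both plain and
    cumulative.  Axes whose Gollob df would be non-positive are reported
    without tests.
    """
    ss_ge = result.ss_interaction
    rows = []
    cum = 0.0
    for n in range(1, result.K + 1):
        lam = result.singular_values[n - 1]
        ss = result.r * lam**2
        pct = 100.0 * ss / ss_ge if ss_ge > 0 else 0.0
        cum += pct
        df = gollob_df(result.g, result.e, n)
        if df > 0:
            ms = ss / df
            if residual_ms is not None and residual_df is not None and residual_ms > 0:
                F = ms / residual_ms
                p = float(stats.f.sf(F, df, residual_df))
            else:
                F = p = np.nan
        else:
            df, ms, F, p = 0, np.nan, np.nan, np.nan
        rows.append(
            {
                "source": f"PC{n}",
                "df": df,
                "SS": ss,
                "MS": ms,
                "F": F,
                "p": p,
                "pct_GE": pct,
                "cum_pct_GE": cum,
            }
        )
    return pd.DataFrame(rows)


def ammi1_coords(result: AMMIResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AMMI1 biplot coordinates: marginal mean vs IPC1 score.

    The ordinate uses the symmetric partition sqrt(lambda_1) * score so
    genotypes and environments share one scale.
    """
    if result.K < 1:
        raise ValueError("no interaction axes available")
    s1 = np.sqrt(result.singular_values[0])
    genotypes = pd.DataFrame(
        {
            "mean": result.grand_mean + result.genotype_effects,
            "ipc1": s1 * result.genotype_scores["IPC1"],
        }
    )
    environments = pd.DataFrame(
        {
            "mean": result.grand_mean + result.environment_effects,
            "ipc1": s1 * result.environment_scores["IPC1"],
        }
    )
    return genotypes, environments


def _replicate_table(dataset: METDataset, trait: str) -> pd.DataFrame:
    if dataset.level != "replicate":
        raise ValueError("replicate-level data required")
    if trait not in dataset.traits:
        raise KeyError(f"unknown trait {trait!r}")
    return dataset.data[dataset.data["trait"] == trait]


def pooled_residual(dataset: METDataset, trait: str) -> tuple[float, int]:
    """Pooled within-cell residual mean square and df from replicate data.

    This is the error stratum of the combined analysis when replicates
    within a cell are treated as the plot error: df = sum over cells of
    (n_cell - 1).
    """
    sub = _replicate_table(dataset, trait)
    grouped = sub.groupby(["genotype", "environment"], sort=False)["value"]
    ss = float(((sub["value"] - grouped.transform("mean")) ** 2).sum())
    df = int((grouped.size() - 1).sum())
    if df <= 0:
        raise ValueError("no residual degrees of freedom (r must exceed 1)")
    return ss / df, df


def bartlett_homogeneity(dataset: METDataset, trait: str) -> tuple[float, float]:
    """Bartlett's test of error-variance homogeneity across environments.

    Applied descriptively to the within-cell residuals of each
    environment before pooling errors in the combined analysis; it gates
    nothing downstream.
    """
    sub = _replicate_table(dataset, trait)
    resid = sub["value"] - sub.groupby(["genotype", "environment"], sort=False)[
        "value"
    ].transform("mean")
    groups = [resid[sub["environment"] == env].to_numpy() for env in dataset.environments]
    stat, p = stats.bartlett(*groups)
    return float(stat), float(p)


def lsd(
    dataset: METDataset, trait: str, alpha: float = 0.05, factor: str = "genotype"
) -> float:
    """Least significant difference between factor means at level alpha.

    Uses the pooled within-cell error; each genotype mean averages
    r * e plots (r * g for environment means).
    """
    sub = _replicate_table(dataset, trait)
    ms, df = pooled_residual(dataset, trait)
    if factor == "genotype":
        n_per_mean = len(sub) / len(dataset.genotypes)
    elif factor == "environment":
        n_per_mean = len(sub) / len(dataset.environments)
    else:
        raise ValueError("factor must be 'genotype' or 'environment'")
    t = stats.t.ppf(1 - alpha / 2, df)
    return float(t * np.sqrt(2.0 * ms / n_per_mean))


def anova_from_dataset(
    dataset: METDataset, trait: str, r: int | None = None
) -> tuple[pd.DataFrame, AMMIResult]:
    """Convenience: joint ANOVA + IPCA rows straight from a dataset.

    At replicate level the pooled residual is computed automatically and
    attached to the decomposition; at cell-mean level F columns stay
    empty unless the caller supplies a residual elsewhere.
    """
    matrix = cell_means(dataset, trait, r=r)
    result = ammi_decompose(matrix)
    if dataset.level == "replicate":
        ms, df = pooled_residual(dataset, trait)
        result.residual_ms, result.residual_df = ms, df
    table = joint_anova(matrix, result.residual_ms, result.residual_df)
    pcs = ipca_tests(result, result.residual_ms, result.residual_df)
    pcs = pcs.rename(columns={"pct_GE": "pct_TSS"})
    table = pd.concat([table, pcs.drop(columns=["cum_pct_GE"])], ignore_index=True)
    # Table layout: main effects, PC axes, residual stratum last
    order = [i for i, s in enumerate(table["source"]) if s != "Residual"]
    order += [i for i, s in enumerate(table["source"]) if s == "Residual"]
    return table.iloc[order].reset_index(drop=True), result
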