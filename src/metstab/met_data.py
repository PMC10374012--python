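"""Data model and I/O for multi-environment trial (MET) tables.

A MET evaluates a common set of genotypes in several environments
(locations) under a replicated design.  Observations live in a tidy
long-format table — one row per plot (replicate level) or per
genotype-environment cell (cell-mean level) — and are pivoted into a
dense genotype x environment matrix of cell means before any
decomposition.

The packaged lentil fixture carries grain iron (Fe, mg/kg), zinc
(Zn, mg/kg) and phytic acid (PA, g/100 g dry weight) cell means for 16
Indian lentil cultivars grown at six locations with three replicates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "METDataset",
    "CellMeanMatrix",
    "BalanceError",
    "load_met_table",
    "write_met_table",
    "lentil_fixture",
    "cell_means",
    "descriptive_stats",
    "DescriptiveStats",
    "phytic_acid_from_phosphorus",
    "phosphorus_from_absorbance",
    "TRAIT_DIRECTIONS",
    "AL_CONTAMINATION_PPM",
]

#: Nutritional direction of each fixture trait: grain Fe and Zn are
#: bred upward, phytic acid (an absorption inhibitor) downward.
TRAIT_DIRECTIONS = {"Fe": "higher_better", "Zn": "higher_better", "PA": "lower_better"}

#: Phytic acid contains 28.2% phosphorus by mass; assay phosphorus is
#: converted to phytic acid by dividing by this ratio.
PHOSPHORUS_IN_PHYTIC_ACID = 0.282

#: Colorimetric phosphorus calibration line: absorbance = a + b * conc.
CALIBRATION_INTERCEPT = 0.00461
CALIBRATION_SLOPE = 0.16857

#: Grain samples with aluminium above this level are treated as
#: dust-contaminated and excluded from analysis.
AL_CONTAMINATION_PPM = 5.0

REQUIRED_COLUMNS = ("genotype", "environment", "trait", "value")


class BalanceError(ValueError):
    """Raised when a trait's genotype x environment factorial is incomplete.

    ``missing_cells`` lists the absent (genotype, environment) pairs.
    """

    def __init__(self, trait: str, missing_cells: list[tuple[str, str]]):
        self.trait = trait
        self.missing_cells = missing_cells
        shown = ", ".join(f"({g}, {e})" for g, e in missing_cells[:5])
        more = "" if len(missing_cells) <= 5 else f" and {len(missing_cells) - 5} more"
        super().__init__(
            f"trait {trait!r}: incomplete factorial, missing cells {shown}{more}"
        )


@dataclass
class METDataset:
    """Tidy MET observations plus their aggregation level.

    ``data`` holds columns genotype, environment, trait, value and, at
    replicate level, replicate.  Label order follows first appearance.
    """

    data: pd.DataFrame
    level: str  # "replicate" or "cell_mean"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("replicate", "cell_mean"):
            raise ValueError(f"unknown level {self.level!r}")
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("no records")
        values = pd.to_numeric(df["value"], errors="coerce")
        if values.isna().any():
            bad = df.loc[values.isna(), "value"].iloc[0]
            raise ValueError(f"non-numeric value {bad!r}")
        if not np.isfinite(values).all() or (values <= 0).any():
            raise ValueError("concentration values must be strictly positive and finite")
        self.data = df.assign(value=values.astype(float)).reset_index(drop=True)
        if self.level == "replicate":
            if "replicate" not in df.columns:
                raise ValueError("replicate-level data needs a 'replicate' column")
            keys = ["genotype", "environment", "replicate", "trait"]
        else:
            keys = ["genotype", "environment", "trait"]
        if self.data.duplicated(subset=keys).any():
            dup = self.data[self.data.duplicated(subset=keys)].iloc[0]
            raise ValueError(f"duplicate record for {tuple(dup[k] for k in keys)}")
        for trait in self.traits:
            self._check_balance(trait)

    def _check_balance(self, trait: str) -> None:
        sub = self.data[self.data["trait"] == trait]
        genos = list(pd.unique(sub["genotype"]))
        envs = list(pd.unique(sub["environment"]))
        present = set(zip(sub["genotype"], sub["environment"]))
        missing = [(g, e) for g in genos for e in envs if (g, e) not in present]
        if missing:
            raise BalanceError(trait, missing)

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.data["trait"]))

    @property
    def genotypes(self) -> list[str]:
        return list(pd.unique(self.data["genotype"]))

    @property
    def environments(self) -> list[str]:
        return list(pd.unique(self.data["environment"]))

    def trait_direction(self, trait: str) -> str:
        directions = self.metadata.get("trait_directions", TRAIT_DIRECTIONS)
        return directions.get(trait, "higher_better")


@dataclass
class CellMeanMatrix:
    """Dense g x e matrix of cell means for a single trait."""

    values: np.ndarray
    genotype_labels: list[str]
    environment_labels: list[str]
    r: int
    trait: str
    grand_mean: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g, e = self.values.shape
        if g != len(self.genotype_labels) or e != len(self.environment_labels):
            raise ValueError("label lengths do not match matrix shape")
        if self.r < 1:
            raise ValueError("replicate count must be positive")
        mean = float(self.values.mean())
        if self.grand_mean is None:
            self.grand_mean = mean
        elif abs(self.grand_mean - mean) > 1e-9 * max(1.0, abs(mean)):
            raise ValueError("grand_mean inconsistent with matrix entries")

    @property
    def g(self) -> int:
        return self.values.shape[0]

    @property
    def e(self) -> int:
        return self.values.shape[1]

    def require_biplot_shape(self) -> None:
        if self.g < 3 or self.e < 3:
            raise ValueError("biplot operations need at least 3 genotypes and 3 environments")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.genotype_labels, columns=self.environment_labels
        )


def load_met_table(path, level: str = "cell_mean", metadata: dict | None = None) -> METDataset:
    """Read a tidy CSV (genotype, environment, [replicate,] trait, value).

    Rows whose optional ``al_ppm`` column exceeds the dust-contamination
    threshold are dropped; the count is recorded under
    ``metadata['n_excluded_al']``.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError("no records") from None
    if len(df) == 0 or df.columns.size == 0:
        raise ValueError("no records")
    meta = dict(metadata or {})
    if "al_ppm" in df.columns:
        contaminated = df["al_ppm"] > AL_CONTAMINATION_PPM
        meta["n_excluded_al"] = int(contaminated.sum())
        df = df.loc[~contaminated].drop(columns="al_ppm")
    return METDataset(df, level=level, metadata=meta)


def write_met_table(dataset: METDataset, path) -> None:
    """Write a dataset back to tidy CSV (inverse of :func:`load_met_table`)."""
    cols = ["genotype", "environment"]
    if dataset.level == "replicate":
        cols.append("replicate")
    cols += ["trait", "value"]
    dataset.data[cols].to_csv(path, index=False)


def lentil_fixture() -> METDataset:
    """The packaged lentil trial: 16 genotypes x 6 locations, Fe/Zn/PA cell means (r=3)."""
    text = resources.files("metstab.data").joinpath("lentil_fe_zn_pa.csv").read_text()
    ds = load_met_table(
        io.StringIO(text),
        level="cell_mean",
        metadata={
            "r": 3,
            "trait_directions": dict(TRAIT_DIRECTIONS),
            "description": "Lentil grain Fe/Zn/phytic-acid cell means, "
            "16 Indian cultivars x 6 locations, 2018-19 season, 3 replicates",
        },
    )
    return ds


def cell_means(dataset: METDataset, trait: str, r: int | None = None) -> CellMeanMatrix:
    """Pivot one trait into a g x e cell-mean matrix.

    At replicate level each entry averages the cell's replicates and
    ``r`` is inferred (all cells must share one replicate count).  At
    cell-mean level values are copied and ``r`` comes from the argument
    or ``metadata['r']`` (default 3, the usual RBD replication).
    """
    if trait not in dataset.traits:
        raise KeyError(f"unknown trait {trait!r}")
    sub = dataset.data[dataset.data["trait"] == trait]
    genos = list(pd.unique(sub["genotype"]))
    envs = list(pd.unique(sub["environment"]))
    if dataset.level == "replicate":
        counts = sub.groupby(["genotype", "environment"], sort=False).size()
        if counts.nunique() != 1:
            raise BalanceError(trait, [])
        r_eff = int(counts.iloc[0])
        table = sub.pivot_table(
            index="genotype", columns="environment", values="value", aggfunc="mean"
        )
    else:
        r_eff = int(r if r is not None else dataset.metadata.get("r", 3))
        table = sub.pivot(index="genotype", columns="environment", values="value")
    table = table.loc[genos, envs]
    if table.isna().any().any():
        missing = [
            (g, e) for g in genos for e in envs if pd.isna(table.at[g, e])
        ]
        raise BalanceError(trait, missing)
    return CellMeanMatrix(
        values=table.to_numpy(),
        genotype_labels=genos,
        environment_labels=envs,
        r=r_eff,
        trait=trait,
    )


@dataclass
class DescriptiveStats:
    """Column-wise summaries in the layout of a trial report table.

    ``environments``: per-environment mean/variance/SD/SE/CV% over the g
    genotype values of that column.  ``genotype_means``: each genotype's
    mean across environments.  ``overall``: the same summary computed
    over the genotype-mean column.  Variances use the sample (n-1)
    divisor; SE = SD/sqrt(n); CV% = 100*SD/mean.
    """

    environments: pd.DataFrame
    genotype_means: pd.Series
    overall: pd.Series


def _summary(x: np.ndarray) -> dict[str, float]:
    n = len(x)
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    sd = float(np.sqrt(var))
    if mean == 0.0 and sd > 0.0:
        raise ZeroDivisionError("CV undefined: zero mean with nonzero SD")
    cv = 0.0 if sd == 0.0 else 100.0 * sd / mean
    return {"mean": mean, "variance": var, "sd": sd, "se": sd / np.sqrt(n), "cv_pct": cv}


def descriptive_stats(matrix: CellMeanMatrix) -> DescriptiveStats:
    """Per-environment and per-genotype descriptive statistics."""
    if matrix.g < 2 or matrix.e < 2:
        raise ValueError("descriptive statistics need at least 2 genotypes and 2 environments")
    env_rows = {
        env: _summary(matrix.values[:, j])
        for j, env in enumerate(matrix.environment_labels)
    }
    genotype_means = pd.Series(
        matrix.values.mean(axis=1), index=matrix.genotype_labels, name="mean"
    )
    return DescriptiveStats(
        environments=pd.DataFrame.from_dict(env_rows, orient="index"),
        genotype_means=genotype_means,
        overall=pd.Series(_summary(genotype_means.to_numpy())),
    )


def phytic_acid_from_phosphorus(p: float) -> float:
    """Convert assayed phosphorus (g/100 g) to phytic acid (g/100 g)."""
    if p < 0:
        raise ValueError("phosphorus concentration cannot be negative")
    return p / PHOSPHORUS_IN_PHYTIC_ACID


def phosphorus_from_absorbance(a: float) -> float:
    """Invert the colorimetric calibration line to a phosphorus concentration."""
    if a < CALIBRATION_INTERCEPT:
        raise ValueError("absorbance below the calibration intercept")
    return (a - CALIBRATION_INTERCEPT) / CALIBRATION_SLOPE
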