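"""Full-study orchestration: every table and figure for one dataset."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.cluster import hierarchy

from . import __version__
from .ammi import anova_from_dataset
from .gge import (
    bootstrap_cl,
    environment_desirability,
    environment_evaluation,
    gge_decompose,
    ideal_genotype_ranking,
    mean_stability,
    which_won_where,
)
from .met_data import METDataset, cell_means, descriptive_stats
from .plotting import VIEWS, render_biplot
from .stability import heritability_table, spearman_matrix, trait_correlations, ward_cluster
from .synthetic import SyntheticMETConfig  # noqa: F401  (re-exported for configs)

__all__ = ["RunConfig", "run_full_analysis", "linkage_to_newick"]

log = logging.getLogger("metstab")


@dataclass
class RunConfig:
    """Configuration of a full-study run."""

    input: str | Path | None  # CSV path; None means the packaged lentil fixture
    output_dir: str | Path
    level: str = "cell_mean"
    traits: list[str] | None = None  # None: all traits in the dataset
    r: int = 3
    svp: str = "row_metric"
    bootstrap_B: int = 0  # 0 disables bootstrap CLs
    seed: int = 0
    trait_directions: dict[str, str] = field(default_factory=dict)
    figure_format: str = "svg"


def linkage_to_newick(linkage_df: pd.DataFrame) -> str:
    """Render a Ward merge list as a newick string with branch lengths."""
    labels = linkage_df.attrs["labels"]
    tree = hierarchy.to_tree(linkage_df[["left", "right", "height", "size"]].to_numpy())

    def walk(node, parent_height: float) -> str:
        length = max(0.0, parent_height - node.dist)
        if node.is_leaf():
            name = str(labels[node.id]).replace(" ", "_")
            return f"{name}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def run_full_analysis(dataset: METDataset, config: RunConfig) -> dict[str, Path]:
    """Write descriptive, ANOVA/AMMI, GGE, heritability and correlation tables.

    Returns a name -> path map of everything written.  Any stage error
    removes the partial outputs and re-raises with the stage name.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    traits = config.traits or dataset.traits
    if not traits:
        raise ValueError("no traits to analyse")
    written: dict[str, Path] = {}
    stage = "setup"

    def emit(name: str, path: Path) -> Path:
        written[name] = path
        return path

    try:
        for trait in traits:
            direction = config.trait_directions.get(
                trait, dataset.trait_direction(trait)
            )
            t0 = time.perf_counter()
            stage = f"{trait}:cell_means"
            matrix = cell_means(dataset, trait, r=config.r)

            stage = f"{trait}:descriptive"
            desc = descriptive_stats(matrix)
            table = desc.environments.copy()
            table.loc["Genotype means"] = desc.overall
            table.to_csv(emit(f"{trait}_descriptive", outdir / f"{trait}_descriptive.csv"))
            desc.genotype_means.to_csv(
                emit(f"{trait}_genotype_means", outdir / f"{trait}_genotype_means.csv")
            )

            stage = f"{trait}:anova"
            anova, ammi = anova_from_dataset(dataset, trait, r=config.r)
            anova.to_csv(emit(f"{trait}_anova", outdir / f"{trait}_anova.csv"), index=False)
            scores = pd.concat(
                [ammi.genotype_scores, ammi.environment_scores],
                keys=["genotype", "environment"],
            )
            scores.to_csv(emit(f"{trait}_ammi_scores", outdir / f"{trait}_ammi_scores.csv"))

            stage = f"{trait}:gge"
            gge = gge_decompose(matrix, svp=config.svp, trait_direction=direction)
            mean_stability(gge).to_csv(
                emit(f"{trait}_mean_stability", outdir / f"{trait}_mean_stability.csv")
            )
            ideal_genotype_ranking(gge).to_csv(
                emit(f"{trait}_ideal_ranking", outdir / f"{trait}_ideal_ranking.csv")
            )
            environment_evaluation(gge).to_csv(
                emit(f"{trait}_environments", outdir / f"{trait}_environments.csv")
            )
            environment_desirability(gge).to_csv(
                emit(f"{trait}_desirability", outdir / f"{trait}_desirability.csv")
            )
            part = which_won_where(gge)
            pd.DataFrame(
                {
                    "environment": list(part.environment_sector),
                    "sector": list(part.environment_sector.values()),
                    "winner": [
                        part.sector_winner[s] for s in part.environment_sector.values()
                    ],
                }
            ).to_csv(
                emit(f"{trait}_which_won_where", outdir / f"{trait}_which_won_where.csv"),
                index=False,
            )

            stage = f"{trait}:correlations"
            rho, pval = spearman_matrix(matrix)
            rho.to_csv(emit(f"{trait}_env_spearman", outdir / f"{trait}_env_spearman.csv"))
            pval.to_csv(
                emit(f"{trait}_env_spearman_p", outdir / f"{trait}_env_spearman_p.csv")
            )

            stage = f"{trait}:clustering"
            for axis in ("genotypes", "environments"):
                newick = linkage_to_newick(ward_cluster(matrix, axis=axis))
                path = emit(f"{trait}_ward_{axis}", outdir / f"{trait}_ward_{axis}.nwk")
                path.write_text(newick + "\n")

            stage = f"{trait}:figures"
            for view in VIEWS:
                path = outdir / f"{trait}_{view}.{config.figure_format}"
                render_biplot(gge, view, emit(f"{trait}_fig_{view}", path))

            if dataset.level == "replicate" and config.bootstrap_B >= 100:
                stage = f"{trait}:bootstrap"
                cl = bootstrap_cl(
                    dataset, trait, B=config.bootstrap_B, seed=config.seed, svp=config.svp
                )
                pd.concat(
                    {
                        "genotype_lower": cl.genotype_lower,
                        "genotype_upper": cl.genotype_upper,
                        "environment_lower": cl.environment_lower,
                        "environment_upper": cl.environment_upper,
                    }
                ).to_csv(emit(f"{trait}_bootstrap_cl", outdir / f"{trait}_bootstrap_cl.csv"))
            log.info(
                "trait %s: %d x %d cells, %.2fs",
                trait,
                matrix.g,
                matrix.e,
                time.perf_counter() - t0,
            )

        if len(traits) >= 2:
            stage = "trait_correlations"
            rho, pval = trait_correlations(dataset)
            rho.to_csv(emit("trait_spearman", outdir / "trait_spearman.csv"))
            pval.to_csv(emit("trait_spearman_p", outdir / "trait_spearman_p.csv"))

        if dataset.level == "replicate":
            stage = "heritability"
            heritability_table(dataset).to_csv(
                emit("heritability", outdir / "heritability.csv"), index=False
            )

        stage = "run_log"
        logpath = emit("run_log", outdir / "run_log.txt")
        logpath.write_text(
            "\n".join(
                [
                    f"metstab {__version__}",
                    f"input: {config.input or 'packaged lentil fixture'}",
                    f"level: {dataset.level}",
                    f"traits: {', '.join(traits)}",
                    f"r: {config.r}  svp: {config.svp}  seed: {config.seed}",
                    f"bootstrap_B: {config.bootstrap_B}",
                    f"outputs: {len(written)}",
                ]
            )
            + "\n"
        )
    except Exception as err:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err
    return written
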