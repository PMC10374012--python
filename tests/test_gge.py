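"""GGE decomposition and biplot geometry against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from metstab import (
    CellMeanMatrix,
    bootstrap_cl,
    cell_means,
    environment_desirability,
    environment_evaluation,
    generate_met,
    gge_decompose,
    ideal_genotype_ranking,
    mean_stability,
    random_config,
    which_won_where,
)
from metstab.gge import DegenerateGeometryError, GGEResult
from conftest import random_matrix


def matrix(values, r=1):
    values = np.asarray(values, dtype=float)
    g, e = values.shape
    return CellMeanMatrix(
        values,
        [f"g{i}" for i in range(g)],
        [f"e{j}" for j in range(e)],
        r=r,
        trait="T",
    )


def scores_result(G, E, trait_direction="higher_better"):
    """Hand-build a GGEResult from given 2-D scores (geometry-only tests)."""
    G = np.asarray(G, dtype=float)
    E = np.asarray(E, dtype=float)
    aea = E.mean(axis=0)
    aea = aea / np.linalg.norm(aea)
    means = G @ aea
    if means[int(np.argmax(means))] < 0:
        aea = -aea
    return GGEResult(
        centered=np.zeros((len(G), len(E))),
        singular_values=np.array([1.0, 1.0]),
        genotype_scores2d=pd.DataFrame(G, index=[f"g{i}" for i in range(len(G))],
                                       columns=["PC1", "PC2"]),
        environment_scores2d=pd.DataFrame(E, index=[f"e{j}" for j in range(len(E))],
                                          columns=["PC1", "PC2"]),
        pc_variance_pct=np.array([50.0, 50.0]),
        svp="row_metric",
        aea_direction=aea,
        trait_direction=trait_direction,
        trait="T",
        genotype_means=pd.Series(means, index=[f"g{i}" for i in range(len(G))]),
    )


class TestDecompose:
    def test_rank_one_after_centering(self):
        # pure genotype effects: centered matrix is rank 1
        Y = 50.0 + np.outer([1.0, 2.0, 3.0, 4.0], np.ones(3))
        res = gge_decompose(matrix(Y))
        assert res.pc_variance_pct[0] == pytest.approx(100.0)
        assert res.pc_variance_pct[1:] == pytest.approx(0.0, abs=1e-9)

    def test_fixture_fe_axis_shares(self, fe_matrix):
        res = gge_decompose(fe_matrix)
        assert res.pc_variance_pct.sum() == pytest.approx(100.0, rel=1e-9)
        # first two axes of the environment-centered Fe decomposition
        assert res.pc_variance_pct[0] == pytest.approx(49.44, abs=0.01)
        assert res.pc_variance_pct[:2].sum() == pytest.approx(67.86, abs=0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        Y = random_matrix(rng, 5, 4)
        res = gge_decompose(matrix(Y))
        C = Y - Y.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(C.T @ C))[::-1]
        np.testing.assert_allclose(res.singular_values**2, eigvals, atol=1e-8)

    def test_row_metric_scaling_invariant(self, fe_matrix):
        res = gge_decompose(fe_matrix, svp="row_metric")
        G = res.genotype_scores2d.to_numpy()
        E = res.environment_scores2d.to_numpy()
        np.testing.assert_allclose(
            (G**2).sum(axis=0), res.singular_values[:2] ** 2, rtol=1e-9
        )
        np.testing.assert_allclose(E.T @ E, np.eye(2), atol=1e-9)

    def test_constant_matrix_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            gge_decompose(matrix(np.full((4, 3), 7.0)))

    def test_environment_permutation_leaves_genotype_stats_unchanged(self, fe_matrix):
        res = gge_decompose(fe_matrix)
        base = mean_stability(res)
        perm = np.random.default_rng(1).permutation(6)
        m2 = CellMeanMatrix(
            fe_matrix.values[:, perm],
            fe_matrix.genotype_labels,
            [fe_matrix.environment_labels[j] for j in perm],
            r=3,
            trait="Fe",
        )
        other = mean_stability(gge_decompose(m2))
        np.testing.assert_allclose(
            base["aea_projection"], other["aea_projection"], atol=1e-9
        )
        np.testing.assert_allclose(base["aec_distance"], other["aec_distance"], atol=1e-9)


class TestMeanStability:
    def test_additive_data_all_stable(self):
        c = random_config(g=6, e=5, r=2, K=0, lambdas=(), sigma_error=0.0, seed=8,
                          effect_sd_g=5.0, effect_sd_e=3.0)
        ds = generate_met(c)
        res = gge_decompose(cell_means(ds, c.trait))
        table = mean_stability(res)
        np.testing.assert_allclose(table["aec_distance"], 0.0, atol=1e-8)

    def test_hand_placed_geometry(self):
        # environments at (+-1, 0) => AEA along x; genotype at (0, 1)
        res = scores_result(
            G=[[0.0, 1.0], [2.0, 0.0], [1.0, 0.5]], E=[[1.0, 0.0], [0.5, 0.0]]
        )
        table = mean_stability(res)
        assert table.loc["g0", "aea_projection"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["g0", "aec_distance"] == pytest.approx(1.0)
        assert table.loc["g1", "mean_rank"] == 1.0

    def test_lower_better_inverts_mean_rank(self):
        res = scores_result(
            G=[[0.0, 1.0], [2.0, 0.0], [1.0, 0.5]],
            E=[[1.0, 0.0], [0.5, 0.0]],
            trait_direction="lower_better",
        )
        table = mean_stability(res)
        assert table.loc["g0", "mean_rank"] == 1.0


class TestIdealRanking:
    def test_genotype_at_ideal_point(self):
        # AEA lies exactly along x, so g0 at (2, 0) IS the ideal point
        res = scores_result(G=[[2.0, 0.0], [1.0, 1.0], [0.0, -1.0]],
                            E=[[1.0, 0.0], [0.8, 0.0]])
        table = ideal_genotype_ranking(res)
        assert table.index[0] == "g0"
        assert table.loc["g0", "ideal_distance"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc["g0", "rank"] == 1.0

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force_distances(self, seed):
        rng = np.random.default_rng(seed)
        Y = random_matrix(rng, 6, 4)
        res = gge_decompose(matrix(Y))
        table = ideal_genotype_ranking(res)
        G = res.genotype_scores2d.to_numpy()
        proj = G @ res.aea_direction
        ideal = proj.max() * res.aea_direction
        expected = sorted(np.sqrt(((G - ideal) ** 2).sum(axis=1)))
        np.testing.assert_allclose(table["ideal_distance"].to_numpy(), expected, atol=1e-9)


class TestEnvironmentEvaluation:
    def test_collinear_environment_fully_representative(self):
        res = scores_result(G=[[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]],
                            E=[[2.0, 0.0], [1.0, 0.0]])
        ev = environment_evaluation(res)
        np.testing.assert_allclose(ev["cos_angle_to_aea"], 1.0, atol=1e-12)
        assert ev.loc["e0", "discriminativeness_rank"] == 1.0

    def test_desirability_composite_and_ties(self):
        res = scores_result(
            G=[[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]],
            E=[[2.0, 0.0], [1.0, 0.0], [1.0, 0.0]],
        )
        des = environment_desirability(res)
        assert des.loc["e0", "rank"] == 1.0
        # tied environments share the average rank
        assert des.loc["e1", "rank"] == des.loc["e2", "rank"] == 2.5
        # brute-force recomputation
        ev = environment_evaluation(res)
        ln = ev["vector_length"]
        norm = (ln - ln.min()) / (ln.max() - ln.min())
        np.testing.assert_allclose(
            des["desirability"], norm * ev["cos_angle_to_aea"], atol=1e-12
        )


class TestWhichWonWhere:
    def test_dominant_genotype_wins_everywhere(self):
        rng = np.random.default_rng(5)
        Y = random_matrix(rng, 5, 4, scale=1.0)
        Y[0] += 50.0  # uniformly dominant after centering
        part = which_won_where(gge_decompose(matrix(Y)))
        assert set(part.mega_environments) == {"g0"}

    @pytest.mark.parametrize("seed", [6, 7, 8])
    def test_winner_is_brute_force_argmax(self, seed):
        """Each environment's winner maximises the rank-2 projection over
        ALL genotypes, not just hull vertices."""
        rng = np.random.default_rng(seed)
        Y = random_matrix(rng, 7, 5)
        res = gge_decompose(matrix(Y))
        part = which_won_where(res)
        G = res.genotype_scores2d
        for env, vec in res.environment_scores2d.iterrows():
            winner = part.sector_winner[part.environment_sector[env]]
            proj = G.to_numpy() @ vec.to_numpy()
            assert proj[G.index.get_loc(winner)] == pytest.approx(proj.max(), abs=1e-9)

    def test_boundaries_perpendicular_to_hull_edges(self, fe_matrix):
        res = gge_decompose(fe_matrix)
        part = which_won_where(res)
        hull = res.genotype_scores2d.loc[part.hull_vertex_genotypes].to_numpy()
        h = len(hull)
        for i, ray in enumerate(part.sector_boundaries):
            edge = hull[(i + 1) % h] - hull[i]
            assert abs(ray @ edge) < 1e-9
            assert np.linalg.norm(ray) == pytest.approx(1.0)

    def test_collinear_scores_rejected(self):
        res = scores_result(G=[[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]],
                            E=[[1.0, 0.0], [0.5, 0.2]])
        with pytest.raises(DegenerateGeometryError):
            which_won_where(res)


class TestBootstrap:
    def test_identical_replicates_zero_width(self):
        c = random_config(g=4, e=4, r=3, K=1, lambdas=(5.0,), sigma_error=0.0, seed=2)
        ds = generate_met(c)
        cl = bootstrap_cl(ds, c.trait, B=100, seed=0)
        np.testing.assert_allclose(
            cl.genotype_upper.to_numpy(), cl.genotype_lower.to_numpy(), atol=1e-9
        )

    def test_deterministic_given_seed(self, replicate_dataset):
        trait = replicate_dataset.traits[0]
        a = bootstrap_cl(replicate_dataset, trait, B=120, seed=7)
        b = bootstrap_cl(replicate_dataset, trait, B=120, seed=7)
        pd.testing.assert_frame_equal(a.genotype_lower, b.genotype_lower)
        pd.testing.assert_frame_equal(a.environment_upper, b.environment_upper)

    def test_mean_level_data_rejected(self, lentil):
        with pytest.raises(ValueError, match="replicate"):
            bootstrap_cl(lentil, "Fe", B=100)

    def test_point_estimate_inside_limits(self, replicate_dataset):
        trait = replicate_dataset.traits[0]
        cl = bootstrap_cl(replicate_dataset, trait, B=200, seed=3)
        G = cl.point.genotype_scores2d
        inside = ((cl.genotype_lower <= G) & (G <= cl.genotype_upper)).to_numpy()
        assert inside.mean() > 0.9
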