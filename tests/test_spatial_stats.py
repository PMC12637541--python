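"""Neighborhood composition, co-existence, density, gradients, enrichment."""

import numpy as np
import pandas as pd
import pytest

from merfish3d import spatial_stats as ss


def cell_table(positions, types, **genes):
    positions = np.asarray(positions, dtype=float)
    table = pd.DataFrame(
        {
            "cell_id": np.arange(len(positions)),
            "x": positions[:, 0],
            "y": positions[:, 1],
            "z": positions[:, 2],
            "section": 0,
            "cell_type": types,
        }
    )
    for gene, counts in genes.items():
        table[gene] = counts
    return table


class TestComposition:
    def test_row_proportions_match_neighbor_counts(self):
        # one focal cell at origin; 3 A's and 1 B nearby, rest far away
        pos = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0, 0, 1], [50, 50, 50]]
        types = ["A", "A", "A", "A", "B", "B"]
        comp = ss.neighborhood_composition(cell_table(pos, types), "knn", 4)
        assert comp.iloc[0].tolist() == pytest.approx([0.75, 0.25])

    def test_single_type_map_gives_one_hot_rows(self):
        rng = np.random.default_rng(0)
        cells = cell_table(rng.uniform(0, 100, (30, 3)), ["A"] * 30)
        comp = ss.neighborhood_composition(cells, "knn", 5)
        assert np.allclose(comp["A"], 1.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        cells = cell_table(
            rng.uniform(0, 100, (200, 3)), rng.choice(["A", "B", "C"], 200)
        )
        for mode, param in [("knn", 10), ("radius", 40.0)]:
            comp = ss.neighborhood_composition(cells, mode, param)
            sums = comp.sum(axis=1).to_numpy()
            assert np.all((np.abs(sums - 1) < 1e-9) | (sums == 0))

    def test_shuffled_labels_approach_global_frequencies(self):
        rng = np.random.default_rng(2)
        n = 1200
        cells = cell_table(
            rng.uniform(0, 100, (n, 3)),
            rng.choice(["A", "B"], n, p=[0.7, 0.3]),
        )
        comp = ss.neighborhood_composition(cells, "knn", 200)
        assert comp["A"].mean() == pytest.approx(0.7, abs=0.03)

    def test_isolated_cells_flagged_in_radius_mode(self):
        pos = [[0, 0, 0], [1, 0, 0], [500, 500, 500]]
        with pytest.warns(UserWarning, match="no neighbors"):
            comp = ss.neighborhood_composition(cell_table(pos, ["A"] * 3), "radius", 5.0)
        assert comp.iloc[2].sum() == 0


class TestCoexistence:
    def _shell_map(self, seed=0):
        # types A and B interleaved in the same shells; C in a disjoint blob
        rng = np.random.default_rng(seed)
        pos, types = [], []
        for _ in range(150):
            center = rng.choice([0, 200])
            p = rng.normal(center, 10, 3)
            pos.append(p)
            types.append(rng.choice(["A", "B"]))
        for _ in range(150):
            pos.append(rng.normal(500, 10, 3))
            types.append("C")
        return cell_table(pos, types)

    def test_cooccurring_types_score_high_disjoint_negative(self):
        cells = self._shell_map()
        comp = ss.neighborhood_composition(cells, "knn", 30)
        scores = ss.coexistence_matrix(comp)
        assert scores.loc["A", "B"] > 0.5
        assert scores.loc["A", "C"] < 0.0

    def test_matrix_symmetric_unit_diagonal_bounded(self):
        cells = self._shell_map(seed=3)
        scores = ss.coexistence_matrix(ss.neighborhood_composition(cells, "knn", 20))
        arr = scores.to_numpy()
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.allclose(np.diag(arr), 1.0)
        finite = arr[np.isfinite(arr)]
        assert (finite >= -1 - 1e-9).all() and (finite <= 1 + 1e-9).all()

    def test_relabeling_cell_ids_leaves_scores_unchanged(self):
        cells = self._shell_map(seed=4)
        shuffled = cells.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = ss.coexistence_matrix(ss.neighborhood_composition(cells, "knn", 15))
        b = ss.coexistence_matrix(ss.neighborhood_composition(shuffled, "knn", 15))
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_graph_thresholding_and_dendrogram_blocks(self):
        labels = ["A", "B", "C", "D"]
        block = np.array(
            [
                [1.0, 0.8, 0.0, 0.01],
                [0.8, 1.0, 0.02, 0.0],
                [0.0, 0.02, 1.0, 0.9],
                [0.01, 0.0, 0.9, 1.0],
            ]
        )
        scores = pd.DataFrame(block, index=labels, columns=labels)
        g = ss.coexistence_graph(scores, min_score=0.07)
        assert set(map(frozenset, g.edges())) == {
            frozenset({"A", "B"}),
            frozenset({"C", "D"}),
        }
        link = ss.coexistence_dendrogram(scores)
        from scipy.cluster.hierarchy import fcluster

        groups = fcluster(link, t=2, criterion="maxclust")
        assert groups[0] == groups[1] and groups[2] == groups[3]
        assert groups[0] != groups[2]
        newick = ss.dendrogram_newick(link, labels)
        assert newick.endswith(";") and all(l in newick for l in labels)

    def test_all_low_scores_give_edgeless_graph(self):
        scores = pd.DataFrame(
            np.eye(3) * 0.95 + 0.05, index=list("ABC"), columns=list("ABC")
        )
        scores[:] = np.where(np.eye(3), 1.0, 0.05)
        g = ss.coexistence_graph(scores, min_score=0.07)
        assert g.number_of_edges() == 0


class TestDensity:
    def test_closed_form_at_known_distance(self):
        # k=30 neighbors exactly on a 10 um sphere -> 30 / ((4/3) pi 1000)
        k = 30
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(k, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pos = np.vstack([[0, 0, 0], dirs * 10.0, rng.uniform(50, 80, (5, 3))])
        cells = cell_table(pos, ["A"] * len(pos))
        dens = ss.knn_density(cells, k=k)
        expect = k / ((4 / 3) * np.pi * 10.0**3)
        assert dens.iloc[0] == pytest.approx(expect, rel=1e-9)

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(1)
        n, k = 200, 10
        pos = rng.uniform(0, 50, (n, 3))
        cells = cell_table(pos, ["A"] * n)
        dens = ss.knn_density(cells, k=k)
        d2 = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        for i in range(n):
            d = np.sort(d2[i])[k]  # k-th neighbor excluding self at index 0
            count = int((d2[i] <= d).sum()) - 1
            expect = count / ((4 / 3) * np.pi * d**3)
            assert dens.iloc[i] == pytest.approx(expect, rel=1e-9)

    def test_poisson_process_mean_density_near_intensity(self):
        rng = np.random.default_rng(2)
        lam = 10000 / 100.0**3
        pos = rng.uniform(0, 100, (10000, 3))
        cells = cell_table(pos, ["A"] * 10000)
        dens = ss.knn_density(cells, k=30)
        interior = (
            (pos > 20).all(axis=1) & (pos < 80).all(axis=1)
        )
        assert dens[interior].mean() == pytest.approx(lam, rel=0.10)

    def test_small_type_gets_missing_values(self):
        cells = cell_table(np.random.default_rng(0).uniform(0, 10, (5, 3)), ["A"] * 5)
        with pytest.warns(UserWarning, match="members"):
            dens = ss.knn_density(cells, k=30)
        assert dens.isna().all()


class TestPercentileFilter:
    def test_floor_rule_retention_arithmetic(self):
        rng = np.random.default_rng(3)
        cells = cell_table(rng.uniform(0, 200, (1000, 3)), ["A"] * 1000)
        out = ss.density_percentile_filter(cells, (0.10, 0.03, 0.005), k=10)
        assert len(out) == 869  # 1000 -> 900 -> 873 -> 869

    def test_zero_fractions_are_identity(self):
        rng = np.random.default_rng(4)
        cells = cell_table(rng.uniform(0, 50, (100, 3)), ["A"] * 100)
        out = ss.density_percentile_filter(cells, (0.0, 0.0, 0.0))
        assert out.equals(cells)

    def test_scattered_outliers_removed_blob_retained(self):
        rng = np.random.default_rng(5)
        blob = rng.normal(0, 10, (2000, 3))
        outliers = rng.uniform(200, 1500, (50, 3))
        cells = cell_table(np.vstack([blob, outliers]), ["A"] * 2050)
        out = ss.density_percentile_filter(cells, k=30)
        kept_ids = set(out["cell_id"])
        outlier_ids = set(range(2000, 2050))
        assert len(outlier_ids & kept_ids) <= 5  # >= 90% of outliers removed
        # the stated fractions remove ~13% of all cells, so once the 50
        # outliers are gone the remainder necessarily comes from the blob
        # boundary; the dense core must survive
        assert len(set(range(2000)) & kept_ids) >= 0.85 * 2000


class TestGradients:
    def test_monotone_gradient_has_near_perfect_correlation(self):
        x = np.linspace(0, 100, 60)
        pos = np.column_stack([x, np.zeros(60), np.zeros(60)])
        # deterministic monotone gradient, linear on the log1p scale
        cells = cell_table(pos, ["A"] * 60, NPPA=np.expm1(x / 20.0))
        out = ss.axis_gradient_correlation(cells, ["NPPA"], "x")
        assert out.loc[0, "correlation"] >= 0.99

    @pytest.mark.parametrize("slope,sign", [(3.0, 1), (-3.0, -1)])
    def test_planted_slope_sign_recovered(self, slope, sign):
        rng = np.random.default_rng(6)
        n = 500
        x = rng.uniform(0, 100, n)
        expr = np.clip(rng.poisson(np.clip(20 + slope * (x - 50) / 10, 0.1, None)), 0, None)
        cells = cell_table(
            np.column_stack([x, np.zeros(n), np.zeros(n)]), ["A"] * n, G=expr
        )
        out = ss.axis_gradient_correlation(cells, ["G"], "x")
        assert np.sign(out.loc[0, "correlation"]) == sign

    def test_shuffled_expression_has_no_gradient(self):
        rng = np.random.default_rng(7)
        n = 500
        x = rng.uniform(0, 100, n)
        cells = cell_table(
            np.column_stack([x, np.zeros(n), np.zeros(n)]),
            ["A"] * n,
            G=rng.poisson(10, n),
        )
        out = ss.axis_gradient_correlation(cells, ["G"], "x")
        assert abs(out.loc[0, "correlation"]) <= 0.1

    def test_constant_gene_gives_missing(self):
        cells = cell_table(
            np.column_stack([np.arange(20.0), np.zeros(20), np.zeros(20)]),
            ["A"] * 20,
            G=np.ones(20),
        )
        out = ss.axis_gradient_correlation(cells, ["G"], "x")
        assert np.isnan(out.loc[0, "correlation"])


class TestPathEnrichment:
    def test_uniform_mixture_enriches_nowhere(self):
        rng = np.random.default_rng(8)
        n = 4000
        pos = np.column_stack(
            [rng.uniform(0, 200, n), rng.uniform(-25, 25, n), rng.uniform(-25, 25, n)]
        )
        cells = cell_table(pos, rng.choice(["A", "B"], n))
        path = np.array([[0.0, 0.0, 0.0], [200.0, 0.0, 0.0]])
        out = ss.path_enrichment(cells, path, radius=25.0, n_bins=5)
        vals = out["enrichment"].dropna()
        assert np.allclose(vals, 1.0, atol=0.25)

    def test_distal_planting_detected(self):
        rng = np.random.default_rng(9)
        prox = np.column_stack(
            [rng.uniform(0, 100, 500), rng.normal(0, 10, 500), rng.normal(0, 10, 500)]
        )
        dist = np.column_stack(
            [rng.uniform(100, 200, 500), rng.normal(0, 10, 500), rng.normal(0, 10, 500)]
        )
        cells = cell_table(
            np.vstack([prox, dist]), ["A"] * 500 + ["B"] * 500
        )
        path = np.array([[0.0, 0.0, 0.0], [200.0, 0.0, 0.0]])
        out = ss.path_enrichment(cells, path, radius=30.0, n_bins=4)
        b = out[out["cell_type"] == "B"].set_index("position")["enrichment"]
        assert b.iloc[-1] > 1.0 > b.iloc[0]

    def test_zero_background_flagged_as_missing(self):
        pos = [[10.0, 0.0, 0.0], [20.0, 0.0, 0.0]]
        cells = cell_table(pos, ["A", "A"])
        bg = pd.Series({"A": 0.0})
        path = np.array([[0.0, 0.0, 0.0], [30.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="background"):
            out = ss.path_enrichment(cells, path, radius=10.0,
                                     background_freqs=bg, n_bins=2)
        assert out["enrichment"].isna().all()
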