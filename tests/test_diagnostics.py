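import itertools

import numpy as np
import pandas as pd
import pytest

from phytosdm import diagnostics, learners
from phytosdm.data_model import GridMap, SiteTable
from phytosdm.errors import ConfigurationError, DegeneracyError, GeometryError

from conftest import linear_sites, tiny_stack


def brute_force_morans_i(values, W):
    """Double-sum evaluation of I, independent of the package path."""
    values = np.asarray(values, float)
    n = len(values)
    z = values - values.mean()
    s0 = W.sum()
    num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / s0) * num / np.sum(z**2)


class TestKnnWeights:
    def test_tie_break_by_site_id(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        w = diagnostics.knn_weights(coords, k=1, site_ids=["a", "b", "c"])
        # middle site is equidistant to both; documented tie-break -> "a"
        assert w.neighbors[1].tolist() == [0]

    def test_k2_n3_everything_neighbors(self):
        coords = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        w = diagnostics.knn_weights(coords, k=2)
        for i in range(3):
            assert sorted(w.neighbors[i].tolist()) == sorted(set(range(3)) - {i})
            np.testing.assert_allclose(w.weights[i], 0.5)

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 100, size=(20, 2))
        k = 4
        w = diagnostics.knn_weights(coords, k=k)
        for i in range(20):
            dists = np.linalg.norm(coords - coords[i], axis=1)
            dists[i] = np.inf
            expected = np.argsort(dists, kind="stable")[:k]
            assert sorted(w.neighbors[i].tolist()) == sorted(expected.tolist())

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        w = diagnostics.knn_weights(rng.uniform(size=(15, 2)), k=5)
        dense = w.dense()
        np.testing.assert_allclose(dense.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diag(dense) == 0)

    def test_k_out_of_range(self):
        with pytest.raises(ConfigurationError):
            diagnostics.knn_weights(np.zeros((3, 2)), k=3)


class TestMoransI:
    def test_alternating_square_is_minus_one(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        w = diagnostics.knn_weights(coords, k=2)  # edge-adjacent neighbors
        values = np.array([1.0, -1.0, 1.0, -1.0])
        assert diagnostics.morans_i(values, w) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_values_degenerate(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        w = diagnostics.knn_weights(coords, k=1)
        with pytest.raises(DegeneracyError):
            diagnostics.morans_i(np.full(3, 5.0), w)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 10, size=(25, 2))
        values = rng.normal(size=25)
        w = diagnostics.knn_weights(coords, k=5)
        expected = brute_force_morans_i(values, w.dense())
        assert diagnostics.morans_i(values, w) == pytest.approx(expected, abs=1e-12)

    def test_permutation_null_mean(self):
        rng = np.random.default_rng(4)
        n = 20
        coords = rng.uniform(0, 10, size=(n, 2))
        w = diagnostics.knn_weights(coords, k=4)
        values = rng.normal(size=n)
        report = diagnostics.morans_mc(values, w, n_sim=4999, seed=1)
        # E[I] under the permutation null = -1/(n-1), within Monte-Carlo error
        assert report["sim_mean"] == pytest.approx(-1.0 / (n - 1), abs=0.02)


class TestMoransMC:
    def test_p_bounds(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 10, size=(15, 2))
        w = diagnostics.knn_weights(coords, k=3)
        report = diagnostics.morans_mc(rng.normal(size=15), w, n_sim=99, seed=2)
        assert 1.0 / 100 <= report["p"] <= 1.0

    def test_clustered_values_detected(self):
        xs, ys = np.meshgrid(np.arange(6), np.arange(5))
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        values = coords[:, 0].copy()  # value = x coordinate: strong clustering
        w = diagnostics.knn_weights(coords, k=5)
        report = diagnostics.morans_mc(values, w, n_sim=999, seed=3)
        assert report["p"] <= 0.01

    def test_invariant_to_adding_constant(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 10, size=(20, 2))
        values = rng.normal(size=20)
        w = diagnostics.knn_weights(coords, k=4)
        a = diagnostics.morans_mc(values, w, n_sim=199, seed=7)
        b = diagnostics.morans_mc(values + 42.0, w, n_sim=199, seed=7)
        assert a["p"] == b["p"]
        assert a["I_observed"] == pytest.approx(b["I_observed"], abs=1e-9)

    def test_determinism(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 10, size=(20, 2))
        values = rng.normal(size=20)
        w = diagnostics.knn_weights(coords, k=4)
        a = diagnostics.morans_mc(values, w, n_sim=199, seed=9)
        b = diagnostics.morans_mc(values, w, n_sim=199, seed=9)
        assert a == b


class TestResidualCorrelation:
    def test_identical_fits_correlate_perfectly(self, small_sites):
        fit = learners.fit_lasso(small_sites, seed=1)
        mat = diagnostics.residual_correlation({"a": fit, "b": fit}, small_sites)
        assert mat.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_residuals(self):
        # build two fixed predictors whose residuals are orthogonal vectors
        n = 8
        r1 = np.array([1.0, -1.0] * 4)
        r2 = np.array([1.0, 1.0, -1.0, -1.0] * 2)
        assert r1 @ r2 == 0
        log_y = np.linspace(-1, 1, n)
        frame = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(n)],
                "x": np.arange(n, dtype=float),
                "y": np.zeros(n),
                "v": np.zeros(n),
                "phytolith_pct": np.exp(log_y),
            }
        )
        sites = SiteTable(frame)

        class OffsetFit(learners.ModelFit):
            def __init__(self, offsets):
                super().__init__(kind="fixed", variables=["v"])
                self._offsets = offsets

            def predict_matrix(self, X):
                return log_y + self._offsets

        mat = diagnostics.residual_correlation(
            {"a": OffsetFit(r1), "b": OffsetFit(r2)}, sites
        )
        assert mat.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_unit_diagonal(self, small_sites):
        fits = {
            "lasso": learners.fit_lasso(small_sites, seed=1),
            "rf": learners.fit_random_forest(small_sites, seed=1, n_trees=50),
        }
        mat = diagnostics.residual_correlation(fits, small_sites)
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat.to_numpy()), 1.0, atol=1e-12)


def brute_force_novelty(cells, site_values, n_pc, k_near):
    """PCA by eigen-decomposition + explicit all-pairs distances."""
    mean, sd = cells.mean(axis=0), cells.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (cells - mean) / sd
    cov = np.cov(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigvec = eigvec[:, order[:n_pc]]
    cell_pc = Z @ eigvec
    site_pc = ((site_values - mean) / sd) @ eigvec
    out = []
    for c in cell_pc:
        d = np.sort(np.linalg.norm(site_pc - c, axis=1))
        out.append(d[:k_near].mean())
    return np.array(out)


class TestEnvPcDistance:
    def _toy(self):
        stack = tiny_stack(
            {"a": [[1.0, 2.0], [3.0, 4.0]], "b": [[0.5, 1.5], [-1.0, 2.0]]}
        )
        geom = stack.geometry
        xx, yy = geom.cell_centers()
        # three sites at three of the four cells
        idx = [(0, 0), (0, 1), (1, 1)]
        frame = pd.DataFrame(
            {
                "site_id": ["p", "q", "r"],
                "x": [xx[i] for i in idx],
                "y": [yy[i] for i in idx],
                "a": [stack["a"][i] for i in idx],
                "b": [stack["b"][i] for i in idx],
            }
        )
        return stack, SiteTable(frame)

    def test_site_cell_distance_zero(self):
        stack, sites = self._toy()
        nov = diagnostics.env_pc_distance(stack, sites, n_ref=10, n_pc=2, k_near=1)
        assert nov.grid.values[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert nov.grid.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_uniform_stack_distance_zero_everywhere(self):
        stack = tiny_stack({"a": np.full((3, 3), 2.0), "b": np.full((3, 3), -1.0)})
        geom = stack.geometry
        xx, yy = geom.cell_centers()
        frame = pd.DataFrame(
            {"site_id": ["s1"], "x": [xx[0, 0]], "y": [yy[0, 0]], "a": [2.0], "b": [-1.0]}
        )
        nov = diagnostics.env_pc_distance(stack, SiteTable(frame), n_ref=100, n_pc=2, k_near=1)
        np.testing.assert_allclose(nov.grid.values, 0.0, atol=1e-9)

    def test_matches_brute_force_oracle(self):
        stack, sites = self._toy()
        nov = diagnostics.env_pc_distance(stack, sites, n_ref=10, n_pc=2, k_near=2)
        cells = stack.table(["a", "b"]).to_numpy()
        expected = brute_force_novelty(cells, sites.covariate_matrix(["a", "b"]), 2, 2)
        np.testing.assert_allclose(nov.grid.values.ravel(), expected, atol=1e-9)

    def test_npc_exceeds_covariates(self):
        stack, sites = self._toy()
        with pytest.raises(ConfigurationError):
            diagnostics.env_pc_distance(stack, sites, n_ref=10, n_pc=3, k_near=1)

    def test_invariant_to_layer_and_site_order(self, small_stack, small_sites):
        a = diagnostics.env_pc_distance(small_stack, small_sites, n_ref=2000, seed=5)
        shuffled_layers = dict(reversed(list(small_stack.layers.items())))
        stack2 = type(small_stack)(shuffled_layers, small_stack.geometry, small_stack.mask)
        sites2 = small_sites.subset(np.arange(small_sites.n)[::-1])
        b = diagnostics.env_pc_distance(stack2, sites2, n_ref=2000, seed=5)
        np.testing.assert_allclose(a.grid.values, b.grid.values, atol=1e-9)

    def test_variance_fractions_valid(self, small_stack, small_sites):
        nov = diagnostics.env_pc_distance(small_stack, small_sites, n_ref=500, seed=1)
        f = nov.variance_fraction
        assert np.all(f >= 0) and np.all(f <= 1)
        assert np.all(np.diff(f) <= 1e-12)  # non-increasing
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        assert nov.retained_variance == pytest.approx(f[:3].sum())


class TestNoveltyMask:
    def _pred_and_novelty(self, distances):
        values = np.asarray(distances, dtype=float)
        geom_stack = tiny_stack({"d": values})
        grid = GridMap(values, np.ones_like(values, dtype=bool), geom_stack.geometry,
                       name="novelty", units="PC units")
        nov = diagnostics.NoveltyMap(
            grid=grid, n_ref=1, n_pc=1, k_near=1, seed=0,
            variance_fraction=np.array([1.0]), retained_variance=1.0,
        )
        pred = GridMap(np.arange(values.size, dtype=float).reshape(values.shape),
                       np.ones_like(values, dtype=bool), grid.geometry, name="pred")
        return pred, nov

    def test_infinite_threshold_is_identity(self):
        pred, nov = self._pred_and_novelty([[1.0, 2.0], [4.0, 5.0]])
        out = diagnostics.apply_novelty_mask(pred, nov, threshold=np.inf)
        np.testing.assert_array_equal(out.values, pred.values)
        np.testing.assert_array_equal(out.mask, pred.mask)

    def test_zero_threshold_masks_everything_positive(self):
        pred, nov = self._pred_and_novelty([[1.0, 2.0], [4.0, 5.0]])
        out = diagnostics.apply_novelty_mask(pred, nov, threshold=0.0)
        assert not out.mask.any()

    def test_counting_oracle(self):
        pred, nov = self._pred_and_novelty([[1.0, 2.0], [4.0, 5.0]])
        out = diagnostics.apply_novelty_mask(pred, nov, threshold=3.0)
        assert out.mask.sum() == 2
        np.testing.assert_array_equal(out.mask, [[True, True], [False, False]])

    def test_unmasked_cells_unchanged_bit_for_bit(self):
        pred, nov = self._pred_and_novelty([[1.0, 2.0], [4.0, 5.0]])
        out = diagnostics.apply_novelty_mask(pred, nov, threshold=3.0)
        np.testing.assert_array_equal(out.values[out.mask], pred.values[out.mask])

    def test_idempotent(self):
        pred, nov = self._pred_and_novelty([[1.0, 2.0], [4.0, 5.0]])
        once = diagnostics.apply_novelty_mask(pred, nov, threshold=3.0)
        twice = diagnostics.apply_novelty_mask(once, nov, threshold=3.0)
        np.testing.assert_array_equal(once.values, twice.values)
        np.testing.assert_array_equal(once.mask, twice.mask)

    def test_geometry_mismatch(self):
        pred, nov = self._pred_and_novelty([[1.0, 2.0], [4.0, 5.0]])
        other = tiny_stack({"d": np.zeros((3, 3))})
        bad = GridMap(np.zeros((3, 3)), np.ones((3, 3), bool), other.geometry)
        with pytest.raises(GeometryError):
            diagnostics.apply_novelty_mask(bad, nov, threshold=3.0)


class TestNppDetrend:
    def test_linear_relation_gives_zero_residuals(self):
        npp_vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        stack = tiny_stack({"npp": npp_vals})
        npp = stack.as_map("npp")
        pred = GridMap(2.0 * npp_vals - 1.0, npp.mask, npp.geometry)
        out = diagnostics.npp_detrend(pred, npp)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_constant_npp_degenerate(self):
        stack = tiny_stack({"npp": np.full((2, 2), 3.0)})
        npp = stack.as_map("npp")
        pred = GridMap(np.arange(4, dtype=float).reshape(2, 2), npp.mask, npp.geometry)
        with pytest.raises(DegeneracyError):
            diagnostics.npp_detrend(pred, npp)

    def test_hand_ols_oracle(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        y = np.array([[2.0, 2.5, 4.0, 4.5, 7.0]])
        stack = tiny_stack({"npp": x})
        npp = stack.as_map("npp")
        pred = GridMap(y, npp.mask, npp.geometry)
        out = diagnostics.npp_detrend(pred, npp)
        design = np.column_stack([np.ones(5), x.ravel()])
        beta = np.linalg.solve(design.T @ design, design.T @ y.ravel())
        expected = y.ravel() - design @ beta
        np.testing.assert_allclose(out.values.ravel(), expected, atol=1e-9)


class TestVariableCluster:
    def test_negated_variable_merges_first(self):
        sites = linear_sites(40, 3, [0.5, 0.0, 0.0], noise_sd=0.1, seed=12)
        frame = sites.frame.copy()
        frame["neg_v00"] = -frame["v00"]
        clustering = diagnostics.variable_cluster(SiteTable(frame))
        assert clustering.distance.loc["v00", "neg_v00"] == pytest.approx(0.0, abs=1e-12)
        # first merge in the linkage joins the |r| = 1 pair at height ~0
        first = clustering.linkage_matrix[0]
        merged = {clustering.variables[int(first[0])], clustering.variables[int(first[1])]}
        assert merged == {"v00", "neg_v00"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_independent_variables_distance_near_one(self):
        sites = linear_sites(4000, 2, [0.0, 0.0], noise_sd=0.1, seed=13)
        clustering = diagnostics.variable_cluster(sites)
        assert clustering.distance.loc["v00", "v01"] == pytest.approx(1.0, abs=0.1)

    def test_three_variable_average_linkage_oracle(self):
        # construct v2 correlated with v0, v1 roughly independent
        rng = np.random.default_rng(14)
        n = 200
        v0 = rng.normal(size=n)
        v1 = rng.normal(size=n)
        v2 = 0.9 * v0 + 0.45 * rng.normal(size=n)
        frame = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(n)],
                "x": np.arange(n, dtype=float),
                "y": np.zeros(n),
                "v0": v0,
                "v1": v1,
                "v2": v2,
            }
        )
        clustering = diagnostics.variable_cluster(SiteTable(frame))
        D = clustering.distance
        # hand average-linkage: first merge = closest pair; second joins the
        # remaining variable at the mean of its two distances
        pairs = list(itertools.combinations(clustering.variables, 2))
        first_pair = min(pairs, key=lambda p: D.loc[p[0], p[1]])
        assert set(first_pair) == {"v0", "v2"}
        third = ({"v0", "v1", "v2"} - set(first_pair)).pop()
        expected_height = np.mean([D.loc[third, a] for a in first_pair])
        assert clustering.linkage_matrix[1][2] == pytest.approx(expected_height, abs=1e-12)

    def test_constant_covariate_excluded(self):
        sites = linear_sites(30, 2, [0.5, 0.0], noise_sd=0.1, seed=15)
        frame = sites.frame.copy()
        frame["const"] = 1.0
        clustering = diagnostics.variable_cluster(SiteTable(frame))
        assert clustering.excluded == ["const"]
        assert "const" not in clustering.variables
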