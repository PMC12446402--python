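"""Spatial weights and Moran statistics against brute-force double-sum oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import occindex as oc


def dense_w(w):
    M = np.zeros((w.n, w.n))
    for i, (nb, wt) in enumerate(zip(w.neighbors, w.weights)):
        for j, v in zip(nb, wt):
            M[i, j] = v
    return M


def brute_global(x, w):
    z = np.asarray(x, float) - np.mean(x)
    W = dense_w(w)
    s0 = W.sum()
    num = sum(W[i, j] * z[i] * z[j] for i in range(w.n) for j in range(w.n))
    return (w.n / s0) * num / (z @ z)


def brute_bivariate(x, y, w):
    zx = (np.asarray(x, float) - np.mean(x)) / np.std(x)
    zy = (np.asarray(y, float) - np.mean(y)) / np.std(y)
    W = dense_w(w)
    return sum(W[i, j] * zx[i] * zy[j] for i in range(w.n) for j in range(w.n)) / W.sum()


def brute_local(x, w):
    z = np.asarray(x, float) - np.mean(x)
    m2 = (z @ z) / w.n
    W = dense_w(w)
    return np.array([z[i] * sum(W[i, j] * z[j] for j in range(w.n)) / m2
                     for i in range(w.n)])


class TestWeights:
    def test_2x2_queen_everyone_has_three_neighbors(self):
        w = oc.SpatialWeights.from_grid(2, 2, "queen")
        assert all(len(nb) == 3 for nb in w.neighbors)

    def test_3x3_rook_degrees(self):
        w = oc.SpatialWeights.from_grid(3, 3, "rook")
        degs = sorted(len(nb) for nb in w.neighbors)
        assert degs == [2, 2, 2, 2, 3, 3, 3, 3, 4]

    def test_supplied_edge_list_round_trips(self):
        edges = [("a", "b"), ("b", "c")]
        w = oc.SpatialWeights.from_adjacency(edges)
        assert sorted(w.edge_list()) == sorted(edges)

    def test_geojson_matches_grid_contiguity(self, fixture_bundle):
        wg = oc.SpatialWeights.from_geojson(fixture_bundle.geometry, scheme="queen")
        assert all(len(nb) == 3 for nb in wg.neighbors)
        wr = oc.SpatialWeights.from_geojson(fixture_bundle.geometry, scheme="rook")
        assert all(len(nb) == 2 for nb in wr.neighbors)

    def test_self_neighbor_rejected(self):
        with pytest.raises(ValueError, match="self-neighbor"):
            oc.SpatialWeights.from_adjacency([("a", "a")])

    def test_asymmetric_adjacency_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            oc.SpatialWeights(["a", "b"], {0: [1], 1: []})

    def test_isolates_recorded(self):
        w = oc.SpatialWeights.from_adjacency([("a", "b")], ids=["a", "b", "c"])
        assert w.isolates == ["c"]


class TestGlobalMoran:
    def test_checkerboard_rook_is_exactly_minus_one(self):
        w = oc.SpatialWeights.from_grid(4, 4, "rook")
        x = pd.Series([1.0 if (i // 4 + i % 4) % 2 else -1.0 for i in range(16)],
                      index=w.ids)
        res = oc.global_moran(x, w, n_perm=99, seed=0)
        assert res.I == pytest.approx(-1.0, abs=1e-14)
        assert res.p_perm <= 0.05

    @pytest.mark.parametrize("dims,scheme", [((5, 5), "queen"), ((4, 6), "rook"),
                                             ((10, 10), "queen")])
    def test_matches_brute_force(self, dims, scheme):
        rng = np.random.default_rng(dims[0] * 7 + dims[1])
        w = oc.SpatialWeights.from_grid(*dims, scheme)
        x = pd.Series(rng.normal(size=w.n), index=w.ids)
        res = oc.global_moran(x, w, n_perm=9, seed=0)
        assert res.I == pytest.approx(brute_global(x, w), abs=1e-12)
        assert res.expected_I == pytest.approx(-1 / (w.n - 1))

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        w = oc.SpatialWeights.from_grid(5, 5)
        x = pd.Series(rng.normal(size=25), index=w.ids)
        a = oc.global_moran(x, w, n_perm=9, seed=0).I
        b = oc.global_moran(3.5 * x + 11.0, w, n_perm=9, seed=0).I
        assert a == pytest.approx(b, abs=1e-12)

    def test_constant_surface_rejected(self):
        w = oc.SpatialWeights.from_grid(3, 3)
        with pytest.raises(ValueError, match="constant surface"):
            oc.global_moran(pd.Series(1.0, index=w.ids), w, n_perm=9, seed=0)

    def test_missing_values_dropped_with_edges(self):
        rng = np.random.default_rng(5)
        w = oc.SpatialWeights.from_grid(5, 5)
        x = pd.Series(rng.normal(size=25), index=w.ids)
        x.iloc[[0, 13]] = np.nan
        res = oc.global_moran(x, w, n_perm=9, seed=0)
        sub = w.subset([t for t in w.ids if not np.isnan(x[t])])
        assert res.I == pytest.approx(brute_global(x.dropna(), sub), abs=1e-12)
        assert res.n == 23

    def test_permutation_p_uniform_under_null(self):
        """Two-sided pseudo p-values over 200 simulated nulls look uniform."""
        w = oc.SpatialWeights.from_grid(6, 6)
        rng = np.random.default_rng(42)
        ps = [oc.global_moran(pd.Series(rng.normal(size=36), index=w.ids),
                              w, n_perm=99, seed=k).p_perm for k in range(200)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBivariateMoran:
    def test_self_case_reduces_to_univariate(self):
        rng = np.random.default_rng(2)
        w = oc.SpatialWeights.from_grid(5, 5)
        x = pd.Series(rng.normal(size=25), index=w.ids)
        uni = oc.global_moran(x, w, n_perm=9, seed=0).I
        bv = oc.bivariate_moran(x, x, w, n_perm=9, seed=0).I
        assert bv == pytest.approx(uni, abs=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        w = oc.SpatialWeights.from_grid(6, 6, "rook")
        x = pd.Series(rng.normal(size=36), index=w.ids)
        y = pd.Series(rng.normal(size=36), index=w.ids)
        res = oc.bivariate_moran(x, y, w, n_perm=9, seed=0)
        assert res.I == pytest.approx(brute_bivariate(x, y, w), abs=1e-12)

    def test_independent_variable_in_null_band(self):
        rng = np.random.default_rng(21)
        w = oc.SpatialWeights.from_grid(7, 7)
        x = pd.Series(rng.normal(size=49), index=w.ids)
        y = pd.Series(rng.normal(size=49), index=w.ids)
        res = oc.bivariate_moran(x, y, w, n_perm=199, seed=0)
        assert res.p_perm > 0.05

    def test_affine_invariance_both_variables(self):
        rng = np.random.default_rng(4)
        w = oc.SpatialWeights.from_grid(5, 5)
        x = pd.Series(rng.normal(size=25), index=w.ids)
        y = pd.Series(rng.normal(size=25), index=w.ids)
        a = oc.bivariate_moran(x, y, w, n_perm=9, seed=0).I
        b = oc.bivariate_moran(2 * x - 1, 0.1 * y + 7, w, n_perm=9, seed=0).I
        assert a == pytest.approx(b, abs=1e-12)


class TestLocalMoran:
    def test_matches_brute_force_and_sums_to_global(self):
        rng = np.random.default_rng(6)
        w = oc.SpatialWeights.from_grid(6, 6)
        x = pd.Series(rng.normal(size=36), index=w.ids)
        lisa = oc.local_moran(x, w, n_perm=99, seed=0)
        assert np.allclose(lisa.table["local_I"], brute_local(x, w), atol=1e-12)
        gI = oc.global_moran(x, w, n_perm=9, seed=0).I
        assert lisa.table["local_I"].sum() == pytest.approx(w.n * gI, abs=1e-10)

    def test_checkerboard_significant_tracts_are_negative_quadrants(self):
        w = oc.SpatialWeights.from_grid(4, 4, "rook")
        x = pd.Series([1.0 if (i // 4 + i % 4) % 2 else -1.0 for i in range(16)],
                      index=w.ids)
        lisa = oc.local_moran(x, w, n_perm=999, alpha=1.0, seed=0)
        assert set(lisa.table["quadrant"]) <= {"HL", "LH"}

    def test_plateau_field_clusters_hh_and_ll(self):
        """Smooth two-plateau field: HH at the high plateau, LL at the low."""
        w = oc.SpatialWeights.from_grid(8, 8)
        vals = np.array([[5.0 if c < 3 else (0.0 if c > 4 else 2.5)
                          for c in range(8)] for r in range(8)]).ravel()
        rng = np.random.default_rng(0)
        x = pd.Series(vals + 0.01 * rng.normal(size=64), index=w.ids)
        lisa = oc.local_moran(x, w, n_perm=999, alpha=0.05, seed=0)
        q = lisa.table["quadrant"]
        high_core = [w.ids[r * 8 + c] for r in range(2, 6) for c in range(0, 2)]
        low_core = [w.ids[r * 8 + c] for r in range(2, 6) for c in range(6, 8)]
        assert (q.loc[high_core] == "HH").mean() > 0.5
        assert (q.loc[low_core] == "LL").mean() > 0.5
        assert not ((q.loc[high_core] == "LL") | (q.loc[low_core] == "HH")).any()

    def test_isolate_gets_missing_local_value(self):
        w = oc.SpatialWeights.from_adjacency([("a", "b"), ("b", "c")],
                                             ids=["a", "b", "c", "d"])
        x = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        lisa = oc.local_moran(x, w, n_perm=99, seed=0)
        assert np.isnan(lisa.table.loc["d", "local_I"])


class TestBivariateLisa:
    def test_anticorrelated_y_marks_high_x_as_hl(self):
        """y = -x with spatial clustering in x: high-x cores sit in low-y lags."""
        w = oc.SpatialWeights.from_grid(8, 8)
        vals = np.array([[float(c) for c in range(8)] for r in range(8)]).ravel()
        rng = np.random.default_rng(3)
        x = pd.Series(vals + 0.05 * rng.normal(size=64), index=w.ids)
        y = -x
        lisa = oc.local_moran_bv(x, y, w, n_perm=999, alpha=1.0, seed=0)
        zx = (x - x.mean()) / x.std()
        high = zx.index[zx > 0.5]
        assert (lisa.table.loc[high, "quadrant"] == "HL").all()

    def test_alpha_one_classifies_every_connected_tract(self):
        rng = np.random.default_rng(9)
        w = oc.SpatialWeights.from_grid(5, 5)
        x = pd.Series(rng.normal(size=25), index=w.ids)
        y = pd.Series(rng.normal(size=25), index=w.ids)
        lisa = oc.local_moran_bv(x, y, w, n_perm=99, alpha=1.0, seed=0)
        assert (lisa.table["quadrant"] != "not_significant").all()


class TestPerGroupMoran:
    def test_single_group_equals_global(self):
        rng = np.random.default_rng(10)
        w = oc.SpatialWeights.from_grid(5, 5)
        x = pd.Series(rng.normal(size=25), index=w.ids)
        groups = pd.Series("only", index=w.ids)
        results, skipped = oc.per_group_moran(x, w, groups, n_perm=9, seed=0)
        assert not skipped
        assert results["only"].I == pytest.approx(
            oc.global_moran(x, w, n_perm=9, seed=0).I, abs=1e-12)

    def test_disconnected_groups_match_subgrids(self):
        rng = np.random.default_rng(12)
        w = oc.SpatialWeights.from_grid(4, 8, "rook")
        x = pd.Series(rng.normal(size=32), index=w.ids)
        groups = pd.Series(["L" if int(t[1:]) % 8 < 4 else "R" for t in w.ids],
                           index=w.ids)
        results, skipped = oc.per_group_moran(x, w, groups, n_perm=9, seed=0)
        for g in ("L", "R"):
            ids = groups.index[groups == g]
            sub = w.subset(ids)
            expected = oc.global_moran(x.loc[ids], sub, n_perm=9, seed=0).I
            assert results[g].I == pytest.approx(expected, abs=1e-12)

    def test_tiny_group_skipped_with_reason(self):
        rng = np.random.default_rng(13)
        w = oc.SpatialWeights.from_grid(3, 3, "rook")
        x = pd.Series(rng.normal(size=9), index=w.ids)
        groups = pd.Series(["A"] * 7 + ["B"] * 2, index=w.ids)
        results, skipped = oc.per_group_moran(x, w, groups, n_perm=9, seed=0)
        assert "B" in skipped and "A" in results
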