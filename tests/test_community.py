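import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from intertidal import community


def _dm(X, ids=None):
    ids = ids or [f"s{i}" for i in range(len(X))]
    return DistanceMatrix(squareform(pdist(np.asarray(X))), ids=ids)


class TestTransforms:
    def test_log1p(self, toy_table):
        out = community.transform_community(toy_table)
        assert out.loc["s1", "B"] == 0.0
        assert out.loc["s2", "A"] == pytest.approx(np.log(3))
        assert (np.diff(np.log1p(np.arange(10))) > 0).all()

    def test_env_sqrt_except_ph(self, toy_metadata):
        out = community.transform_env(toy_metadata)
        assert out.loc["s1", "salinity"] == pytest.approx(5.0)
        assert out.loc["s1", "pH"] == pytest.approx(8.1)

    def test_env_negative_rejected_by_name(self, toy_metadata):
        meta = toy_metadata.copy()
        meta["Cd"] = [-0.2, 0.1, 0.1]
        with pytest.raises(ValueError, match="Cd"):
            community.transform_env(meta)


class TestBrayCurtis:
    def test_identity_disjoint_and_formula(self):
        df = pd.DataFrame([[1, 2, 0], [1, 2, 0], [0, 0, 5]],
                          index=["a", "b", "c"], columns=list("xyz"))
        bc = community.bray_curtis(df)
        assert bc["a", "b"] == 0.0
        assert bc["a", "c"] == 1.0
        df2 = pd.DataFrame([[1, 2], [2, 1]], index=["a", "b"])
        assert community.bray_curtis(df2)["a", "b"] == pytest.approx(1 / 3)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame([[1, 1], [0, 0]], index=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            community.bray_curtis(df)


class TestNmds:
    def test_euclidean_configuration_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.random((12, 2))
        res = community.nmds(_dm(X), k=2, n_restarts=8, seed=1)
        assert res.stress < 0.01

    def test_duplicate_samples_coincide(self):
        X = np.array([[0, 0], [0, 0], [1, 0], [0, 1], [1, 1], [2, 1]])
        res = community.nmds(_dm(X.astype(float)), k=2, n_restarts=8, seed=0)
        c = res.coordinates
        assert np.linalg.norm(c.iloc[0] - c.iloc[1]) < 0.05

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        dm = _dm(rng.random((8, 3)))
        a = community.nmds(dm, seed=9, n_restarts=4)
        b = community.nmds(dm, seed=9, n_restarts=4)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        X = np.vstack([np.zeros((3, 2)), np.ones((3, 2)) * 10
                       + np.arange(6).reshape(3, 2) * 0.01])
        groups = pd.Series(["a"] * 3 + ["b"] * 3,
                           index=[f"s{i}" for i in range(6)])
        res = community.anosim(_dm(X), groups, n_perm=199, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_hand_ranked_two_plus_two(self):
        """Within distances {1,1}, between {5,5,5,5}: R = 1 by hand ranking."""
        D = np.array([[0, 1, 5, 5],
                      [1, 0, 5, 5],
                      [5, 5, 0, 1],
                      [5, 5, 1, 0]], dtype=float)
        dm = DistanceMatrix(D, ids=list("abcd"))
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        res = community.anosim(dm, groups, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_rank_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        X = rng.random((10, 3))
        D = squareform(pdist(X))
        groups = pd.Series(["a"] * 5 + ["b"] * 5,
                           index=[f"s{i}" for i in range(10)])
        r1 = community.anosim(DistanceMatrix(D, groups.index), groups,
                              n_perm=99, seed=3).statistic
        r2 = community.anosim(DistanceMatrix(D**2, groups.index), groups,
                              n_perm=99, seed=3).statistic
        assert r1 == pytest.approx(r2)

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(1)
        dm = _dm(rng.random((4, 2)))
        groups = pd.Series(["a", "a", "a", "b"],
                           index=[f"s{i}" for i in range(4)])
        with pytest.raises(ValueError):
            community.anosim(dm, groups, n_perm=99)


class TestMantel:
    def test_identity_and_antiidentity(self):
        rng = np.random.default_rng(0)
        d1 = _dm(rng.random((8, 3)))
        res = community.mantel(d1, d1, n_perm=199, seed=1)
        assert res.statistic == pytest.approx(1.0)
        # rank-reversed distances: max+min-d has inverted ranks
        vals = d1.data
        rev = vals.max() + vals.min() - vals
        np.fill_diagonal(rev, 0)
        d2 = DistanceMatrix(rev, ids=list(d1.ids))
        res = community.mantel(d1, d2, n_perm=199, method="spearman", seed=1)
        assert res.statistic == pytest.approx(-1.0)

    def test_constant_matrix_rejected(self):
        ones = np.ones((5, 5)) - np.eye(5)
        dm = DistanceMatrix(ones, ids=list("abcde"))
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="constant"):
            community.mantel(dm, _dm(rng.random((5, 2))), n_perm=99)

    def test_p_value_never_zero(self):
        rng = np.random.default_rng(0)
        d1 = _dm(rng.random((8, 3)))
        res = community.mantel(d1, d1, n_perm=99, seed=0)
        assert res.p_value >= 1 / 100


class TestPartialMantel:
    def _three(self, seed, n=14):
        rng = np.random.default_rng(seed)
        return [_dm(rng.random((n, 3))) for _ in range(3)]

    def test_uncorrelated_control_preserves_r(self):
        d1, d2, d3 = self._three(0)
        shared = np.random.default_rng(1).random((14, 3))
        d1 = _dm(shared + 0.05 * np.random.default_rng(2).random((14, 3)))
        d2 = _dm(shared + 0.05 * np.random.default_rng(3).random((14, 3)))
        simple = community.mantel(d1, d2, n_perm=99, seed=0).statistic
        partial = community.partial_mantel(d1, d2, d3, n_perm=99, seed=0)
        assert partial.statistic == pytest.approx(simple, abs=0.15)

    def test_matches_first_order_formula(self):
        d1, d2, d3 = self._three(4)
        r12 = community.mantel(d1, d2, n_perm=99, seed=0).statistic
        r13 = community.mantel(d1, d3, n_perm=99, seed=0).statistic
        r23 = community.mantel(d2, d3, n_perm=99, seed=0).statistic
        expected = (r12 - r13 * r23) / np.sqrt((1 - r13**2) * (1 - r23**2))
        got = community.partial_mantel(d1, d2, d3, n_perm=99, seed=0).statistic
        assert got == pytest.approx(expected, abs=1e-10)

    def test_degenerate_control_rejected(self):
        d1, d2, _ = self._three(5)
        with pytest.raises(ValueError, match="degenerate"):
            community.partial_mantel(d1, d2, d1, n_perm=99, seed=0)

    def test_d2_driven_by_d3_partials_to_zero(self):
        rng = np.random.default_rng(6)
        X = rng.random((14, 3))
        d3 = _dm(X)
        d2 = _dm(X + 0.02 * rng.random((14, 3)))  # d2 almost purely d3
        d1 = _dm(rng.random((14, 3)))
        res = community.partial_mantel(d1, d2, d3, n_perm=99, seed=0)
        assert abs(res.statistic) < 0.25

    def test_exact_duplicate_control_rejected(self):
        d1, d2, _ = self._three(7)
        with pytest.raises(ValueError, match="degenerate"):
            community.partial_mantel(d1, d2,
                                     DistanceMatrix(d2.data, ids=list(d2.ids)),
                                     n_perm=99, seed=0)


class TestGeoDistance:
    def _meta(self, coords):
        return pd.DataFrame(coords, columns=["latitude", "longitude"],
                            index=[f"s{i}" for i in range(len(coords))])

    def test_same_point_zero(self):
        geo = community.geo_distance_matrix(
            self._meta([[24.5, 118.1], [24.5, 118.1]]), mode="haversine")
        assert geo.data[0, 1] == 0.0

    def test_one_degree_longitude_at_equator(self):
        geo = community.geo_distance_matrix(
            self._meta([[0.0, 0.0], [0.0, 1.0]]), mode="haversine")
        assert geo.data[0, 1] == pytest.approx(111.195, rel=1e-3)

    def test_modes_agree_locally(self):
        rng = np.random.default_rng(0)
        lat = 24.4 + rng.random(8) * 0.2
        lon = 118.0 + rng.random(8) * 0.8
        meta = self._meta(np.column_stack([lat, lon]))
        hav = community.geo_distance_matrix(meta, mode="haversine").data
        cart = community.geo_distance_matrix(meta, mode="cartesian").data
        iu = np.triu_indices(8, 1)
        assert np.allclose(hav[iu], cart[iu], rtol=0.01)

    def test_missing_coordinates_rejected(self):
        meta = self._meta([[24.5, 118.1], [np.nan, 118.2]])
        with pytest.raises(ValueError):
            community.geo_distance_matrix(meta)


class TestDistanceDecay:
    def test_monotone_decay_gives_minus_one(self):
        # communities on a line: dissimilarity strictly increases with distance
        x = np.arange(6, dtype=float)
        comm = DistanceMatrix(np.abs(x[:, None] - x[None, :]) / 10,
                              ids=[f"s{i}" for i in range(6)])
        geo = DistanceMatrix(np.abs(x[:, None] - x[None, :]) * 3,
                             ids=[f"s{i}" for i in range(6)])
        res = community.distance_decay(comm, geo, n_perm=199, seed=0)
        assert res.statistic == pytest.approx(-1.0)


class TestPcaEnv:
    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        env = pd.DataFrame(rng.random((10, 4)),
                           index=[f"s{i}" for i in range(10)])
        res = community.pca_env(env)
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_rank_one_data(self):
        base = np.arange(8, dtype=float)
        env = pd.DataFrame({"a": base, "b": 2 * base + 1},
                           index=[f"s{i}" for i in range(8)])
        res = community.pca_env(env)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        env = pd.DataFrame(rng.random((12, 3)),
                           index=[f"s{i}" for i in range(12)])
        L = community.pca_env(env).loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_too_few_rows_rejected(self):
        env = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            community.pca_env(env)


class TestEnvGroupTest:
    def _env(self, values):
        return pd.DataFrame({"v": values},
                            index=[f"s{i}" for i in range(len(values))])

    def test_identical_groups(self):
        env = self._env([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=env.index)
        res = community.env_group_test(env, groups)
        assert res.loc["v", "t"] == pytest.approx(0.0)
        assert res.loc["v", "p"] == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 8)
        b = rng.normal(5, 1, 8)
        env = self._env(np.concatenate([a, b]))
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=env.index)
        assert community.env_group_test(env, groups).loc["v", "p"] < 0.001

    def test_small_group_gives_na(self):
        env = self._env([1.0, np.nan, np.nan, 2.0, 3.0, 4.0])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=env.index)
        res = community.env_group_test(env, groups)
        assert np.isnan(res.loc["v", "t"])

    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        groups = pd.Series(["a"] * 8 + ["b"] * 8,
                           index=[f"s{i}" for i in range(16)])
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            env = self._env(rng.normal(size=16))
            rejections += community.env_group_test(env, groups).loc["v", "p"] < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08
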