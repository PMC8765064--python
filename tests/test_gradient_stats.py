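"""Correlation, Mantel, BIOENV, Mann-Whitney, and Z-score engines."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from cryograd import (
    bioenv_search,
    correlation,
    mann_whitney_u,
    mantel_test,
    zscore_table,
)

from conftest import make_meta


def exact_mwu_two_sided(x, y):
    """Enumeration oracle: two-sided exact Mann-Whitney p (no ties)."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)
    ranks = rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), n):
        r = ranks[list(idx)]
        us.append(r.sum() - n * (n + 1) / 2)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(1.0, p)


class TestCorrelation:
    def test_monotone_spearman_is_one(self):
        assert correlation([1, 2, 3], [2, 4, 6], "spearman") == pytest.approx(1.0)

    def test_exact_negative_linear_pearson(self):
        assert correlation([1, 2, 3], [6, 4, 2], "pearson") == pytest.approx(-1.0)

    def test_spearman_hand_formula(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 2
        assert correlation([1, 2, 3, 4], [1, 3, 2, 4],
                           "spearman") == pytest.approx(0.8)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlation([1, 1, 1], [1, 2, 3])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_spearman_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        base = correlation(x, y, "spearman")
        assert correlation(np.exp(x), y, "spearman") == pytest.approx(base)
        assert correlation(x, y**3, "spearman") == pytest.approx(base)


class TestMantel:
    def make_dm(self, values, ids):
        return DistanceMatrix(values, ids=ids)

    def test_self_and_scale_give_r_one(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((8, 3))
        d = squareform(pdist(pts))
        ids = [f"S{i}" for i in range(8)]
        d1 = self.make_dm(d, ids)
        assert mantel_test(d1, d1, 99, seed=0).r == pytest.approx(1.0)
        assert mantel_test(d1, self.make_dm(2 * d, ids), 99,
                           seed=0).r == pytest.approx(1.0)

    def test_p_bounded_by_permutation_count(self):
        rng = np.random.default_rng(2)
        ids = [f"S{i}" for i in range(10)]
        d1 = self.make_dm(squareform(pdist(rng.standard_normal((10, 2)))), ids)
        d2 = self.make_dm(squareform(pdist(rng.standard_normal((10, 2)))), ids)
        res = mantel_test(d1, d2, n_perm=999, seed=3)
        assert res.p >= 1 / 1000
        assert res.p <= 1.0

    def test_r_invariant_to_affine_transform(self):
        rng = np.random.default_rng(3)
        ids = [f"S{i}" for i in range(9)]
        d = squareform(pdist(rng.standard_normal((9, 2))))
        d1 = self.make_dm(d, ids)
        d2 = self.make_dm(squareform(pdist(rng.standard_normal((9, 2)))), ids)
        base = mantel_test(d1, d2, 99, seed=0)
        scaled = mantel_test(d1, self.make_dm(0.5 * d2.data, ids), 99, seed=0)
        assert scaled.r == pytest.approx(base.r)
        assert scaled.p == base.p

    def test_agrees_with_skbio_r(self):
        rng = np.random.default_rng(4)
        ids = [f"S{i}" for i in range(12)]
        d1 = self.make_dm(squareform(pdist(rng.standard_normal((12, 2)))), ids)
        d2 = self.make_dm(squareform(pdist(rng.standard_normal((12, 2)))), ids)
        ours = mantel_test(d1, d2, 999, seed=0)
        theirs_r, _, _ = skbio_mantel(d1, d2, method="pearson",
                                      permutations=0)
        assert ours.r == pytest.approx(float(theirs_r))

    def test_mismatched_ids_error(self):
        d1 = self.make_dm(np.array([[0, 1.0], [1.0, 0]]), ["A", "B"])
        d2 = self.make_dm(np.array([[0, 1.0], [1.0, 0]]), ["A", "C"])
        with pytest.raises(ValueError):
            mantel_test(d1, d2, 99)


class TestBioenv:
    def env_frame(self, seed=0, n=20, p=5):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.standard_normal((n, p)),
            index=[f"S{i}" for i in range(n)],
            columns=[f"v{j}" for j in range(p)],
        )

    def test_single_variable_self_recovery(self):
        env = self.env_frame()
        z1 = (env["v0"] - env["v0"].mean()) / env["v0"].std(ddof=1)
        d = DistanceMatrix(squareform(pdist(z1.to_numpy()[:, None])),
                           ids=list(env.index))
        res = bioenv_search(d, env)
        assert res.best_subset == frozenset({"v0"})
        assert res.rho == pytest.approx(1.0)

    def test_table_is_exhaustive_and_matches_brute_force(self):
        env = self.env_frame(n=15, p=4)
        rng = np.random.default_rng(9)
        d = DistanceMatrix(
            squareform(pdist(rng.standard_normal((15, 2)))),
            ids=list(env.index),
        )
        res = bioenv_search(d, env)
        assert len(res.table) == 2**4 - 1
        z = (env - env.mean()) / env.std(ddof=1)
        tri = np.tril_indices(15, k=-1)
        comm = d.data[tri]
        for subset, _, rho in res.table.itertuples(index=False):
            ed = squareform(pdist(z[list(subset)].to_numpy()))[tri]
            expected = np.corrcoef(rankdata(comm), rankdata(ed))[0, 1]
            assert rho == pytest.approx(expected)
        assert res.rho == pytest.approx(res.table["rho"].max())

    def test_noise_variable_never_beats_true_subset(self):
        env = self.env_frame(seed=5, n=25, p=5)
        z = (env - env.mean()) / env.std(ddof=1)
        d = DistanceMatrix(
            squareform(pdist(z[["v0", "v1"]].to_numpy())), ids=list(env.index)
        )
        res = bioenv_search(d, env)
        assert res.best_subset == frozenset({"v0", "v1"})
        table = res.table.set_index("subset")["rho"]
        rho_true = table[("v0", "v1")]
        for extra in ["v2", "v3", "v4"]:
            assert table[("v0", "v1", extra)] <= rho_true

    def test_max_subset_limits_size(self):
        env = self.env_frame(n=12, p=4)
        rng = np.random.default_rng(11)
        d = DistanceMatrix(squareform(pdist(rng.standard_normal((12, 1)))),
                           ids=list(env.index))
        res = bioenv_search(d, env, max_subset=2)
        assert res.table["size"].max() == 2
        assert len(res.best_subset) <= 2

    def test_missing_values_rejected(self):
        env = self.env_frame()
        env.iloc[0, 0] = np.nan
        d = DistanceMatrix(squareform(pdist(np.arange(20.0)[:, None])),
                           ids=list(env.index))
        with pytest.raises(ValueError, match="missing"):
            bioenv_search(d, env)


class TestMannWhitney:
    def test_hand_enumeration_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        _, p = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == pytest.approx(1.0)

    def test_two_sided_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(6), rng.standard_normal(9)
        _, pxy = mann_whitney_u(x, y)
        _, pyx = mann_whitney_u(y, x)
        assert pxy == pytest.approx(pyx)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_enumeration_oracle_small_samples(self, data):
        n = data.draw(st.integers(1, 4))
        m = data.draw(st.integers(1, 8 - n))
        vals = data.draw(
            st.lists(
                st.floats(-50, 50, allow_nan=False),
                min_size=n + m, max_size=n + m, unique=True,
            )
        )
        x, y = vals[:n], vals[n:]
        u, p = mann_whitney_u(x, y)
        u_exp, p_exp = exact_mwu_two_sided(x, y)
        assert u == pytest.approx(u_exp)
        assert p == pytest.approx(p_exp)


class TestZscore:
    def test_hand_values_sample_sd(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=list("abc"))
        z = zscore_table(df)
        np.testing.assert_allclose(z["f"], [-1.0, 0.0, 1.0])

    def test_constant_feature_zeroed_with_warning(self):
        df = pd.DataFrame({"f": [2.0, 2.0, 2.0], "g": [1.0, 2.0, 3.0]},
                          index=list("abc"))
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_table(df)
        np.testing.assert_array_equal(z["f"], 0.0)

    def test_standardized_means_are_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.random((10, 4)))
        z = zscore_table(df)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0)

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            zscore_table(pd.DataFrame({"f": [1.0]}))
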