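"""Permutation inference: exchangeability contracts and oracle checks.

The heavier oracle-equivalence and type-I calibration runs live in
test_acceptance; these tests cover the per-operation contracts at small
problem sizes, including an independent flood-fill cluster oracle and a
cross-check against MNE's cluster permutation test.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

from hftag import permstats


def floodfill_clusters(tmap, t_crit, adj):
    """Independent oracle: BFS over same-sign suprathreshold points."""
    n_units, n_bins = tmap.shape
    sign = np.where(tmap > t_crit, 1, np.where(tmap < -t_crit, -1, 0))
    seen = set()
    clusters = []
    for u in range(n_units):
        for b in range(n_bins):
            if sign[u, b] == 0 or (u, b) in seen:
                continue
            comp, queue = [], [(u, b)]
            seen.add((u, b))
            while queue:
                cu, cb = queue.pop()
                comp.append((cu, cb))
                neigh = [(cu, cb - 1), (cu, cb + 1)] + \
                    [(v, cb) for v in range(n_units) if adj[cu, v]]
                for vu, vb in neigh:
                    if 0 <= vb < n_bins and sign[vu, vb] == sign[cu, cb] \
                            and (vu, vb) not in seen:
                        seen.add((vu, vb))
                        queue.append((vu, vb))
            clusters.append((frozenset(comp),
                             sum(tmap[cu, cb] for cu, cb in comp)))
    return clusters


class TestConditionPermutationTest:
    def test_identical_conditions_not_significant(self, rng):
        v = rng.normal(size=10)
        res = permstats.condition_permutation_test(v, v.copy(), n_perm=200,
                                                   seed=1)
        assert res.observed_stat == 0.0
        assert res.p > 0.4

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="4"):
            permstats.condition_permutation_test([1, 2, 3], [0, 1, 2])

    def test_add_one_lower_bound(self, rng):
        a = rng.normal(1.0, 0.1, size=12)  # overwhelming effect
        b = rng.normal(0.0, 0.1, size=12)
        res = permstats.condition_permutation_test(a, b, n_perm=250, seed=0)
        assert res.p == pytest.approx(1 / 251)
        assert res.null_distribution.shape == (250,)

    def test_exhaustive_half_swap_oracle_n6(self, rng):
        a = rng.normal(0.4, 1.0, size=6)
        b = rng.normal(0.0, 1.0, size=6)
        diff = a - b
        t_obs = diff.mean() / (diff.std(ddof=1) / np.sqrt(6))
        null = []
        for subset in itertools.combinations(range(6), 3):
            d = diff.copy()
            d[list(subset)] *= -1
            null.append(d.mean() / (d.std(ddof=1) / np.sqrt(6)))
        p_exact = (1 + sum(t >= t_obs for t in null)) / (1 + len(null))
        res = permstats.condition_permutation_test(a, b, n_perm=1000, seed=3)
        assert abs(res.p - p_exact) < 0.05

    def test_half_swap_null_symmetric_under_condition_flip(self, rng):
        a = rng.normal(0.3, 1.0, size=14)
        b = rng.normal(0.0, 1.0, size=14)
        null_ab = permstats.condition_permutation_test(
            a, b, n_perm=2000, seed=5).null_distribution
        null_ba = permstats.condition_permutation_test(
            b, a, n_perm=2000, seed=5).null_distribution
        ks = stats.ks_2samp(np.abs(null_ab), np.abs(null_ba)).statistic
        assert ks < 0.05

    def test_bernoulli_scheme_available(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        res = permstats.condition_permutation_test(a, b, n_perm=100, seed=0,
                                                   scheme="bernoulli")
        assert 0 < res.p <= 1


class TestRoiGlobalPermutation:
    def test_no_suprathreshold_rois_gives_zero_stat(self):
        a = np.tile(np.linspace(0, 1, 8)[:, None], (1, 5))
        res = permstats.roi_global_permutation(a, a.copy(), n_perm=100, seed=0)
        assert res.global_stat == 0.0
        assert res.global_p > 0.05
        assert not res.suprathreshold.any()

    def test_detects_multi_roi_effect(self, rng):
        n, n_roi = 16, 10
        a = rng.normal(size=(n, n_roi))
        b = a + rng.normal(0, 0.3, size=(n, n_roi))
        a[:, :3] += 1.0
        res = permstats.roi_global_permutation(a, b, n_perm=500, seed=1)
        assert res.suprathreshold[:3].all()
        assert res.global_p < 0.05

    def test_needs_two_rois(self, rng):
        with pytest.raises(ValueError, match="ROI"):
            permstats.roi_global_permutation(rng.normal(size=(8, 1)),
                                             rng.normal(size=(8, 1)))

    def test_unsigned_variant(self, rng):
        a = rng.normal(size=(12, 6))
        b = a.copy()
        b[:, 0] += 1.0  # strong negative a-b effect in ROI 0
        res = permstats.roi_global_permutation(a, b, n_perm=200, seed=2,
                                               signed=False)
        assert res.global_stat > 0  # |t| sum is positive despite direction


class TestClusterPermutation:
    def make_adj(self):
        return permstats.grid_adjacency(2, 2)

    def test_identical_conditions_no_clusters(self, rng):
        d = rng.normal(size=(10, 4, 6))
        res = permstats.cluster_permutation(d, d.copy(), self.make_adj(),
                                            n_perm=50, seed=0)
        assert res.clusters == []

    def test_cluster_identification_matches_floodfill_oracle(self, rng):
        for trial in range(8):
            n_units, n_bins = 10, 20
            adj = rng.random((n_units, n_units)) < 0.2
            adj = adj | adj.T
            np.fill_diagonal(adj, False)
            n = 12
            diff = rng.normal(size=(n, n_units, n_bins)) \
                + rng.choice([0, 1.2], p=[0.7, 0.3],
                             size=(1, n_units, n_bins))
            tmap = diff.mean(0) / (diff.std(0, ddof=1) / np.sqrt(n))
            t_crit = stats.t.ppf(0.975, n - 1)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = permstats.cluster_permutation(
                    diff, np.zeros_like(diff), adj, n_perm=5, seed=trial)
            got = {frozenset((u, b) for u, b in c["members"])
                   for c in res.clusters}
            expected = {comp for comp, _ in
                        floodfill_clusters(tmap, t_crit, adj)}
            assert got == expected

    def test_exhaustive_sign_flip_oracle_n8(self, rng):
        n, n_units, n_bins = 8, 3, 6
        adj = permstats.grid_adjacency(1, 3)
        diff = rng.normal(size=(n, n_units, n_bins))
        diff[:, 1, 2:5] += 1.6
        res = permstats.cluster_permutation(diff, np.zeros_like(diff), adj,
                                            n_perm=1000, seed=9)
        top = res.clusters[0]
        t_crit = stats.t.ppf(0.975, n - 1)
        null = []
        for signs in itertools.product([-1, 1], repeat=n):
            d = np.asarray(signs)[:, None, None] * diff
            tmap = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(n))
            masses = [m for _, m in floodfill_clusters(tmap, t_crit, adj)]
            null.append(max(np.abs(masses)) if masses else 0.0)
        p_exact = (1 + sum(m >= abs(top["mass"]) for m in null)) / (1 + len(null))
        assert abs(top["corrected_p"] - p_exact) < 0.05

    def test_boxcar_recovery_on_clique(self, rng):
        # effect on a 4-unit clique over bins 5..14 (70-180 ms at ~11 ms bins)
        n, n_units, n_bins = 14, 6, 25
        adj = np.zeros((n_units, n_units), dtype=bool)
        adj[np.ix_(range(4), range(4))] = True
        adj[4, 5] = adj[5, 4] = True
        np.fill_diagonal(adj, False)
        injected = {(u, b) for u in range(4) for b in range(5, 15)}
        diff = rng.normal(size=(n, n_units, n_bins))
        for u, b in injected:
            diff[:, u, b] += 1.5
        res = permstats.cluster_permutation(diff, np.zeros_like(diff), adj,
                                            n_perm=300, seed=4)
        top = set(map(tuple, res.clusters[0]["members"]))
        assert len(top & injected) >= 0.8 * len(injected)
        assert res.clusters[0]["corrected_p"] < 0.05

    def test_orphan_units_warn(self, rng):
        adj = np.zeros((3, 3), dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        d = rng.normal(size=(8, 3, 4))
        with pytest.warns(UserWarning, match="singleton"):
            permstats.cluster_permutation(d, np.zeros_like(d), adj,
                                          n_perm=10, seed=0)

    def test_matches_mne_cluster_test(self, rng):
        """Independent cross-check against MNE's sign-flip cluster test."""
        mne = pytest.importorskip("mne")
        from scipy import sparse
        n, n_units, n_bins = 12, 4, 10
        adj = permstats.grid_adjacency(2, 2)
        diff = rng.normal(size=(n, n_units, n_bins))
        diff[:, :2, 3:7] += 1.0
        t_crit = float(stats.t.ppf(0.975, n - 1))
        res = permstats.cluster_permutation(diff, np.zeros_like(diff), adj,
                                            n_perm=2000, seed=0)
        X = diff.transpose(0, 2, 1)  # (obs, times, spaces) for MNE
        t_obs, clusters, pvals, _ = mne.stats.spatio_temporal_cluster_1samp_test(
            X, threshold=t_crit, n_permutations=2000,
            adjacency=sparse.coo_matrix(adj), tail=0, seed=1, verbose=False,
            out_type="mask")
        # same number of clusters, same top-cluster membership, close p
        assert len(clusters) == len(res.clusters)
        top_mne = clusters[int(np.argmin(pvals))]
        got_top = {(u, b) for u, b in res.clusters[0]["members"]}
        mne_top = {(u, b) for b, u in zip(*np.nonzero(top_mne))}
        assert got_top == mne_top
        assert abs(res.clusters[0]["corrected_p"] - pvals.min()) < 0.05


class TestWindowedRoiTrfTest:
    times = np.arange(-0.050, 0.4001, 0.004)

    def test_window_tiling_and_detection(self, rng):
        # 5 full 20 ms windows tile [70, 180] ms; effect in ROI 2, 60 ms wide
        n, n_roi = 14, 6
        a = rng.normal(size=(n, n_roi, self.times.size))
        b = a + rng.normal(0, 0.2, size=a.shape)
        mask = (self.times >= 0.090) & (self.times < 0.150)
        a[:, 2, mask] += 1.0
        adj = np.ones((n_roi, n_roi), dtype=bool)
        res = permstats.windowed_roi_trf_test(a, b, self.times, adj,
                                              n_perm=300, seed=0)
        top = res.clusters[0]
        assert {u for u, _ in top["members"]} == {2}
        assert all(0 <= w <= 4 for _, w in top["members"])
        assert top["corrected_p"] < 0.05

    def test_identical_conditions_no_clusters(self, rng):
        a = rng.normal(size=(8, 4, self.times.size))
        adj = np.ones((4, 4), dtype=bool)
        res = permstats.windowed_roi_trf_test(a, a.copy(), self.times, adj,
                                              n_perm=20, seed=0)
        assert res.clusters == []

    def test_uncovered_window_rejected(self, rng):
        short_times = np.arange(0.0, 0.1, 0.004)
        a = rng.normal(size=(8, 4, short_times.size))
        with pytest.raises(ValueError, match="cover"):
            permstats.windowed_roi_trf_test(a, a, short_times,
                                            np.ones((4, 4), bool))

    def test_misaligned_window_rejected(self, rng):
        times = np.arange(-0.050, 0.4001, 0.003)  # 20 ms not a multiple
        a = rng.normal(size=(8, 4, times.size))
        with pytest.raises(ValueError, match="whole number"):
            permstats.windowed_roi_trf_test(a, a, times, np.ones((4, 4), bool))
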