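import numpy as np
import pytest

from relaycomm.infotheory import MIMatrix, mi_matrix, zscore
from relaycomm.io import TimeSeriesPanel, rng_service
from relaycomm.nulls import (
    NullEnsemble,
    null_gaussian,
    null_region_shuffle,
    pcs_null_distribution,
    screen_pcs,
    variogram,
    variogram_matched_null,
)
from relaycomm.paths import PathEnsemble
from relaycomm.relay import pcs

from conftest import random_connectome


class TestRegionShuffle:
    def test_mi_conjugation_identity(self, rng):
        panel = zscore(TimeSeriesPanel("s", rng.standard_normal((150, 6))))
        m = mi_matrix(panel)
        shuffled, perm = null_region_shuffle(panel, rng)
        m_s = mi_matrix(shuffled)
        off = ~np.eye(6, dtype=bool)
        # MI of the shuffled panel is exactly the permutation-conjugated MI
        np.testing.assert_array_equal(
            m_s.values[off], m.values[np.ix_(perm, perm)][off]
        )

    def test_off_diagonal_multiset_preserved(self, rng):
        panel = zscore(TimeSeriesPanel("s", rng.standard_normal((100, 5))))
        m = mi_matrix(panel)
        shuffled, _ = null_region_shuffle(panel, rng)
        m_s = mi_matrix(shuffled)
        iu = np.triu_indices(5, 1)
        assert sorted(m.values[iu]) == sorted(m_s.values[iu])

    def test_identity_permutation_preserves_pcs(self, rng):
        conn = random_connectome(rng, n=7, p=0.5)
        panel = zscore(TimeSeriesPanel("s", rng.standard_normal((200, 7))))
        ens = PathEnsemble.build(conn, 3)
        real = pcs(ens, mi_matrix(panel))

        class IdentityRng:
            def permutation(self, n):
                return np.arange(n)

        shuffled, perm = null_region_shuffle(panel, rng_service(0))
        # force the identity explicitly
        ident = TimeSeriesPanel("s", panel.values, zscored=True)
        again = pcs(ens, mi_matrix(ident))
        np.testing.assert_array_equal(real.values, again.values)
        assert len(perm) == 7


class TestGaussianNull:
    def test_moments_within_lln_bound(self, rng):
        t = 400
        panel = null_gaussian(5, t, rng)
        assert np.all(np.abs(panel.values.mean(axis=0)) < 4 / np.sqrt(t))
        assert np.all(np.abs(panel.values.var(axis=0) - 1) < 4 / np.sqrt(t))

    def test_mi_at_independence_bias_level(self, rng):
        # oracle: distribution of plug-in MI between independent N(0,1) pairs
        from relaycomm import mutual_information

        t = 300
        oracle = []
        for _ in range(60):
            v = rng.standard_normal((t, 2))
            v = (v - v.mean(axis=0)) / v.std(axis=0)
            oracle.append(mutual_information(v[:, 0], v[:, 1], 0.5))
        mu, sd = np.mean(oracle), np.std(oracle)
        panel = zscore(null_gaussian(6, t, rng))
        m = mi_matrix(panel)
        iu = np.triu_indices(6, 1)
        assert abs(m.values[iu].mean() - mu) < 4 * sd

    def test_errors(self):
        with pytest.raises(ValueError):
            null_gaussian(0, 100)


class TestVariogram:
    def test_constant_field_is_zero(self, rng):
        d = rng.uniform(0, 50, 40)
        lag, gamma = variogram(np.full(40, 0.7), d, n_bins=8)
        np.testing.assert_allclose(gamma, 0.0)

    def test_coordinate_field_matches_loop_oracle(self, rng):
        # field equal to its own coordinate: semivariance is (d_a-d_b)^2/2,
        # growing quadratically with lag
        d = np.sort(rng.uniform(0, 10, 30))
        v = d.copy()
        n_bins = 6
        lag, gamma = variogram(v, d, n_bins=n_bins)
        edges = np.linspace(0, d.max() - d.min(), n_bins + 1)
        expected = {b: [] for b in range(n_bins)}
        for a in range(30):
            for b in range(a + 1, 30):
                h = abs(d[a] - d[b])
                idx = min(int(np.digitize(h, edges)) - 1, n_bins - 1)
                expected[max(idx, 0)].append(0.5 * (v[a] - v[b]) ** 2)
        kept = [np.mean(vals) for vals in expected.values() if len(vals) >= 2]
        np.testing.assert_allclose(gamma, kept)
        assert gamma[-1] > gamma[0]  # grows with lag

    def test_permutation_flattens_variogram(self, rng):
        d = np.sort(rng.uniform(0, 10, 60))
        v = d + 0.1 * rng.standard_normal(60)
        _, gamma_orig = variogram(v, d, n_bins=6)
        _, gamma_perm = variogram(rng.permutation(v), d, n_bins=6)
        # permuted field loses the trend: late-lag semivariance shrinks
        assert gamma_perm[-1] < gamma_orig[-1]
        assert np.ptp(gamma_perm) < np.ptp(gamma_orig)


class TestVariogramMatchedNull:
    @staticmethod
    def trended_mi(rng, n=20):
        from conftest import make_regions

        centroids = rng.uniform(0, 60, (n, 3))
        regions = make_regions(centroids)
        dist = regions.pairwise_distances()
        iu = np.triu_indices(n, 1)
        vals = np.full((n, n), np.nan)
        tri = 2.0 * np.exp(-dist[iu] / 30.0) + 0.05 * rng.standard_normal(len(iu[0]))
        tri = np.maximum(tri, 0)
        vals[iu] = tri
        vals[(iu[1], iu[0])] = tri
        return MIMatrix(vals, "s", 0.5, 100), dist

    def test_returned_surrogate_is_min_sse_run(self, rng):
        mi, dist = self.trended_mi(rng)
        surrogate, sse_log, best_run = variogram_matched_null(
            mi, dist, n_runs=10, rng=rng
        )
        assert len(sse_log) == 10
        assert sse_log[best_run] == np.min(sse_log)

    def test_preserves_distance_trend_better_than_permutation(self, rng):
        mi, dist = self.trended_mi(rng)
        iu = np.triu_indices(mi.n_regions, 1)
        d = dist[iu]
        _, gamma0 = variogram(mi.values[iu], d, n_bins=10)
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            surrogate, sse_log, _ = variogram_matched_null(
                mi, dist, n_runs=10, rng=r, n_bins=10
            )
            _, gamma_perm = variogram(
                r.permutation(mi.values[iu]), d, n_bins=10
            )
            sse_perm = float(np.sum((gamma0 - gamma_perm) ** 2))
            if np.min(sse_log) < sse_perm:
                wins += 1
        assert wins >= int(0.9 * n_seeds)

    def test_degenerate_variogram_errors(self, rng):
        n = 10
        vals = np.full((n, n), 0.5)
        np.fill_diagonal(vals, np.nan)
        mi = MIMatrix(vals, "s", 0.5, 100)
        dist = np.abs(
            np.arange(n)[:, None] - np.arange(n)[None, :]
        ).astype(float)
        with pytest.raises(ValueError, match="degenerate"):
            variogram_matched_null(mi, dist, n_runs=2, rng=rng)


class TestPcsNullDistribution:
    def test_fixed_seed_bitwise_identical(self, rng):
        conn = random_connectome(rng, n=8, p=0.5)
        cohort = [
            zscore(TimeSeriesPanel(f"s{i}", rng.standard_normal((120, 8))))
            for i in range(2)
        ]
        ens = PathEnsemble.build(conn, 3)
        a = pcs_null_distribution(cohort, conn, ens, "region_shuffle", 3, rng_service(9))
        b = pcs_null_distribution(cohort, conn, ens, "region_shuffle", 3, rng_service(9))
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_replicates_obey_pcs_invariants(self, rng):
        conn = random_connectome(rng, n=7, p=0.5)
        cohort = [zscore(TimeSeriesPanel("s0", rng.standard_normal((100, 7))))]
        ens = PathEnsemble.build(conn, 3)
        null = pcs_null_distribution(cohort, conn, ens, "iid_gaussian", 4, rng)
        assert null.replicates.shape == (4, 7, 7)
        for rep in null.replicates:
            np.testing.assert_array_equal(rep, rep.T)
            assert rep.min() >= 0 and rep.max() <= 3


class TestScreenPcs:
    @staticmethod
    def null_from(reps):
        return NullEnsemble(model="region_shuffle", replicates=np.asarray(reps))

    def test_real_equal_to_null_mean(self, rng):
        base = rng.uniform(0, 5, (4, 4))
        base = (base + base.T) / 2
        reps = np.stack([base + s for s in (-1, 0, 1)])
        res = screen_pcs(base, self.null_from(reps))
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(res.z[off], 0.0, atol=1e-12)
        # two of three replicates >= real -> p = 3/4 with the add-one rule
        np.testing.assert_allclose(res.p[off], 0.75)

    def test_real_above_every_replicate(self):
        reps = np.zeros((10, 3, 3))
        real = np.ones((3, 3))
        np.fill_diagonal(real, 0)
        res = screen_pcs(real, self.null_from(reps + 1e-6 * np.arange(10)[:, None, None]))
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(res.p[off], 1 / 11)  # add-one rule

    def test_monotone_in_real_value(self, rng):
        reps = rng.normal(2, 0.5, (50, 3, 3))
        reps = (reps + reps.transpose(0, 2, 1)) / 2
        lo = np.full((3, 3), 2.0)
        hi = np.full((3, 3), 3.0)
        r_lo = screen_pcs(lo, self.null_from(reps))
        r_hi = screen_pcs(hi, self.null_from(reps))
        off = ~np.eye(3, dtype=bool)
        assert np.all(r_hi.z[off] > r_lo.z[off])
        assert np.all(r_hi.p[off] <= r_lo.p[off])

    def test_masks_shrink_with_tighter_thresholds(self, rng):
        reps = rng.normal(1, 0.3, (80, 5, 5))
        reps = (reps + reps.transpose(0, 2, 1)) / 2
        real = rng.uniform(1, 3, (5, 5))
        real = (real + real.T) / 2
        null = self.null_from(reps)
        loose = screen_pcs(real, null, z_threshold=1.0, fdr_q=0.2)
        tight = screen_pcs(real, null, z_threshold=2.5, fdr_q=0.01)
        assert np.all(tight.mask_z <= loose.mask_z)
        assert np.all(tight.mask_fdr <= loose.mask_fdr)
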