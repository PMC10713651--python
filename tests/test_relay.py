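import numpy as np
import pytest

from relaycomm.infotheory import MIMatrix, mi_matrix, zscore
from relaycomm.io import TimeSeriesPanel
from relaycomm.paths import PathEnsemble
from relaycomm.relay import (
    DPI_MODES,
    PCSMatrix,
    communication_density,
    dpi_check,
    group_average_pcs,
    nodal_pcs,
    pcs,
    system_summary,
)

from conftest import make_connectome, make_regions


def random_mi(rng, n):
    m = rng.uniform(0, 2, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, np.nan)
    return m


def brute_force_dpi(path, m, mode):
    """Direct transcription of the inequality sets."""
    if len(path) <= 2:
        return False
    src = path[0]
    tgt = path[-1]
    phi_s = [m[src, v] for v in path[1:]]
    ok_s = all(phi_s[a] >= phi_s[a + 1] for a in range(len(phi_s) - 1))
    rev = path[::-1]
    phi_t = [m[tgt, v] for v in rev[1:]]
    ok_t = all(phi_t[a] >= phi_t[a + 1] for a in range(len(phi_t) - 1))
    if mode == "source":
        return ok_s
    if mode == "bidirectional":
        return ok_s and ok_t
    for a in range(len(path)):
        for b in range(a + 1, len(path)):
            for c in range(b + 1, len(path)):
                u, v, w = path[a], path[b], path[c]
                if m[u, w] > min(m[u, v], m[v, w]):
                    return False
    return True


class TestDpiCheck:
    def test_rising_last_step_rejected(self):
        # path (i, x1, x2, j) where I(j, i) > I(x2, i): the source-anchored
        # sequence rises at its last step, so the path is not a relay pathway
        m = np.full((4, 4), np.nan)
        pairs = {
            (0, 1): 1.0,  # I(i, x1)
            (0, 2): 0.5,  # I(i, x2)
            (0, 3): 0.8,  # I(i, j)  > I(i, x2): violation
            (1, 2): 1.0,
            (1, 3): 0.6,
            (2, 3): 1.0,
        }
        for (a, b), v in pairs.items():
            m[a, b] = m[b, a] = v
        res = dpi_check((0, 1, 2, 3), m, mode="source")
        assert res.assessable and not res.is_relay

    def test_all_equal_mi_satisfies_every_mode(self):
        m = np.full((4, 4), 0.7)
        np.fill_diagonal(m, np.nan)
        for mode in DPI_MODES:
            assert dpi_check((0, 1, 2, 3), m, mode).is_relay  # non-strict ties

    def test_one_hop_not_assessable(self, rng):
        m = random_mi(rng, 3)
        res = dpi_check((0, 1), m)
        assert not res.assessable and not res.is_relay

    def test_agrees_with_brute_force_oracle(self, rng):
        n = 5
        path = (0, 1, 2, 3, 4)
        for _ in range(200):
            m = random_mi(rng, n)
            for mode in DPI_MODES:
                assert dpi_check(path, m, mode).is_relay == brute_force_dpi(
                    path, m, mode
                )

    def test_mode_nesting(self, rng):
        # all_triplets => bidirectional => source
        path = (0, 1, 2, 3)
        for _ in range(300):
            m = random_mi(rng, 4)
            r_s = dpi_check(path, m, "source").is_relay
            r_b = dpi_check(path, m, "bidirectional").is_relay
            r_t = dpi_check(path, m, "all_triplets").is_relay
            assert (not r_t or r_b) and (not r_b or r_s)

    def test_missing_mi_errors(self):
        m = np.full((3, 3), np.nan)
        m[0, 1] = m[1, 0] = 0.5
        with pytest.raises(ValueError, match="missing MI"):
            dpi_check((0, 1, 2), m)


class TestPcs:
    def test_two_node_graph_pcs_zero(self):
        conn = make_connectome(
            np.array([[0, 1], [1, 0]]), [(0, 0, 0), (5, 0, 0)]
        )
        ens = PathEnsemble.build(conn, k=5)
        m = MIMatrix(
            np.array([[np.nan, 0.5], [0.5, np.nan]]), "s", 0.5, 100
        )
        out = pcs(ens, m)
        assert out.values[0, 1] == 0
        assert out.missing_mask[0, 1]  # no multi-step path exists

    def test_bounded_by_multistep_path_count(self, rng, triangle):
        ens = PathEnsemble.build(triangle, k=5)
        m = MIMatrix(random_mi(rng, 3), "s", 0.5, 100)
        out = pcs(ens, m)
        for (i, j), plist in ens.paths.items():
            n_multi = sum(1 for p in plist if len(p) > 2)
            assert 0 <= out.values[i, j] <= n_multi <= ens.k

    def test_region_permutation_conjugates_pcs(self, rng):
        from conftest import random_connectome
        from relaycomm.connectome import euclidean_weighting

        conn = random_connectome(rng, n=8, p=0.5)
        mvals = random_mi(rng, 8)
        out = pcs(
            PathEnsemble.build(conn, 3), MIMatrix(mvals, "s", 0.5, 10), "bidirectional"
        )
        perm = rng.permutation(8)
        # relabel regions: row/col i of the permuted system is perm[i] of the original
        adj_p = conn.adjacency[np.ix_(perm, perm)]
        regions_p = make_regions(conn.regions.centroids[perm])
        conn_p = euclidean_weighting(adj_p, regions_p)
        m_p = MIMatrix(mvals[np.ix_(perm, perm)], "s", 0.5, 10)
        # direction-symmetric modes conjugate exactly; source mode anchors at
        # the stored path orientation and is not permutation-equivariant
        out_p = pcs(PathEnsemble.build(conn_p, 3), m_p, "bidirectional")
        np.testing.assert_array_equal(
            out_p.values, out.values[np.ix_(perm, perm)]
        )

    def test_invariants_enforced(self):
        with pytest.raises(Exception):
            PCSMatrix(values=np.array([[0, 6], [6, 0]]), subject_id="s", k=5)
        with pytest.raises(Exception):
            PCSMatrix(values=np.array([[0, 1], [2, 0]]), subject_id="s", k=5)


class TestCommunicationDensity:
    def test_all_relay_gives_100(self, triangle):
        ens = PathEnsemble.build(triangle, k=5)
        m = MIMatrix(np.full((3, 3), 0.5) - np.diag([0.5] * 3) + np.diag([np.nan] * 3) * 0, "s", 0.5, 10)
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, np.nan)
        dens = communication_density(ens, MIMatrix(vals, "s", 0.5, 10))
        assert dens.overall == 100.0
        assert all(v == 100.0 for v in dens.per_rank.values())

    def test_rank_grouping(self, rng):
        from conftest import random_connectome

        conn = random_connectome(rng, n=8, p=0.5)
        ens = PathEnsemble.build(conn, k=5)
        m = MIMatrix(random_mi(rng, 8), "s", 0.5, 10)
        dens = communication_density(ens, m)
        assert set(dens.per_rank) <= set(range(1, 6))
        assert all(0 <= v <= 100 for v in dens.per_rank.values())
        # overall is the assessable-path-weighted combination of ranks
        assert 0 <= dens.overall <= 100

    def test_no_assessable_paths_errors(self):
        conn = make_connectome(
            np.array([[0, 1], [1, 0]]), [(0, 0, 0), (5, 0, 0)]
        )
        ens = PathEnsemble.build(conn, k=5)
        vals = np.full((2, 2), 0.5)
        np.fill_diagonal(vals, np.nan)
        with pytest.raises(ValueError):
            communication_density(ens, MIMatrix(vals, "s", 0.5, 10))


class TestGroupAveragePcs:
    def test_single_subject_identity(self, rng):
        p = PCSMatrix(np.zeros((4, 4), dtype=int), "s", 5)
        avg, summary = group_average_pcs([p])
        np.testing.assert_array_equal(avg, p.values)
        assert summary["n_subjects"] == 1

    def test_two_subject_mean(self):
        a = np.zeros((3, 3), dtype=int)
        b = np.zeros((3, 3), dtype=int)
        b[0, 1] = b[1, 0] = 2
        avg, _ = group_average_pcs(
            [PCSMatrix(a, "x", 5), PCSMatrix(b, "y", 5)]
        )
        assert avg[0, 1] == 1.0

    def test_percentiles_match_sort_oracle(self, rng):
        mats = []
        for s in range(5):
            v = rng.integers(0, 6, (6, 6))
            v = np.triu(v, 1)
            mats.append(PCSMatrix(v + v.T, f"s{s}", 5))
        avg, summary = group_average_pcs(mats)
        iu = np.triu_indices(6, 1)
        vals = np.sort(avg[iu])
        assert summary["median"] == pytest.approx(np.median(vals))
        assert summary["p5"] == pytest.approx(np.percentile(vals, 5))
        assert summary["p95"] == pytest.approx(np.percentile(vals, 95))


class TestNodalPcs:
    def test_constant_matrix(self):
        c = np.full((5, 5), 3.0)
        np.fill_diagonal(c, 0)
        np.testing.assert_allclose(nodal_pcs(c), 3.0)

    def test_hand_computed_three_nodes(self):
        m = np.array([[0, 1, 2], [1, 0, 4], [2, 4, 0]], dtype=float)
        np.testing.assert_allclose(nodal_pcs(m), [1.5, 2.5, 3.0])

    def test_node_means_conserve_global_mean(self, rng):
        v = rng.integers(0, 6, (7, 7))
        v = np.triu(v, 1)
        v = v + v.T
        nodal = nodal_pcs(v.astype(float))
        iu = np.triu_indices(7, 1)
        assert nodal.mean() == pytest.approx(v[iu].mean())


class TestSystemSummary:
    def test_single_system_equals_global_mean(self, rng):
        v = rng.integers(0, 6, (6, 6)).astype(float)
        v = np.triu(v, 1)
        v = v + v.T
        regions = make_regions(rng.uniform(0, 10, (6, 3)))
        block, scalars = system_summary(v, regions)
        iu = np.triu_indices(6, 1)
        assert block.loc["VIS", "VIS"] == pytest.approx(v[iu].mean())
        assert scalars["within_unimodal"] == pytest.approx(v[iu].mean())

    def test_two_system_hand_blocks(self):
        v = np.array(
            [
                [0, 1, 2, 3],
                [1, 0, 4, 5],
                [2, 4, 0, 6],
                [3, 5, 6, 0],
            ],
            dtype=float,
        )
        regions = make_regions(
            np.arange(12).reshape(4, 3),
            systems=["A", "A", "B", "B"],
            modality=["unimodal", "unimodal", "transmodal", "transmodal"],
        )
        block, scalars = system_summary(v, regions)
        assert block.loc["A", "A"] == 1.0  # pair (0,1)
        assert block.loc["B", "B"] == 6.0  # pair (2,3)
        assert block.loc["A", "B"] == pytest.approx((2 + 3 + 4 + 5) / 4)
        assert block.loc["A", "B"] == block.loc["B", "A"]  # symmetric blocks
        assert scalars["within_unimodal"] == 1.0
        assert scalars["within_transmodal"] == 6.0
        assert scalars["cross_modal"] == pytest.approx(3.5)
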