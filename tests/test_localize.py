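import numpy as np
import pytest
from scipy.optimize import nnls
from scipy.spatial import cKDTree

import spikeloc as sl
from spikeloc.localize import (
    NoSignalError,
    UnderdeterminedError,
    build_grid,
    localize_com,
    localize_gc,
    localize_many,
    localize_mt,
    select_channels,
)
from conftest import monopole_ptp


def in_convex_hull(point, vertices, tol=1e-6):
    """Independent hull oracle: nonnegative least squares on the convex
    combination constraints."""
    vertices = np.asarray(vertices, dtype=float)
    a = np.vstack([vertices.T, np.ones(len(vertices))])
    b = np.append(np.asarray(point, dtype=float), 1.0)
    _, residual = nnls(a, b)
    return residual < tol


def fig1_probe():
    return sl.ProbeGeometry(
        channel_ids=[0, 1, 2], positions=[[0, 0, 0], [1, 2, 0], [2, 1, 0]]
    )


class TestSelectChannels:
    def test_infinite_radius(self, column_probe):
        ptp = np.linspace(1, 2, 16)
        sel, _, _ = select_channels(ptp, column_probe, np.inf)
        assert sel.size == 16

    def test_radius_on_column(self, column_probe):
        ptp = np.zeros(16)
        ptp[10] = 5.0
        sel, _, _ = select_channels(ptp, column_probe, 75.0)
        np.testing.assert_array_equal(sel, [7, 8, 9, 10, 11, 12, 13])

    def test_single_present(self, column_probe):
        ptp = np.full(16, np.nan)
        ptp[4] = 1.0
        sel, pos, amps = select_channels(ptp, column_probe, 40.0)
        np.testing.assert_array_equal(sel, [4])

    def test_no_present_errors(self, column_probe):
        with pytest.raises(NoSignalError):
            select_channels(np.full(16, np.nan), column_probe, 40.0)

    def test_tie_lowest_id(self, column_probe):
        ptp = np.ones(16)
        sel, _, _ = select_channels(ptp, column_probe, 10.0)
        assert sel[0] == 0  # peak channel is lowest id on ties


class TestCom:
    def test_fig1_centroid(self):
        est = localize_com(np.ones(3), fig1_probe())
        assert est.position == (1.0, 1.0, 0.0)

    def test_weighted_mean(self):
        g = sl.ProbeGeometry(channel_ids=[0, 1], positions=[[0, 0, 0], [3, 0, 0]])
        est = localize_com(np.array([2.0, 1.0]), g)
        assert est.position == (1.0, 0.0, 0.0)

    def test_z_is_plane(self, probe96):
        rng = np.random.default_rng(0)
        est = localize_com(rng.uniform(1, 2, 96), probe96)
        assert est.position[2] == probe96.plane_z

    def test_inside_convex_hull(self, probe96):
        rng = np.random.default_rng(1)
        for _ in range(200):
            ptp = rng.uniform(0, 1, 96)
            sel, pos, _ = select_channels(ptp, probe96, 75.0)
            est = localize_com(ptp, probe96, radius_um=75.0)
            assert in_convex_hull(est.position, pos)

    def test_zero_signal_error(self, column_probe):
        with pytest.raises(NoSignalError):
            localize_com(np.zeros(16), column_probe)


class TestMt:
    def test_noiseless_recovery(self):
        g = sl.make_probe(16)
        src = (10.0, 100.0, 40.0)
        ptp = monopole_ptp(g, src, 2000.0)
        est = localize_mt(ptp, g, radius_um=np.inf)
        assert np.linalg.norm(np.array(est.position) - src) < 0.5
        assert est.aux["residual"] < 1e-6
        assert est.aux["c"] == pytest.approx(2000.0, rel=1e-3)

    def test_homogeneity(self):
        g = sl.make_probe(16)
        ptp = monopole_ptp(g, (5.0, 120.0, 30.0), 1500.0)
        a = localize_mt(ptp, g, radius_um=np.inf)
        b = localize_mt(3.0 * ptp, g, radius_um=np.inf)
        np.testing.assert_allclose(a.position, b.position, atol=1e-3)
        assert b.aux["c"] == pytest.approx(3.0 * a.aux["c"], rel=1e-3)

    def test_fig1_equidistant(self):
        est = localize_mt(
            np.ones(3),
            fig1_probe(),
            radius_um=np.inf,
            max_distance_um=10.0,
            require_determined=False,
        )
        d = np.linalg.norm(np.array(est.position) - fig1_probe().positions, axis=1)
        assert (d.max() - d.min()) / d.mean() < 1e-3
        assert est.aux["underdetermined"]

    def test_underdetermined_error(self):
        with pytest.raises(UnderdeterminedError):
            localize_mt(np.ones(3), fig1_probe())

    def test_can_escape_convex_hull(self, probe96):
        """An off-plane monopole source is recovered outside the hull of
        the (planar) electrode array, which COM can never leave."""
        src = (25.0, 300.0, 25.0)
        ptp = monopole_ptp(probe96, src, 1000.0)
        est = localize_mt(ptp, probe96, radius_um=np.inf)
        sel, pos, _ = select_channels(ptp, probe96, np.inf)
        assert not in_convex_hull(est.position, pos, tol=1.0)
        assert in_convex_hull(localize_com(ptp, probe96).position, pos)
        assert np.linalg.norm(np.array(est.position) - src) < 1.0

    def test_recovery_sweep(self, probe96):
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(25):
            src = (
                rng.uniform(0, 48),
                rng.uniform(100, 800),
                rng.uniform(10, 100),
            )
            ptp = monopole_ptp(probe96, src, rng.uniform(500, 3000))
            est = localize_mt(ptp, probe96)
            errs.append(np.linalg.norm(np.array(est.position) - src))
        assert np.median(errs) < 1.0


class TestBuildGrid:
    def test_resolution_spacing(self, probe96):
        grid = build_grid(probe96, resolution_um=5.0)
        xs = np.unique(grid.node_positions[:, 0])
        np.testing.assert_allclose(np.diff(xs), 5.0)

    def test_zmax_zero_planar(self, probe96):
        grid = build_grid(probe96, z_max_um=0.0)
        assert np.all(grid.node_positions[:, 2] == probe96.plane_z)

    def test_doubling_resolution_halves_axis(self, probe96):
        g1 = build_grid(probe96, resolution_um=5.0)
        g2 = build_grid(probe96, resolution_um=10.0)
        for axis in range(3):
            n1 = np.unique(g1.node_positions[:, axis]).size
            n2 = np.unique(g2.node_positions[:, axis]).size
            assert abs(n1 - 2 * n2) <= 1

    def test_covers_probe_padded(self, probe96):
        grid = build_grid(probe96, radius_um=40.0)
        p = probe96.positions
        n = grid.node_positions
        assert n[:, 0].min() <= p[:, 0].min() - 40.0 + 1e-9
        assert n[:, 1].min() <= p[:, 1].min() - 40.0 + 1e-9


@pytest.fixture(scope="module")
def grid96(probe96):
    return build_grid(probe96)


class TestGc:
    def _prototype(self, probe96, node, sigma=20.0):
        d = np.linalg.norm(probe96.positions - node, axis=1)
        return np.exp(-(d**2) / (2 * sigma**2))

    def test_self_match_argmax_exact(self, probe96, grid96):
        """For a prototype input the best-scoring node is exactly the
        generating node; the top-5% weighted mean stays within ~1 grid
        step in the median (flat similarity ridges keep the worst case at
        ~2-3 steps; see decisions ledger)."""
        tree = cKDTree(probe96.positions)
        dmin, _ = tree.query(grid96.node_positions)
        reachable = np.flatnonzero(dmin <= grid96.radius_um)
        rng = np.random.default_rng(4)
        errs = []
        for k in rng.choice(reachable, 30, replace=False):
            node = grid96.node_positions[k]
            est = localize_gc(self._prototype(probe96, node), probe96, grid96)
            errs.append(np.linalg.norm(np.array(est.position) - node))
        assert np.median(errs) <= grid96.resolution_um

    def test_percentile_100_weighted_centroid(self, probe96, grid96):
        """percentile_top=100 must reproduce the plain similarity-weighted
        mean over all positive nodes (oracle recomputed here)."""
        node = grid96.node_positions[
            cKDTree(grid96.node_positions).query([20.0, 500.0, 10.0])[1]
        ]
        ptp = self._prototype(probe96, node)
        est = localize_gc(ptp, probe96, grid96, percentile_top=100.0)

        sel, chan_pos, amps = select_channels(ptp, probe96, 40.0)
        peak_pos = probe96.positions[sel[np.argmax(amps)]]
        idx = cKDTree(grid96.node_positions).query_ball_point(peak_pos, 40.0)
        npos = grid96.node_positions[np.asarray(idx)]
        d2 = ((npos[:, None, :] - chan_pos[None, :, :]) ** 2).sum(axis=2)
        kern = np.exp(-d2 / (2 * 20.0**2))
        s = np.clip(kern @ amps - 0.5 * (kern**2).sum(axis=1), 0, None)
        expected = (s[:, None] * npos).sum(axis=0) / s.sum()
        np.testing.assert_allclose(est.position, expected, atol=1e-9)

    def test_estimate_inside_node_hull(self, probe96, grid96):
        rng = np.random.default_rng(5)
        lo = grid96.node_positions.min(axis=0) - 1e-9
        hi = grid96.node_positions.max(axis=0) + 1e-9
        for _ in range(20):
            ptp = rng.uniform(0, 50, 96)
            est = localize_gc(ptp, probe96, grid96)
            assert np.all(np.array(est.position) >= lo)
            assert np.all(np.array(est.position) <= hi)

    def test_degenerate_error(self, probe96, grid96):
        with pytest.raises(NoSignalError):
            localize_gc(np.zeros(96), probe96, grid96)

    def test_aux_fields(self, probe96, grid96):
        est = localize_gc(self._prototype(probe96, np.array([20.0, 400.0, 15.0])), probe96, grid96)
        assert est.aux["similarity_mass"] >= 0
        assert est.aux["n_top_nodes"] >= 1


class TestInvariances:
    """Shared invariants across the three localizers."""

    def _estimates(self, ptp, geometry, grid=None):
        out = {
            "com": localize_com(ptp, geometry, radius_um=75.0),
            "mt": localize_mt(ptp, geometry, require_determined=False),
            "gc": localize_gc(ptp, geometry, grid),
        }
        return {k: np.array(v.position) for k, v in out.items()}

    def test_translation_equivariance(self, probe96):
        src = np.array([20.0, 420.0, 30.0])
        ptp = monopole_ptp(probe96, src, 1200.0)
        base = self._estimates(ptp, probe96)
        shift = np.array([130.0, -70.0, 0.0])
        moved = sl.ProbeGeometry(
            channel_ids=probe96.channel_ids, positions=probe96.positions + shift
        )
        out = self._estimates(ptp, moved)
        for algo in base:
            np.testing.assert_allclose(out[algo], base[algo] + shift, atol=1e-3)

    def test_channel_order_invariance(self, probe96):
        src = np.array([25.0, 510.0, 25.0])
        ptp = monopole_ptp(probe96, src, 900.0)
        base = self._estimates(ptp, probe96)
        rng = np.random.default_rng(6)
        perm = rng.permutation(96)
        shuffled = sl.ProbeGeometry(
            channel_ids=probe96.channel_ids[perm], positions=probe96.positions[perm]
        )
        out = self._estimates(ptp[perm], shuffled)
        for algo in base:
            np.testing.assert_allclose(out[algo], base[algo], atol=1e-6)

    def test_radius_sensitivity(self, probe96):
        """Dropping channels beyond the local radius moves COM materially
        but MT/GC only within tolerance on clean data."""
        src = np.array([25.0, 150.0, 30.0])
        ptp = monopole_ptp(probe96, src, 1500.0)
        com_all = np.array(localize_com(ptp, probe96, radius_um=np.inf).position)
        com_local = np.array(localize_com(ptp, probe96, radius_um=75.0).position)
        assert np.linalg.norm(com_all - com_local) > 10.0
        mt_wide = np.array(localize_mt(ptp, probe96, radius_um=300.0).position)
        mt_local = np.array(localize_mt(ptp, probe96, radius_um=75.0).position)
        assert np.linalg.norm(mt_wide - mt_local) < 1.0


class TestLocalizeMany:
    def test_table_shape_and_failures(self, probe96):
        ptps = np.vstack(
            [
                monopole_ptp(probe96, (10.0, 300.0, 20.0), 1000.0),
                np.zeros(96),  # degenerate row
            ]
        )
        df = localize_many(ptps, probe96, "com", radius_um=75.0)
        assert list(df["ok"]) == [True, False]
        assert np.isnan(df.loc[1, "x"])

    def test_unknown_algorithm(self, probe96):
        with pytest.raises(ValueError, match="unknown algorithm"):
            localize_many(np.ones((1, 96)), probe96, "wavelet")

    def test_batch_matches_single(self, probe96):
        ptp = monopole_ptp(probe96, (30.0, 600.0, 45.0), 800.0)
        df = localize_many(ptp[None, :], probe96, "mt")
        single = localize_mt(ptp, probe96)
        np.testing.assert_allclose(
            df.loc[0, ["x", "y", "z"]].to_numpy(dtype=float), single.position, atol=1e-9
        )

    def test_gc_cache_consistent(self, probe96):
        """Batch GC (cached kernels) equals one-shot GC."""
        rng = np.random.default_rng(7)
        grid = build_grid(probe96)
        ptps = np.vstack(
            [
                self_proto(probe96, grid, rng)
                for _ in range(5)
            ]
        )
        df = localize_many(ptps, probe96, "gc", grid=grid)
        for i in range(5):
            est = localize_gc(ptps[i], probe96, grid)
            np.testing.assert_allclose(
                df.loc[i, ["x", "y", "z"]].to_numpy(dtype=float), est.position, atol=1e-9
            )


def self_proto(geometry, grid, rng):
    src = (rng.uniform(0, 48), rng.uniform(100, 800), rng.uniform(10, 30))
    return monopole_ptp(geometry, src, rng.uniform(500, 2000))
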