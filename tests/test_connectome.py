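import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scalehub as sh
from scalehub.connectome import (
    EndpointAssignment, load_matrix_mtx, save_matrix_mtx,
)


def _assignment(pairs, lengths, K):
    a = np.array([min(p) for p in pairs])
    b = np.array([max(p) for p in pairs])
    return EndpointAssignment(parcel_a=a, parcel_b=b,
                              lengths_mm=np.asarray(lengths, float), K=K)


@pytest.fixture(scope="module")
def setup(ico2):
    mesh, sphere = ico2
    parc = sh.spherical_kmeans(sphere, 10, seed=0)
    return mesh, parc


class TestMapEndpoints:

    def test_endpoint_at_vertex_gets_its_parcel(self, setup):
        mesh, parc = setup
        v = 17
        ts = sh.TractSet("s", mesh.vertices[[v]], mesh.vertices[[3]], [50.0])
        asg = sh.map_endpoints(ts, mesh, parc)
        assert {asg.parcel_a[0], asg.parcel_b[0]} == {parc.labels[v],
                                                      parc.labels[3]}

    def test_nearest_vertex_tie_goes_to_lower_index(self, setup):
        mesh, parc = setup
        i, j = mesh.faces[0][:2]  # adjacent vertices: edge midpoint ties
        mid = (mesh.vertices[i] + mesh.vertices[j]) / 2
        ts = sh.TractSet("s", mid[None, :], mesh.vertices[[5]], [50.0])
        va, vb, da, db = sh.snap_endpoints(ts, mesh)
        assert va[0] == min(i, j)

    def test_far_endpoint_unassigned(self, setup):
        mesh, parc = setup
        far = mesh.vertices[0] * 1.5  # tens of mm off-surface
        ts = sh.TractSet("s", far[None, :], mesh.vertices[[5]], [50.0])
        asg = sh.map_endpoints(ts, mesh, parc, snap_tolerance_mm=2.0)
        assert asg.parcel_a[0] == 0

    def test_pairs_order_normalized(self, setup):
        mesh, parc = setup
        ts = sh.TractSet("s", mesh.vertices[:20], mesh.vertices[20:40],
                         np.full(20, 50.0))
        asg = sh.map_endpoints(ts, mesh, parc)
        assert (asg.parcel_a <= asg.parcel_b).all()

    def test_mesh_mismatch_rejected(self, setup, ico3):
        mesh, parc = setup
        mesh3, _ = ico3
        ts = sh.TractSet("s", mesh.vertices[:1], mesh.vertices[1:2], [50.0])
        with pytest.raises(ValueError):
            sh.map_endpoints(ts, mesh3, parc)


class TestBuildConnectivity:
    def test_threshold_keeps_only_supported_edges(self):
        pairs = [(1, 2)] * 3 + [(1, 3)] * 2
        asg = _assignment(pairs, [50.0] * 5, K=3)
        w = sh.build_connectivity(asg, min_fibers=3)
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 3
        np.testing.assert_array_equal(w, expected)

    def test_intra_parcel_tracts_never_form_edges(self):
        asg = _assignment([(2, 2)] * 10, [25.0] * 10, K=4)
        assert sh.build_connectivity(asg).sum() == 0

    def test_unassigned_tracts_excluded(self):
        asg = _assignment([(0, 2)] * 5, [50.0] * 5, K=3)
        assert sh.build_connectivity(asg).sum() == 0

    def test_invalid_min_fibers_rejected(self):
        asg = _assignment([(1, 2)], [50.0], K=2)
        with pytest.raises(ValueError):
            sh.build_connectivity(asg, min_fibers=0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10 ** 6))
    def test_symmetric_zero_diagonal_and_weight_budget(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(3, 9))
        n = int(rng.integers(1, 60))
        pairs = rng.integers(0, K + 1, size=(n, 2))
        asg = _assignment([tuple(p) for p in pairs], rng.uniform(20, 200, n), K)
        w = sh.build_connectivity(asg, min_fibers=1)
        np.testing.assert_array_equal(w, w.T)
        assert np.diag(w).sum() == 0
        assert w.sum() / 2 <= n  # kept edge weights never exceed tract count

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        K = 6
        pairs = [tuple(sorted(p)) for p in rng.integers(1, K + 1, size=(80, 2))]
        asg = _assignment(pairs, [50.0] * 80, K)
        w = sh.build_connectivity(asg, min_fibers=2)
        perm = rng.permutation(K) + 1
        ppairs = [tuple(sorted((perm[a - 1], perm[b - 1]))) for a, b in pairs]
        wp = sh.build_connectivity(_assignment(ppairs, [50.0] * 80, K),
                                   min_fibers=2)
        idx = perm - 1
        np.testing.assert_array_equal(wp[np.ix_(idx, idx)], w)


class TestShortAssociationRatio:
    def test_hand_counted_example(self):
        # parcel 1 holds a U-fiber cluster; (2,3) is a short edge; (4,5) long
        pairs = [(1, 1)] * 3 + [(2, 3)] * 3 + [(4, 5)] * 3
        lengths = [10.0] * 3 + [15.0] * 3 + [80.0] * 3
        asg = _assignment(pairs, lengths, K=5)
        assert sh.short_association_ratio(asg, min_fibers=3) == pytest.approx(0.2)

    def test_no_tracts_gives_zero(self):
        asg = _assignment([], [], K=4)
        assert sh.short_association_ratio(asg) == 0.0

    def test_all_long_connections_give_zero(self):
        asg = _assignment([(1, 2)] * 5 + [(3, 4)] * 4, [90.0] * 9, K=4)
        assert sh.short_association_ratio(asg) == 0.0

    def test_small_k_rejected(self):
        asg = _assignment([(1, 1)], [25.0], K=1)
        with pytest.raises(ValueError):
            sh.short_association_ratio(asg)

    def test_ratio_decreases_with_scale_on_synthetic_cohort(self, small_cohort):
        """Finer parcellations leave fewer possible connections occupied by
        short association fibers (the direction seen in real cohorts)."""
        from scipy.stats import spearmanr
        cohort = small_cohort
        scales = (20, 40, 60, 80)
        ens = sh.parcellation_ensemble(cohort.sphere, scales, n_repeats=1,
                                       master_seed=2)
        means = []
        for s in scales:
            vals = []
            for ts in cohort.tracts:
                asg = sh.map_endpoints(ts, cohort.mesh, ens[(s, 0)])
                vals.append(sh.short_association_ratio(asg))
            means.append(np.mean(vals))
        rho, _ = spearmanr(scales, means)
        assert rho < 0


def test_matrix_mtx_roundtrip(tmp_path):
    w = np.array([[0, 3, 0], [3, 0, 5], [0, 5, 0]])
    save_matrix_mtx(w, tmp_path / "w.mtx")
    np.testing.assert_array_equal(load_matrix_mtx(tmp_path / "w.mtx"), w)
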