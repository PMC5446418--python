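import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scalehub as sh
from oracles import brute_force_betweenness, random_test_graph


def _path_graph():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1
    w[1, 2] = w[2, 1] = 1
    return w


class TestBetweenness:
    def test_path_graph(self):
        np.testing.assert_array_equal(
            sh.betweenness_centrality(_path_graph()), [0.0, 1.0, 0.0])

    def test_star_graph(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 1
        bc = sh.betweenness_centrality(w)
        assert bc[0] == 6.0  # C(4, 2) leaf pairs all route via the center
        np.testing.assert_array_equal(bc[1:], 0.0)

    def test_weighted_triangle_reroutes_through_strong_edges(self):
        # distances 1/3, 1/3, 1: the two strong edges undercut the direct one
        w = np.array([[0, 3, 1], [3, 0, 3], [1, 3, 0]], dtype=float)
        np.testing.assert_array_equal(
            sh.betweenness_centrality(w), [0.0, 1.0, 0.0])

    def test_disconnected_pairs_contribute_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1  # component {0,1}; 2 and 3 isolated
        np.testing.assert_array_equal(sh.betweenness_centrality(w),
                                      np.zeros(4))

    def test_negative_weights_rejected(self):
        w = np.array([[0, -1], [-1, 0]], dtype=float)
        with pytest.raises(ValueError):
            sh.betweenness_centrality(w)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_brute_force_enumeration(self, weighted):
        """Every geodesic and every tie is identified exactly; the summed
        statistic matches the oracle's exact rational value to float
        round-off (any miscount would deviate by >= 1/n^2, not 1e-12)."""
        rng = np.random.default_rng(123 if weighted else 321)
        for _ in range(25):
            w = random_test_graph(rng, n_max=9, weighted=weighted)
            np.testing.assert_allclose(sh.betweenness_centrality(w),
                                       brute_force_betweenness(w),
                                       rtol=1e-12, atol=1e-12)


class TestZNormalize:
    def test_three_point_example(self):
        np.testing.assert_allclose(
            sh.znormalize_map([1.0, 2.0, 3.0]),
            [-1.224744871391589, 0.0, 1.224744871391589], atol=1e-12)

    def test_output_moments(self):
        rng = np.random.default_rng(0)
        z = sh.znormalize_map(rng.normal(3, 7, size=500))
        assert abs(z.mean()) <= 1e-12
        assert abs(z.std() - 1.0) <= 1e-12

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(a=st.floats(0.01, 100), b=st.floats(-50, 50),
           seed=st.integers(0, 1000))
    def test_positive_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        np.testing.assert_allclose(sh.znormalize_map(a * x + b),
                                   sh.znormalize_map(x), atol=1e-9)

    def test_constant_map_rejected_with_diagnosis(self):
        with pytest.raises(ValueError, match="degenerate"):
            sh.znormalize_map(np.full(10, 2.0))


class TestProjection:
    def test_single_parcel_constant_map(self, ico2):
        _, sphere = ico2
        parc = sh.spherical_kmeans(sphere, 1, seed=0)
        out = sh.project_to_vertices(np.array([4.2]), parc)
        assert (out == 4.2).all()

    def test_roundtrip_recovers_nodal_values(self, ico2):
        _, sphere = ico2
        parc = sh.spherical_kmeans(sphere, 9, seed=1)
        vals = np.arange(1.0, 10.0)
        vmap = sh.project_to_vertices(vals, parc)
        recovered = np.array([vmap[parc.labels == k].mean()
                              for k in range(1, 10)])
        np.testing.assert_array_equal(recovered, vals)

    def test_excluded_vertices_get_zero(self):
        parc = sh.Parcellation(labels=np.array([0, 1, 2, 1]), K=2, seed=0)
        out = sh.project_to_vertices(np.array([5.0, 7.0]), parc)
        np.testing.assert_array_equal(out, [0.0, 5.0, 7.0, 5.0])

    def test_size_mismatch_rejected(self, ico2):
        _, sphere = ico2
        parc = sh.spherical_kmeans(sphere, 9, seed=1)
        with pytest.raises(ValueError):
            sh.project_to_vertices(np.arange(5.0), parc)


class TestSubjectHubMap:
    def test_identical_repeats_equal_single_repeat(self, small_matrices):
        cohort, parcs, per_subject = small_matrices
        mats = per_subject[0]
        single = sh.subject_hub_map([mats[0]], [parcs[0]], cohort.mesh, 0.0)
        tripled = sh.subject_hub_map([mats[0]] * 3, [parcs[0]] * 3,
                                     cohort.mesh, 0.0)
        np.testing.assert_allclose(tripled, single, atol=1e-12)

    def test_invariant_to_repeat_order(self, small_matrices):
        cohort, parcs, per_subject = small_matrices
        mats = per_subject[0]
        fwd = sh.subject_hub_map(mats, parcs, cohort.mesh, 10.0)
        rev = sh.subject_hub_map(mats[::-1], parcs[::-1], cohort.mesh, 10.0)
        np.testing.assert_allclose(fwd, rev, atol=1e-12)

    def test_invariant_to_uniform_matrix_scaling(self, small_matrices):
        """Scaling every fiber count by 10 preserves shortest-path trees and
        geodesic counts; z-scoring removes the residual scale."""
        cohort, parcs, per_subject = small_matrices
        mats = per_subject[0]
        base = sh.subject_hub_map(mats, parcs, cohort.mesh, 10.0)
        scaled = sh.subject_hub_map([10 * m for m in mats], parcs,
                                    cohort.mesh, 10.0)
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_all_constant_repeats_rejected(self, small_matrices):
        cohort, parcs, _ = small_matrices
        K = parcs[0].K
        empty = np.zeros((K, K))
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                sh.subject_hub_map([empty], [parcs[0]], cohort.mesh, 0.0)


class TestGroupAverage:
    def test_identical_subjects_give_their_znormalized_map(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=100)
        out = sh.group_average_map([m, m.copy(), m.copy()])
        np.testing.assert_allclose(out, sh.znormalize_map(m), atol=1e-12)

    def test_two_maps_pointwise_mean(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 50))
        out = sh.group_average_map([a, b])
        np.testing.assert_allclose(
            out, (sh.znormalize_map(a) + sh.znormalize_map(b)) / 2, atol=1e-12)

    def test_subject_order_irrelevant(self):
        rng = np.random.default_rng(3)
        maps = list(rng.normal(size=(4, 60)))
        np.testing.assert_allclose(sh.group_average_map(maps),
                                   sh.group_average_map(maps[::-1]),
                                   atol=1e-12)

    def test_mesh_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sh.group_average_map([np.zeros(5) + np.arange(5),
                                  np.arange(6.0)])


class TestConventionRobustness:
    """BC summation and SD conventions must wash out of the final maps."""

    def _his_sc(self, small_matrices, **kw):
        cohort, parcs, per_subject = small_matrices
        ddof = kw.pop("ddof", 0)
        subj = [sh.subject_hub_map(mats, parcs, cohort.mesh, 10.0,
                                   ddof=ddof, **kw)
                for mats in per_subject]
        X = sh.group_average_map(subj, ddof=ddof)
        return sh.his_score(sh.his_strength({40: X}))

    def test_ordered_vs_unordered_pair_convention(self, small_matrices):
        base = self._his_sc(small_matrices)
        doubled = self._his_sc(small_matrices, ordered_pairs=True)
        np.testing.assert_allclose(doubled, base, atol=1e-9)

    def test_sample_vs_population_sd(self, small_matrices):
        base = self._his_sc(small_matrices)
        sample = self._his_sc(small_matrices, ddof=1)
        np.testing.assert_allclose(sample, base, atol=1e-9)
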