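"""Neutrosophic c-means core: distances, updates, objective, convergence."""

import numpy as np
import pytest

from ncmhap import (
    NCMParams,
    SNPMatrix,
    indeterminacy_center,
    masked_distance2,
    ncm_cluster,
    ncm_objective,
    simulate_instance,
    SimulationConfig,
    update_centers,
    update_memberships,
)
from ncmhap.ncm import _point_center_dist2, _point_row_dist2

from conftest import random_matrix


def scalar_memberships(x: SNPMatrix, centers, p: NCMParams):
    """Independent scalar evaluation of the membership closed forms.

    Plain per-point loops with a brute-force normalizer; shares nothing with
    the vectorized implementation path.
    """
    centers = np.asarray(centers, float)
    n_pts = x.n_fragments
    t = np.zeros((n_pts, 2))
    i_mem = np.zeros(n_pts)
    f_mem = np.zeros(n_pts)
    ex = 1.0 / (p.m_fuzz - 1.0)
    midpoint = (centers[0] + centers[1]) / 2.0
    for i in range(n_pts):
        row = x.row_string(i)
        d = [masked_distance2(row, centers[j]) for j in range(2)]
        dbar = masked_distance2(row, midpoint)
        if min(d) == 0.0:
            t[i, int(np.argmin(d))] = 1.0
            continue
        if dbar == 0.0:
            i_mem[i] = 1.0
            continue
        raw_t = [(1.0 / p.w1) * dj ** (-ex) for dj in d]
        raw_i = (1.0 / p.w2) * dbar ** (-ex)
        raw_f = (1.0 / p.w3) * (p.delta**2) ** (-ex)
        k = 1.0 / (sum(raw_t) + raw_i + raw_f)
        t[i] = [k * v for v in raw_t]
        i_mem[i] = k * raw_i
        f_mem[i] = k * raw_f
    return t, i_mem, f_mem


class TestMaskedDistance:
    def test_coincident(self):
        assert masked_distance2("11", (1.0, 1.0)) == 0.0

    def test_masked_mean_by_hand(self):
        assert masked_distance2("1-0", (0.0, 0.5, 0.0)) == pytest.approx(0.5)

    def test_maximal_single_site(self):
        assert masked_distance2("0", (1.0,)) == 1.0

    def test_all_gap_rejected(self):
        with pytest.raises(ValueError):
            masked_distance2("--", (0.5, 0.5))


class TestIndeterminacyCenter:
    def test_two_clusters_always_midpoint(self):
        centers = np.array([[0.0, 0.0], [1.0, 1.0]])
        for t_row in ([0.9, 0.1], [0.1, 0.9], [0.5, 0.5]):
            assert np.allclose(
                indeterminacy_center(t_row, centers), [0.5, 0.5]
            )

    def test_three_clusters_argmax_pair(self):
        centers = np.array([[0.0], [1.0], [0.6]])
        out = indeterminacy_center([0.5, 0.3, 0.2], centers)
        assert np.allclose(out, (centers[0] + centers[1]) / 2)


class TestMemberships:
    def test_matches_independent_scalar_oracle(self, rng):
        p = NCMParams()
        for _ in range(20):
            x = random_matrix(rng, m=5, n=int(rng.integers(3, 8)))
            centers = rng.uniform(size=(2, x.n_sites))
            t, i_mem, f_mem = update_memberships(x, centers, p)
            te, ie, fe = scalar_memberships(x, centers, p)
            assert np.allclose(t, te, atol=1e-10, rtol=0)
            assert np.allclose(i_mem, ie, atol=1e-10, rtol=0)
            assert np.allclose(f_mem, fe, atol=1e-10, rtol=0)

    def test_normalization_exact(self, rng):
        p = NCMParams()
        for _ in range(20):
            x = random_matrix(rng, m=int(rng.integers(2, 10)), n=6)
            centers = rng.uniform(size=(2, 6))
            t, i_mem, f_mem = update_memberships(x, centers, p)
            total = t.sum(axis=1) + i_mem + f_mem
            assert np.allclose(total, 1.0, atol=1e-12, rtol=0)

    def test_zero_distance_limit_convention(self):
        x = SNPMatrix.from_strings(["11"])
        centers = np.array([[1.0, 1.0], [0.0, 0.0]])
        t, i_mem, f_mem = update_memberships(x, centers, NCMParams())
        assert t.tolist() == [[1.0, 0.0]]
        assert i_mem[0] == 0.0 and f_mem[0] == 0.0

    def test_equidistant_point_symmetric(self):
        x = SNPMatrix.from_strings(["10"])
        centers = np.array([[0.0, 0.0], [1.0, 1.0]])
        t, _, _ = update_memberships(x, centers, NCMParams())
        assert t[0, 0] == pytest.approx(t[0, 1])

    def test_fcm_limit_with_expensive_indeterminacy(self):
        """Pricing out the I/F terms (large w2, w3) recovers FCM memberships."""
        x = SNPMatrix.from_strings(["0101"] * 3 + ["1010"] * 3)
        centers = np.array([[0.1, 0.9, 0.1, 0.9], [0.9, 0.1, 0.9, 0.1]])
        p = NCMParams(w1=1.0, w2=1e6, w3=1e6)
        t, i_mem, f_mem = update_memberships(x, centers, p)
        d = _point_center_dist2(x.alleles, x.observed, centers)
        fcm = (1.0 / d) / (1.0 / d).sum(axis=1, keepdims=True)
        assert np.allclose(t / t.sum(axis=1, keepdims=True), fcm, atol=1e-9)
        assert i_mem.max() + f_mem.max() < 1e-5
        assert np.array_equal(np.argmax(t, axis=1), np.array([0, 0, 0, 1, 1, 1]))


class TestCenters:
    def test_unweighted_mean_of_identical_rows(self):
        x = SNPMatrix.from_strings(["00", "00"])
        t = np.array([[1.0, 0.0], [1.0, 0.0]])
        centers = update_centers(x, t, NCMParams(), prev_centers=np.full((2, 2), 0.5))
        assert np.allclose(centers[0], [0.0, 0.0])

    def test_masked_mean_each_column_from_its_observer(self):
        x = SNPMatrix.from_strings(["0-", "-1"])
        t = np.ones((2, 2))
        centers = update_centers(x, t, NCMParams(), prev_centers=np.full((2, 2), 0.5))
        assert np.allclose(centers, [[0.0, 1.0], [0.0, 1.0]])

    def test_cluster_scale_invariance(self, rng):
        """Scaling one cluster's memberships by a constant leaves its center alone."""
        x = random_matrix(rng, m=6, n=5, gap=0.2)
        t = rng.uniform(0.1, 0.9, size=(6, 2))
        prev = np.full((2, 5), 0.5)
        c0 = update_centers(x, t, NCMParams(), prev)
        t_scaled = t.copy()
        t_scaled[:, 0] *= 0.37
        c1 = update_centers(x, t_scaled, NCMParams(), prev)
        assert np.allclose(c0[0], c1[0])

    def test_uncovered_column_keeps_previous_value(self):
        x = SNPMatrix.from_strings(["0-", "1-"])
        t = np.ones((2, 2)) * 0.5
        prev = np.array([[0.5, 0.123], [0.5, 0.877]])
        centers = update_centers(x, t, NCMParams(), prev)
        assert centers[0, 1] == 0.123 and centers[1, 1] == 0.877


class TestObjective:
    def test_perfect_fit_is_zero(self):
        x = SNPMatrix.from_strings(["00", "11"])
        centers = np.array([[0.0, 0.0], [1.0, 1.0]])
        t = np.eye(2)
        z = np.zeros(2)
        assert ncm_objective(x, t, z, z, centers, NCMParams()) == 0.0

    def test_pure_outlier_term(self):
        x = SNPMatrix.from_strings(["00"])
        centers = np.array([[0.0, 0.0], [1.0, 1.0]])
        p = NCMParams()
        j = ncm_objective(
            x, np.zeros((1, 2)), np.zeros(1), np.ones(1), centers, p
        )
        assert j == pytest.approx(p.delta**2 * p.w3)

    def test_matches_term_by_term_summation(self, rng):
        p = NCMParams()
        for _ in range(10):
            x = random_matrix(rng, m=4, n=5)
            centers = rng.uniform(size=(2, 5))
            t = rng.uniform(size=(4, 2))
            i_mem = rng.uniform(size=4)
            f_mem = rng.uniform(size=4)
            expected = 0.0
            midpoint = (centers[0] + centers[1]) / 2
            for i in range(4):
                row = x.row_string(i)
                for j in range(2):
                    expected += p.w1 * t[i, j] ** p.m_fuzz * masked_distance2(
                        row, centers[j]
                    )
                expected += p.w2 * i_mem[i] ** p.m_fuzz * masked_distance2(
                    row, midpoint
                )
                expected += p.delta**2 * p.w3 * f_mem[i] ** p.m_fuzz
            got = ncm_objective(x, t, i_mem, f_mem, centers, p)
            assert got == pytest.approx(expected, rel=1e-9)


class TestClusterLoop:
    def test_fixed_point_from_true_centers(self, separable_matrix):
        truth = np.array([[0, 1, 0, 1], [1, 0, 1, 0]], dtype=float)
        state = ncm_cluster(separable_matrix, truth, NCMParams(), seed=0)
        assert state.converged and state.n_iter <= 2
        assert np.allclose(state.centers, truth, atol=1e-3)

    def test_infinite_epsilon_runs_exactly_one_iteration(self, separable_matrix):
        state = ncm_cluster(
            separable_matrix, "random", NCMParams(epsilon=np.inf), seed=3
        )
        assert state.n_iter == 1 and state.converged

    def test_bit_identical_across_runs(self, rng):
        x = random_matrix(rng, m=8, n=10)
        a = ncm_cluster(x, "random", NCMParams(), seed=42)
        b = ncm_cluster(x, "random", NCMParams(), seed=42)
        assert np.array_equal(a.T, b.T)
        assert np.array_equal(a.centers, b.centers)
        assert a.objective_trace == b.objective_trace

    def test_objective_trace_non_increasing(self, rng):
        for _ in range(30):
            x = random_matrix(rng, m=int(rng.integers(3, 10)), n=int(rng.integers(3, 10)))
            state = ncm_cluster(x, "random", NCMParams(), seed=int(rng.integers(1000)))
            trace = np.array(state.objective_trace)
            assert np.all(np.isfinite(trace))
            assert np.all(np.diff(trace) <= 1e-8)

    def test_normalization_holds_at_convergence(self, rng):
        x = random_matrix(rng, m=10, n=12)
        state = ncm_cluster(x, "random", NCMParams(), seed=5)
        total = state.T.sum(axis=1) + state.I + state.F
        assert np.allclose(total, 1.0, atol=1e-12, rtol=0)

    def test_noisy_fragment_sheds_mass_into_indeterminacy(self):
        """A fragment disagreeing ~50% with both haplotypes carries more
        I+F than the clean fragments it is mixed with."""
        inst = simulate_instance(SimulationConfig(l=60, c=8, e=0.05, seed=9))
        x = inst.matrix
        rng = np.random.default_rng(1)
        noisy = rng.integers(0, 2, size=x.n_sites).astype(np.uint8)
        alleles = np.vstack([x.alleles, noisy])
        observed = np.vstack([x.observed, np.ones(x.n_sites, bool)])
        x2 = SNPMatrix(alleles, observed)
        truth, _ = inst.truth.to_arrays()
        state = ncm_cluster(x2, truth.astype(float), NCMParams(), seed=0)
        slack = state.I + state.F
        assert slack[-1] > np.median(slack[:-1])
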