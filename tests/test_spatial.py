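import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metapart.spatial import (
    connectivity_weights,
    distance_matrix,
    morans_expectation,
    morans_i,
    pcnm,
    screen_eigenbasis,
    truncation_threshold,
    validate_projected,
)


class TestDistanceMatrix:
    def test_three_four_five_triangle(self):
        d = distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == pytest.approx(5.0)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(1)
        d = distance_matrix(rng.uniform(0, 100, (8, 2)))
        assert np.allclose(d, d.T)
        assert np.diag(d).tolist() == [0.0] * 8

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        d = distance_matrix(rng.uniform(0, 50, (3, 2)))
        for i, j, k in itertools.permutations(range(3)):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9


def brute_force_mst_longest_edge(d):
    """Exhaustive minimum spanning tree over all edge subsets (n ≤ 6)."""
    n = d.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best_weight, best_longest = np.inf, None
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if not ok:
            continue
        w = sum(d[i, j] for i, j in subset)
        if w < best_weight - 1e-12:
            best_weight = w
            best_longest = max(d[i, j] for i, j in subset)
    return best_longest


class TestTruncationThreshold:
    def test_regular_transect_gives_spacing(self):
        coords = np.column_stack([np.arange(10.0) * 3.0, np.zeros(10)])
        assert truncation_threshold(distance_matrix(coords)) == pytest.approx(3.0)

    def test_two_clusters_gives_bridge_gap(self):
        a = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        b = a + [100.0, 0.0]
        d = distance_matrix(np.vstack([a, b]))
        assert truncation_threshold(d) == pytest.approx(99.0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.integers(4, 6))
    def test_matches_exhaustive_spanning_tree_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        d = distance_matrix(rng.uniform(0, 10, (n, 2)))
        assert truncation_threshold(d) == pytest.approx(brute_force_mst_longest_edge(d))


def brute_force_pcoa_eigenvalues(dstar):
    """Independent double-centering with the explicit centering matrix H."""
    n = dstar.shape[0]
    h = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * h @ (dstar**2) @ h
    return np.sort(np.linalg.eigvalsh(b))[::-1]


class TestPcnm:
    def test_two_point_eigenpair(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        basis = pcnm(d, t=2.0)
        assert basis.eigenvalues == pytest.approx([2.0])
        assert np.abs(basis.eigenvectors[:, 0]) == pytest.approx(
            [1 / np.sqrt(2)] * 2
        )

    def test_columns_orthonormal(self):
        rng = np.random.default_rng(2)
        d = distance_matrix(rng.uniform(0, 100, (12, 2)))
        basis = pcnm(d)
        gram = basis.eigenvectors.T @ basis.eigenvectors
        assert np.allclose(gram, np.eye(basis.n_axes), atol=1e-8)

    def test_eigenpairs_satisfy_the_eigen_identity(self):
        rng = np.random.default_rng(3)
        d = distance_matrix(rng.uniform(0, 100, (10, 2)))
        basis = pcnm(d)
        t = basis.truncation
        dstar = np.where(d <= t, d, 4 * t)
        np.fill_diagonal(dstar, 0.0)
        n = d.shape[0]
        h = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * h @ (dstar**2) @ h
        for k in range(basis.n_axes):
            resid = b @ basis.eigenvectors[:, k] - basis.eigenvalues[k] * basis.eigenvectors[:, k]
            assert np.linalg.norm(resid) < 1e-8

    def test_eigenvalue_sum_equals_trace(self):
        rng = np.random.default_rng(4)
        d = distance_matrix(rng.uniform(0, 100, (9, 2)))
        basis = pcnm(d)
        t = basis.truncation
        dstar = np.where(d <= t, d, 4 * t)
        np.fill_diagonal(dstar, 0.0)
        n = d.shape[0]
        h = np.eye(n) - np.ones((n, n)) / n
        trace = np.trace(-0.5 * h @ (dstar**2) @ h)
        assert basis.eigenvalues.sum() == pytest.approx(trace, abs=1e-8)

    def test_rigid_motion_leaves_eigenvalues_unchanged(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 100, (11, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + [250.0, -90.0]
        e1 = pcnm(distance_matrix(pts)).eigenvalues
        e2 = pcnm(distance_matrix(moved)).eigenvalues
        assert e1 == pytest.approx(e2, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_pcoa_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 11)
        d = distance_matrix(rng.uniform(0, 60, (n, 2)))
        basis = pcnm(d)
        t = basis.truncation
        dstar = np.where(d <= t, d, 4 * t)
        np.fill_diagonal(dstar, 0.0)
        oracle = brute_force_pcoa_eigenvalues(dstar)
        keep = np.abs(oracle) > 1e-9 * np.abs(oracle).max()
        assert basis.eigenvalues == pytest.approx(oracle[keep], abs=1e-8)

    def test_broad_axes_are_sinusoidal_coarse_to_fine_on_a_transect(self):
        """Leading positive axes are sinusoids of increasing frequency."""
        coords = np.column_stack([np.arange(20.0), np.zeros(20)])
        basis = pcnm(distance_matrix(coords))
        x = coords[:, 0]
        vecs = basis.eigenvectors[:, basis.eigenvalues > 0]

        def best_sinusoid_fit(v):
            best_f, best_r2 = None, -np.inf
            for f in np.linspace(0.5, 8.0, 400):
                phase = np.pi * f * x / x.max()
                design = np.column_stack([np.sin(phase), np.cos(phase), np.ones_like(x)])
                fitted = design @ np.linalg.lstsq(design, v, rcond=None)[0]
                r2 = 1 - ((v - fitted) ** 2).sum() / ((v - v.mean()) ** 2).sum()
                if r2 > best_r2:
                    best_f, best_r2 = f, r2
            return best_f, best_r2

        freqs = []
        for k in range(3):
            f, r2 = best_sinusoid_fit(vecs[:, k])
            assert r2 > 0.9
            freqs.append(f)
        assert freqs[0] < freqs[1] < freqs[2]

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pcnm(np.array([[0.0, 1.0], [2.0, 0.0]]), t=1.0)


class TestMoransI:
    def path_weights(self, n):
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 1.0
        return w

    def test_alternating_path_gives_minus_one(self):
        v = np.array([1.0, -1.0, 1.0, -1.0])
        i, _ = morans_i(v, self.path_weights(4), n_perm=0)
        assert i == pytest.approx(-1.0)

    def test_null_expectation_matches_permutation_mean(self):
        rng = np.random.default_rng(8)
        n = 12
        v = rng.standard_normal(n)
        w = self.path_weights(n)
        z = v - v.mean()
        stats = []
        for _ in range(4000):
            zp = z[rng.permutation(n)]
            stats.append(n / w.sum() * (zp @ w @ zp) / (z @ z))
        assert np.mean(stats) == pytest.approx(morans_expectation(n), abs=0.01)

    def test_smooth_gradient_is_significantly_positive(self):
        n = 25
        v = np.linspace(0, 1, n)
        i, p = morans_i(v, self.path_weights(n), n_perm=999, rng=np.random.default_rng(0))
        assert i > 0.5
        assert p <= 0.005

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            morans_i(np.ones(5), self.path_weights(5))


@pytest.fixture(scope="module")
def screened():
    coords = np.column_stack([np.arange(20.0) * 5, np.zeros(20)])
    d = distance_matrix(coords)
    basis = pcnm(d)
    return screen_eigenbasis(basis, d, alpha=0.05, n_perm=199,
                             rng=np.random.default_rng(42))


class TestScreening:
    def test_negative_eigenvalue_axes_never_retained(self, screened):
        assert not (screened.retained & (screened.eigenvalues <= 0)).any()

    def test_retained_subset_of_positive(self, screened):
        assert (screened.eigenvalues[screened.retained] > 0).all()

    def test_broad_scale_axis_retained(self, screened):
        assert screened.retained[0]

    def test_weights_are_binary_at_threshold(self):
        d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 1.0], [3.0, 1.0, 0.0]])
        w = connectivity_weights(d, 1.5)
        assert w.tolist() == [[0, 1, 0], [1, 0, 1], [0, 1, 0]]


class TestProjectionGuard:
    def test_latlon_like_coordinates_rejected(self):
        rng = np.random.default_rng(0)
        latlon = np.column_stack(
            [rng.uniform(-55.1, -54.9, 46), rng.uniform(-3.1, -2.9, 46)]
        )
        with pytest.raises(ValueError, match="project"):
            validate_projected(latlon)

    def test_metric_coordinates_accepted(self):
        rng = np.random.default_rng(0)
        validate_projected(rng.uniform(0, 2000, (46, 2)))
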