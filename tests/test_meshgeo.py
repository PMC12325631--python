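"""Node triangulation, extrema detection, geodesics, pair statistics."""

import numpy as np
import pytest

from dropstress import (
    find_extrema,
    geodesic_distances,
    make_shape,
    make_stress_fixture,
    pair_statistics,
    triangulate_nodes,
)
from dropstress.sh import basis_index, real_sh_basis


def brute_force_extrema(f, mesh):
    """Independent double-loop classification over mesh edges."""
    n = mesh.n_vertices
    ge = np.ones(n, bool)
    le = np.ones(n, bool)
    for i, j in mesh.edges:
        if f[i] < f[j]:
            ge[i] = False
            le[j] = False
        if f[i] > f[j]:
            le[i] = False
            ge[j] = False
    return np.nonzero(ge)[0], np.nonzero(le)[0]


@pytest.fixture(scope="module")
def mesh41(quad41):
    return triangulate_nodes(quad41)


class TestTriangulation:
    def test_euler_characteristic(self, mesh41, quad95):
        assert mesh41.euler_characteristic == 2
        assert triangulate_nodes(quad95).euler_characteristic == 2

    def test_area_approaches_sphere_area(self, quad95):
        mesh = triangulate_nodes(quad95)
        assert mesh.surface_area() == pytest.approx(4 * np.pi, rel=5e-3)

    def test_all_vertex_degrees_at_least_three(self, mesh41):
        assert min(len(nb) for nb in mesh41.adjacency()) >= 3

    def test_vertices_on_droplet_surface(self, quad41):
        shape = make_shape("sphere", radius=7.0)
        pos = 7.0 * quad41.directions
        mesh = triangulate_nodes(quad41, positions=pos)
        assert np.allclose(np.linalg.norm(mesh.vertices, axis=1), 7.0)


class TestExtrema:
    @pytest.mark.parametrize("pattern,params", [
        ("dipole", None),
        ("single-harmonic", {"l": 4, "m": 4}),   # sectoral
        ("single-harmonic", {"l": 5, "m": 2}),
        ("band-limited-random", {"l_min": 3, "l_max": 6}),
    ])
    def test_matches_brute_force(self, quad41, mesh41, pattern, params):
        f, _ = make_stress_fixture(quad41, pattern, params, seed=8)
        ex = find_extrema(f, mesh41)
        bf_max, bf_min = brute_force_extrema(f, mesh41)
        np.testing.assert_array_equal(ex.maxima, bf_max)
        np.testing.assert_array_equal(ex.minima, bf_min)

    def test_dipole_has_single_pair(self, quad41, mesh41):
        f, _ = make_stress_fixture(quad41, "dipole")
        ex = find_extrema(f, mesh41)
        assert len(ex.maxima) == 1 and len(ex.minima) == 1
        assert not ex.degenerate

    def test_sectoral_harmonic_equal_counts(self, quad41, mesh41):
        (B,) = real_sh_basis(4, quad41.polar, quad41.azimuth)
        f = B[:, basis_index(4, 4)]
        ex = find_extrema(f, mesh41)
        assert len(ex.maxima) == len(ex.minima)

    def test_constant_field_degenerate(self, quad41, mesh41):
        with pytest.warns(UserWarning, match="plateau"):
            ex = find_extrema(np.zeros(len(quad41)), mesh41)
        assert ex.degenerate
        assert len(ex.maxima) == len(quad41)
        assert len(ex.minima) == len(quad41)


class TestGeodesics:
    def test_symmetry_zero_diagonal_triangle_inequality(self, mesh41):
        idx = np.array([0, 17, 100, 333, 600])
        D = geodesic_distances(mesh41, sources=idx, targets=idx)
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(D), 0.0)
        for i in range(len(idx)):
            for j in range(len(idx)):
                for k in range(len(idx)):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_near_antipodal_nodes_at_pi(self, quad41, mesh41):
        d = quad41.directions
        i = 0
        j = int(np.argmin(d @ d[i]))
        psi = np.arccos(np.clip(d[i] @ d[j], -1, 1))
        D = geodesic_distances(mesh41, sources=[i], targets=[j])
        assert D[0, 0] == pytest.approx(psi, rel=0.02)

    def test_random_pairs_match_great_circles(self, quad41, mesh41):
        """R·ψ within 2% over 100 random well-separated pairs."""
        rng = np.random.default_rng(12)
        ii = rng.integers(0, mesh41.n_vertices, 100)
        jj = rng.integers(0, mesh41.n_vertices, 100)
        D = geodesic_distances(mesh41, sources=np.unique(ii))
        row = {v: k for k, v in enumerate(np.unique(ii))}
        checked = 0
        for i, j in zip(ii, jj):
            psi = np.arccos(np.clip(quad41.directions[i] @ quad41.directions[j],
                                    -1, 1))
            if psi < 0.3:
                continue
            assert D[row[i], j] == pytest.approx(psi, rel=0.02)
            checked += 1
        assert checked > 50

    def test_error_small_at_both_resolutions(self, quad41, quad95):
        """Median great-circle error stays at the 1e-4..1e-3 level at both
        node counts (the k-ring metric error is nearly scale-invariant, so
        refining nodes does not systematically shrink it further)."""
        rng = np.random.default_rng(13)

        def median_err(q):
            mesh = triangulate_nodes(q)
            n = mesh.n_vertices
            src = rng.integers(0, n, 20)
            D = geodesic_distances(mesh, sources=src)
            errs = []
            for a, i in enumerate(src):
                for j in rng.integers(0, n, 30):
                    psi = np.arccos(np.clip(q.directions[i] @ q.directions[j],
                                            -1, 1))
                    if psi > 0.3:
                        errs.append(abs(D[a, j] / psi - 1))
            return np.median(errs)

        m41, m95 = median_err(quad41), median_err(quad95)
        assert m41 < 2e-3 and m95 < 2e-3

    def test_scaled_sphere_distances_scale(self, quad41):
        mesh_r = triangulate_nodes(quad41, positions=5.0 * quad41.directions)
        mesh_1 = triangulate_nodes(quad41)
        D_r = geodesic_distances(mesh_r, sources=[3], targets=[500])
        D_1 = geodesic_distances(mesh_1, sources=[3], targets=[500])
        assert D_r[0, 0] == pytest.approx(5.0 * D_1[0, 0], rel=1e-10)


class TestPairStatistics:
    def test_dipole_single_pair_at_pi(self, quad41, mesh41):
        f, _ = make_stress_fixture(quad41, "dipole")
        ex = find_extrema(f, mesh41)
        ps = pair_statistics(ex, mesh41, f)
        assert ps.all_distances.shape == (1,)
        assert ps.all_distances[0] == pytest.approx(np.pi, rel=0.02)
        assert ps.all_stress_diff[0] == pytest.approx(f.max() - f.min())

    def test_adjacent_no_longer_than_all_pairs_minima(self, quad41, mesh41):
        f, _ = make_stress_fixture(quad41, "band-limited-random",
                                   {"l_min": 4, "l_max": 8}, seed=21)
        ex = find_extrema(f, mesh41)
        ps = pair_statistics(ex, mesh41, f)
        assert ps.adjacent_distances.min() >= 0
        assert ps.adjacent_distances.max() <= ps.all_distances.max() + 1e-12
        assert ps.adjacent_distances.min() <= np.median(ps.all_distances)

    def test_planted_extrema_geometry_recovered(self, quad41, mesh41):
        """Single-harmonic field: adjacent max/min spacing ~ half wavelength."""
        (B,) = real_sh_basis(4, quad41.polar, quad41.azimuth)
        f = B[:, basis_index(4, 4)]
        ex = find_extrema(f, mesh41)
        ps = pair_statistics(ex, mesh41, f)
        # sectoral degree-4: extrema alternate every π/4 in azimuth on the
        # equator; adjacent geodesic spacing ≈ π/4
        assert np.median(ps.adjacent_distances) == pytest.approx(np.pi / 4,
                                                                 rel=0.15)

    def test_missing_extrema_warns_with_empty_result(self, quad41, mesh41):
        from dropstress.meshgeo import ExtremaSet
        ex = ExtremaSet(maxima=np.array([1]), minima=np.array([], int),
                        degenerate=False)
        with pytest.warns(UserWarning):
            ps = pair_statistics(ex, mesh41, np.zeros(len(quad41)))
        assert ps.all_distances.size == 0

    def test_cell_vs_total_statistics_similar(self, quad41, mesh41):
        """Small-scale extrema stats barely change when the (smooth,
        droplet-scale) tissue component is added to the field."""
        f_cell, _ = make_stress_fixture(quad41, "band-limited-random",
                                        {"l_min": 6, "l_max": 10}, seed=30)
        (B,) = real_sh_basis(2, quad41.polar, quad41.azimuth)
        tissue = 0.1 * f_cell.std() * B[:, basis_index(2, 0)]
        f_total = f_cell + tissue
        ps_c = pair_statistics(find_extrema(f_cell, mesh41), mesh41, f_cell)
        ps_t = pair_statistics(find_extrema(f_total, mesh41), mesh41, f_total)
        med_c = np.median(ps_c.adjacent_distances)
        med_t = np.median(ps_t.adjacent_distances)
        assert abs(med_t - med_c) / med_c <= 0.10
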