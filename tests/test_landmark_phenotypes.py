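import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.sparse.csgraph import dijkstra
from scipy.sparse import coo_matrix
from scipy.spatial.distance import squareform
from scipy.stats import special_ortho_group

from facedissect.core_io import LandmarkSet, SurfaceMesh
from facedissect.landmark_phenotypes import (
    angles,
    default_proportion_battery,
    default_regions,
    euclidean_distances,
    extract_phenotypes,
    geodesic_distances,
    landmark_curvatures,
    manhattan_distances,
    proportion_indices,
    region_volume_surface,
    triangle_areas,
    vertex_curvatures,
)
from facedissect._fast_marching import MeshGeodesics


@pytest.fixture(scope="module")
def aligned_set(tiny_sample):
    from facedissect.align import align_landmark_sets

    aligned, _ = align_landmark_sets(tiny_sample.averaged_landmarks())
    return aligned[0]


def _lms(dictionary, coords26):
    return LandmarkSet(coords26, dictionary, "t", "1")


class TestDistances:
    def test_345_triangle(self, dictionary):
        coords = np.zeros((26, 3))
        coords[1] = [3.0, 4.0, 0.0]
        coords[2:] = np.arange(24)[:, None] * [1.0, 2.0, 3.0] + 10.0
        d = euclidean_distances(_lms(dictionary, coords))
        assert d[0] == pytest.approx(5.0)

    def test_counts_are_325(self, aligned_set):
        assert euclidean_distances(aligned_set).shape == (325,)
        assert manhattan_distances(aligned_set).shape == (325,)

    def test_triangle_inequality_all_triples(self, aligned_set):
        d = squareform(euclidean_distances(aligned_set))
        for i, j, k in itertools.combinations(range(26), 3):
            assert d[i, j] + d[j, k] >= d[i, k] - 1e-9

    def test_manhattan_basics(self, dictionary):
        coords = np.random.default_rng(0).normal(size=(26, 3))
        coords[0] = [0.0, 0.0, 0.0]
        coords[1] = [1.0, 2.0, 3.0]
        coords[2] = [5.0, 0.0, 0.0]
        m = manhattan_distances(_lms(dictionary, coords))
        e = euclidean_distances(_lms(dictionary, coords))
        assert m[0] == pytest.approx(6.0)
        assert m[1] == pytest.approx(5.0) == pytest.approx(e[1])  # axis-aligned pair
        ratio = m / e
        assert (ratio <= np.sqrt(3) + 1e-12).all()
        assert (m >= e - 1e-12).all()

    def test_euclidean_rigid_invariant_manhattan_not(self, dictionary):
        rng = np.random.default_rng(1)
        coords = rng.normal(scale=30.0, size=(26, 3))
        r = special_ortho_group.rvs(3, random_state=rng)
        moved = coords @ r.T + rng.normal(scale=10.0, size=3)
        np.testing.assert_allclose(
            euclidean_distances(_lms(dictionary, moved)),
            euclidean_distances(_lms(dictionary, coords)),
            rtol=1e-9,
        )
        m1 = manhattan_distances(_lms(dictionary, coords))
        m2 = manhattan_distances(_lms(dictionary, moved))
        assert not np.allclose(m1, m2, rtol=1e-3)


class TestGeodesics:
    def test_flat_surface_matches_euclidean(self, planar_grid, dictionary):
        mesh, idx = planar_grid
        solver = MeshGeodesics(mesh.vertices, mesh.faces)
        src, tgt = idx[5, 5], idx[30, 35]
        field = solver.distance_field(int(src))
        chord = np.linalg.norm(mesh.vertices[tgt] - mesh.vertices[src])
        assert field[tgt] == pytest.approx(chord, rel=0.01)

    def test_icosphere_quarter_arc(self, icosphere50):
        solver = MeshGeodesics(icosphere50.vertices, icosphere50.faces)
        v = icosphere50.vertices
        src = 0
        cosang = (v @ v[src]) / (np.linalg.norm(v, axis=1) * np.linalg.norm(v[src]))
        tgt = int(np.argmin(np.abs(np.arccos(np.clip(cosang, -1, 1)) - np.pi / 2)))
        field = solver.distance_field(src)
        expected = 50.0 * np.pi / 2  # great-circle arc, 78.54 mm
        assert field[tgt] == pytest.approx(expected, rel=0.02)

    def test_geodesic_bounds_chord_and_dijkstra(self, tiny_sample):
        # Euclidean chord <= fast-marching geodesic <= edge-graph Dijkstra
        ind = tiny_sample.individuals[0]
        mesh = ind.mesh
        lms = ind.true_landmarks
        geo = geodesic_distances(mesh, lms)
        eu = euclidean_distances(lms)
        assert (geo >= eu - 1e-6).all()

        from scipy.spatial import cKDTree

        vid = cKDTree(mesh.vertices).query(lms.coords)[1]
        edges = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [0, 2]]])
        w = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
        n = mesh.n_vertices
        g = coo_matrix((np.r_[w, w], (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])), shape=(n, n))
        dij = dijkstra(g.tocsr(), indices=vid)
        upper = dij[:, vid][np.triu_indices(26, 1)]
        # snapped chord differs from landmark chord; compare on snapped points
        assert (geo <= upper + 1e-6).all()

    def test_far_landmark_errors(self, icosphere50, dictionary):
        coords = np.zeros((26, 3))
        coords[:, 0] = np.linspace(200, 300, 26)  # all off-surface
        with pytest.raises(ValueError, match="farther than"):
            geodesic_distances(icosphere50, _lms(dictionary, coords))


class TestCurvature:
    def test_sphere_curvature(self, icosphere50, dictionary):
        # MC = 1/r, GC = 1/r^2 with outward normals on a convex sphere
        rng = np.random.default_rng(2)
        vid = rng.choice(len(icosphere50.vertices), size=26, replace=False)
        lms = _lms(dictionary, icosphere50.vertices[vid])
        profs = landmark_curvatures(icosphere50, lms, radius_mm=10.0)
        mc = np.array([p.mean_curvature for p in profs])
        gc = np.array([p.gaussian_curvature for p in profs])
        assert np.allclose(mc, 1 / 50.0, rtol=0.05)
        assert np.allclose(gc, 1 / 50.0**2, rtol=0.05)

    def test_plane_curvature_zero(self, planar_grid, dictionary):
        mesh, idx = planar_grid
        vid = idx[10:23:2, 10:23:4].reshape(-1)[:26]
        lms = _lms(dictionary, mesh.vertices[vid])
        profs = landmark_curvatures(mesh, lms, radius_mm=15.0)
        for p in profs:
            assert abs(p.mean_curvature) < 1e-6
            assert abs(p.gaussian_curvature) < 1e-6

    def test_saddle_negative_gaussian(self, dictionary):
        x, y = np.meshgrid(np.linspace(-20, 20, 41), np.linspace(-20, 20, 41))
        z = x * y / 20.0
        verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
        idx = np.arange(41 * 41).reshape(41, 41)
        faces = []
        for i in range(40):
            for j in range(40):
                a, b, c, d = idx[i, j], idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]
                faces += [(a, b, c), (a, c, d)]
        mesh = SurfaceMesh(verts, np.asarray(faces))
        center = int(idx[20, 20])
        coords = np.tile(verts[center], (26, 1)) + np.arange(26)[:, None] * 0.01
        lms = _lms(dictionary, verts[[center] * 26])
        profs = landmark_curvatures(mesh, lms, radius_mm=8.0)
        assert profs[0].gaussian_curvature < 0

    def test_profile_invariants(self, tiny_sample):
        ind = tiny_sample.individuals[0]
        profs = landmark_curvatures(ind.mesh, ind.true_landmarks, radius_mm=10.0)
        for p in profs:
            assert abs(p.k_max) >= abs(p.k_min)
            assert p.mean_curvature == pytest.approx((p.k_max + p.k_min) / 2)
            assert p.gaussian_curvature == pytest.approx(p.k_max * p.k_min)

    def test_too_few_neighbors_names_landmark(self, dictionary, icosphere50):
        lms = _lms(dictionary, icosphere50.vertices[:26])
        with pytest.raises(ValueError, match="glabella"):
            landmark_curvatures(icosphere50, lms, radius_mm=0.01)


class TestProportionIndices:
    def test_battery_size_default(self):
        assert len(default_proportion_battery()) == 32

    def test_values(self, dictionary, aligned_set):
        vals = proportion_indices(aligned_set)
        assert len(vals) == 32
        arr = np.array(list(vals.values()))
        assert (arr > 0).all() and (arr <= 100).all()

    def test_equal_and_ratio_cases(self, dictionary):
        coords = np.zeros((26, 3))
        coords[:, 0] = np.arange(26, dtype=float)
        # facial_index: nasion(1)-gnathion(9) dist 8; zygion_l(14)-zygion_r(15) dist 1
        vals = proportion_indices(_lms(dictionary, coords))
        assert vals["facial_index"] == pytest.approx(100.0 / 8)

    def test_smaller_over_larger_times_100(self, dictionary):
        rng = np.random.default_rng(3)
        coords = rng.normal(scale=30, size=(26, 3))
        lms = _lms(dictionary, coords)
        vals = proportion_indices(lms)
        for idx in default_proportion_battery():
            num = np.linalg.norm(lms[idx.numerator[0]] - lms[idx.numerator[1]])
            den = np.linalg.norm(lms[idx.denominator[0]] - lms[idx.denominator[1]])
            lo, hi = sorted((num, den))
            assert vals[idx.name] == pytest.approx(100 * lo / hi)


class TestAngles:
    def test_right_angle_and_collinear(self, dictionary):
        coords = np.random.default_rng(4).normal(size=(26, 3)) + 50
        coords[0] = [1.0, 0.0, 0.0]
        coords[1] = [0.0, 0.0, 0.0]
        coords[2] = [0.0, 1.0, 0.0]
        vals, labels = angles(_lms(dictionary, coords))
        # triple (0,1,2): angles at landmark 0, 1, 2 in that order
        assert vals[1] == pytest.approx(90.0)  # vertex at origin
        coords[2] = [-1.0, 0.0, 0.0]  # collinear, vertex 1 in the middle
        vals, _ = angles(_lms(dictionary, coords))
        assert vals[1] == pytest.approx(180.0)

    def test_count_and_sum_180(self, aligned_set):
        vals, labels = angles(aligned_set)
        assert vals.shape == (7800,)
        assert len(labels) == 7800
        sums = vals.reshape(-1, 3).sum(axis=1)
        np.testing.assert_allclose(sums, 180.0, atol=1e-6)

    def test_coincident_triple_flagged_na(self, dictionary):
        coords = np.random.default_rng(5).normal(size=(26, 3))
        coords[1] = coords[0]
        vals, _ = angles(_lms(dictionary, coords))
        assert np.isnan(vals[:3]).all()  # triple (0,1,2)
        assert np.isfinite(vals[-3:]).all()


class TestTriangleAreas:
    def test_345_area(self, dictionary):
        coords = np.random.default_rng(6).normal(size=(26, 3)) + 50
        coords[0] = [0.0, 0.0, 0.0]
        coords[1] = [3.0, 0.0, 0.0]
        coords[2] = [3.0, 4.0, 0.0]
        vals, _ = triangle_areas(_lms(dictionary, coords))
        assert vals[0] == pytest.approx(6.0)

    def test_collinear_zero(self, dictionary):
        coords = np.random.default_rng(7).normal(size=(26, 3)) + 50
        coords[0], coords[1], coords[2] = [0, 0, 0], [1, 1, 1], [2, 2, 2]
        vals, _ = triangle_areas(_lms(dictionary, coords))
        assert vals[0] == pytest.approx(0.0, abs=1e-9)

    def test_count_and_cross_product_oracle(self, aligned_set):
        vals, _ = triangle_areas(aligned_set)
        assert vals.shape == (2600,)
        coords = aligned_set.coords
        oracle = []
        for i, j, k in itertools.combinations(range(26), 3):
            oracle.append(0.5 * np.linalg.norm(np.cross(coords[j] - coords[i], coords[k] - coords[i])))
        np.testing.assert_allclose(vals, oracle, rtol=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_heron_equals_cross_product_random(self, dictionary, seed):
        coords = np.random.default_rng(seed).normal(scale=40.0, size=(26, 3))
        vals, _ = triangle_areas(_lms(dictionary, coords))
        i, j, k = 0, 1, 2
        oracle = 0.5 * np.linalg.norm(np.cross(coords[j] - coords[i], coords[k] - coords[i]))
        assert vals[0] == pytest.approx(oracle, rel=1e-7)


class TestRegionHulls:
    def test_unit_tetrahedron(self, dictionary):
        from facedissect.landmark_phenotypes import RegionDefinition

        coords = np.random.default_rng(8).normal(size=(26, 3)) + 50
        coords[0], coords[1] = [0, 0, 0], [1, 0, 0]
        coords[2], coords[3] = [0, 1, 0], [0, 0, 1]
        region = RegionDefinition("tetra", tuple(dictionary.names[:4]))
        out = region_volume_surface(_lms(dictionary, coords), [region])
        assert out["tetra"][0] == pytest.approx(1 / 6)

    def test_unit_cube(self, dictionary):
        from facedissect.landmark_phenotypes import RegionDefinition

        coords = np.random.default_rng(9).normal(size=(26, 3)) + 50
        corners = np.array(list(itertools.product([0, 1], repeat=3)), float)
        coords[:8] = corners
        region = RegionDefinition("cube", tuple(dictionary.names[:8]))
        out = region_volume_surface(_lms(dictionary, coords), [region])
        vol, area = out["cube"]
        assert vol == pytest.approx(1.0)
        assert area == pytest.approx(6.0)

    def test_interior_point_does_not_change_volume(self, dictionary):
        from facedissect.landmark_phenotypes import RegionDefinition

        coords = np.random.default_rng(10).normal(size=(26, 3)) + 50
        corners = np.array(list(itertools.product([0, 1], repeat=3)), float)
        coords[:8] = corners
        coords[8] = [0.5, 0.5, 0.5]  # interior
        r8 = RegionDefinition("cube", tuple(dictionary.names[:8]))
        r9 = RegionDefinition("cube9", tuple(dictionary.names[:9]))
        out = region_volume_surface(_lms(dictionary, coords), [r8, r9])
        assert out["cube"][0] == pytest.approx(out["cube9"][0])

    def test_coplanar_warns_volume_zero(self, dictionary):
        from facedissect.landmark_phenotypes import RegionDefinition

        coords = np.random.default_rng(11).normal(size=(26, 3)) + 50
        coords[:4, 2] = 0.0
        coords[:4, :2] = [[0, 0], [1, 0], [1, 1], [0, 1]]
        region = RegionDefinition("flat", tuple(dictionary.names[:4]))
        with pytest.warns(UserWarning, match="coplanar"):
            out = region_volume_surface(_lms(dictionary, coords), [region])
        assert out["flat"][0] == 0.0
        assert out["flat"][1] == pytest.approx(1.0)

    def test_default_regions_count(self):
        assert len(default_regions()) == 10


class TestExtraction:
    def test_full_battery_counts(self, tiny_sample):
        # landmarks and meshes must share a frame for the mesh families
        inds = tiny_sample.individuals[:3]
        sets = [i.true_landmarks for i in inds]
        meshes = [i.mesh for i in inds]
        m = extract_phenotypes(sets, meshes)
        counts = m.metadata["category"].value_counts()
        assert counts["Point"] == 78
        assert counts["Curvature"] == 52
        assert counts["Euclidean"] == counts["Manhattan"] == counts["Geodesic"] == 325
        assert counts["Index"] == 32
        assert counts["Angle"] == 7800
        assert counts["Triangle_area"] == 2600
        assert counts["Volume"] == counts["Surface_area"] == 10

    def test_mesh_families_require_meshes(self, tiny_sample):
        sets = [tiny_sample.individuals[0].true_landmarks]
        with pytest.raises(ValueError, match="mesh"):
            extract_phenotypes(sets, None, families=("Curvature",))

    def test_rigid_invariance_of_geometric_families(self, dictionary):
        rng = np.random.default_rng(12)
        coords = rng.normal(scale=30.0, size=(26, 3))
        r = special_ortho_group.rvs(3, random_state=rng)
        moved = coords @ r.T + rng.normal(scale=5.0, size=3)
        fams = ("Euclidean", "Index", "Angle", "Triangle_area", "Volume", "Surface_area")
        m1 = extract_phenotypes([_lms(dictionary, coords)], families=fams)
        m2 = extract_phenotypes([_lms(dictionary, moved)], families=fams)
        np.testing.assert_allclose(
            m1.values.to_numpy(), m2.values.to_numpy(), rtol=1e-6, atol=1e-8
        )
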