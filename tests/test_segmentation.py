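import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facedissect.core_io import SurfaceMesh
from facedissect.facial_segmentation import (
    Segment,
    displacement_field,
    extract_segment_phenotypes,
    hierarchical_segmentation,
    knn_weights,
    moran_attribute_fields,
    morans_i,
    segment_moran,
    segment_pca,
    segment_surface_area,
    vertex_similarity,
)
from facedissect.synthetic_face import PopulationModel, simulate_population


@pytest.fixture(scope="module")
def fields(tiny_sample):
    return displacement_field(tiny_sample)


@pytest.fixture(scope="module")
def similarity(fields):
    return vertex_similarity(fields)


@pytest.fixture(scope="module")
def hierarchy(similarity):
    return hierarchical_segmentation(similarity, levels=7, min_size=1)


class TestDisplacementField:
    def test_template_individuals_have_zero_field(self, small_template):
        model = PopulationModel.null(sigma_individual=0.0, sigma_measurement=0.0)
        s = simulate_population(small_template, model, 2, seed=0)
        f = displacement_field(s)
        assert np.abs(f).max() < 1e-9

    def test_translation_removed_by_alignment(self, small_template):
        model = PopulationModel.null(sigma_individual=0.0, sigma_measurement=0.0)
        s = simulate_population(small_template, model, 2, seed=0)
        t = np.array([5.0, -3.0, 2.0])
        for ind in s.individuals:
            ind.mesh = SurfaceMesh(ind.mesh.vertices + t, ind.mesh.faces)
            ind.true_landmarks = ind.true_landmarks.with_coords(
                ind.true_landmarks.coords + t
            )
        raw = displacement_field(s, align=False)
        np.testing.assert_allclose(raw, np.tile(t, (len(s), small_template.mesh.n_vertices, 1)))
        aligned = displacement_field(s, align=True)
        assert np.abs(aligned).max() < 1e-9

    def test_field_tracks_landmark_displacement(self, small_template):
        model = PopulationModel.null(sigma_individual=0.5, sigma_measurement=0.0)
        s = simulate_population(small_template, model, 3, seed=1)
        f = displacement_field(s, align=False)
        lm_ids = small_template.landmark_vertex_ids
        for i, ind in enumerate(s.individuals):
            truth = ind.true_landmarks.coords - small_template.mesh.vertices[lm_ids]
            np.testing.assert_allclose(f[i, lm_ids], truth, atol=1e-8)

    def test_vertex_count_mismatch_errors(self, tiny_sample):
        import copy

        s = copy.copy(tiny_sample)
        s.individuals = [copy.copy(tiny_sample.individuals[0])]
        m = tiny_sample.individuals[0].mesh
        s.individuals[0].mesh = SurfaceMesh(m.vertices[:-1], m.faces[(m.faces < len(m.vertices) - 1).all(axis=1)])
        with pytest.raises(ValueError, match="register"):
            displacement_field(s)


class TestVertexSimilarity:
    def test_diagonal_is_one(self, similarity):
        np.testing.assert_allclose(np.diag(similarity), 1.0)

    def test_range_and_symmetry(self, similarity):
        assert (similarity >= 0).all() and (similarity <= 1).all()
        np.testing.assert_allclose(similarity, similarity.T)

    def test_shared_latent_factor_gives_one(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(size=(50, 3))
        f = np.stack([latent, 2.0 * latent], axis=1)  # two vertices, same factor
        s = vertex_similarity(f)
        assert s[0, 1] == pytest.approx(1.0)

    def test_independent_noise_low_similarity(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=(500, 2, 3))
        s = vertex_similarity(f)
        assert s[0, 1] < 0.15

    def test_zero_variance_vertex_warns_and_zeroes(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=(20, 3, 3))
        f[:, 1, :] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            s = vertex_similarity(f)
        assert (s[1] == 0).all()


class TestHierarchy:
    def test_seven_levels_gives_127_segments(self, hierarchy):
        assert len(hierarchy) == 127

    def test_levels_one_is_single_segment(self, similarity):
        h = hierarchical_segmentation(similarity, levels=1)
        assert len(h) == 1
        assert len(h.segments[1].vertex_ids) == similarity.shape[0]

    def test_children_partition_parent(self, hierarchy):
        for seg in hierarchy.segments.values():
            kids = hierarchy.children(seg.segment_id)
            if kids:
                union = np.sort(np.concatenate([k.vertex_ids for k in kids]))
                np.testing.assert_array_equal(union, np.sort(seg.vertex_ids))

    def test_levels_are_disjoint_partitions(self, hierarchy):
        n = hierarchy.n_vertices
        for level in range(1, 8):
            segs = hierarchy.at_level(level)
            allv = np.concatenate([s.vertex_ids for s in segs])
            assert len(allv) == n
            assert len(np.unique(allv)) == n

    def test_planted_two_block_recovery(self):
        rng = np.random.default_rng(3)
        n = 60
        w = np.full((n, n), 0.1)
        w[:30, :30] = 0.9
        w[30:, 30:] = 0.9
        w += rng.normal(0, 0.01, (n, n))
        w = np.clip((w + w.T) / 2, 0, 1)
        np.fill_diagonal(w, 1.0)
        h = hierarchical_segmentation(w, levels=2, min_size=1)
        kids = h.at_level(2)
        sides = [set(k.vertex_ids.tolist()) for k in kids]
        assert {frozenset(s) for s in sides} == {
            frozenset(range(30)),
            frozenset(range(30, 60)),
        }

    def test_min_size_stops_branch_with_warning(self, similarity):
        with pytest.warns(UserWarning, match="branch stops"):
            h = hierarchical_segmentation(similarity, levels=20, min_size=50)
        assert len(h) < 2**20 - 1

    def test_asymmetric_matrix_rejected(self):
        w = np.random.default_rng(4).random((10, 10))
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_segmentation(w, levels=2)


class TestSegmentPCA:
    def test_planted_rank_one_retained(self):
        rng = np.random.default_rng(5)
        n, v = 200, 12
        load = rng.normal(size=(v, 3))
        latent = rng.normal(scale=5.0, size=n)
        f = latent[:, None, None] * load[None] + rng.normal(scale=0.1, size=(n, v, 3))
        model = segment_pca(f, np.arange(v), n_null=50, seed=0)
        assert model.n_retained == 1

    def test_pure_noise_rarely_retains(self):
        rng = np.random.default_rng(6)
        hits = 0
        runs = 50
        for r in range(runs):
            f = rng.normal(size=(200, 10, 3))
            model = segment_pca(f, np.arange(10), n_null=30, seed=r)
            if model.n_retained <= 1:
                hits += 1
        assert hits >= int(0.95 * runs)

    def test_explained_variance_monotone_and_sums_le_one(self, fields, hierarchy):
        model = segment_pca(fields, hierarchy.segments[2], n_null=30, seed=0)
        evr = model.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1.0 + 1e-9

    def test_scores_reproducible_and_sign_fixed(self, fields, hierarchy):
        a = segment_pca(fields, hierarchy.segments[3], n_null=30, seed=7)
        b = segment_pca(fields, hierarchy.segments[3], n_null=30, seed=7)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_coarse_null_rejected(self, fields, hierarchy):
        with pytest.raises(ValueError, match="n_null"):
            segment_pca(fields, hierarchy.segments[2], n_null=5)


class TestSegmentArea:
    def test_unit_square_two_triangles(self):
        mesh = SurfaceMesh(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], [[0, 1, 2], [0, 2, 3]]
        )
        seg = Segment(1, 1, None, np.arange(4))
        assert segment_surface_area(mesh, seg) == pytest.approx(1.0)

    def test_level_areas_sum_to_whole(self, tiny_sample, hierarchy):
        # the boundary-band slack grows as segments shrink toward the mesh
        # edge length, so the 2% bound applies while segments stay large
        mesh = tiny_sample.individuals[0].mesh
        total = mesh.surface_area()
        for level in (2, 3, 4):
            areas = [
                segment_surface_area(mesh, s) for s in hierarchy.at_level(level)
            ]
            assert sum(areas) == pytest.approx(total, rel=0.02)
        deep = sum(segment_surface_area(mesh, s) for s in hierarchy.at_level(7))
        assert deep == pytest.approx(total, rel=0.10)
        assert deep <= total + 1e-9  # unassigned 3-way faces only ever undercount

    def test_icosphere_octant(self):
        import trimesh

        s = trimesh.creation.icosphere(subdivisions=5, radius=50.0)
        mesh = SurfaceMesh(np.asarray(s.vertices), np.asarray(s.faces))
        v = mesh.vertices
        octant = np.where((v[:, 0] >= 0) & (v[:, 1] >= 0) & (v[:, 2] >= 0))[0]
        area = segment_surface_area(mesh, octant)
        assert area == pytest.approx(4 * np.pi * 50**2 / 8, rel=0.05)


class TestMoran:
    def grid_weights(self, n=15):
        xs, ys = np.meshgrid(np.arange(n), np.arange(n))
        locs = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        return locs, knn_weights(locs, k=4)

    def test_null_mean_is_minus_one_over_n_minus_1(self):
        locs, w = self.grid_weights(10)
        rng = np.random.default_rng(7)
        x = rng.normal(size=len(locs))
        vals = [morans_i(rng.permutation(x), w) for _ in range(3000)]
        n = len(locs)
        assert np.mean(vals) == pytest.approx(-1.0 / (n - 1), abs=3e-3)

    def test_smooth_gradient_positive(self):
        locs, w = self.grid_weights(15)
        x = locs[:, 0] + locs[:, 1]
        assert morans_i(x, w) > 0.5

    def test_checkerboard_negative(self):
        locs, w = self.grid_weights(14)
        x = ((locs[:, 0] + locs[:, 1]) % 2) * 2.0 - 1.0
        assert morans_i(x, w) < 0

    def test_constant_attribute_errors(self):
        locs, w = self.grid_weights(6)
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(len(locs)), w)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        a=st.floats(min_value=0.1, max_value=10.0),
        b=st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_affine_invariance(self, a, b):
        locs, w = self.grid_weights(8)
        x = np.sin(locs[:, 0]) + 0.3 * locs[:, 1]
        assert morans_i(a * x + b, w) == pytest.approx(morans_i(x, w), rel=1e-9)

    def test_row_standardized_weights(self):
        locs, w = self.grid_weights(8)
        rs = w.weights.sum(axis=1)
        np.testing.assert_allclose(rs, 1.0)
        assert np.diag(w.weights).sum() == 0.0


class TestSegmentPhenotypes:
    def test_block_categories_and_shapes(self, tiny_sample, hierarchy, fields):
        attrs = moran_attribute_fields(tiny_sample, fields, ("Module_mor_z",))
        small = hierarchical_segmentation(
            vertex_similarity(fields), levels=3, min_size=1
        )
        m = extract_segment_phenotypes(
            tiny_sample, small, fields, n_null=25, seed=0, moran_attributes=attrs
        )
        cats = set(m.metadata["category"])
        assert {"Module_PCs", "Module_surf_area", "Module_mor_z"} <= cats
        assert (m.metadata["category"] == "Module_surf_area").sum() == 7
        assert m.values.shape[0] == len(tiny_sample)

    def test_segment_moran_on_template(self, tiny_sample, hierarchy):
        z = tiny_sample.template.mesh.vertices[:, 2]
        val = segment_moran(tiny_sample.template, hierarchy.segments[1], z)
        assert val > 0.5  # z over a smooth face dome is strongly autocorrelated
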