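"""Geometry: mesh generation, spacing, patches, control transforms."""

import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components, dijkstra

from hippomeg import anatomy as anat


@pytest.fixture(scope="module")
def cortex():
    return anat.generate_cortex_mesh(2000, 3.7, seed=1)


@pytest.fixture(scope="module")
def hippo(cortex):
    return anat.generate_hippocampus_mesh(162, 3.7, seed=1,
                                          cortex_mesh=cortex)


@pytest.fixture(scope="module")
def combined(cortex, hippo):
    return anat.make_source_space(cortex, hippo)


class TestCortexGeneration:
    def test_deterministic_given_seed(self):
        a = anat.generate_cortex_mesh(500, 3.7, seed=1)
        b = anat.generate_cortex_mesh(500, 3.7, seed=1)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)
        assert np.array_equal(a.normals, b.normals)

    def test_mean_edge_length_matches_spacing(self, cortex):
        lengths = np.linalg.norm(
            cortex.vertices[cortex.edges()[:, 0]]
            - cortex.vertices[cortex.edges()[:, 1]], axis=1)
        assert 3.15 <= lengths.mean() <= 4.25

    def test_exact_vertex_count(self, cortex):
        assert cortex.n_vertices == 2000

    def test_invariants_audit(self, cortex):
        cortex.validate(target_spacing_mm=3.7)
        assert np.abs(np.linalg.norm(cortex.normals, axis=1) - 1).max() < 1e-9

    def test_infeasible_parameters_raise(self):
        with pytest.raises(anat.GeometryError, match="50"):
            anat.generate_cortex_mesh(50, 3.7, seed=0)
        with pytest.raises(anat.GeometryError, match="-1"):
            anat.generate_cortex_mesh(500, -1.0, seed=0)


class TestHippocampusGeneration:
    def test_exact_vertex_count_and_invariants(self, hippo):
        assert hippo.n_vertices == 162
        hippo.validate(target_spacing_mm=3.7)

    def test_nested_inside_cortex(self, cortex, hippo):
        limit = np.linalg.norm(cortex.vertices, axis=1).min()
        assert (np.linalg.norm(hippo.vertices, axis=1) < limit).all()

    def test_intersecting_tube_raises(self, cortex):
        with pytest.raises(anat.GeometryError, match="intersects"):
            anat.generate_hippocampus_mesh(162, 3.7, centroid_depth_mm=2.0,
                                           seed=1, cortex_mesh=cortex)

    def test_geodesic_axis_extent_on_straight_capsule(self):
        # tip-to-tip surface meridian of the unbent capsule = axis length
        mesh = anat.generate_hippocampus_mesh(200, 3.7, seed=3,
                                              axis_length_mm=50.0,
                                              bend_radius_mm=None)
        axis = mesh.vertices @ np.array([0.0, 1.0, 0.0])
        tip_a, tip_b = int(np.argmin(axis)), int(np.argmax(axis))
        d = dijkstra(mesh.adjacency(), directed=False, indices=tip_a)[tip_b]
        assert abs(d - 50.0) <= mesh.mean_edge_length()


class TestMatchMeshSpacing:
    def test_already_at_target_is_noop(self, hippo):
        out = anat.match_mesh_spacing(hippo, hippo.mean_edge_length())
        assert out is hippo

    def test_dense_tube_decimated_to_target(self):
        dense = anat.generate_hippocampus_mesh(2000, 1.0, seed=2,
                                               bend_radius_mm=None)
        out = anat.match_mesh_spacing(dense, 3.69)
        assert 3.51 <= out.mean_edge_length() <= 3.87
        assert out.is_connected()
        assert out.n_vertices < dense.n_vertices

    def test_coarser_than_target_raises(self, hippo):
        with pytest.raises(anat.GeometryError, match="coarser"):
            anat.match_mesh_spacing(hippo, 1.0)


def _cylinder_mesh(n_rings=40, n_seg=24, radius=15.0, dz=2.0):
    """Regular structured cylinder where axial geodesics are exact."""
    verts, faces = [], []
    for i in range(n_rings):
        for j in range(n_seg):
            t = 2 * np.pi * j / n_seg
            verts.append([radius * np.cos(t), radius * np.sin(t), i * dz])
    for i in range(n_rings - 1):
        for j in range(n_seg):
            a = i * n_seg + j
            b = i * n_seg + (j + 1) % n_seg
            faces.append([a, b, a + n_seg])
            faces.append([b, b + n_seg, a + n_seg])
    v = np.asarray(verts, float)
    f = np.asarray(faces, int)
    n = v.copy()
    n[:, 2] = 0
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    return anat.SurfaceMesh(v, f, n, anat.CORTICAL)


class TestPatchWeights:
    def test_seed_weight_is_one(self, hippo):
        pw = anat.patch_weights(hippo, 10, 6.0)
        assert pw.weights[10] == 1.0
        assert pw.weights.max() == 1.0

    def test_sigma_from_fwhm(self):
        assert np.isclose(6.0 * anat.FWHM_TO_SIGMA, 2.548, atol=0.001)

    def test_gaussian_of_geodesic_distance_on_cylinder(self):
        # along a generatrix the graph geodesic equals the true geodesic
        mesh = _cylinder_mesh()
        seed = 20 * 24  # ring 20, segment 0
        pw = anat.patch_weights(mesh, seed, fwhm_mm=6.0)
        d = dijkstra(mesh.adjacency(), directed=False, indices=seed)
        sigma = 6.0 * anat.FWHM_TO_SIGMA
        same_line = np.arange(15, 26) * 24  # +/- 10 mm along the axis
        expected = np.exp(-d[same_line] ** 2 / (2 * sigma**2))
        got = pw.weights[same_line]
        mask = expected > 1e-3
        assert np.allclose(got[mask], expected[mask], rtol=0.10)

    def test_half_weight_at_half_fwhm(self):
        mesh = _cylinder_mesh(dz=3.0)
        seed = 20 * 24
        pw = anat.patch_weights(mesh, seed, fwhm_mm=6.0)
        neighbour = seed + 24            # exactly 3 mm along the axis
        assert np.isclose(pw.weights[neighbour], 0.5, rtol=0.10)

    def test_truncation_produces_sparsity(self, cortex):
        pw = anat.patch_weights(cortex, 0, 6.0)
        assert (pw.weights == 0.0).sum() > 0.9 * cortex.n_vertices

    def test_disconnected_mesh_warns_and_confines(self):
        m = _cylinder_mesh(n_rings=6)
        # split into two components by dropping a ring of faces
        mid_faces = [i for i, f in enumerate(m.faces)
                     if not ((m.faces[i] // 24 == 2).any()
                             and (m.faces[i] // 24 == 3).any())]
        split = anat.SurfaceMesh(m.vertices, m.faces[mid_faces], m.normals,
                                 m.structure_label)
        n_comp, labels = connected_components(split.adjacency(),
                                              directed=False)
        assert n_comp == 2
        with pytest.warns(RuntimeWarning, match="confined"):
            pw = anat.patch_weights(split, 0, 20.0)
        assert pw.weights[labels != labels[0]].max() == 0.0


class TestSourceSpace:
    def test_combined_counts_and_offsets(self, combined, cortex, hippo):
        assert combined.n_vertices == cortex.n_vertices + hippo.n_vertices
        assert combined.vertex_offset == (0, cortex.n_vertices)
        assert combined.structure_of(0) == "cortical"
        assert combined.structure_of(cortex.n_vertices) == "hippocampal"

    def test_cortical_blocks_bit_identical(self, combined, cortex):
        single = anat.make_source_space(cortex)
        assert np.array_equal(single.vertices,
                              combined.vertices[:cortex.n_vertices])


class TestTransformHippocampus:
    def test_zero_shift_is_identity(self, combined):
        out = anat.transform_hippocampus(combined, shift_mm=(0, 0, 0))
        assert np.array_equal(out.hippocampal_mesh.vertices,
                              combined.hippocampal_mesh.vertices)

    def test_shift_round_trip(self, combined):
        fwd_ = anat.transform_hippocampus(combined, shift_mm=(10, 0, 0))
        back = anat.transform_hippocampus(fwd_, shift_mm=(-10, 0, 0))
        assert np.abs(back.hippocampal_mesh.vertices
                      - combined.hippocampal_mesh.vertices).max() < 1e-12

    def test_cortical_mesh_untouched(self, combined):
        out = anat.transform_hippocampus(combined, shift_mm=(5, 5, 5),
                                         rotation_deg=30.0)
        assert out.cortical_mesh is combined.cortical_mesh

    def test_rotation_is_rigid(self, combined):
        out = anat.transform_hippocampus(combined, rotation_deg=17.0,
                                         rotation_axis=(0, 0, 1))
        v0 = combined.hippocampal_mesh.vertices
        v1 = out.hippocampal_mesh.vertices
        d0 = np.linalg.norm(v0[:50, None] - v0[None, :50], axis=-1)
        d1 = np.linalg.norm(v1[:50, None] - v1[None, :50], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-9
        assert np.abs(np.linalg.norm(out.hippocampal_mesh.normals, axis=1)
                      - 1).max() < 1e-9

    def test_cortical_kind_rejected(self, cortex):
        space = anat.make_source_space(cortex)
        with pytest.raises(ValueError, match="combined"):
            anat.transform_hippocampus(space, shift_mm=(1, 0, 0))

    def test_shift_battery_has_24_distinct_models(self):
        shifts = anat.shift_battery()
        assert len(shifts) == 24
        assert len({tuple(s) for s in shifts}) == 24
        mags = sorted({np.linalg.norm(s) for s in shifts})
        assert mags == [5.0, 10.0, 15.0, 20.0]


class TestNearestCorticalNeighbours:
    def test_matches_brute_force(self, combined):
        pairs = anat.nearest_cortical_neighbours(combined,
                                                 np.arange(0, 162, 7))
        cv = combined.cortical_mesh.vertices
        hv = combined.hippocampal_mesh.vertices
        for h, c, d in pairs:
            all_d = np.linalg.norm(cv - hv[h], axis=1)
            assert c == int(np.argmin(all_d))
            assert np.isclose(d, all_d.min())

    def test_coincident_vertex_distance_zero(self, cortex, hippo):
        fake = anat.SurfaceMesh(cortex.vertices[:162].copy(), hippo.faces,
                                hippo.normals, anat.HIPPOCAMPAL)
        space = anat.SourceSpace((cortex, fake), (0, cortex.n_vertices),
                                 "combined")
        pairs = anat.nearest_cortical_neighbours(space, [5])
        assert pairs[0][2] == 0.0
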