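"""Meshing, spherical mapping, SH fitting and the 85 shape markers."""

import numpy as np
import pytest
import trimesh

import prostacad as pc
from prostacad.phantom import ellipsoid_mask, star_shaped_mask
from prostacad.shape import (
    ARConfig,
    MeshTopologyError,
    SphericalMapping,
    SurfaceMesh,
    attraction_displacement,
    point_in_mesh,
)
from prostacad.spharm import real_sh_degree_block, sh_index


def ball_mask(shape, center, radius):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum((g - c) ** 2 for g, c in zip(grids, center))
    return q <= radius**2


def euler_characteristic(mesh: SurfaceMesh) -> int:
    v = mesh.n_vertices
    f = mesh.triangles.shape[0]
    e = mesh.directed_edges.shape[0] // 2
    return v - e + f


def unit_sphere_mapping(subdiv=3, radius_fn=None):
    """Exact spherical mapping from an icosphere; optional radius function."""
    ico = trimesh.creation.icosphere(subdiv)
    coords = np.asarray(ico.vertices)
    coords = coords / np.linalg.norm(coords, axis=1, keepdims=True)
    theta = np.arccos(np.clip(coords[:, 2], -1, 1))
    phi = np.mod(np.arctan2(coords[:, 1], coords[:, 0]), 2 * np.pi)
    radii = np.ones(len(coords)) if radius_fn is None else radius_fn(theta, phi)
    return SphericalMapping(coords, theta, phi, radii)


class TestMeshFromMask:
    def test_ball_gives_closed_genus0_mesh(self):
        mesh = pc.mesh_from_mask(ball_mask((24, 24, 24), (11.5,) * 3, 8))
        assert euler_characteristic(mesh) == 2

    def test_single_voxel_lesion(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        mesh = pc.mesh_from_mask(mask)
        assert euler_characteristic(mesh) == 2
        assert mesh.n_vertices >= 4

    def test_ellipsoid_surface_area_within_5pct(self):
        a, b, c = 10.0, 6.0, 4.0
        mask = ellipsoid_mask((28, 20, 16), (a, b, c))
        mesh = pc.mesh_from_mask(mask)
        # Thomsen approximation, independent of the meshing path
        p = 1.6075
        analytic = 4 * np.pi * (
            ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3
        ) ** (1 / p)
        assert mesh.as_trimesh().area == pytest.approx(analytic, rel=0.05)

    def test_multiple_components_rejected(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[2:4, 2:4, 2:4] = True
        mask[8:10, 8:10, 8:10] = True
        with pytest.raises(MeshTopologyError, match="components"):
            pc.mesh_from_mask(mask)

    def test_torus_rejected_as_nonzero_genus(self):
        shape = (32, 32, 16)
        x, y, z = np.ogrid[0:32, 0:32, 0:16]
        ring = (np.sqrt((x - 15.5) ** 2 + (y - 15.5) ** 2) - 9) ** 2 + (z - 7.5) ** 2
        with pytest.raises(MeshTopologyError, match="Euler"):
            pc.mesh_from_mask(ring <= 3.5**2)

    def test_vertex_cap_respected(self):
        mask = ball_mask((40, 40, 40), (19.5,) * 3, 15)
        mesh = pc.mesh_from_mask(mask, max_vertices=500)
        assert mesh.n_vertices <= 500
        assert euler_characteristic(mesh) == 2


class TestChooseOrigin:
    def test_centered_ball(self):
        mask = ball_mask((21, 21, 21), (10, 10, 10), 7)
        mesh = pc.mesh_from_mask(mask)
        origin = pc.choose_origin(mesh, mask)
        np.testing.assert_allclose(origin, [10, 10, 10], atol=0.5)

    def test_translation_equivariance(self):
        m1 = ball_mask((24, 24, 24), (9, 9, 9), 6)
        m2 = ball_mask((24, 24, 24), (13, 12, 11), 6)
        o1 = pc.choose_origin(pc.mesh_from_mask(m1), m1)
        o2 = pc.choose_origin(pc.mesh_from_mask(m2), m2)
        np.testing.assert_allclose(o2 - o1, [4, 3, 2], atol=1e-9)

    def test_crescent_falls_back_to_interior_point(self):
        # thick shell cut by an offset ball: the voxel centroid lies in the void
        outer = ball_mask((32, 32, 32), (15.5, 15.5, 15.5), 11)
        inner = ball_mask((32, 32, 32), (17.5, 15.5, 15.5), 8)
        crescent = outer & ~inner
        idx = np.argwhere(crescent)
        centroid = np.round(idx.mean(axis=0)).astype(int)
        assert not crescent[tuple(centroid)]  # precondition: centroid outside
        mesh = pc.mesh_from_mask(crescent)
        origin = pc.choose_origin(mesh, crescent)
        assert point_in_mesh(mesh, origin)


class TestAttractionRepulsion:
    def test_icosphere_is_near_fixed_point(self):
        ico = trimesh.creation.icosphere(3)
        mesh = SurfaceMesh(np.asarray(ico.vertices) * 3.0, np.asarray(ico.faces))
        mapping = pc.attraction_repulsion(mesh, np.zeros(3))
        assert mapping.n_cycles < 50
        assert np.abs(mapping.unit_coords - np.asarray(ico.vertices)).max() < 0.05

    def test_unit_norm_after_every_cycle(self):
        ico = trimesh.creation.icosphere(2)
        mesh = SurfaceMesh(np.asarray(ico.vertices) * 2.0, np.asarray(ico.faces))
        for cycles in (1, 2, 5):
            cfg = ARConfig(max_cycles=cycles, displacement_tol=0.0)
            m = pc.attraction_repulsion(mesh, np.zeros(3), cfg)
            np.testing.assert_allclose(
                np.linalg.norm(m.unit_coords, axis=1), 1.0, atol=1e-9
            )

    def test_attraction_step_matches_scalar_oracle(self):
        """Vectorized attraction equals a scalar per-node evaluation of the
        update rule, including a minimal two-node system."""
        rng = np.random.default_rng(0)
        # two nodes, one (bidirectional) neighbor link
        coords2 = np.array([[0.0, 0.0, 1.0], [0.0, 0.8, 0.6]])
        cases = [
            (coords2, np.array([0, 1]), np.array([1, 0])),
        ]
        ico = trimesh.creation.icosphere(1)
        mesh = SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))
        e = mesh.directed_edges
        cases.append((np.asarray(ico.vertices), e[:, 0], e[:, 1]))
        for coords, src, dst in cases:
            c_a1, c_a2 = rng.uniform(0.05, 0.3, 2)
            got = attraction_displacement(coords, src, dst, c_a1, c_a2)
            expected = np.zeros_like(coords)
            for i in range(len(coords)):
                for j in dst[src == i]:
                    d = coords[j] - coords[i]
                    dist = np.linalg.norm(d)
                    expected[i] += c_a1 * (d * dist**2 + c_a2 * d / dist)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_phantom_lesion_mapping_is_unit_norm_and_bijective(self, small_cohort):
        case = small_cohort[0]
        mesh = pc.mesh_from_mask(case.lesion_mask, max_vertices=800)
        origin = pc.choose_origin(mesh, case.lesion_mask)
        mapping = pc.attraction_repulsion(mesh, origin)
        np.testing.assert_allclose(
            np.linalg.norm(mapping.unit_coords, axis=1), 1.0, atol=1e-9
        )
        assert mapping.theta.min() >= 0 and mapping.theta.max() <= np.pi
        assert mapping.phi.min() >= 0 and mapping.phi.max() < 2 * np.pi


class TestFitSH:
    def test_exact_sphere_all_mass_at_order_zero(self):
        mapping = unit_sphere_mapping(3)
        model = pc.fit_sh(mapping, max_order=5)
        assert model.order_errors[0] == pytest.approx(0.0, abs=1e-9)
        c00 = model.coefficients[sh_index(0, 0)]
        assert c00 == pytest.approx(np.sqrt(4 * np.pi), rel=1e-9)

    def test_planted_degree3_coefficient_recovered(self):
        beta = 1

        def radius_fn(theta, phi):
            return 1.0 + 0.2 * real_sh_degree_block(3, theta, phi)[:, 3 + beta]

        mapping = unit_sphere_mapping(4, radius_fn)
        model = pc.fit_sh(mapping, max_order=10)
        k = sh_index(3, beta)
        assert model.coefficients[k] == pytest.approx(0.2, abs=1e-3)
        others = np.delete(model.coefficients, [k, sh_index(0, 0)])
        assert np.abs(others).max() <= 1e-3

    def test_coefficient_count_bookkeeping(self):
        with pytest.warns(UserWarning, match="rank-limited"):
            model = pc.fit_sh(unit_sphere_mapping(2), max_order=85)
        assert model.coefficients.shape == (86**2,)
        assert model.coefficients.size == 7396

    def test_errors_non_increasing(self):
        rng = np.random.default_rng(3)

        def radius_fn(theta, phi):
            return 1.0 + 0.1 * np.cos(3 * theta) + 0.05 * np.sin(2 * phi)

        model = pc.fit_sh(unit_sphere_mapping(3, radius_fn), max_order=12)
        assert np.all(np.diff(model.order_errors) <= 1e-12)


class TestShapeMarkers:
    def test_marker_vector_length_85(self, small_cohort):
        vec = pc.shape_features_from_mask(small_cohort[0].lesion_mask, max_vertices=600)
        assert len(vec) == 85
        assert np.all(np.diff(vec.values) <= 1e-12)

    def test_exact_sphere_markers_near_zero(self):
        with pytest.warns(UserWarning, match="rank-limited"):
            model = pc.fit_sh(unit_sphere_mapping(3), max_order=85)
        vec = pc.shape_feature_vector(model)
        assert np.abs(vec.values).max() < 1e-9

    def test_insufficient_order_rejected(self):
        model = pc.fit_sh(unit_sphere_mapping(2), max_order=10)
        with pytest.raises(ValueError):
            pc.shape_feature_vector(model, n_markers=85)

    def test_rotation_robustness(self):
        """Rotating the mask 90 degrees about a grid axis leaves the
        complexity markers essentially unchanged (pose invariance)."""
        mask = star_shaped_mask(
            (30, 30, 30), (14.5, 14.5, 14.5), 6.0, 0.25,
            rng=np.random.default_rng(8),
        )
        rotated = np.rot90(mask, k=1, axes=(0, 1)).copy()
        v1 = pc.shape_features_from_mask(mask).values
        v2 = pc.shape_features_from_mask(rotated).values
        lead = max(v1[0], v2[0])
        scale = np.maximum(np.abs(v1), np.abs(v2))
        resolved = scale > 0.05 * lead  # markers above resolution noise
        rel = np.abs(v1 - v2)[resolved] / scale[resolved]
        assert rel.max() < 0.05
        # the numerically tiny tail stays tiny in absolute terms
        assert np.abs(v1 - v2)[~resolved].max() < 0.05 * lead

    def test_scale_invariance_of_normalized_markers(self):
        def radius_fn(theta, phi):
            return 1.0 + 0.15 * np.cos(2 * theta) * np.cos(phi)

        base = unit_sphere_mapping(3, radius_fn)
        doubled = SphericalMapping(
            base.unit_coords, base.theta, base.phi, 2.0 * base.radii
        )
        m1 = pc.fit_sh(base, max_order=10)
        m2 = pc.fit_sh(doubled, max_order=10)
        # raw RMS errors scale with the lesion
        np.testing.assert_allclose(m2.order_errors, 2.0 * m1.order_errors, rtol=1e-9)
        v1 = pc.shape_feature_vector(m1, n_markers=10).values
        v2 = pc.shape_feature_vector(m2, n_markers=10).values
        np.testing.assert_allclose(v1, v2, atol=1e-6)

    def test_smooth_ellipsoid_converges_before_spiky_star(self):
        """Error-curve analogue of benign-vs-malignant complexity: the smooth
        ellipsoid drops below tolerance at strictly lower order."""
        tol = 0.02
        ellipsoid = ellipsoid_mask((30, 22, 18), (10, 6, 4))
        star = star_shaped_mask(
            (32, 32, 32), (15.5, 15.5, 15.5), 6.5, 0.35,
            rng=np.random.default_rng(4),
        )
        ve = pc.shape_features_from_mask(ellipsoid, max_vertices=800).values
        vs = pc.shape_features_from_mask(star, max_vertices=800).values

        def crossing(values):
            below = np.flatnonzero(values < tol)
            return int(below[0]) + 1 if below.size else len(values) + 1

        assert crossing(ve) < crossing(vs)
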