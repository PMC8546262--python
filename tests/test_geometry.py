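"""Geometry: sphere construction, nesting, lesions, metrics, refinement, I/O."""

import numpy as np
import pytest

from lesioncond.geometry import (
    GeometryError,
    LesionSpec,
    add_spherical_lesion,
    lesion_metrics,
    load_surface,
    make_geodesic_sphere,
    make_icosphere,
    make_sphere_head,
    refine_near_points,
    save_surface,
)


class TestIcosphere:
    @pytest.mark.parametrize("subdiv,faces,verts", [(0, 20, 12), (1, 80, 42), (3, 1280, 642)])
    def test_counts(self, subdiv, faces, verts):
        s = make_icosphere((0, 0, 0), 10.0, subdiv)
        assert s.n_triangles == faces
        assert s.n_vertices == verts

    def test_volume_converges_from_below(self):
        exact = 4.0 / 3.0 * np.pi * 92.0**3
        vols = [make_icosphere((0, 0, 0), 92.0, s).signed_volume_mm3() for s in range(5)]
        assert all(v < exact for v in vols)
        assert all(b > a for a, b in zip(vols, vols[1:]))
        assert vols[4] > 0.995 * exact  # within 0.5% at subdivision 4

    def test_closed_and_oriented(self):
        s = make_icosphere((5.0, -2.0, 1.0), 3.0, 2)
        s.validate()  # closure, winding, positive volume, non-degenerate

    def test_rejects_bad_radius(self):
        with pytest.raises(GeometryError):
            make_icosphere((0, 0, 0), -1.0, 1)


class TestGeodesicSphere:
    @pytest.mark.parametrize("f", [1, 3, 8, 13])
    def test_counts_and_closure(self, f):
        s = make_geodesic_sphere((0, 0, 0), 50.0, f)
        assert s.n_triangles == 20 * f * f
        s.validate()
        assert np.allclose(np.linalg.norm(s.vertices, axis=1), 50.0)


class TestSphereHead:
    def test_element_counts_near_request(self):
        head = make_sphere_head(elements_per_surface=3200)
        for s in head.surfaces:
            assert 1280 <= s.n_triangles <= 5120
        assert len(head.surfaces) == 4
        assert head.labels == ("scalp", "skull", "csf", "brain")

    def test_rejects_non_nested_radii(self):
        with pytest.raises(GeometryError):
            make_sphere_head(radii=(80, 86, 70, 60))

    def test_default_conductivities(self):
        head = make_sphere_head(elements_per_surface=320)
        assert head.conductivities == (0.414, 0.016, 1.71, 0.37)
        assert head.outside_conductivity(0) == 0.0
        assert head.outside_conductivity(2) == 0.016


class TestLesion:
    def test_large_lesion_volume_matches_sphere(self, coarse_head):
        # 27.3 mm radius -> 85.2 ml, the top of the clinical volume range
        model = add_spherical_lesion(
            coarse_head, LesionSpec((-49.5, 0, 0), 27.3, 1.71), elements=1280
        )
        m = lesion_metrics(model)
        assert m.volume_ml == pytest.approx(85.2, rel=0.02)

    def test_small_lesion_volume(self, coarse_head):
        model = add_spherical_lesion(
            coarse_head, LesionSpec((-40.0, 0, 0), 2.88, 0.74), elements=1280
        )
        assert lesion_metrics(model).volume_ml == pytest.approx(0.1, rel=0.02)

    def test_depth_is_scalp_radius_minus_center_distance(self, coarse_head):
        model = add_spherical_lesion(
            coarse_head, LesionSpec((0, 0, 55.0), 10.0, 1.23), elements=320
        )
        edge = 2 * np.pi * 92 / 20  # coarse scalp edge length scale
        assert lesion_metrics(model).depth_mm == pytest.approx(92 - 55, abs=edge)

    def test_central_lesion_depth_is_scalp_radius(self, coarse_head):
        model = add_spherical_lesion(
            coarse_head, LesionSpec((0, 0, 0), 10.0, 1.23), elements=320
        )
        assert lesion_metrics(model).depth_mm == pytest.approx(92.0, rel=0.01)

    def test_lesion_piercing_brain_rejected(self, coarse_head):
        with pytest.raises(GeometryError):
            add_spherical_lesion(coarse_head, LesionSpec((-60, 0, 0), 23.0, 1.23))

    def test_original_model_unchanged(self, coarse_head):
        n = len(coarse_head.surfaces)
        model = add_spherical_lesion(
            coarse_head, LesionSpec((-40, 0, 0), 10.0, 1.0), elements=320
        )
        assert len(coarse_head.surfaces) == n == 4
        assert len(model.surfaces) == 5
        assert model.conductivity_of("lesion") == 1.0

    def test_metrics_require_lesion(self, coarse_head):
        with pytest.raises(GeometryError):
            lesion_metrics(coarse_head)

    def test_conductivity_bounds(self):
        with pytest.raises(GeometryError):
            LesionSpec((0, 0, 0), 10.0, 2.5)


class TestRefinement:
    def test_counts_near_4000_for_default_head(self, coarse_layout):
        head = make_sphere_head(elements_per_surface=3200)
        pts = np.array([[92, 0, 0], [-92, 0, 0.0]])
        refined = refine_near_points(head.scalp, pts, 25.0)
        assert 3600 <= refined.n_triangles <= 4400
        refined.validate()

    def test_tiny_radius_is_noop(self, coarse_head):
        out = refine_near_points(coarse_head.scalp, [[0, 0, 200.0]], 0.01)
        assert out.n_triangles == coarse_head.scalp.n_triangles

    def test_closure_preserved_and_on_sphere(self, coarse_head):
        out = refine_near_points(coarse_head.scalp, [[92, 0, 0]], 30.0)
        out.validate()
        assert np.allclose(np.linalg.norm(out.vertices, axis=1), 92.0)
        assert out.n_triangles > coarse_head.scalp.n_triangles


class TestMeshIO:
    @pytest.mark.parametrize("ext", ["ply", "stl", "off"])
    def test_roundtrip(self, tmp_path, ext):
        s = make_icosphere((0, 0, 0), 10.0, 1, label="scalp")
        path = tmp_path / f"scalp.{ext}"
        save_surface(s, path)
        back = load_surface(path)
        assert back.n_triangles == s.n_triangles
        assert back.signed_volume_mm3() == pytest.approx(s.signed_volume_mm3(), rel=1e-6)
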