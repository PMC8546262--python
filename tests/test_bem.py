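"""Boundary-element solver: source terms, kernels, oracle checks, recording."""

from dataclasses import replace

import numpy as np
import pytest

from lesioncond import analytic
from lesioncond.bem import (
    BEMError,
    SourceConfig,
    _lin_pot_block,
    assemble_system,
    infinite_medium_potential,
    record_at_electrodes,
    stimulation_sources,
)
from lesioncond.geometry import make_icosphere, make_sphere_head


@pytest.fixture(scope="module")
def dipair():
    return SourceConfig(
        positions=[[0.0, 0.0, 10.0], [0.0, 0.0, -10.0]], currents=[1e-4, -1e-4]
    )


class TestInfiniteMedium:
    def test_single_monopole_closed_form(self):
        src = SourceConfig(positions=[[0, 0, 0], [1e6, 0, 0]], currents=[1e-4, -1e-4])
        # 1e-4 A / (4 pi 0.414 S/m 0.01 m) = 1.922e-3 V (far cathode negligible)
        val = infinite_medium_potential(src, [[10.0, 0, 0]], 0.414)[0]
        assert val == pytest.approx(1.922e-3, rel=1e-3)

    def test_equidistant_point_is_zero(self, dipair):
        assert infinite_medium_potential(dipair, [[50.0, 0, 0]], 1.0)[0] == pytest.approx(
            0.0, abs=1e-18
        )

    def test_linearity_in_current(self, dipair):
        doubled = SourceConfig(dipair.positions, 2 * dipair.currents)
        pts = [[5.0, 3.0, 20.0], [0.0, 7.0, -13.0]]
        assert np.allclose(
            infinite_medium_potential(doubled, pts, 0.5),
            2 * infinite_medium_potential(dipair, pts, 0.5),
        )

    def test_evaluation_at_source_rejected(self, dipair):
        with pytest.raises(ValueError):
            infinite_medium_potential(dipair, [[0.0, 0.0, 10.0]], 1.0)

    def test_currents_must_balance(self):
        with pytest.raises(ValueError):
            SourceConfig(positions=[[0, 0, 0]], currents=[1e-4])


class TestKernel:
    def test_closed_surface_solid_angle_sums(self):
        s = make_icosphere((0, 0, 0), 1.0, 2)
        inside = np.array([[0.1, 0.2, -0.05], [0.0, 0.0, 0.0]])
        B = _lin_pot_block(inside, s.vertices, s.triangles, self_block=False)
        assert np.allclose(B.sum(axis=1), 4 * np.pi, rtol=1e-10)
        outside = np.array([[2.0, 0.3, 0.0]])
        Bo = _lin_pot_block(outside, s.vertices, s.triangles, self_block=False)
        # exact value 0; residual is cancellation error of O(1) weights
        assert Bo.sum() == pytest.approx(0.0, abs=1e-4)

    def test_self_block_rows_sum_to_2pi(self):
        s = make_icosphere((0, 0, 0), 1.0, 1)
        B = _lin_pot_block(s.vertices, s.vertices, s.triangles, self_block=True)
        assert np.allclose(B.sum(axis=1), 2 * np.pi)

    def test_linear_weights_match_quadrature(self):
        rng = np.random.default_rng(1)
        for _ in range(4):
            tri = rng.normal(size=(3, 3))
            p = rng.normal(size=3) * 0.5
            nrm = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            area = 0.5 * np.linalg.norm(nrm)
            from lesioncond.bem import _lin_solid_angle_chunk

            out = _lin_solid_angle_chunk(
                p[None, :], tri[None, :, :], (nrm / (2 * area))[None, :], np.array([area])
            )[0, 0]
            # midpoint quadrature on a barycentric lattice
            n = 64
            acc = np.zeros(3)
            for i in range(n):
                for j in range(n - i):
                    for bary in (
                        np.array([i + 1 / 3, j + 1 / 3, n - i - j - 2 / 3]) / n,
                        (
                            np.array([i + 2 / 3, j + 2 / 3, n - i - j - 4 / 3]) / n
                            if j < n - i - 1
                            else None
                        ),
                    ):
                        if bary is None:
                            continue
                        pt = bary @ tri
                        r = pt - p
                        dOm = (r @ (nrm / (n * n) / 2.0)) / np.linalg.norm(r) ** 3
                        acc += bary * dOm
            assert np.allclose(out, acc, rtol=5e-3, atol=1e-6)


@pytest.fixture(scope="module")
def antipodal_setup():
    head = make_sphere_head(elements_per_surface=320)
    src = SourceConfig(
        positions=[[89.0, 0.0, 0.0], [-89.0, 0.0, 0.0]], currents=[1e-4, -1e-4]
    )
    system = assemble_system(head, src)
    return head, src, system


class TestSolve:
    def test_zero_currents_zero_field(self, antipodal_setup):
        head, _, system = antipodal_setup
        src0 = SourceConfig(
            positions=[[89.0, 0, 0], [-89.0, 0, 0]], currents=[0.0, 0.0]
        )
        field = system.solve(src0)
        assert np.allclose(field.values, 0.0)

    def test_linearity_in_current(self, antipodal_setup):
        head, src, system = antipodal_setup
        src2 = SourceConfig(src.positions, 3.0 * src.currents)
        a = system.solve(src).values
        b = system.solve(src2).values
        assert np.allclose(b, 3.0 * a, rtol=1e-9)

    def test_midplane_antisymmetry(self, antipodal_setup):
        """Antipodal pair on a sphere: scalp potentials are antisymmetric
        under reflection through the pair's mid-plane."""
        head, src, system = antipodal_setup
        phi = system.solve(src).surface_values("scalp")
        verts = head.scalp.vertices
        mirrored = verts * np.array([-1.0, 1.0, 1.0])
        # vertex-exact mirror partner exists for the geodesic sphere
        from scipy.spatial import cKDTree

        d, idx = cKDTree(verts).query(mirrored)
        assert d.max() < 1e-6
        scale = np.abs(phi).max()
        assert np.abs(phi + phi[idx]).max() < 0.01 * scale

    def test_monopole_outside_scalp_rejected(self, antipodal_setup):
        head, _, _ = antipodal_setup
        bad = SourceConfig(positions=[[50.0, 0, 0], [-89.0, 0, 0]], currents=[1e-4, -1e-4])
        with pytest.raises(BEMError):
            assemble_system(head, bad)

    def test_homogeneous_sphere_matches_series(self):
        """Equal conductivities in all shells reduce to the homogeneous
        sphere; BEM must match the analytic series closely even at the
        coarse unit-test mesh."""
        head = make_sphere_head(
            elements_per_surface=320, conductivities=(0.37, 0.37, 0.37, 0.37)
        )
        src = SourceConfig(
            positions=[[89.0, 0, 0], [-89.0, 0, 0]], currents=[1e-4, -1e-4]
        )
        system = assemble_system(head, src)
        phi = system.solve(src).surface_values("scalp")
        model = analytic.LayeredSphereModel((0.092,), (0.37,))
        ref = analytic.pair_potential(
            model, 0.089, [1, 0, 0], [-1, 0, 0], 1e-4, head.scalp.vertices * 1e-3,
            n_max=2500,
        )
        rdm, mag = analytic.rdm_mag(ref - ref.mean(), phi - phi.mean())
        assert rdm < 0.05
        assert abs(np.log(mag)) < 0.1


class TestRecording:
    def test_126_electrodes_recorded(self, coarse_head, coarse_layout):
        src = stimulation_sources(coarse_head, coarse_layout, ("T7", "T8"))
        system = assemble_system(coarse_head, src)
        rec = record_at_electrodes(system.solve(src), coarse_layout, exclude=("T7", "T8"))
        assert len(rec.measurement_labels) == 126
        assert rec.values_for(["nasion"])[0] == 0.0

    def test_vertex_electrode_gets_vertex_potential(self, coarse_head, coarse_layout):
        from lesioncond.bem import interpolation_operator

        src = stimulation_sources(coarse_head, coarse_layout, ("T7", "T8"))
        system = assemble_system(coarse_head, src)
        field = system.solve(src)
        scalp_phi = field.surface_values("scalp")
        vid = 37
        layout = coarse_layout.with_positions(
            np.vstack([coarse_head.scalp.vertices[vid], coarse_layout.positions[1:]])
        )
        rec = record_at_electrodes(field, layout)
        # expected: exact vertex value minus the interpolated reference value
        ref_pos = layout.position_of(layout.reference_label)
        Wref = interpolation_operator(coarse_head.scalp, ref_pos[None, :])
        ref_val = float((Wref @ scalp_phi)[0])
        assert rec.potentials[0] == pytest.approx(scalp_phi[vid] - ref_val, abs=1e-12)

    def test_monopole_depth_and_direction(self, coarse_head, coarse_layout):
        src = stimulation_sources(coarse_head, coarse_layout, ("T7", "T8"))
        r = np.linalg.norm(src.positions, axis=1)
        assert np.allclose(r, 89.0, atol=1e-9)

    def test_far_electrode_rejected(self, coarse_head, coarse_layout):
        src = stimulation_sources(coarse_head, coarse_layout, ("T7", "T8"))
        system = assemble_system(coarse_head, src)
        bad = coarse_layout.with_positions(coarse_layout.positions * 1.2)
        with pytest.raises(ValueError):
            record_at_electrodes(system.solve(src), bad)
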