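"""Nodal field evaluation, grid sampling, isosurfacing and integrity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcell import (
    DomainError,
    PCellParams,
    check_integrity,
    eval_field,
    extract_isosurface,
    sample_grid,
    scale_params,
    surface_ratio,
)
from pcell.interface_io import PhantomSpec, make_phantom
from pcell.mesh import TriangleMesh

PI = np.pi


class TestEvalField:
    @pytest.mark.parametrize(
        "xyz, s, expected",
        [
            ((0, 0, 0), 1.0, 3.0),
            ((PI, PI, PI), 1.0, -3.0),
            ((PI, PI, PI), 2.0, 0.0),  # 3*cos(pi/2)
            ((PI, 0, 0), 1.0, 1.0),
        ],
    )
    def test_reference_points(self, xyz, s, expected):
        p = PCellParams(k=0.0, s=s)
        assert eval_field(*xyz, p) == pytest.approx(expected, abs=1e-12)

    def test_nonfinite_coordinates_rejected(self):
        p = PCellParams()
        with pytest.raises(DomainError):
            eval_field(np.nan, 0, 0, p)
        with pytest.raises(DomainError):
            eval_field(np.inf, 0, 0, p)

    @settings(deadline=None, max_examples=50)
    @given(
        x=st.floats(-10, 10), y=st.floats(-10, 10), z=st.floats(-10, 10),
        s=st.floats(0.5, 2.0), k=st.floats(-0.9, 0.9),
    )
    def test_range_and_point_symmetry(self, x, y, z, s, k):
        p = PCellParams(k=k, s=s)
        v = eval_field(x, y, z, p)
        assert -3.0 <= v <= 3.0
        assert eval_field(-x, -y, -z, p) == pytest.approx(v, abs=1e-12)


class TestSampleGrid:
    def test_tiny_grid_center_and_corners(self):
        f = sample_grid(PCellParams(k=0, s=1, N=3))
        assert f.values[1, 1, 1] == pytest.approx(3.0)
        corners = f.values[::2, ::2, ::2]
        assert corners == pytest.approx(-3.0)

    def test_spacing(self):
        f = sample_grid(PCellParams(N=100))
        assert f.spacing == pytest.approx(2 * PI / 99)

    @pytest.mark.parametrize("s", [0.75, 1.0, 1.3, 1.5])
    def test_corner_value_closed_form(self, s):
        """Cube corners sit at canonical (+-pi)^3 so f = 3 cos(pi/s)."""
        f = sample_grid(PCellParams(k=0, s=s, N=21))
        assert f.values[0, 0, 0] == pytest.approx(3 * np.cos(PI / s), abs=1e-12)

    def test_value_range(self):
        f = sample_grid(PCellParams(k=0.4, s=1.2, N=40))
        assert f.values.min() >= -3.0 and f.values.max() <= 3.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            PCellParams(N=2)


class TestExtractIsosurface:
    def test_standard_cell_surface_ratio(self, standard_mesh, standard_params):
        """The N=100 tessellation reproduces the reference area 2.3451 L^2."""
        sr = surface_ratio(standard_mesh, standard_params.L)
        assert sr == pytest.approx(2.3451, rel=5e-3)

    def test_sphere_phantom_area(self):
        ph = make_phantom(PhantomSpec("sphere", size=1.0, L=4.0, density=120))
        mesh = extract_isosurface(ph.field, 0.0)
        assert mesh.area() == pytest.approx(ph.area, rel=0.01)

    def test_isovalue_outside_range_rejected(self, standard_field):
        with pytest.raises(DomainError):
            extract_isosurface(standard_field, 3.5)

    def test_degenerate_isovalue_perturbed(self):
        """A level colliding with sampled values still yields a mesh."""
        f = sample_grid(PCellParams(k=0, s=1, N=11))
        level = float(f.values[5, 5, 0])  # an exact nodal value
        mesh = extract_isosurface(f, level)
        assert mesh.n_faces > 0
        assert np.isfinite(mesh.vertices).all()

    def test_boundary_vertices_on_cube(self, standard_mesh, standard_params):
        L = standard_params.L
        be = standard_mesh.boundary_edges()
        pts = standard_mesh.vertices[np.unique(be)]
        on_face = np.isclose(np.abs(pts), L / 2, atol=1e-6 * L).any(axis=1)
        assert on_face.all()

    def test_no_degenerate_faces(self, standard_mesh):
        assert (standard_mesh.face_areas() > 0).all()


class TestIntegrity:
    def test_standard_cell_passes(self, standard_mesh):
        rep = check_integrity(standard_mesh)
        assert rep.passes
        assert rep.n_components == 1
        assert rep.n_boundary_loops == 6
        assert rep.loops_per_face == (1, 1, 1, 1, 1, 1)

    @pytest.mark.parametrize("s, expected", [(1.5, True), (1.55, False), (0.7, False)])
    def test_s_boundary(self, s, expected):
        p = PCellParams(k=0.0, s=s, N=100)
        mesh = extract_isosurface(sample_grid(p), 0.0)
        assert check_integrity(mesh).passes is expected

    @pytest.mark.parametrize("k, expected", [(-0.9, True), (0.9, True), (2.0, False)])
    def test_k_boundary(self, k, expected):
        p = PCellParams(k=k, s=1.0, N=100)
        mesh = extract_isosurface(sample_grid(p), k)
        assert check_integrity(mesh).passes is expected

    def test_k_sweep_all_pass(self):
        for k in np.arange(-0.9, 0.91, 0.1):
            p = PCellParams(k=round(float(k), 1), s=1.0, N=60)
            mesh = extract_isosurface(sample_grid(p), p.k)
            assert check_integrity(mesh).passes, f"k={k} failed integrity"


class TestScaleAndSymmetry:
    def test_scale_params_multiplies_L(self):
        p = PCellParams(L=2 * PI)
        assert scale_params(p, 2.0).L == pytest.approx(4 * PI)
        assert scale_params(p, 1.0) == p

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(DomainError):
            scale_params(PCellParams(), 0.0)
        with pytest.raises(DomainError):
            scale_params(PCellParams(), -1.0)

    def test_dimensionless_scale_invariance(self):
        """Surface ratio is exactly invariant under uniform scaling."""
        p = PCellParams(k=0.3, s=1.1, N=50)
        p3 = scale_params(p, 3.0)
        sr = surface_ratio(extract_isosurface(sample_grid(p), p.k), p.L)
        sr3 = surface_ratio(extract_isosurface(sample_grid(p3), p3.k), p3.L)
        assert sr3 == pytest.approx(sr, rel=1e-12)

    @pytest.mark.parametrize("k", [0.3, 0.7])
    def test_k_sign_symmetry_of_area(self, k):
        """x -> x + pi*s maps level k to -k, so areas match."""
        srs = []
        for kk in (k, -k):
            p = PCellParams(k=kk, s=1.0, N=80)
            srs.append(surface_ratio(extract_isosurface(sample_grid(p), kk), p.L))
        assert srs[0] == pytest.approx(srs[1], rel=5e-3)

    def test_cube_symmetry_of_area(self, standard_field, standard_mesh):
        """Axis permutations of the grid leave the area invariant."""
        from pcell.implicit_cell import SampledField

        base = standard_mesh.area()
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            f = SampledField(standard_field.values.transpose(perm), standard_field.L)
            area = extract_isosurface(f, 0.0).area()
            assert area == pytest.approx(base, rel=1e-3)

    def test_area_convergence_under_refinement(self, standard_mesh):
        p = PCellParams(k=0.0, s=1.0, N=140)
        fine = extract_isosurface(sample_grid(p), 0.0).area()
        assert abs(standard_mesh.area() - fine) / fine < 0.01


class TestValidityFlags:
    @pytest.mark.parametrize(
        "k, s, valid", [(0.0, 1.0, True), (0.95, 1.0, True), (1.2, 1.0, False),
                        (0.0, 1.55, False), (0.0, 0.75, True)]
    )
    def test_recommended_ranges(self, k, s, valid):
        assert PCellParams(k=k, s=s).is_valid is valid
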