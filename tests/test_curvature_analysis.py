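"""Paraboloid curvature estimator, sign-rule labels, and region growth."""

import numpy as np
import pytest

from pcell import (
    PCellParams,
    VertexLabel,
    classify_vertices,
    extract_isosurface,
    grow_regions,
    paraboloid_curvatures,
    sample_grid,
)
from pcell.curvature_analysis import CurvatureMap, analyze_cell, region_statistics
from pcell.interface_io import PhantomSpec, make_phantom


def analytic_mean_curvature(points: np.ndarray) -> np.ndarray:
    """Exact mean curvature of the implicit surface f = cos x + cos y +
    cos z (canonical coordinates), oriented along -grad f."""
    g = -np.sin(points)
    hess = np.zeros((len(points), 3, 3))
    for i in range(3):
        hess[:, i, i] = -np.cos(points[:, i])
    gn = np.linalg.norm(g, axis=1)
    ghg = np.einsum("ni,nij,nj->n", g, hess, g)
    tr = np.einsum("nii->n", hess)
    return (ghg - gn**2 * tr) / (2 * gn**3)


class TestPhantomOracles:
    def test_sphere(self):
        ph = make_phantom(PhantomSpec("sphere", size=1.0))
        c = paraboloid_curvatures(ph.mesh)
        ok = c.fit_ok
        assert ok.mean() > 0.99
        # outward normals: both curvatures -1/r, i.e. a convex body
        assert np.median(np.abs(c.k1[ok] - ph.k1)) < 0.02
        assert np.median(np.abs(c.k2[ok] - ph.k2)) < 0.02

    def test_cylinder(self):
        ph = make_phantom(PhantomSpec("cylinder", size=1.0, density=60))
        c = paraboloid_curvatures(ph.mesh)
        ok = c.fit_ok
        assert np.median(np.abs(c.k1[ok] - 0.0)) < 0.02
        assert np.median(np.abs(c.k2[ok] - (-1.0))) < 0.02

    def test_saddle_at_origin(self):
        ph = make_phantom(PhantomSpec("saddle", size=0.5, density=40))
        c = paraboloid_curvatures(ph.mesh)
        i = np.argmin(
            np.linalg.norm(ph.mesh.vertices[:, :2], axis=1) + (~c.fit_ok) * 1e9
        )
        assert c.k1[i] == pytest.approx(1.0, abs=0.02)
        assert c.k2[i] == pytest.approx(-1.0, abs=0.02)
        assert c.H[i] == pytest.approx(0.0, abs=0.02)

    def test_error_decreases_under_refinement(self):
        errs = []
        for density in (40, 160):
            ph = make_phantom(PhantomSpec("sphere", size=1.0, density=density))
            c = paraboloid_curvatures(ph.mesh)
            errs.append(np.median(np.abs(np.abs(c.k1[c.fit_ok]) - 1.0)))
        assert errs[1] < errs[0]

    def test_derived_quantities_exact(self):
        ph = make_phantom(PhantomSpec("sphere", size=2.0))
        c = paraboloid_curvatures(ph.mesh)
        assert np.allclose(c.G, c.k1 * c.k2)
        assert np.allclose(c.H, 0.5 * (c.k1 + c.k2))
        assert np.allclose(c.R, np.hypot(c.k1, c.k2))
        assert (c.R >= np.abs(c.k1) - 1e-12).all()
        assert (c.k1 >= c.k2).all()


class TestClassification:
    @pytest.mark.parametrize(
        "k1, k2, expected",
        [
            (0.3, 0.1, VertexLabel.CONCAVE),
            (0.3, 0.0, VertexLabel.CONCAVE),
            (0.3, -0.1, VertexLabel.SADDLE_FLAT),
            (0.0, 0.0, VertexLabel.SADDLE_FLAT),
            (-0.1, -0.3, VertexLabel.CONVEX),
            (0.0, -0.3, VertexLabel.CONVEX),
        ],
    )
    def test_sign_rule(self, k1, k2, expected):
        c = CurvatureMap(
            k1=np.array([k1]), k2=np.array([k2]), fit_ok=np.array([True])
        )
        assert classify_vertices(c)[0] == expected.value

    def test_failed_fits_are_saddle(self):
        c = CurvatureMap(
            k1=np.array([0.5]), k2=np.array([0.2]), fit_ok=np.array([False])
        )
        assert classify_vertices(c)[0] == VertexLabel.SADDLE_FLAT.value

    def test_normal_flip_swaps_labels(self):
        """Flipping all normals exchanges concave and convex exactly."""
        p = PCellParams(k=-0.7, s=1.0, N=60)
        mesh = extract_isosurface(sample_grid(p), p.k)
        c = paraboloid_curvatures(mesh)
        labels = classify_vertices(c)
        mesh.vertex_normals = -mesh.vertex_normals
        flipped = classify_vertices(paraboloid_curvatures(mesh))
        swap = {VertexLabel.CONCAVE.value: VertexLabel.CONVEX.value,
                VertexLabel.CONVEX.value: VertexLabel.CONCAVE.value,
                VertexLabel.SADDLE_FLAT.value: VertexLabel.SADDLE_FLAT.value}
        assert (flipped == np.vectorize(swap.get)(labels)).all()


class TestRegions:
    @pytest.mark.parametrize("k, label", [(-0.7, "concave"), (0.7, "convex")])
    def test_eight_symmetric_regions(self, k, label):
        _, _, _, regions = analyze_cell(PCellParams(k=k, s=1.0, N=100))
        assert len(regions) == 8
        assert all(r.label == label for r in regions)
        areas = np.array([r.A_r_pct for r in regions])
        assert areas.max() / areas.min() - 1 < 0.05

    def test_standard_cell_has_no_regions(self):
        _, _, _, regions = analyze_cell(PCellParams(k=0.0, s=1.0, N=80))
        assert regions == []

    @pytest.mark.parametrize("n", [80, 120])
    def test_region_count_stable_under_resolution(self, n):
        _, _, _, regions = analyze_cell(PCellParams(k=-0.7, s=1.0, N=n))
        assert len(regions) == 8

    def test_region_vertices_connected_and_uniform(self):
        mesh, _, labels, regions = analyze_cell(PCellParams(k=-0.7, s=1.0, N=60))
        adj = mesh.vertex_adjacency()
        for r in regions:
            ids = set(r.vertex_ids.tolist())
            assert len({labels[i] for i in ids}) == 1
            # connectivity: breadth-first from one seed reaches all
            seen = {r.vertex_ids[0]}
            frontier = [r.vertex_ids[0]]
            while frontier:
                nxt = []
                for v in frontier:
                    for w in adj[v].indices:
                        if w in ids and w not in seen:
                            seen.add(w)
                            nxt.append(w)
                frontier = nxt
            assert seen == ids
            assert 0 < r.A_r_pct <= 100


class TestMinimalSurfaceCharacter:
    def test_estimator_matches_analytic_H(self, standard_mesh, standard_params):
        """Oracle equivalence: on the k=0 cell the paraboloid estimate of
        mean curvature tracks the exact implicit-surface value (the
        truncated nodal surface is only approximately minimal)."""
        c = paraboloid_curvatures(standard_mesh)
        ok = c.fit_ok
        h_true = analytic_mean_curvature(standard_mesh.vertices[ok])
        est = np.mean(np.abs(c.H[ok]))
        true = np.mean(np.abs(h_true))
        assert est == pytest.approx(true, rel=0.05)

    def test_saddle_character(self, standard_mesh):
        """Gaussian curvature non-positive almost everywhere at k=0."""
        c = paraboloid_curvatures(standard_mesh)
        assert np.mean(c.G[c.fit_ok] <= 0) >= 0.95

    def test_mean_H_small_relative_to_curvedness(self, standard_mesh):
        """|H| sits an order of magnitude below the curvedness scale and
        the signed mean cancels: the surface bows neither way."""
        c = paraboloid_curvatures(standard_mesh)
        ok = c.fit_ok
        assert np.mean(np.abs(c.H[ok])) < 0.15 * np.mean(c.R[ok])
        assert abs(np.mean(c.H[ok])) < 0.05 * np.mean(np.abs(c.H[ok]))


class TestRegionStatistics:
    @pytest.fixture(scope="class")
    def k_stats(self):
        grid = [PCellParams(k=k, s=1.0, N=70) for k in (-0.7, -0.5, -0.3, 0.3, 0.5, 0.7)]
        return region_statistics(grid)

    def test_curvedness_grows_with_abs_k(self, k_stats):
        df = k_stats.set_index("k")
        for a, b in [(0.3, 0.5), (0.5, 0.7), (-0.3, -0.5), (-0.5, -0.7)]:
            assert df.loc[b, "R_mean_L"] > df.loc[a, "R_mean_L"]

    def test_area_grows_with_abs_k(self, k_stats):
        df = k_stats.set_index("k")
        assert df.loc[0.7, "A_r_pct"] > df.loc[0.3, "A_r_pct"]
        assert df.loc[-0.7, "A_r_pct"] > df.loc[-0.3, "A_r_pct"]

    def test_s_effect_at_fixed_k(self):
        """Shrinking s concentrates curvature: R_mean up, A_r% down."""
        stats = region_statistics(
            [PCellParams(k=-0.5, s=s, N=70) for s in (0.85, 1.15)]
        ).set_index("s")
        assert stats.loc[0.85, "R_mean"] > stats.loc[1.15, "R_mean"]
        assert stats.loc[0.85, "A_r_pct"] < stats.loc[1.15, "A_r_pct"]
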