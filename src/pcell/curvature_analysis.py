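"""Per-vertex principal curvatures and concave/convex region detection.

Curvatures are estimated with the paraboloid method: around each mesh
vertex the surface is written as a height field over the local tangent
plane (span of two directions orthogonal to the oriented vertex
normal), a full quadratic

    h(u, v) = a u^2 + b u v + c v^2 + d u + e v + f0

is fitted by least squares to the two-ring neighborhood, and the
principal curvatures are recovered from the first and second
fundamental forms of the fitted Monge patch.  Heights are measured
along the vertex normal, so a patch bending towards the normal carries
positive curvature.

With normals oriented outward from the internal phase, pockets of the
surface that dent away from the pore (k < 0 cells) have both principal
curvatures positive and are labelled *concave*; bulges (k > 0 cells)
have both negative and are labelled *convex*; everything else —
including the nearly minimal k = 0 surface, where k1 ~ -k2 — is
saddle/flat.  Connected regions of uniformly concave or convex vertices
are grown over mesh edges and summarized by their area share A_r% of
the total surface and mean curvedness R_mean = mean sqrt(k1^2 + k2^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .implicit_cell import PCellParams, extract_isosurface, sample_grid
from .mesh import TriangleMesh

__all__ = [
    "CurvatureMap",
    "SurfaceRegion",
    "VertexLabel",
    "paraboloid_curvatures",
    "classify_vertices",
    "grow_regions",
    "region_statistics",
]

MIN_NEIGHBORS = 6
NOISE_AREA_FRACTION = 1e-3  # regions below 0.1% of S are artifacts


@dataclass
class CurvatureMap:
    """Principal curvatures per vertex, k1 >= k2 (units 1/mm).

    G = k1*k2 (Gaussian, 1/mm^2), H = (k1+k2)/2 (mean, 1/mm), and the
    curvedness R = sqrt(k1^2 + k2^2) follow exactly from k1, k2.
    ``fit_ok`` marks vertices with enough neighbors for a stable fit.
    """

    k1: np.ndarray
    k2: np.ndarray
    fit_ok: np.ndarray

    @property
    def G(self) -> np.ndarray:
        return self.k1 * self.k2

    @property
    def H(self) -> np.ndarray:
        return 0.5 * (self.k1 + self.k2)

    @property
    def R(self) -> np.ndarray:
        return np.sqrt(self.k1**2 + self.k2**2)

    def to_frame(self, mesh: TriangleMesh) -> pd.DataFrame:
        v = mesh.vertices
        return pd.DataFrame(
            {
                "vertex": np.arange(len(v)),
                "x": v[:, 0], "y": v[:, 1], "z": v[:, 2],
                "k1": self.k1, "k2": self.k2,
                "G": self.G, "H": self.H, "R": self.R,
                "fit_ok": self.fit_ok,
            }
        )


def _tangent_frame(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent pairs for unit normals (vectorized)."""
    n = normals
    helper = np.zeros_like(n)
    smallest = np.argmin(np.abs(n), axis=1)
    helper[np.arange(len(n)), smallest] = 1.0
    t1 = np.cross(n, helper)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(n, t1)
    return t1, t2


def _neighbor_lists(mesh: TriangleMesh, rings: int):
    adj = mesh.vertex_adjacency()
    reach = adj.copy()
    power = adj.copy()
    for _ in range(rings - 1):
        power = (power @ adj).astype(bool)
        reach = (reach + power).astype(bool)
    reach = reach.tolil()
    reach.setdiag(False)
    return reach.rows


def paraboloid_curvatures(mesh: TriangleMesh, rings: int = 2) -> CurvatureMap:
    """Least-squares paraboloid fit over the ``rings``-ring neighborhood.

    Vertices that cannot gather :data:`MIN_NEIGHBORS` neighbors even
    after widening to ``rings + 1`` are flagged ``fit_ok=False`` and get
    zero curvatures.
    """
    if mesh.vertex_normals is None:
        raise ValueError("mesh needs oriented vertex normals for curvature")
    V = mesh.n_vertices
    nbrs = _neighbor_lists(mesh, rings)
    wide = None
    t1, t2 = _tangent_frame(mesh.vertex_normals)
    k1 = np.zeros(V)
    k2 = np.zeros(V)
    ok = np.zeros(V, bool)
    verts = mesh.vertices
    normals = mesh.vertex_normals
    for i in range(V):
        idx = nbrs[i]
        if len(idx) < MIN_NEIGHBORS:
            if wide is None:
                wide = _neighbor_lists(mesh, rings + 1)
            idx = wide[i]
            if len(idx) < MIN_NEIGHBORS:
                continue
        rel = verts[idx] - verts[i]
        u = rel @ t1[i]
        v = rel @ t2[i]
        h = rel @ normals[i]
        A = np.column_stack([u * u, u * v, v * v, u, v, np.ones(len(u))])
        try:
            coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        except np.linalg.LinAlgError:
            continue
        a, b, c, d, e, _ = coef
        # fundamental forms of the Monge patch h(u, v)
        E = 1.0 + d * d
        F = d * e
        G2 = 1.0 + e * e
        w = np.sqrt(1.0 + d * d + e * e)
        Lf, Mf, Nf = 2.0 * a / w, b / w, 2.0 * c / w
        det1 = E * G2 - F * F
        K = (Lf * Nf - Mf * Mf) / det1
        H = (E * Nf - 2.0 * F * Mf + G2 * Lf) / (2.0 * det1)
        disc = max(H * H - K, 0.0)
        root = np.sqrt(disc)
        k1[i], k2[i] = H + root, H - root
        ok[i] = True
    return CurvatureMap(k1=k1, k2=k2, fit_ok=ok)


class VertexLabel(Enum):
    SADDLE_FLAT = 0
    CONCAVE = 1
    CONVEX = 2


def classify_vertices(curv: CurvatureMap) -> np.ndarray:
    """Sign-rule classification of each vertex.

    concave: min(k1, k2) >= 0 and max(k1, k2) > 0
    convex:  max(k1, k2) <= 0 and min(k1, k2) < 0
    everything else (mixed signs, flat, or failed fits): saddle/flat.
    """
    lo = np.minimum(curv.k1, curv.k2)
    hi = np.maximum(curv.k1, curv.k2)
    labels = np.full(len(lo), VertexLabel.SADDLE_FLAT.value, dtype=np.int8)
    labels[(lo >= 0) & (hi > 0)] = VertexLabel.CONCAVE.value
    labels[(hi <= 0) & (lo < 0)] = VertexLabel.CONVEX.value
    labels[~curv.fit_ok] = VertexLabel.SADDLE_FLAT.value
    return labels


@dataclass
class SurfaceRegion:
    """A maximal connected patch of uniformly concave or convex vertices."""

    label: str  # "concave" | "convex"
    vertex_ids: np.ndarray
    area: float  # mm^2
    A_r_pct: float  # area as % of total surface area S
    R_mean: float  # mean curvedness over the region, 1/mm
    R_mean_L: float  # dimensionless R_mean * L


def grow_regions(
    mesh: TriangleMesh,
    labels: np.ndarray,
    curv: CurvatureMap,
    min_area_fraction: float = NOISE_AREA_FRACTION,
) -> list[SurfaceRegion]:
    """Connected components of same-label vertices under edge adjacency.

    Regions smaller than ``min_area_fraction`` of the total area are
    discarded as tessellation noise.  Regions are returned sorted by
    descending area, ties broken by the smallest vertex id.
    """
    total_area = mesh.area()
    if total_area == 0:
        return []
    L = mesh.L or float(np.ptp(mesh.vertices, axis=0).max())
    vert_areas = mesh.vertex_areas()
    adj = mesh.vertex_adjacency().tocoo()
    keep = (labels[adj.row] == labels[adj.col]) & (
        labels[adj.row] != VertexLabel.SADDLE_FLAT.value
    )
    from scipy.sparse import coo_matrix

    sub = coo_matrix(
        (np.ones(keep.sum()), (adj.row[keep], adj.col[keep])),
        shape=adj.shape,
    )
    n_comp, comp = connected_components(sub, directed=False)
    regions = []
    labelled = labels != VertexLabel.SADDLE_FLAT.value
    for cid in np.unique(comp[labelled]):
        ids = np.flatnonzero((comp == cid) & labelled)
        if len(ids) == 0:
            continue
        area = float(vert_areas[ids].sum())
        if area < min_area_fraction * total_area:
            continue
        rmean = float(curv.R[ids].mean())
        name = VertexLabel(labels[ids[0]]).name.lower()
        regions.append(
            SurfaceRegion(
                label=name,
                vertex_ids=ids,
                area=area,
                A_r_pct=100.0 * area / total_area,
                R_mean=rmean,
                R_mean_L=rmean * L,
            )
        )
    regions.sort(key=lambda r: (-r.area, int(r.vertex_ids[0])))
    return regions


def analyze_cell(params: PCellParams, rings: int = 2):
    """Full curvature pipeline for one cell: mesh, map, labels, regions."""
    field = sample_grid(params)
    mesh = extract_isosurface(field, params.k)
    curv = paraboloid_curvatures(mesh, rings=rings)
    labels = classify_vertices(curv)
    regions = grow_regions(mesh, labels, curv)
    return mesh, curv, labels, regions


def region_statistics(params_grid: list[PCellParams], rings: int = 2) -> pd.DataFrame:
    """Aggregate region properties per (k, s): region count, and the
    mean over regions of R_mean, R_mean*L and A_r%."""
    rows = []
    for p in params_grid:
        _, _, _, regions = analyze_cell(p, rings=rings)
        if regions:
            rows.append(
                {
                    "k": p.k, "s": p.s, "L": p.L,
                    "n_regions": len(regions),
                    "label": regions[0].label,
                    "R_mean": float(np.mean([r.R_mean for r in regions])),
                    "R_mean_L": float(np.mean([r.R_mean_L for r in regions])),
                    "A_r_pct": float(np.mean([r.A_r_pct for r in regions])),
                }
            )
        else:
            rows.append(
                {
                    "k": p.k, "s": p.s, "L": p.L, "n_regions": 0,
                    "label": "none", "R_mean": 0.0, "R_mean_L": 0.0,
                    "A_r_pct": 0.0,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["s", "k"], kind="stable").reset_index(drop=True)
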