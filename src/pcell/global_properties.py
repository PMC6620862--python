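"""Global geometric properties of a P-cell.

Four quantities characterize the cell as a whole:

* volume fraction ``f_v`` — internal-phase volume over the cube volume,
* pore size ``p_s`` — radius of the largest sphere inscribable in the
  cell pore (the internal phase),
* surface ratio ``S/L^2`` — P-surface area over the squared cell side,
* specific surface ``(S/V) * L`` — area per unit internal volume, made
  dimensionless with the side length.

The internal phase is {f > k}: it contains the cell centre (where the
nodal function attains its maximum 3) and hosts the pore through which
tissue grows.  Volumes are estimated by occupancy counting with a
first-order interface correction and cross-checked with a
divergence-theorem estimate on the face-capped mesh; the pore radius
comes from an exact Euclidean distance transform with sub-voxel
corrections and a quadratic refinement of the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .implicit_cell import (
    DomainError,
    PCellParams,
    SampledField,
    extract_closed_internal_surface,
    extract_isosurface,
    sample_grid,
)
from .mesh import TriangleMesh

__all__ = [
    "GlobalProperties",
    "PoreSize",
    "volume_fraction",
    "pore_size",
    "surface_ratio",
    "area_volume_ratio",
    "surface_distance",
    "compute_properties",
    "property_table",
]


def surface_distance(field: SampledField, k: float) -> np.ndarray:
    """Signed distance from every grid node to the surface {f = k} (mm).

    Positive inside the internal phase {f > k}.  Built from the exact
    Euclidean distance transform to the opposite-phase nodes, with a
    first-order sub-voxel correction: the nearest opposite node q does
    not sit on the surface, which lies (|f(q) - k| / |grad f(q)|) closer
    along the connecting direction.
    """
    f = field.values
    internal = f > k
    h = field.spacing
    grad = np.maximum(field.gradient_magnitude(), 1e-12)

    def one_side(mask):
        d, idx = distance_transform_edt(mask, sampling=h, return_indices=True)
        nearest = tuple(idx)
        delta = np.clip(np.abs(f[nearest] - k) / grad[nearest], 0.0, h)
        return np.maximum(d - delta, 0.0)

    d_in = one_side(internal)
    d_out = one_side(~internal)
    return np.where(internal, d_in, -d_out)


def volume_fraction(field: SampledField, k: float, method: str = "interface") -> float:
    """Volume fraction f_v of the internal phase {f > k}.

    ``method="interface"`` (default): per-voxel occupancy with a linear
    sub-voxel correction derived from the field linearization
    (f - k)/|grad f|.  ``method="mesh"``: independent estimate via the
    divergence theorem on the face-capped internal boundary mesh.  The
    two agree to a fraction of a percent at production resolution.
    """
    f = field.values
    vmin, vmax = f.min(), f.max()
    if k >= vmax:
        warnings.warn(f"isovalue k={k} at or above field maximum; f_v = 0")
        return 0.0
    if k <= vmin:
        warnings.warn(f"isovalue k={k} at or below field minimum; f_v = 1")
        return 1.0
    if method == "mesh":
        mesh = extract_closed_internal_surface(f, k, field.L)
        tm = mesh.to_trimesh()
        return float(abs(tm.volume) / field.L**3)
    if method != "interface":
        raise ValueError(f"unknown method {method!r}")
    h = field.spacing
    g = (f - k) / np.maximum(field.gradient_magnitude(), 1e-12)
    # mean approximate signed distance over the 8 corners of each voxel
    gc = (
        g[:-1, :-1, :-1] + g[1:, :-1, :-1] + g[:-1, 1:, :-1] + g[:-1, :-1, 1:]
        + g[1:, 1:, :-1] + g[1:, :-1, 1:] + g[:-1, 1:, 1:] + g[1:, 1:, 1:]
    ) / 8.0
    phi = np.clip(0.5 + gc / h, 0.0, 1.0)
    return float(phi.mean())


@dataclass(frozen=True)
class PoreSize:
    """Largest inscribed sphere of the cell pore."""

    radius: float
    center: tuple[float, float, float]

    def __float__(self) -> float:
        return self.radius


def _surface_samples(mesh) -> np.ndarray:
    """Dense point sampling of a mesh: vertices, edge midpoints and
    face centroids (spacing roughly half the tessellation edge)."""
    v, f = mesh.vertices, mesh.faces
    mids = np.concatenate(
        [
            0.5 * (v[f[:, 0]] + v[f[:, 1]]),
            0.5 * (v[f[:, 1]] + v[f[:, 2]]),
            0.5 * (v[f[:, 2]] + v[f[:, 0]]),
        ]
    )
    centroids = v[f].mean(axis=1)
    return np.concatenate([v, mids, centroids])


def pore_size(field: SampledField, k: float) -> PoreSize:
    """Radius of the maximum sphere inscribable in the internal phase.

    The corrected distance transform locates the basin of the maximum;
    the radius is then refined by maximizing the distance to a dense
    point sampling of the extracted surface (simplex search), which
    removes the O(h) bias of node-based distances.
    """
    internal = field.values > k
    if not internal.any():
        raise DomainError(f"internal phase empty at k={k}")
    sd = surface_distance(field, k)
    i0 = np.unravel_index(int(np.argmax(sd)), sd.shape)
    ax = field.axis()
    center = np.array([ax[i0[0]], ax[i0[1]], ax[i0[2]]])
    radius = float(sd[i0])

    from scipy.optimize import minimize
    from scipy.spatial import cKDTree

    mesh = extract_isosurface(field, k)
    if mesh.n_faces == 0:
        return PoreSize(radius, tuple(float(c) for c in center))
    tree = cKDTree(_surface_samples(mesh))
    half = field.L / 2.0

    def neg_dist(x):
        if np.any(np.abs(x) > half):
            return 0.0
        return -float(tree.query(x)[0])

    res = minimize(
        neg_dist, center, method="Nelder-Mead",
        options={"xatol": 1e-4 * field.L, "fatol": 1e-6 * field.L, "maxiter": 400},
    )
    if -res.fun > radius:
        radius = float(-res.fun)
        center = np.asarray(res.x)
    return PoreSize(radius, tuple(float(c) for c in center))


def surface_ratio(mesh: TriangleMesh, L: float) -> float:
    """Dimensionless surface ratio S / L^2."""
    if mesh.n_faces == 0:
        raise ValueError("empty mesh has no surface ratio")
    return mesh.area() / L**2


def area_volume_ratio(mesh: TriangleMesh, f_v: float, L: float) -> float:
    """Specific surface area (S / V_internal) * L, dimensionless.

    Equals surface_ratio / f_v by definition.
    """
    if f_v <= 0:
        raise DomainError("area-volume ratio undefined for empty internal phase")
    return surface_ratio(mesh, L) / f_v


@dataclass(frozen=True)
class GlobalProperties:
    """All global properties of one P-cell."""

    params: PCellParams
    f_v: float
    V_P_surface: float
    V_unit_cell: float
    p_s: float
    p_s_over_L: float
    S: float
    surface_ratio: float
    area_volume_ratio: float


def compute_properties(
    params: PCellParams, field: SampledField | None = None
) -> GlobalProperties:
    """Sample, extract, and measure one cell end to end."""
    if field is None:
        field = sample_grid(params)
    mesh = extract_isosurface(field, params.k)
    f_v = volume_fraction(field, params.k)
    ps = pore_size(field, params.k)
    sr = surface_ratio(mesh, params.L)
    return GlobalProperties(
        params=params,
        f_v=f_v,
        V_P_surface=f_v * params.L**3,
        V_unit_cell=params.L**3,
        p_s=ps.radius,
        p_s_over_L=ps.radius / params.L,
        S=sr * params.L**2,
        surface_ratio=sr,
        area_volume_ratio=sr / f_v if f_v > 0 else np.nan,
    )


_TABLE_COLUMNS = [
    "k", "s", "L", "N", "f_v", "V_P_surface", "V_unit_cell",
    "p_s", "p_s_over_L", "S", "surface_ratio", "area_volume_ratio",
    "k_in_range", "s_in_range", "error",
]


def property_table(params_grid: list[PCellParams]) -> pd.DataFrame:
    """One row of global properties per parameter combination.

    Individual failures are recorded in the ``error`` column and the
    sweep continues.  Rows are sorted by (s, k) for deterministic output.
    """
    rows = []
    for p in params_grid:
        row = {
            "k": p.k, "s": p.s, "L": p.L, "N": p.N,
            "k_in_range": p.k_in_range, "s_in_range": p.s_in_range,
            "error": "",
        }
        try:
            g = compute_properties(p)
            row.update(
                f_v=g.f_v, V_P_surface=g.V_P_surface, V_unit_cell=g.V_unit_cell,
                p_s=g.p_s, p_s_over_L=g.p_s_over_L, S=g.S,
                surface_ratio=g.surface_ratio, area_volume_ratio=g.area_volume_ratio,
            )
        except Exception as exc:  # per-row failure, sweep continues
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return df.sort_values(["s", "k"], kind="stable").reset_index(drop=True)
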