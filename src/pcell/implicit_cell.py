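"""Nodal-equation modeling of the Schwarz Primitive (P) unit cell.

The P-surface is represented by the leading-term nodal approximation

    f(x, y, z) = cos(x/s) + cos(y/s) + cos(z/s) = k

evaluated in canonical coordinates on the cube [-pi, pi]^3 and mapped
affinely onto a physical cubic cell of side ``L`` (mm).  The level
offset ``k`` selects the level surface and the scale parameter ``s``
acts as a uniform scaling of the surface about the cell barycentre
followed by truncation with the cube.  Working in canonical coordinates
makes every dimensionless property exactly invariant under a change of
``L``.

The module samples the field on a regular grid, extracts the level
surface with marching cubes, and checks the topological integrity of
the resulting cell (a single sheet with one circular opening per cube
face).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage import measure

from .mesh import TriangleMesh

TWO_PI = 2.0 * np.pi

__all__ = [
    "PCellParams",
    "SampledField",
    "IntegrityReport",
    "DomainError",
    "eval_field",
    "sample_grid",
    "extract_isosurface",
    "extract_closed_internal_surface",
    "check_integrity",
    "scale_params",
]


class DomainError(ValueError):
    """Raised when an input lies outside the mathematical domain of an
    operation (non-finite coordinate, isovalue beyond the field range,
    non-positive scale factor, ...)."""


@dataclass(frozen=True)
class PCellParams:
    """Analytical parameters of one P-cell.

    Attributes
    ----------
    k : float
        Level-set offset (dimensionless).  The recommended range for a
        topologically intact cell at s = 1 is the open interval (-1, 1).
    s : float
        Scale parameter (dimensionless).  Recommended range [0.75, 1.5]
        at k = 0; outside it the cell loses its integrity.
    L : float
        Side length of the cubic cell in mm (default 2*pi).
    N : int
        Grid points per axis for sampling (default 100).
    """

    k: float = 0.0
    s: float = 1.0
    L: float = TWO_PI
    N: int = 100

    def __post_init__(self):
        if not (np.isfinite(self.k) and np.isfinite(self.s) and np.isfinite(self.L)):
            raise DomainError("P-cell parameters must be finite")
        if self.N < 3:
            raise ValueError(f"grid resolution N must be >= 3, got {self.N}")
        if self.L <= 0:
            raise ValueError(f"cell side L must be positive, got {self.L}")
        if self.s <= 0:
            raise ValueError(f"scale parameter s must be positive, got {self.s}")

    @property
    def k_in_range(self) -> bool:
        """k strictly inside (-1, 1), the intact range at s = 1."""
        return -1.0 < self.k < 1.0

    @property
    def s_in_range(self) -> bool:
        """s inside [0.75, 1.5], the intact range at k = 0."""
        return 0.75 <= self.s <= 1.5

    @property
    def is_valid(self) -> bool:
        """Both parameters inside their recommended intervals."""
        return self.k_in_range and self.s_in_range

    @property
    def spacing(self) -> float:
        """Grid spacing L/(N-1) in mm."""
        return self.L / (self.N - 1)


def eval_field(x, y, z, params: PCellParams):
    """Evaluate the nodal function at physical coordinates (mm).

    Coordinates are mapped to canonical coordinates c = 2*pi*x/L before
    evaluating cos(c/s) so that the surface geometry scales exactly with
    the cell side.  Returns values in [-3, 3].
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(z).all()):
        raise DomainError("coordinates must be finite")
    c = TWO_PI / (params.L * params.s)
    out = np.cos(c * x) + np.cos(c * y) + np.cos(c * z)
    return float(out) if out.ndim == 0 else out


def field_gradient(points: np.ndarray, params: PCellParams) -> np.ndarray:
    """Analytic gradient of the nodal function wrt physical coordinates."""
    c = TWO_PI / (params.L * params.s)
    return -c * np.sin(c * np.asarray(points, float))


@dataclass
class SampledField:
    """Scalar field sampled on a node-centered N^3 grid over the cell.

    The grid spans [-L/2, L/2]^3 inclusive of the endpoints, with
    spacing L/(N-1).  ``params`` is kept when the field comes from the
    nodal equation so that gradients can be evaluated analytically.
    """

    values: np.ndarray
    L: float
    params: PCellParams | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3 or len(set(self.values.shape)) != 1:
            raise ValueError("values must be a cubic N^3 array")
        if not np.isfinite(self.values).all():
            raise ValueError("field values must be finite")

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def spacing(self) -> float:
        return self.L / (self.N - 1)

    @property
    def origin(self) -> np.ndarray:
        return np.full(3, -self.L / 2.0)

    def axis(self) -> np.ndarray:
        return np.linspace(-self.L / 2.0, self.L / 2.0, self.N)

    def gradient_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-node gradient components (analytic when possible)."""
        if self.params is not None:
            ax = self.axis()
            c = TWO_PI / (self.L * self.params.s)
            g1 = -c * np.sin(c * ax)
            gx = np.broadcast_to(g1[:, None, None], self.values.shape)
            gy = np.broadcast_to(g1[None, :, None], self.values.shape)
            gz = np.broadcast_to(g1[None, None, :], self.values.shape)
            return gx, gy, gz
        return tuple(np.gradient(self.values, self.spacing))

    def gradient_magnitude(self) -> np.ndarray:
        gx, gy, gz = self.gradient_arrays()
        return np.sqrt(gx**2 + gy**2 + gz**2)

    def normals_at(self, points: np.ndarray) -> np.ndarray:
        """Unit normals at arbitrary points, oriented outward from the
        internal phase {f > k}, i.e. along -grad f."""
        points = np.asarray(points, float)
        if self.params is not None:
            g = field_gradient(points, self.params)
        else:
            gx, gy, gz = (np.asarray(a) for a in self.gradient_arrays())
            from scipy.ndimage import map_coordinates

            idx = (points - self.origin) / self.spacing
            g = np.stack(
                [map_coordinates(a, idx.T, order=1, mode="nearest") for a in (gx, gy, gz)],
                axis=1,
            )
        n = -g
        norm = np.linalg.norm(n, axis=-1, keepdims=True)
        norm[norm < 1e-300] = 1.0
        return n / norm


def sample_grid(params: PCellParams) -> SampledField:
    """Sample the nodal function on the cell's node-centered grid."""
    ax = np.linspace(-params.L / 2.0, params.L / 2.0, params.N)
    c = TWO_PI / (params.L * params.s)
    f1 = np.cos(c * ax)
    values = f1[:, None, None] + f1[None, :, None] + f1[None, None, :]
    return SampledField(values, params.L, params)


def _resolve_level(values: np.ndarray, level: float) -> float:
    """Perturb a level that collides with sampled values to avoid
    ambiguous marching-cubes cases (deterministic, 1e-9 nudge)."""
    if np.min(np.abs(values - level)) < 1e-12:
        return level + 1e-9
    return level


def extract_isosurface(field: SampledField, k: float) -> TriangleMesh:
    """Extract the level surface {f = k} clipped to the cube.

    Returns a cleaned triangle mesh with vertex normals oriented outward
    from the internal phase {f > k}.  Raises :class:`DomainError` when k
    lies outside the sampled value range.
    """
    vmin, vmax = field.values.min(), field.values.max()
    if not (vmin < k < vmax):
        raise DomainError(
            f"isovalue k={k} outside the field value range [{vmin:.6g}, {vmax:.6g}]"
        )
    level = _resolve_level(field.values, k)
    h = field.spacing
    try:
        verts, faces, _, _ = measure.marching_cubes(
            field.values, level=level, spacing=(h, h, h)
        )
    except (ValueError, RuntimeError) as exc:  # empty level set
        warnings.warn(f"empty level set at k={k}: {exc}")
        return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), int), L=field.L)
    verts = verts + field.origin
    mesh = TriangleMesh(verts, faces.astype(np.int64), L=field.L).cleaned()
    mesh.vertex_normals = field.normals_at(mesh.vertices)
    _orient_faces(mesh)
    return mesh


def _orient_faces(mesh: TriangleMesh) -> None:
    """Flip face winding where it disagrees with the vertex normals."""
    if mesh.n_faces == 0 or mesh.vertex_normals is None:
        return
    fn = mesh.face_normals()
    vn = mesh.vertex_normals[mesh.faces].mean(axis=1)
    flip = np.einsum("ij,ij->i", fn, vn) < 0
    mesh.faces[flip] = mesh.faces[flip][:, ::-1]


def extract_closed_internal_surface(
    values: np.ndarray, level: float, L: float, origin: np.ndarray | None = None
) -> TriangleMesh:
    """Watertight boundary of the internal phase {f > level} inside the cube.

    The node grid is padded with one external layer so marching cubes
    closes the surface across the cube faces; pad-layer vertices are
    then clamped back onto the faces.  The result bounds the internal
    region and is suitable for divergence-theorem volume estimates.
    """
    values = np.asarray(values, float)
    N = values.shape[0]
    h = L / (N - 1)
    if origin is None:
        origin = np.full(3, -L / 2.0)
    pad_value = values.min() - 1.0
    padded = np.pad(values, 1, constant_values=pad_value)
    level = _resolve_level(padded, level)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=level, spacing=(h, h, h), gradient_direction="descent"
    )
    verts = verts + (origin - h)
    lo, hi = origin, origin + (N - 1) * h
    verts = np.clip(verts, lo, hi)
    mesh = TriangleMesh(verts, faces.astype(np.int64), L=L).cleaned()
    return mesh


@dataclass(frozen=True)
class IntegrityReport:
    """Topological integrity of a P-cell mesh.

    A cell passes when the surface is a single connected sheet whose
    boundary consists of exactly six loops, one lying on each cube
    face — the standard P-cell topology with open lateral ducts.
    """

    n_components: int
    n_boundary_loops: int
    loops_per_face: tuple[int, int, int, int, int, int]
    nonmanifold: bool = False

    @property
    def passes(self) -> bool:
        return (
            not self.nonmanifold
            and self.n_components == 1
            and self.n_boundary_loops == 6
            and self.loops_per_face == (1, 1, 1, 1, 1, 1)
        )


def check_integrity(mesh: TriangleMesh, tol: float = 1e-6) -> IntegrityReport:
    """Count connected components and per-face boundary loops.

    A loop counts for a cube face only when all its vertices lie on that
    face plane within ``tol * L``; a loop spanning several faces (the
    signature of merged lateral openings) is assigned to none, which
    fails the per-face criterion.
    """
    if mesh.n_faces == 0:
        raise ValueError("cannot check integrity of an empty mesh")
    if mesh.L is None:
        raise ValueError("mesh has no cell side L recorded")
    L = mesh.L
    half = L / 2.0
    atol = tol * L
    loops = mesh.boundary_loops()
    per_face = [0] * 6
    for loop in loops:
        pts = mesh.vertices[loop]
        for axis in range(3):
            for j, side in enumerate((-half, half)):
                if np.all(np.abs(pts[:, axis] - side) < atol):
                    per_face[2 * axis + j] += 1
                    break
            else:
                continue
            break
    return IntegrityReport(
        n_components=mesh.n_components(),
        n_boundary_loops=len(loops),
        loops_per_face=tuple(per_face),
        nonmanifold=mesh.has_nonmanifold_edges(),
    )


def scale_params(params: PCellParams, factor: float) -> PCellParams:
    """Uniformly scale the cell about its barycentre.

    Only the physical side L changes; the canonical geometry — and with
    it every dimensionless property (f_v, S/L^2, p_s/L) — is unchanged.
    """
    if not np.isfinite(factor) or factor <= 0:
        raise DomainError(f"scale factor must be positive and finite, got {factor}")
    return replace(params, L=params.L * factor)
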