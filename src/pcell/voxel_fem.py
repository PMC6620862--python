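"""Voxel finite-element stiffness assessment of solid P-cells.

Each occupied voxel becomes an eight-node trilinear brick element with
the isotropic linear-elastic material matrix built from (E_s, nu_s).
Apparent moduli follow the reaction-force definition used for porous
cells: a uniform displacement is prescribed on one cell face, the
opposite face is supported, and

    E = (F_R / A) / eps_A

with F_R the total reaction on the loaded face, A = L^2 the cell cross
section and eps_A the applied strain (default 0.1%).

Compression uses frictionless kinematic supports (axial restraint on
the bottom face plus minimal in-plane pinning), so a homogeneous full
cube reproduces E_s exactly — the patch test.  Shear uses the clamped
boundary conditions of the experiment it models: the -x face fully
fixed, the +x face driven in y, and the +/-y faces restrained in x;
the resulting G_app is an apparent, not pure, shear modulus.

Lengths are mm and moduli GPa, so forces come out in kN and stresses in
GPa (von Mises is reported in MPa).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.ndimage import label as nd_label
from scipy.sparse.linalg import cg, splu, spilu, LinearOperator

from .solid_design import VoxelSolid

logger = logging.getLogger("pcell")

__all__ = [
    "Material",
    "ElasticitySolution",
    "TI6AL4V",
    "hex_element_stiffness",
    "elasticity_matrix",
    "assemble",
    "solve_compression",
    "solve_shear",
    "von_mises_field",
    "von_mises_from_stress",
    "stiffness_porosity_curve",
]


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic constituent material.

    The shear modulus ``G_s`` is kept separately because it is used only
    to normalize apparent shear moduli; the elasticity matrix is built
    from (E_s, nu_s).
    """

    E_s: float  # GPa
    G_s: float  # GPa
    nu_s: float

    def __post_init__(self):
        if self.E_s <= 0:
            raise ValueError("elastic modulus must be positive")
        if not 0.0 <= self.nu_s < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")


#: Ti-6Al-4V, the workhorse biocompatible alloy for AM bone scaffolds.
TI6AL4V = Material(E_s=110.0, G_s=40.0, nu_s=0.3)


def elasticity_matrix(material: Material) -> np.ndarray:
    """6x6 isotropic stiffness in Voigt order (xx, yy, zz, yz, xz, xy)."""
    E, nu = material.E_s, material.nu_s
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D

# local node order of the hex8 element: corners of the unit voxel
_LOCAL_NODES = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ]
)
_XI = _LOCAL_NODES * 2.0 - 1.0  # natural coordinates of the nodes


def _b_matrix(xi: np.ndarray, h: float) -> np.ndarray:
    """Strain-displacement matrix (6 x 24) at natural point xi."""
    dN = np.empty((8, 3))
    for a in range(8):
        xa = _XI[a]
        dN[a, 0] = 0.125 * xa[0] * (1 + xi[1] * xa[1]) * (1 + xi[2] * xa[2])
        dN[a, 1] = 0.125 * (1 + xi[0] * xa[0]) * xa[1] * (1 + xi[2] * xa[2])
        dN[a, 2] = 0.125 * (1 + xi[0] * xa[0]) * (1 + xi[1] * xa[1]) * xa[2]
    dN *= 2.0 / h  # d xi / dx for a cube of side h
    B = np.zeros((6, 24))
    for a in range(8):
        c = 3 * a
        B[0, c] = dN[a, 0]
        B[1, c + 1] = dN[a, 1]
        B[2, c + 2] = dN[a, 2]
        B[3, c + 1] = dN[a, 2]
        B[3, c + 2] = dN[a, 1]
        B[4, c] = dN[a, 2]
        B[4, c + 2] = dN[a, 0]
        B[5, c] = dN[a, 1]
        B[5, c + 1] = dN[a, 0]
    return B


def hex_element_stiffness(material: Material, h: float) -> np.ndarray:
    """24x24 stiffness of a cubic trilinear brick of side h (mm),
    integrated with 2x2x2 Gauss quadrature (exact for this element)."""
    D = elasticity_matrix(material)
    g = 1.0 / np.sqrt(3.0)
    detJ = (h / 2.0) ** 3
    Ke = np.zeros((24, 24))
    for xi in _XI * g:
        B = _b_matrix(xi, h)
        Ke += B.T @ D @ B * detJ
    return Ke


@dataclass
class _FEModel:
    """Assembled voxel model: node numbering, stiffness, geometry."""

    solid: VoxelSolid
    material: Material
    K: sparse.csr_matrix
    edof: np.ndarray  # (nel, 24)
    elements: np.ndarray  # (nel, 3) voxel indices
    node_grid_id: np.ndarray  # (M+1)^3 -> node id or -1
    node_index: np.ndarray  # (n_nodes, 3) grid indices
    Ke: np.ndarray

    @property
    def n_dofs(self) -> int:
        return self.K.shape[0]

    def face_nodes(self, axis: int, end: int) -> np.ndarray:
        """Node ids on a cell face (end=0 low, end=1 high)."""
        M = self.solid.M
        target = 0 if end == 0 else M
        return np.flatnonzero(self.node_index[:, axis] == target)


def _percolating(occ: np.ndarray, axis: int) -> tuple[np.ndarray, int]:
    """Keep only components connecting both faces along ``axis``."""
    labels, n = nd_label(occ)
    if n == 0:
        raise ValueError("empty solid: nothing to analyze")
    low = np.unique(np.take(labels, 0, axis=axis))
    high = np.unique(np.take(labels, -1, axis=axis))
    good = (set(low) & set(high)) - {0}
    if not good:
        raise ValueError("structure does not connect the loading faces")
    keep = np.isin(labels, sorted(good))
    removed = int(occ.sum() - keep.sum())
    if removed:
        logger.info("removed %d floating voxels (%d components kept)", removed, len(good))
    return keep, removed


def assemble(solid: VoxelSolid, material: Material, load_axis: int = 2) -> _FEModel:
    """Build the global stiffness system for the load-bearing solid.

    Floating components (not connecting the two constraint faces along
    ``load_axis``) are removed with a logged count before assembly.
    """
    occ, _ = _percolating(solid.occupancy, load_axis)
    clean = VoxelSolid(occ, solid.voxel_size)
    M = clean.M
    elements = np.argwhere(occ)
    nel = len(elements)
    node_grid_id = np.full((M + 1, M + 1, M + 1), -1, dtype=np.int64)
    corner = elements[:, None, :] + _LOCAL_NODES[None, :, :]  # (nel, 8, 3)
    flat = (
        corner[..., 0] * (M + 1) ** 2 + corner[..., 1] * (M + 1) + corner[..., 2]
    )
    used = np.unique(flat)
    node_grid_id.ravel()[used] = np.arange(len(used))
    node_index = np.stack(
        np.unravel_index(used, (M + 1, M + 1, M + 1)), axis=1
    )
    conn = node_grid_id.ravel()[flat]  # (nel, 8)
    edof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(nel, 24)
    Ke = hex_element_stiffness(material, clean.voxel_size)
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()
    data = np.broadcast_to(Ke.ravel(), (nel, 576)).ravel()
    n_dofs = 3 * len(used)
    K = sparse.coo_matrix((data, (rows, cols)), shape=(n_dofs, n_dofs)).tocsr()
    return _FEModel(
        solid=clean,
        material=material,
        K=K,
        edof=edof,
        elements=elements,
        node_grid_id=node_grid_id,
        node_index=node_index,
        Ke=Ke,
    )


@dataclass
class ElasticitySolution:
    """Converged displacement solution with the derived apparent modulus."""

    model: _FEModel = field(repr=False)
    displacements: np.ndarray = field(repr=False)  # (n_nodes, 3), mm
    F_R: float  # reaction on the driven face, N
    A: float  # cross-section, mm^2
    eps_A: float  # applied strain
    modulus: float  # apparent E or G_app, GPa
    modulus_ratio: float  # normalized by E_s or G_s
    mode: str  # "compression" | "shear"
    residual: float


_DIRECT_LIMIT = 90_000  # dofs; larger systems go to preconditioned CG


def _solve_system(K: sparse.csr_matrix, prescribed: dict[int, float]):
    n = K.shape[0]
    u = np.zeros(n)
    pres = np.fromiter(prescribed.keys(), dtype=np.int64)
    vals = np.fromiter((prescribed[i] for i in pres), dtype=float)
    u[pres] = vals
    free = np.setdiff1d(np.arange(n), pres)
    rhs = -K[free][:, pres] @ vals
    Kff = K[free][:, free].tocsc()
    if len(free) <= _DIRECT_LIMIT:
        uf = splu(Kff).solve(rhs)
    else:
        ilu = spilu(Kff, drop_tol=1e-5, fill_factor=12)
        Mop = LinearOperator(Kff.shape, ilu.solve)
        uf, info = cg(Kff, rhs, rtol=1e-10, maxiter=20_000, M=Mop)
        if info != 0:
            raise RuntimeError(f"CG failed to converge (info={info})")
    u[free] = uf
    resid = float(
        np.linalg.norm(Kff @ uf - rhs) / max(np.linalg.norm(rhs), 1e-300)
    )
    return u, resid


def _reaction(K, u, dofs) -> float:
    return float((K[dofs] @ u).sum())


def solve_compression(
    solid: VoxelSolid,
    material: Material,
    eps_A: float = 0.001,
    axis: int = 2,
    model: _FEModel | None = None,
) -> ElasticitySolution:
    """Uniaxial compression: prescribed axial displacement on the top
    face, frictionless axial support on the bottom face, minimal
    in-plane pinning to remove rigid-body motion."""
    if model is None:
        model = assemble(solid, material, load_axis=axis)
    L = model.solid.L
    bot = model.face_nodes(axis, 0)
    top = model.face_nodes(axis, 1)
    prescribed = {int(3 * n + axis): 0.0 for n in bot}
    delta = -eps_A * L
    prescribed.update({int(3 * n + axis): delta for n in top})
    # in-plane pinning on the bottom face: block both translations and
    # the rotation about the load axis without constraining Poisson
    # expansion more than necessary
    inplane = [a for a in range(3) if a != axis]
    pin = bot[np.lexsort([model.node_index[bot, a] for a in inplane])]
    n0 = int(pin[0])
    for a in inplane:
        prescribed[3 * n0 + a] = 0.0
    for cand in pin[1:]:
        if model.node_index[cand, inplane[0]] != model.node_index[n0, inplane[0]]:
            prescribed[3 * int(cand) + inplane[1]] = 0.0
            break
    u, resid = _solve_system(model.K, prescribed)
    top_dofs = 3 * top + axis
    F = abs(_reaction(model.K, u, top_dofs))  # kN (GPa * mm^2)
    A = L * L
    E_app = (F / A) / eps_A
    return ElasticitySolution(
        model=model,
        displacements=u.reshape(-1, 3),
        F_R=F * 1e3,  # N
        A=A,
        eps_A=eps_A,
        modulus=E_app,
        modulus_ratio=E_app / material.E_s,
        mode="compression",
        residual=resid,
    )


def solve_shear(
    solid: VoxelSolid,
    material: Material,
    eps_A: float = 0.001,
    model: _FEModel | None = None,
) -> ElasticitySolution:
    """Clamped shear: -x face fully fixed, +x face driven in y by
    eps_A * L, +/-y faces restrained in x."""
    if model is None:
        model = assemble(solid, material, load_axis=0)
    L = model.solid.L
    fixed = model.face_nodes(0, 0)
    driven = model.face_nodes(0, 1)
    ytop = model.face_nodes(1, 1)
    ybot = model.face_nodes(1, 0)
    prescribed: dict[int, float] = {}
    for n in fixed:
        for a in range(3):
            prescribed[int(3 * n + a)] = 0.0
    delta = eps_A * L
    for n in driven:
        prescribed[int(3 * n + 1)] = delta
    for n in np.concatenate([ytop, ybot]):
        prescribed.setdefault(int(3 * n + 0), 0.0)
    u, resid = _solve_system(model.K, prescribed)
    driven_dofs = 3 * driven + 1
    F = abs(_reaction(model.K, u, driven_dofs))
    A = L * L
    G_app = (F / A) / eps_A
    return ElasticitySolution(
        model=model,
        displacements=u.reshape(-1, 3),
        F_R=F * 1e3,
        A=A,
        eps_A=eps_A,
        modulus=G_app,
        modulus_ratio=G_app / material.G_s,
        mode="shear",
        residual=resid,
    )


def von_mises_from_stress(stress: np.ndarray) -> np.ndarray:
    """Von Mises invariant from Voigt stresses (..., 6)."""
    s = np.asarray(stress, float)
    sx, sy, sz, tyz, txz, txy = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (tyz**2 + txz**2 + txy**2)
    )


def von_mises_field(solution: ElasticitySolution) -> np.ndarray:
    """Per-element von Mises stress (MPa) at the element centroid."""
    model = solution.model
    D = elasticity_matrix(model.material)
    B0 = _b_matrix(np.zeros(3), model.solid.voxel_size)
    u = solution.displacements.ravel()
    ue = u[model.edof]  # (nel, 24)
    strain = ue @ B0.T  # (nel, 6)
    stress = strain @ D.T  # GPa
    return von_mises_from_stress(stress) * 1e3  # MPa


def reaction_balance(solution: ElasticitySolution, axis: int | None = None) -> float:
    """Relative imbalance between the reactions on the two constrained
    faces (should vanish for a converged solution)."""
    model = solution.model
    K = model.K
    u = solution.displacements.ravel()
    if solution.mode == "compression":
        ax = 2 if axis is None else axis
        dof_a = 3 * model.face_nodes(ax, 1) + ax
        dof_b = 3 * model.face_nodes(ax, 0) + ax
    else:
        dof_a = 3 * model.face_nodes(0, 1) + 1
        dof_b = 3 * model.face_nodes(0, 0) + 1
    fa = _reaction(K, u, dof_a)
    fb = _reaction(K, u, dof_b)
    return abs(fa + fb) / max(abs(fa), 1e-300)


def stiffness_porosity_curve(
    specs,
    material: Material,
    N: int | None = None,
    include_shear: bool = False,
):
    """Stiffness-porosity table, one row per solid cell spec.

    Each spec is solidified on its own grid (resolution ``N`` overrides
    the spec's), compressed (and optionally sheared), and reported as
    (k, s, t, P, E/E_s[, G_app/G_s], F_R) with a family label: "k" for
    cells on the k-sweep (s = 1), "s" for the s-sweep (k = 0).
    """
    import pandas as pd

    from .implicit_cell import sample_grid
    from .solid_design import porosity, solidify

    rows = []
    for spec in specs:
        p = spec.params
        if N is not None:
            from dataclasses import replace

            p = replace(p, N=N)
        row = {
            "k": p.k, "s": p.s, "L": p.L, "t": spec.t,
            "family": "k" if p.s == 1.0 else ("s" if p.k == 0.0 else "ks"),
            "error": "",
        }
        try:
            fld = sample_grid(p)
            solid, _ = solidify(fld, p.k, spec.t)
            row["P"] = porosity(solid)
            sol = solve_compression(solid, material)
            row["E_over_Es"] = sol.modulus_ratio
            row["F_R"] = sol.F_R
            if include_shear:
                row["G_over_Gs"] = solve_shear(solid, material).modulus_ratio
        except Exception as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
            logger.warning("stiffness sweep row failed: %s", row["error"])
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["family", "s", "k", "t"], kind="stable").reset_index(drop=True)
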