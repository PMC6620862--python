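"""File formats, phantom oracles, configuration, and figure-table sweeps.

STL input/output goes through :mod:`trimesh` (both the binary 50-byte
triangle layout and the ASCII dialect).  Phantoms are analytic bodies —
sphere, cylinder, plane, saddle — whose closed-form areas, volumes and
principal curvatures serve as oracles for the estimators in the rest of
the package.  ``reproduce_figures`` drives the deterministic parameter
sweeps behind the characteristic property plots and writes them as CSV
tables.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .implicit_cell import DomainError, PCellParams, SampledField, sample_grid
from .mesh import TriangleMesh

__all__ = [
    "write_stl",
    "read_stl",
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "RunConfig",
    "reproduce_figures",
]


# ---------------------------------------------------------------------------
# STL


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write a standards-conformant STL file.

    The binary dialect uses the 80-byte header, uint32 triangle count
    and 50-byte triangle records; ``dialect="ascii"`` writes the text
    form.
    """
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    tm = mesh.to_trimesh()
    path = Path(path)
    if dialect == "binary":
        data = trimesh.exchange.stl.export_stl(tm)
    else:
        data = trimesh.exchange.stl.export_stl_ascii(tm).encode()
    path.write_bytes(data)


def read_stl(path) -> TriangleMesh:
    """Read an STL file (either dialect) into a :class:`TriangleMesh`."""
    raw = Path(path).read_bytes()
    kwargs = trimesh.exchange.stl.load_stl(io.BytesIO(raw))
    tm = trimesh.Trimesh(**kwargs)
    return TriangleMesh.from_trimesh(tm)


# ---------------------------------------------------------------------------
# phantoms


@dataclass(frozen=True)
class PhantomSpec:
    """An analytic body with closed-form geometry.

    kind: sphere | sphere-void | cylinder | plane | saddle
    size: radius for sphere/cylinder, half-extent for plane/saddle (mm)
    L: side of the embedding cube for field phantoms (mm)
    density: grid points (fields) or subdivisions (meshes)
    """

    kind: str
    size: float = 1.0
    L: float = 4.0
    density: int = 80

    def __post_init__(self):
        if self.size <= 0 or self.L <= 0:
            raise DomainError("phantom sizes must be positive")
        if self.kind not in ("sphere", "sphere-void", "cylinder", "plane", "saddle"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")


@dataclass
class Phantom:
    """Generated phantom with its oracle values.

    ``k1``/``k2`` are the principal curvatures at the reference surface
    point (the whole surface for sphere/cylinder/plane, the origin for
    the saddle), under outward-pointing normals.
    """

    spec: PhantomSpec
    field: SampledField | None
    mesh: TriangleMesh | None
    area: float
    volume: float | None
    k1: float
    k2: float


def _grid_mesh(height, a: float, n: int, normal_fn) -> TriangleMesh:
    xs = np.linspace(-a, a, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    Z = height(X, Y)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    idx = np.arange(n * n).reshape(n, n)
    qa, qb, qc, qd = idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:], idx[:-1, 1:]
    faces = np.concatenate(
        [
            np.stack([qa.ravel(), qb.ravel(), qc.ravel()], axis=1),
            np.stack([qa.ravel(), qc.ravel(), qd.ravel()], axis=1),
        ]
    )
    normals = normal_fn(verts)
    return TriangleMesh(verts, faces, normals)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Generate the phantom field/mesh plus closed-form oracles."""
    r, n = spec.size, spec.density
    if spec.kind in ("sphere", "sphere-void"):
        # field: f = r - |x|, internal phase {f > 0} = inside the sphere
        ax = np.linspace(-spec.L / 2, spec.L / 2, n)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        values = r - np.sqrt(X**2 + Y**2 + Z**2)
        fld = SampledField(values, spec.L)
        sub = max(2, min(6, int(np.log2(max(n, 8))) - 2))
        tm = trimesh.creation.icosphere(subdivisions=sub, radius=r)
        mesh = TriangleMesh(
            np.asarray(tm.vertices, float),
            np.asarray(tm.faces, np.int64),
            np.asarray(tm.vertices, float) / r,
        )
        return Phantom(
            spec, fld, mesh,
            area=4 * np.pi * r**2,
            volume=4 / 3 * np.pi * r**3,
            k1=-1 / r, k2=-1 / r,
        )
    if spec.kind == "cylinder":
        # open tube of radius r and height 4r, outward normals
        theta = np.linspace(0, 2 * np.pi, 4 * n, endpoint=False)
        zs = np.linspace(-2 * r, 2 * r, n)
        T, Zc = np.meshgrid(theta, zs, indexing="ij")
        verts = np.column_stack(
            [r * np.cos(T).ravel(), r * np.sin(T).ravel(), Zc.ravel()]
        )
        nt, nz = len(theta), len(zs)
        idx = np.arange(nt * nz).reshape(nt, nz)
        ia = idx[:, :-1]
        ib = np.roll(idx, -1, axis=0)[:, :-1]
        ic = np.roll(idx, -1, axis=0)[:, 1:]
        idd = idx[:, 1:]
        faces = np.concatenate(
            [
                np.stack([ia.ravel(), ib.ravel(), ic.ravel()], axis=1),
                np.stack([ia.ravel(), ic.ravel(), idd.ravel()], axis=1),
            ]
        )
        normals = verts.copy()
        normals[:, 2] = 0.0
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        mesh = TriangleMesh(verts, faces, normals)
        return Phantom(
            spec, None, mesh,
            area=2 * np.pi * r * 4 * r, volume=None,
            k1=0.0, k2=-1 / r,
        )
    if spec.kind == "plane":
        mesh = _grid_mesh(
            lambda x, y: np.zeros_like(x), r, n,
            lambda v: np.tile([0.0, 0.0, 1.0], (len(v), 1)),
        )
        return Phantom(spec, None, mesh, area=(2 * r) ** 2, volume=None, k1=0.0, k2=0.0)
    # saddle z = (x^2 - y^2) / 2: k1 = 1, k2 = -1, H = 0 at the origin
    def saddle_normals(v):
        g = np.column_stack([-v[:, 0], v[:, 1], np.ones(len(v))])
        return g / np.linalg.norm(g, axis=1, keepdims=True)

    mesh = _grid_mesh(lambda x, y: 0.5 * (x**2 - y**2), r, n, saddle_normals)
    return Phantom(spec, None, mesh, area=np.nan, volume=None, k1=1.0, k2=-1.0)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Flat run configuration mirroring every CLI flag.

    Round-trips losslessly through YAML; unknown keys are rejected.
    """

    k: float = 0.0
    s: float = 1.0
    L: float = 2 * np.pi
    N: int = 100
    t: float = 0.3
    E_s: float = 110.0
    G_s: float = 40.0
    nu_s: float = 0.3
    eps_A: float = 0.001
    fem_resolution: int = 48
    k_values: list = field(default_factory=lambda: [round(float(v), 1) for v in np.arange(-0.9, 0.91, 0.1)])
    s_values: list = field(default_factory=lambda: [round(float(v), 2) for v in np.arange(0.75, 1.51, 0.05)])
    thicknesses: list = field(default_factory=lambda: [0.2, 0.4, 0.6])
    out: str = "."

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    def params(self) -> PCellParams:
        return PCellParams(k=self.k, s=self.s, L=self.L, N=self.N)


# ---------------------------------------------------------------------------
# figure-table reproduction


def _write_csv(df: pd.DataFrame, path: Path, meta: str) -> None:
    with open(path, "w") as fh:
        fh.write(meta)
        df.to_csv(fh, index=False, float_format="%.6g")


def reproduce_figures(
    outdir,
    N: int = 80,
    curvature_N: int = 70,
    thicknesses: tuple[float, ...] = (0.2, 0.4, 0.6),
    fem_resolution: int = 0,
) -> dict[str, Path]:
    """Write the deterministic sweep tables behind the property figures.

    Emits global-property sweeps over k (s = 1) and s (k = 0), the
    combined (k, s) grid, curvature-region statistics, porosity versus
    thickness, and — when ``fem_resolution`` > 0 — a stiffness-porosity
    table.  Reruns produce byte-identical files.
    """
    from . import __version__
    from .curvature_analysis import region_statistics
    from .global_properties import property_table
    from .solid_design import SolidCellSpec, porosity, solidify
    from .voxel_fem import TI6AL4V, stiffness_porosity_curve

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def meta(desc: str) -> str:
        return f"# pcell {__version__} | {desc} | N={N}\n"

    k_grid = [PCellParams(k=round(k, 1), s=1.0, N=N) for k in np.arange(-0.9, 0.91, 0.1)]
    s_grid = [PCellParams(k=0.0, s=round(s, 2), N=N) for s in np.arange(0.75, 1.51, 0.05)]
    combo = [
        PCellParams(k=k, s=s, N=N)
        for s in (0.85, 1.0, 1.15)
        for k in (-0.5, 0.0, 0.5)
    ]
    tables = {
        "global_vs_k.csv": (property_table(k_grid), "global properties, k sweep at s=1"),
        "global_vs_s.csv": (property_table(s_grid), "global properties, s sweep at k=0"),
        "global_grid.csv": (property_table(combo), "global properties, (k, s) grid"),
    }
    curv_k = [PCellParams(k=k, s=1.0, N=curvature_N) for k in (-0.7, -0.5, -0.3, 0.3, 0.5, 0.7)]
    curv_s = [PCellParams(k=-0.5, s=s, N=curvature_N) for s in (0.85, 1.0, 1.15)]
    tables["curvature_vs_k.csv"] = (
        region_statistics(curv_k), "region curvedness and area, k sweep at s=1"
    )
    tables["curvature_vs_s.csv"] = (
        region_statistics(curv_s), "region curvedness and area, s sweep at k=-0.5"
    )

    rows = []
    for t in thicknesses:
        for p in [PCellParams(k=round(k, 1), s=1.0, N=N) for k in np.arange(-0.6, 0.61, 0.3)] + [
            PCellParams(k=0.0, s=round(s, 2), N=N) for s in (0.85, 1.0, 1.15, 1.3)
        ]:
            fld = sample_grid(p)
            try:
                solid, _ = solidify(fld, p.k, t)
                P = porosity(solid)
                err = ""
            except Exception as exc:
                P, err = np.nan, f"{type(exc).__name__}"
            rows.append({"k": p.k, "s": p.s, "t": t, "P": P, "error": err})
    por = pd.DataFrame(rows).sort_values(["t", "s", "k"], kind="stable").reset_index(drop=True)
    tables["porosity_vs_params.csv"] = (por, "porosity vs (k, s) at three thicknesses")

    if fem_resolution > 0:
        specs = [
            SolidCellSpec(
                PCellParams(k=k, s=1.0, L=5.0, N=fem_resolution + 1), t=0.4,
                P=np.nan, V_P_cell=np.nan,
            )
            for k in (-0.5, 0.0, 0.5)
        ] + [
            SolidCellSpec(
                PCellParams(k=0.0, s=s, L=5.0, N=fem_resolution + 1), t=0.4,
                P=np.nan, V_P_cell=np.nan,
            )
            for s in (0.85, 1.15)
        ]
        df = stiffness_porosity_curve(specs, TI6AL4V, include_shear=True)
        tables["stiffness_porosity.csv"] = (df, "apparent moduli vs porosity")

    for name, (df, desc) in tables.items():
        path = outdir / name
        _write_csv(df, path, meta(desc))
        written[name] = path
    return written
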