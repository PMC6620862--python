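"""Shell solidification and the porosity-driven design workflow.

A scaffold strut is not the surface itself but a thin shell obtained by
offsetting the P-surface inward (into the internal phase {f > k}) by a
thickness ``t`` and filling the space between the two surfaces.  The
offset is realized on the Euclidean distance field of the internal
phase, which is robust at saddle points where naive vertex-normal
offsetting self-intersects.

Porosity of the solidified cell is P = 1 - V_solid / L^3; for thin
shells it is approximated to first order by P = 1 - (S/L^2) (t/L),
which is inverted to pick the thickness that achieves a target
porosity.  ``design_cell`` runs the full workflow: pick (k, s) from
dimensionless targets via inverse lookup on precomputed sweep tables,
set the physical side L from a dimensional target, and set t from the
target porosity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .curvature_analysis import region_statistics
from .global_properties import property_table, surface_distance
from .implicit_cell import (
    PCellParams,
    SampledField,
    extract_closed_internal_surface,
    sample_grid,
)
from .mesh import TriangleMesh

logger = logging.getLogger("pcell")

__all__ = [
    "SolidCellSpec",
    "VoxelSolid",
    "DesignResult",
    "InfeasibleDesignError",
    "solidify",
    "porosity",
    "thickness_for_porosity",
    "design_cell",
]


class InfeasibleDesignError(ValueError):
    """A design target cannot be met within the achievable range."""


@dataclass(frozen=True)
class SolidCellSpec:
    """A fully specified solid P-cell: surface parameters plus shell
    thickness, with the (thin-shell) porosity they imply."""

    params: PCellParams
    t: float  # shell thickness, mm
    P: float  # porosity, dimensionless
    V_P_cell: float  # solid volume, mm^3


@dataclass
class VoxelSolid:
    """Voxelized shell occupancy on an M^3 grid over the cell."""

    occupancy: np.ndarray
    voxel_size: float  # mm

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, bool)

    @property
    def M(self) -> int:
        return self.occupancy.shape[0]

    @property
    def L(self) -> float:
        return self.M * self.voxel_size

    @property
    def material_volume(self) -> float:
        return float(self.occupancy.sum()) * self.voxel_size**3


def solidify(
    field: SampledField, k: float, t: float, with_mesh: bool = True
) -> tuple[VoxelSolid, TriangleMesh | None]:
    """Solidify the surface {f = k} into an inward shell of thickness t.

    The shell is { x : f(x) > k and dist(x, {f = k}) <= t }, built from
    the corrected signed distance ``sd`` of the internal phase: the
    level function psi = min(sd, t - sd) is positive exactly on the
    shell.  Voxels (one per grid cell) are occupied when psi, averaged
    over their corners, is positive; the returned mesh is the watertight
    psi = 0 surface (outer surface + inner offset + rim caps on the cube
    faces).
    """
    if t < 0:
        raise ValueError(f"thickness must be non-negative, got {t}")
    h = field.spacing
    if t == 0:
        M = field.N - 1
        empty = VoxelSolid(np.zeros((M, M, M), bool), h)
        return empty, TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), int), L=field.L)
    sd = surface_distance(field, k)
    p_s = float(sd.max())
    if t >= p_s:
        raise InfeasibleDesignError(
            f"thickness t={t} mm >= pore radius {p_s:.4g} mm: shell closes the pore"
        )
    if t < 2 * h:
        warnings.warn(
            f"thickness t={t} mm under-resolved at voxel size {h:.4g} mm"
        )
    # signed distance is locally linear, so its corner mean is an
    # accurate voxel-center value; the shell test 0 < sd <= t is applied
    # *after* averaging to keep shells thinner than a voxel unbiased
    sdc = (
        sd[:-1, :-1, :-1] + sd[1:, :-1, :-1] + sd[:-1, 1:, :-1]
        + sd[:-1, :-1, 1:] + sd[1:, 1:, :-1] + sd[1:, :-1, 1:]
        + sd[:-1, 1:, 1:] + sd[1:, 1:, 1:]
    ) / 8.0
    solid = VoxelSolid((sdc > 0.0) & (sdc <= t), h)
    shell = None
    if with_mesh:
        psi = np.minimum(sd, t - sd)
        shell = extract_closed_internal_surface(psi, 0.0, field.L)
    return solid, shell


def porosity(solid: VoxelSolid, L: float | None = None) -> float:
    """Void fraction P = 1 - V_solid / L^3 of the solidified cell."""
    L = solid.L if L is None else L
    return 1.0 - solid.material_volume / L**3


def thickness_for_porosity(
    P_target: float,
    surface_ratio: float,
    L: float,
    p_s: float | None = None,
) -> float:
    """Invert the thin-shell porosity relation for the thickness.

    t = (1 - P_target) * L / (S / L^2).  When the pore radius is known,
    a thickness that would close the pore raises
    :class:`InfeasibleDesignError` reporting the reachable porosity.
    """
    if not 0.0 < P_target < 1.0:
        raise ValueError(f"porosity target must lie in (0, 1), got {P_target}")
    if surface_ratio <= 0:
        raise ValueError("surface ratio must be positive")
    t = (1.0 - P_target) * L / surface_ratio
    if p_s is not None and t >= p_s:
        p_min = 1.0 - surface_ratio * p_s / L
        raise InfeasibleDesignError(
            f"target porosity {P_target} needs t={t:.4g} mm >= pore radius "
            f"{p_s:.4g} mm; achievable porosities are > {p_min:.4g}"
        )
    return t


# ---------------------------------------------------------------------------
# design workflow


_SWEEP_CACHE: dict[tuple, object] = {}


def _k_family_table(N: int):
    key = ("k", N)
    if key not in _SWEEP_CACHE:
        grid = [PCellParams(k=round(k, 2), s=1.0, N=N) for k in np.arange(-0.9, 0.91, 0.1)]
        _SWEEP_CACHE[key] = property_table(grid)
    return _SWEEP_CACHE[key]


def _s_family_table(N: int):
    key = ("s", N)
    if key not in _SWEEP_CACHE:
        grid = [PCellParams(k=0.0, s=round(s, 2), N=N) for s in np.arange(0.75, 1.51, 0.05)]
        _SWEEP_CACHE[key] = property_table(grid)
    return _SWEEP_CACHE[key]


@dataclass(frozen=True)
class DesignResult:
    """Outcome of the design workflow with achieved-vs-requested report."""

    spec: SolidCellSpec
    requested: dict
    achieved: dict


def design_cell(
    requirements: dict,
    N: int = 60,
    curvature_N: int = 60,
) -> DesignResult:
    """Pick (k, s, L, t) meeting the given targets.

    ``requirements`` may contain:

    * ``f_v`` — target volume fraction (dimensionless); inverted on the
      k-sweep at s = 1 by linear interpolation.
    * ``p_s_target`` — target pore radius in mm (dimensional): sets L.
    * ``R_mean_target`` — target region curvedness in 1/mm
      (dimensional): sets L; requires k != 0 so that regions exist.
    * ``P_target`` — target porosity (dimensionless): sets t.

    At least one dimensionless target is required and at most one
    dimensional target is allowed.
    """
    known = {"f_v", "p_s_target", "R_mean_target", "P_target"}
    unknown = set(requirements) - known
    if unknown:
        raise ValueError(f"unknown design targets: {sorted(unknown)}")
    dimensional = [key for key in ("p_s_target", "R_mean_target") if key in requirements]
    dimensionless = [key for key in ("f_v", "P_target") if key in requirements]
    if not dimensionless:
        raise ValueError("at least one dimensionless target (f_v or P_target) required")
    if len(dimensional) > 1:
        raise InfeasibleDesignError(
            "conflicting targets: p_s_target and R_mean_target both fix the cell size L"
        )

    table = _k_family_table(N)
    ok = table[table["error"] == ""].sort_values("f_v")
    achieved: dict = {}

    # 1. dimensionless architecture targets -> (k, s)
    if "f_v" in requirements:
        fv = requirements["f_v"]
        lo, hi = ok["f_v"].min(), ok["f_v"].max()
        if not lo <= fv <= hi:
            raise InfeasibleDesignError(
                f"f_v={fv} outside the achievable interval [{lo:.4g}, {hi:.4g}] "
                "of the k-sweep at s=1"
            )
        k_sel = float(np.interp(fv, ok["f_v"], ok["k"]))
        achieved["f_v"] = float(np.interp(k_sel, table["k"], table["f_v"]))
    else:
        k_sel = 0.0
    s_sel = 1.0
    by_k = table.sort_values("k")
    p_s_over_L = float(np.interp(k_sel, by_k["k"], by_k["p_s_over_L"]))
    sr = float(np.interp(k_sel, by_k["k"], by_k["surface_ratio"]))

    # 2. dimensional target -> L
    L = 2.0 * np.pi
    if "p_s_target" in requirements:
        L = requirements["p_s_target"] / p_s_over_L
        achieved["p_s"] = p_s_over_L * L
    elif "R_mean_target" in requirements:
        if abs(k_sel) < 0.05:
            raise InfeasibleDesignError(
                "R_mean target needs concave/convex regions, which require k != 0"
            )
        stats = region_statistics([PCellParams(k=k_sel, s=s_sel, N=curvature_N)])
        r_mean_L = float(stats["R_mean_L"].iloc[0])
        if r_mean_L <= 0:
            raise InfeasibleDesignError("no regions detected at the selected (k, s)")
        L = r_mean_L / requirements["R_mean_target"]
        achieved["R_mean"] = r_mean_L / L

    # 3. porosity target -> t
    p_s = p_s_over_L * L
    if "P_target" in requirements:
        t = thickness_for_porosity(requirements["P_target"], sr, L, p_s=p_s)
        P = requirements["P_target"]
    else:
        t = 0.1 * p_s  # thin default shell, well clear of pore closure
        P = 1.0 - sr * t / L
    achieved["P"] = P
    params = PCellParams(k=k_sel, s=s_sel, L=L, N=N)
    spec = SolidCellSpec(params=params, t=t, P=P, V_P_cell=(1.0 - P) * L**3)
    logger.info("designed cell k=%.4g s=%.4g L=%.4g mm t=%.4g mm", k_sel, s_sel, L, t)
    return DesignResult(spec=spec, requested=dict(requirements), achieved=achieved)
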