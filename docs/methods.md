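# Methods

`pcell` models a single Schwarz Primitive (P) unit cell for bone-scaffold
design and characterizes it geometrically and mechanically. This note
records the models, the numerical choices, and their limits.

## The nodal P-cell

The P-surface is represented by the leading-term nodal (periodic nodal
surface) approximation

    f(x, y, z) = cos(x/s) + cos(y/s) + cos(z/s) = k,

evaluated in canonical coordinates on the cube [-pi, pi]^3. Physical
coordinates are obtained by an affine map onto a cube of side `L`
(default 2*pi mm), so `L` is a pure scale: every dimensionless property
(volume fraction `f_v`, surface ratio `S/L^2`, relative pore size
`p_s/L`) is *exactly* invariant under rescaling. The level offset `k`
selects the level surface; the scale parameter `s` uniformly scales the
surface about the cell barycentre before truncation by the cube.

The internal phase is `{f > k}` — the region containing the cell
centre, where `f` attains its maximum 3. This is the pore space tissue
grows into. With this convention `f_v` decreases as `k` increases,
matching the geometric intuition that raising the level surface shrinks
the phase above it.

Recommended parameter windows, enforced as validity flags rather than
hard errors: `k` in (-1, 1) at `s = 1` and `s` in [0.75, 1.5] at
`k = 0`. Outside these the cell loses *integrity*, which we
operationalize as: the extracted surface forms a single connected sheet
whose boundary consists of exactly six loops, one per cube face (the
six lateral openings that make the pore network of a tiled scaffold
interconnected). The sweep in `scripts/acceptance.py` confirms the
breakdown: loops merge across cube edges at `s = 1.55` while `s = 1.50`
is intact; below `s = 0.75` extra disconnected sheets appear; at
`|k| >= 1` the lateral openings close.

## Sampling and isosurfacing

The field is sampled on a node-centered N^3 grid (endpoints included,
spacing `L/(N-1)`; default `N = 100`) and the level surface extracted
with marching cubes (scikit-image, linear interpolation). A level that
collides with a sampled value within 1e-12 is nudged by 1e-9 to avoid
ambiguous cube configurations; duplicate vertices are merged at
1e-9 * L and zero-area faces dropped. At `N = 100` the tessellated
standard cell (k=0, s=1) has surface ratio 2.3528 against the reference
value 2.3451 for the continuous surface (+0.33%), and the area changes
by well under 1% between `N = 100` and `N = 140`.

Vertex normals are taken from the analytic gradient, oriented outward
from the internal phase (along `-grad f`), and face windings are made
consistent with them.

## Global properties

* **Volume fraction** — per-voxel occupancy counting with a first-order
  interface correction: the field is linearized into an approximate
  signed distance `(f - k)/|grad f|`, averaged over voxel corners, and
  converted to a clipped linear fill fraction. An independent estimate
  applies the divergence theorem to a watertight internal-boundary mesh
  built by padding the grid with an external layer and clamping the pad
  vertices back onto the cube faces. The two estimators agree to a few
  parts in 10^3 at N = 100.
* **Pore size** — radius of the largest inscribed sphere of the
  internal phase. An exact Euclidean distance transform (with a
  sub-voxel correction using the field linearization at the nearest
  opposite-phase node) locates the basin of the maximum; a Nelder-Mead
  refinement of the centre against a dense point sampling of the
  extracted surface (vertices, edge midpoints, face centroids) removes
  the O(h) node bias. For the standard cell this reproduces the
  closed-form `p_s/L = sqrt(3)/4` to about 1e-6.
* **Surface ratio and specific surface** — direct triangle-area sums;
  `(S/V) L = (S/L^2)/f_v` holds exactly by construction.

## Curvature analysis

Principal curvatures are estimated with the paraboloid method: for each
vertex a full quadratic height field over the local tangent plane is
least-squares fitted to the two-ring neighborhood (widened to three
rings when fewer than 6 neighbors are available; such vertices are
flagged and excluded from labeling). Curvatures come from the first and
second fundamental forms of the fitted Monge patch, with heights
measured along the analytic vertex normal: a patch bending toward the
normal carries positive curvature. On sphere and cylinder phantoms the
median error is below 1% at the default tessellation and decreases
under refinement.

Vertices are labeled by the sign rule: concave when
`min(k1, k2) >= 0 and max(k1, k2) > 0`, convex when
`max(k1, k2) <= 0 and min(k1, k2) < 0`, saddle/flat otherwise. With
outward normals, cells with `k < 0` develop concave pockets (eight, one
per cube corner, identical by cubic symmetry) and cells with `k > 0`
the corresponding eight convex bulges. Regions are maximal connected
same-label vertex sets under edge adjacency; patches below 0.1% of the
total area are discarded as tessellation noise. Each region reports its
area share `A_r%` and mean curvedness `R_mean = mean sqrt(k1^2+k2^2)`
(dimensionless as `R_mean * L`). Region statistics average over the
eight regions, which differ from one another by well under 5%.

**A caution on minimality.** The truncated nodal surface is *not*
minimal. The exact mean curvature of the implicit surface at `k = 0`
(computed from gradients and Hessians of `f`) has `mean(|H|) * L =
0.414`; our estimator reproduces this within a few percent. `H` is
small only relative to the curvedness scale (`mean|H| / mean R` is
about 0.10) and its signed mean cancels. Claims that the k=0 cell has
`H` identically near zero hold for the true minimal P-surface, not for
its single-term nodal approximation.

## Shell solidification and porosity

The solid strut is the inward offset shell
`{0 < d(x) <= t}` where `d` is the signed distance to the surface,
positive inside the internal phase. The offset is realized on the
corrected Euclidean distance field rather than by vertex-normal
offsetting, which self-intersects at saddle points. Voxel occupancy
applies the shell window to the corner-averaged signed distance — the
distance is locally linear, so averaging before windowing keeps shells
thinner than a voxel volumetrically unbiased. The watertight shell
mesh (outer surface, inner offset, rim caps on the cube faces) is the
zero level of `psi = min(d, t - d)` extracted with the same padded
marching-cubes construction.

Porosity is `P = 1 - V_solid/L^3`; its thin-shell approximation
`P = 1 - (S/L^2)(t/L)` is inverted for thickness in the design
workflow. At `t/L = 0.005` the voxel porosity at N = 160 matches the
thin-shell relation to 0.3%, and `P` is linear in `t` with R^2 > 0.999
over practical thicknesses. A thickness at or above the pore radius is
rejected ("shell closes the pore").

The design workflow maps targets to parameters in three steps:
dimensionless architecture targets (`f_v`) are inverted on precomputed
sweep tables (k family at s = 1, linear interpolation); one dimensional
target (pore radius in mm, or region curvedness in 1/mm) fixes the cell
side `L` by pure scaling; a porosity target fixes `t` through the
thin-shell relation, checked against pore closure. Unreachable targets
raise errors reporting the achievable interval.

## Voxel finite elements

Every occupied voxel becomes an 8-node trilinear brick with the
isotropic elasticity matrix built from `E_s` and `nu_s` (2x2x2 Gauss
quadrature, exact for this element). Components that do not connect the
two loading faces are removed before assembly with a logged count.
Systems up to ~90k dofs are solved directly (sparse LU); larger ones by
conjugate gradients with an incomplete-LU preconditioner to a relative
residual of 1e-8.

Apparent moduli follow the reaction-force definition
`E = (F_R/A)/eps_A` with `A = L^2` and `eps_A = 0.001`. Compression
uses frictionless kinematic supports: the bottom face is restrained
only along the load axis, plus the minimal in-plane pinning that
removes rigid-body motion. This choice makes the homogeneous full cube
reproduce `E_s` exactly at any resolution (patch test) and guarantees
`E <= E_s` for porous cells; a fully clamped bottom would stiffen the
cube by a Poisson-confinement artifact. Shear uses the clamped
configuration of the physical test it models — the -x face fully fixed,
the +x face driven in y, the +/-y faces restrained in x — so `G_app` is
an *apparent* modulus: for the full cube it equals `E/(2(1+nu))` = 42.3
GPa, about 6% above the nominal `G_s = 40` GPa of Ti-6Al-4V (the
printed constants are not perfectly isotropy-consistent; the elasticity
matrix uses `E_s, nu_s` and `G_s` only normalizes).

Default material: Ti-6Al-4V (`E_s = 110` GPa, `G_s = 40` GPa,
`nu_s = 0.3`). The FEM reference cell is `L = 5` mm; the production
element size of 0.05 mm (100 elements per edge) is supported, while the
package's default study sizes use 24-48 elements per edge, where the
compression modulus is converged to a few percent and every qualitative
trend is stable across resolutions.

Von Mises stress is evaluated from the strain-displacement matrix at
element centroids and reported in MPa.

### Voxel geometry and shear trends

Voxelization reproduces the compression behavior faithfully: `E` grows
with `t`, falls with `s`, grows with `k`, and the k-family
stiffness-porosity curve lies above the s-family one. The clamped shear
response of voxelized thin shells is more delicate. In this model the
apparent shear modulus peaks near `s = 1.15` rather than at the
standard cell and *decreases* from `k = -0.5` to `k = +0.5`
(G_app/G_s of 0.10 vs 0.07 at t = 0.5 mm), and these orderings are
stable from 32 to 48 elements per edge. Smooth-geometry solvers on the
same architectures have been reported to place the shear maximum at
`s = 1` and to find `G_app` growing with `k`; we attribute the
difference to the stair-stepped boundary, whose artificial shear
compliance depends on local surface orientation and does not cancel
between cells the way it does in compression. Shear results from this
module should therefore be read as comparative within a fixed
resolution, not as converged trend statements across architectures.

## Synthetic phantoms

Phantoms supply closed-form oracles: a sphere field/mesh (area 4 pi
r^2, curvatures -1/r under outward normals), a sphere-void field for
pore sizing, an open cylinder tube (0 and -1/r), a plane patch (0, 0),
and a saddle `z = (x^2 - y^2)/2` (+1, -1 at the origin). They exercise
isosurface area, volume fraction, inscribed-sphere radius, and the
curvature estimator. What they do not emulate: measurement noise,
manufacturing roughness, or multi-cell assemblies — passing the
phantoms validates the estimators on smooth analytic geometry only.

## Known limitations

* Single unit cell only; no multi-cell or graded-scaffold assembly, and
  no C1 continuity repair for `s != 1` tilings.
* The nodal representation is an approximation of the true minimal
  P-surface (see the minimality caution above).
* Voxel FEM trades boundary fidelity for robustness; stresses at the
  stair-stepped boundary are local averages, not surface-accurate
  values.
* No permeability, plasticity, fatigue, or strength prediction.
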