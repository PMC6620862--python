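"""Lightweight triangle-mesh container shared by all modules.

The mesh is a plain (vertices, faces) pair with optional oriented vertex
normals.  Heavy lifting (STL export, watertight volume, winding repair)
is delegated to :mod:`trimesh`; this container only adds the pieces the
cell analysis needs: boundary-loop extraction on the cube faces, cheap
connected components, and deterministic cleanup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class TriangleMesh:
    """Tessellated surface patch clipped to a cubic cell.

    Parameters
    ----------
    vertices : (V, 3) float array, mm
    faces : (F, 3) int array
        Vertex-index triples with consistent winding.
    vertex_normals : (V, 3) float array or None
        Oriented unit normals (outward from the internal phase for
        field-derived meshes).
    L : float or None
        Side of the cubic cell the mesh is clipped to, used when
        classifying boundary loops by cube face.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = None
    L: float | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- basic quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = (v[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def area(self) -> float:
        """Total surface area in mm^2."""
        return float(self.face_areas().sum())

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas (one third of incident face areas)."""
        fa = self.face_areas()
        va = np.zeros(self.n_vertices)
        np.add.at(va, self.faces.ravel(), np.repeat(fa / 3.0, 3))
        return va

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        a, b, c = (v[self.faces[:, i]] for i in range(3))
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1)
        norm[norm == 0] = 1.0
        return n / norm[:, None]

    # -- topology ---------------------------------------------------------

    def edges(self) -> np.ndarray:
        """All directed edges (3F, 2)."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def _edge_face_counts(self):
        e = np.sort(self.edges(), axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def boundary_edges(self) -> np.ndarray:
        """Edges used by exactly one face, (B, 2)."""
        uniq, counts = self._edge_face_counts()
        return uniq[counts == 1]

    def has_nonmanifold_edges(self) -> bool:
        _, counts = self._edge_face_counts()
        return bool((counts > 2).any())

    def boundary_loops(self) -> list[np.ndarray]:
        """Closed vertex cycles formed by the boundary edges.

        Open chains (which should not occur on a clean clipped
        isosurface) are returned as well so callers can flag them.
        """
        be = self.boundary_edges()
        if len(be) == 0:
            return []
        adj: dict[int, list[int]] = {}
        for u, v in be:
            adj.setdefault(int(u), []).append(int(v))
            adj.setdefault(int(v), []).append(int(u))
        seen: set[int] = set()
        loops = []
        for start in sorted(adj):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            prev, cur = -1, start
            while True:
                nxt = None
                for w in adj[cur]:
                    if w != prev and w not in seen:
                        nxt = w
                        break
                if nxt is None:
                    # either closed back to start or an open chain end
                    break
                loop.append(nxt)
                seen.add(nxt)
                prev, cur = cur, nxt
            loops.append(np.asarray(loop))
        return loops

    def n_components(self) -> int:
        if self.n_faces == 0:
            return 0
        e = self.edges()
        m = coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])),
            shape=(self.n_vertices, self.n_vertices),
        )
        n, _ = connected_components(m, directed=False)
        # vertices not referenced by any face do not count as components
        used = np.zeros(self.n_vertices, bool)
        used[self.faces.ravel()] = True
        if used.all():
            return n
        _, labels = connected_components(m, directed=False)
        return len(np.unique(labels[used]))

    def vertex_adjacency(self):
        """Symmetric boolean CSR adjacency over mesh edges."""
        e = self.edges()
        data = np.ones(len(e), dtype=bool)
        m = coo_matrix(
            (data, (e[:, 0], e[:, 1])),
            shape=(self.n_vertices, self.n_vertices),
        ).tocsr()
        return m + m.T

    # -- cleanup / conversion ---------------------------------------------

    def cleaned(self, merge_tol: float | None = None) -> "TriangleMesh":
        """Merge duplicate vertices and drop degenerate faces.

        merge_tol defaults to 1e-9 times the cell side (or the bounding
        box diagonal when L is unknown).
        """
        if merge_tol is None:
            scale = self.L
            if scale is None:
                scale = float(np.ptp(self.vertices, axis=0).max() or 1.0)
            merge_tol = 1e-9 * scale
        key = np.round(self.vertices / merge_tol).astype(np.int64)
        _, first, inverse = np.unique(
            key, axis=0, return_index=True, return_inverse=True
        )
        verts = self.vertices[first]
        faces = inverse[self.faces]
        ok = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 2] != faces[:, 0])
        )
        faces = faces[ok]
        normals = None
        if self.vertex_normals is not None:
            normals = self.vertex_normals[first]
        m = TriangleMesh(verts, faces, normals, self.L)
        areas = m.face_areas()
        scale = m.L or float(np.ptp(m.vertices, axis=0).max() or 1.0)
        m.faces = m.faces[areas > 1e-16 * scale**2]
        return m

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(),
            faces=self.faces.copy(),
            process=False,
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, L: float | None = None) -> "TriangleMesh":
        return cls(
            np.asarray(tm.vertices, float),
            np.asarray(tm.faces, np.int64),
            np.asarray(tm.vertex_normals, float),
            L,
        )
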