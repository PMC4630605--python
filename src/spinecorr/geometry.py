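"""Low-level geometric primitives shared across the package.

Everything here is deterministic, pure numpy, and unit-agnostic (the rest of
the package uses mm).  The block/loft meshers produce conforming tetrahedral
meshes from structured hexahedral grids using the translation-invariant
six-tetrahedra split around the main cell diagonal, which guarantees matching
face diagonals between neighbouring cells (and between separately generated
blocks that share grid planes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> R @ x + t``."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    @classmethod
    def about_point(cls, rotation: np.ndarray, pivot, translation=None) -> "RigidTransform":
        """Rotation about ``pivot`` followed by an optional translation."""
        R = np.asarray(rotation, dtype=float)
        p = np.asarray(pivot, dtype=float)
        t = p - R @ p
        if translation is not None:
            t = t + np.asarray(translation, dtype=float)
        return cls(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def intrinsic_yxz(sagittal_deg: float, coronal_deg: float, axial_deg: float) -> np.ndarray:
    """Rotation matrix for intrinsic Y (sagittal), X (coronal), Z (axial) angles.

    This is the fixed angle convention used throughout the package for
    vertebral orientations: first rotate about the left-right axis (motion in
    the sagittal plane), then the anteroposterior axis (coronal plane), then
    the craniocaudal axis (axial plane), each about the already-rotated frame.
    """
    return rot_y(sagittal_deg) @ rot_x(coronal_deg) @ rot_z(axial_deg)


def extract_yxz_angles(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`intrinsic_yxz`; returns (sagittal, coronal, axial) deg."""
    R = np.asarray(R, dtype=float)
    # R = Ry(a) Rx(b) Rz(c);  R[2,1] ... derive from composition.
    # Row/col expressions: R[1,2] = -sin(b)? compute symbolically:
    # Ry*Rx*Rz:
    #   R[1][2] = -s_b? Let's use: R[1,2] = -sin(b)*... safer numeric approach below.
    b = np.arcsin(np.clip(-R[1, 2], -1.0, 1.0))
    cb = np.cos(b)
    if abs(cb) < 1e-12:  # gimbal lock: split arbitrarily, axial = 0
        a = np.arctan2(R[0, 1], R[0, 0])
        c = 0.0
    else:
        a = np.arctan2(R[0, 2], R[2, 2])
        c = np.arctan2(R[1, 0], R[1, 1])
    return float(np.rad2deg(a)), float(np.rad2deg(b)), float(np.rad2deg(c))


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit proper rotation + translation mapping point set p onto q.

    Returns (R, t) minimising ``sum |R p_i + t - q_i|^2`` (Kabsch / orthogonal
    Procrustes with the reflection guard).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    H = (p - pc).T @ (q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, qc - R @ pc


# ---------------------------------------------------------------------------
# triangulated-surface measures
# ---------------------------------------------------------------------------


def surface_volume(vertices: np.ndarray, triangles: np.ndarray) -> float:
    """Enclosed volume of a closed, outward-wound surface (divergence theorem)."""
    v = np.asarray(vertices, dtype=float)
    t = np.asarray(triangles, dtype=int)
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def surface_edges(triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (unique undirected edges, multiplicity of each edge)."""
    t = np.asarray(triangles, dtype=int)
    e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    e = np.sort(e, axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return uniq, counts


def euler_characteristic(vertices: np.ndarray, triangles: np.ndarray) -> int:
    t = np.asarray(triangles, dtype=int)
    nv = len(np.unique(t))
    edges, _ = surface_edges(t)
    return int(nv - len(edges) + len(t))


def boundary_edge_count(triangles: np.ndarray) -> int:
    """Number of edges referenced by exactly one triangle (0 for closed)."""
    _, counts = surface_edges(triangles)
    return int((counts == 1).sum())


def is_closed_manifold(triangles: np.ndarray) -> bool:
    _, counts = surface_edges(triangles)
    return bool(np.all(counts == 2))


def mean_edge_length(vertices: np.ndarray, triangles: np.ndarray) -> float:
    edges, _ = surface_edges(triangles)
    v = np.asarray(vertices, dtype=float)
    return float(np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1).mean())


# ---------------------------------------------------------------------------
# tetrahedra
# ---------------------------------------------------------------------------


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tet4 elements (positive for right-handed ordering)."""
    x = np.asarray(nodes, dtype=float)
    t = np.asarray(tets, dtype=int)
    a = x[t[:, 1]] - x[t[:, 0]]
    b = x[t[:, 2]] - x[t[:, 0]]
    c = x[t[:, 3]] - x[t[:, 0]]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


# faces of a tet in outward orientation for a positively oriented element
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Outward-wound boundary triangles of a tet mesh (faces owned once)."""
    t = np.asarray(tets, dtype=int)
    faces = t[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def min_dihedral_angles(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Minimum dihedral angle (deg) of each tet."""
    x = np.asarray(nodes, dtype=float)
    t = np.asarray(tets, dtype=int)
    # face normals (4 faces per tet)
    p = x[t]  # (n,4,3)
    n_faces = []
    for f in _TET_FACES:
        a, b, c = p[:, f[0]], p[:, f[1]], p[:, f[2]]
        n = np.cross(b - a, c - a)
        n_faces.append(n / np.linalg.norm(n, axis=1, keepdims=True))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    angs = []
    for i, j in pairs:
        cosang = np.clip(-np.einsum("ij,ij->i", n_faces[i], n_faces[j]), -1.0, 1.0)
        angs.append(np.degrees(np.arccos(cosang)))
    return np.min(np.stack(angs, axis=1), axis=1)


# ---------------------------------------------------------------------------
# structured hex -> tet meshing
# ---------------------------------------------------------------------------

# 6-tet split of the unit hex around the main diagonal c000-c111.  Corner
# ordering: index bit 0 -> i, bit 1 -> j, bit 2 -> k  (c_{kji} as bits).
# Cells on the y < 0 side of the anatomical midplane use the y-mirrored
# pattern so that meshes of bilaterally symmetric geometry are themselves
# mirror-symmetric (the two patterns share face diagonals on the midplane,
# and translated copies of one pattern always conform).
_HEX_CORNERS = np.array(
    [[i, j, k] for k in (0, 1) for j in (0, 1) for i in (0, 1)]
)  # c000,c100,c010,c110,c001,c101,c011,c111 order: index = i + 2j + 4k
_HEX_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 3, 2, 7],
        [0, 2, 6, 7],
        [0, 6, 4, 7],
        [0, 4, 5, 7],
        [0, 5, 1, 7],
    ]
)
_MIRROR_Y = np.array([2, 3, 0, 1, 6, 7, 4, 5])
_HEX_TETS_MIRROR = _MIRROR_Y[_HEX_TETS]


def hex_cell_tets(corner_ids: np.ndarray, mirrored: bool) -> np.ndarray:
    """Six-tet split of one hex; ``mirrored`` selects the y-mirrored pattern."""
    pattern = _HEX_TETS_MIRROR if mirrored else _HEX_TETS
    return corner_ids[pattern]


@dataclass
class MeshBuilder:
    """Accumulates tet blocks with node welding on exact rounded coordinates."""

    decimals: int = 6
    nodes: list = field(default_factory=list)
    tets: list = field(default_factory=list)
    _index: dict = field(default_factory=dict)

    def node_id(self, xyz) -> int:
        key = tuple(np.round(np.asarray(xyz, dtype=float), self.decimals))
        idx = self._index.get(key)
        if idx is None:
            idx = len(self.nodes)
            self._index[key] = idx
            self.nodes.append(np.asarray(xyz, dtype=float))
        return idx

    def add_hex_grid(self, grid_nodes: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        """Add a structured grid of hex cells split into 6 tets each.

        ``grid_nodes``: (nx+1, ny+1, nz+1, 3) node coordinates.
        ``mask``: (nx, ny, nz) bool cell selector (default all).
        Returns the element indices (into the global tet list) that were added.
        """
        g = np.asarray(grid_nodes, dtype=float)
        nx, ny, nz = g.shape[0] - 1, g.shape[1] - 1, g.shape[2] - 1
        if mask is None:
            mask = np.ones((nx, ny, nz), dtype=bool)
        ids = np.full(g.shape[:3], -1, dtype=int)
        added = []
        for k in range(nz):
            for j in range(ny):
                for i in range(nx):
                    if not mask[i, j, k]:
                        continue
                    corner_ids = []
                    for di, dj, dk in _HEX_CORNERS:
                        ii, jj, kk = i + di, j + dj, k + dk
                        if ids[ii, jj, kk] < 0:
                            ids[ii, jj, kk] = self.node_id(g[ii, jj, kk])
                        corner_ids.append(ids[ii, jj, kk])
                    corner_ids = np.asarray(corner_ids)
                    yc = np.mean(
                        [g[i + di, j + dj, k + dk][1] for di, dj, dk in _HEX_CORNERS]
                    )
                    for tet in hex_cell_tets(corner_ids, mirrored=yc < -1e-9):
                        self.tets.append(tet)
                        added.append(len(self.tets) - 1)
        return np.asarray(added, dtype=int)

    def add_loft(self, bottom: np.ndarray, top: np.ndarray, n_layers: int) -> np.ndarray:
        """Loft between two (m+1, n+1, 3) node grids with n_layers cell layers."""
        b = np.asarray(bottom, dtype=float)
        t = np.asarray(top, dtype=float)
        if b.shape != t.shape:
            raise ValueError("bottom/top grids must have identical shape")
        frac = np.linspace(0.0, 1.0, n_layers + 1)
        grid = b[:, :, None, :] * (1 - frac)[None, None, :, None] + t[:, :, None, :] * frac[
            None, None, :, None
        ]
        return self.add_hex_grid(grid)

    def add_tets(self, nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
        """Add an existing tet block, welding nodes on rounded coordinates."""
        nodes = np.asarray(nodes, dtype=float)
        ids = np.array([self.node_id(p) for p in nodes], dtype=int)
        added = []
        for tet in np.asarray(tets, dtype=int):
            self.tets.append(ids[tet])
            added.append(len(self.tets) - 1)
        return np.asarray(added, dtype=int)

    def build(self) -> tuple[np.ndarray, np.ndarray]:
        nodes = np.asarray(self.nodes, dtype=float)
        tets = np.asarray(self.tets, dtype=int)
        vols = tet_volumes(nodes, tets)
        flip = vols < 0
        if np.any(flip):  # restore positive orientation after reflections/lofts
            tets[flip] = tets[flip][:, [0, 1, 3, 2]]
        return nodes, tets


def box_grid(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Tensor-product node grid from 1-D coordinate arrays -> (nx,ny,nz,3)."""
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    return np.stack([X, Y, Z], axis=-1)
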