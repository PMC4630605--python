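"""Intervertebral disks, ligaments and facet-joint contacts.

The disk is a prism-stacked tet mesh spanning the two facing endplates: its
bottom/top node layers coincide exactly with the vertebral endplate nodes,
so the assembled model is conforming by coordinate welding.  A central
cylindrical region sized to a configurable share of the disk volume (50% by
default) is labeled nucleus pulposus; the rest is annulus ground substance.
Collagen fibers are tension-only springs criss-crossing the annulus wall in
two balanced families with a mean inclination of +/-30 degrees to the disk's
axial plane.

Six ligament groups are tension-only nonlinear springs: anterior and
posterior longitudinal (ALL/PLL), flaval (LF) and interspinous (ISL) with
three springs per level, supraspinous (SSL) with one, and capsular (CL) with
twelve per facet joint following the border of the joint capsule.  Facet
joints are frictionless node-to-node gap contacts with a fixed unloaded
clearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import FACET_CLEARANCE_MM, SpineModel, ValidationError
from .materials import LigamentCurve, MaterialTable
from .meshing import TetMesh
from .geometry import boundary_faces

__all__ = [
    "DiskModel",
    "FiberSet",
    "LigamentSet",
    "FacetContactSet",
    "make_circular_endplates",
    "cap_from_grid",
    "build_disk",
    "build_disk_grid",
    "size_nucleus",
    "generate_annulus_fibers",
    "build_ligaments",
    "build_facet_contacts",
    "set_disk_condition",
]

LIGAMENT_COUNTS = {"ALL": 3, "PLL": 3, "LF": 3, "ISL": 3, "SSL": 1}
CAPSULE_SPRINGS_PER_FACET = 12
DISK_CONDITIONS = ("healthy", "soft", "removed")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FiberSet:
    """Annulus fiber springs: tension-only, linear modulus, two families."""

    pairs: np.ndarray  # (n, 2) disk-node indices
    family: np.ndarray  # (n,) +1 / -1
    rest_length: np.ndarray  # (n,) mm
    area: np.ndarray  # (n,) mm^2 effective cross-section per fiber
    inclination_deg: np.ndarray  # (n,) angle to the axial plane at assembly

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class DiskModel:
    """Tet-meshed intervertebral disk with nucleus labels and fiber springs."""

    mesh: TetMesh  # material_labels in {'annulus', 'nucleus'}
    level: str  # junction name, e.g. "L3-L4"
    axis: np.ndarray  # unit craniocaudal axis
    nucleus_radius: float
    nucleus_fraction_target: float
    fibers: FiberSet | None = None
    condition: str = "healthy"

    def nucleus_fraction(self) -> float:
        vols = self.mesh.volumes()
        nuc = self.mesh.material_labels == "nucleus"
        return float(vols[nuc].sum() / vols.sum())

    def height(self) -> float:
        z = self.mesh.nodes @ self.axis
        return float(z.max() - z.min())


@dataclass
class LigamentSpring:
    group: str
    a: np.ndarray  # endpoint coordinates (assembled frame)
    b: np.ndarray
    curve: LigamentCurve
    rest_length: float


@dataclass
class LigamentSet:
    """All ligament springs of one junction."""

    junction: str
    springs: list[LigamentSpring] = field(default_factory=list)

    def count(self, group: str) -> int:
        return sum(1 for s in self.springs if s.group == group)


@dataclass
class GapElement:
    a: np.ndarray  # coordinates on the caudal (superior-facet) side
    b: np.ndarray  # coordinates on the cranial (inferior-facet) side
    direction: np.ndarray  # unit vector from a-side toward b-side
    clearance: float


@dataclass
class FacetContactSet:
    junction: str
    gaps: list[GapElement] = field(default_factory=list)


# ---------------------------------------------------------------------------
# caps (endplate discretizations)
# ---------------------------------------------------------------------------


def make_circular_endplates(
    radius: float, gap: float, n_sectors: int = 22, n_rings: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two parallel circular endplate caps (bottom at z=0, top at z=gap).

    Returns (bottom nodes, top nodes, cap triangulation).  Used for isolated
    disk studies; the spine pipeline extracts caps from vertebral endplates.
    """
    if radius <= 0 or n_sectors < 3 or n_rings < 1:
        raise ValidationError("invalid circular endplate parameters")
    nodes = [np.zeros(3)]
    for r_i in range(1, n_rings + 1):
        r = radius * r_i / n_rings
        ang = 2 * np.pi * np.arange(n_sectors) / n_sectors
        ring = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n_sectors)], axis=1)
        nodes.append(ring)
    nodes = np.concatenate([np.atleast_2d(n) for n in nodes])
    tris = []
    first = 1
    for s in range(n_sectors):
        tris.append([0, first + s, first + (s + 1) % n_sectors])
    for r_i in range(1, n_rings):
        lo = 1 + (r_i - 1) * n_sectors
        hi = 1 + r_i * n_sectors
        for s in range(n_sectors):
            s1 = (s + 1) % n_sectors
            tris.append([lo + s, hi + s, hi + s1])
            tris.append([lo + s, hi + s1, lo + s1])
    bottom = nodes
    top = nodes + np.array([0.0, 0.0, gap])
    return bottom, top, np.asarray(tris, dtype=int)


def cap_from_grid(grid: np.ndarray, cell_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate a masked structured endplate grid.

    The (i,j)-(i+1,j+1) diagonal matches the face diagonals of the
    six-tet hex split used for the vertebra volume meshes, so disk prisms
    built on this cap share faces exactly with the vertebra boundary.
    Returns (cap nodes, triangles into the cap node list).
    """
    ni, nj = cell_mask.shape
    used = np.zeros((ni + 1, nj + 1), dtype=bool)
    for i in range(ni):
        for j in range(nj):
            if cell_mask[i, j]:
                used[i : i + 2, j : j + 2] = True
    idx = -np.ones((ni + 1, nj + 1), dtype=int)
    idx[used] = np.arange(used.sum())
    nodes = grid[used]
    tris = []
    for i in range(ni):
        for j in range(nj):
            if not cell_mask[i, j]:
                continue
            a, b = idx[i, j], idx[i + 1, j]
            c, d = idx[i + 1, j + 1], idx[i, j + 1]
            tris.append([a, b, c])
            tris.append([a, c, d])
    return nodes, np.asarray(tris, dtype=int)


# ---------------------------------------------------------------------------
# disk construction
# ---------------------------------------------------------------------------


def _mask_perimeter_loop(cell_mask: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cyclically ordered cap-node indices of the masked-grid boundary."""
    edges: dict[tuple[int, int], int] = {}
    ni, nj = cell_mask.shape
    for i in range(ni):
        for j in range(nj):
            if not cell_mask[i, j]:
                continue
            a, b = idx[i, j], idx[i + 1, j]
            c, d = idx[i + 1, j + 1], idx[i, j + 1]
            for e in ((a, b), (b, c), (c, d), (d, a)):
                key = tuple(sorted(e))
                edges[key] = edges.get(key, 0) + 1
    border = [e for e, cnt in edges.items() if cnt == 1]
    nxt: dict[int, list[int]] = {}
    for a, b in border:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    start = min(nxt)
    loop = [start]
    prev = None
    while True:
        cands = [c for c in nxt[loop[-1]] if c != prev]
        prev = loop[-1]
        loop.append(cands[0])
        if loop[-1] == start:
            loop.pop()
            break
    return np.asarray(loop, dtype=int)


def build_disk_grid(
    bottom_grid: np.ndarray,
    top_grid: np.ndarray,
    cell_mask: np.ndarray,
    *,
    level: str = "",
    n_layers: int = 3,
    nucleus_fraction: float = 0.5,
    table: MaterialTable | None = None,
    fiber_angle_deg: float = 30.0,
    fiber_area_fraction: float = 0.16,
    with_fibers: bool = True,
) -> DiskModel:
    """Build a disk as a hex loft between two structured endplate grids.

    Uses the same per-cell (midplane-mirrored) six-tet split as the vertebra
    volume mesher, so the disk conforms exactly to the vertebral endplate
    boundary faces and bilaterally symmetric fixtures get mirror-symmetric
    disk meshes.
    """
    table = table or MaterialTable()
    from .geometry import hex_cell_tets, tet_volumes

    bg = np.asarray(bottom_grid, dtype=float)
    tg = np.asarray(top_grid, dtype=float)
    if bg.shape != tg.shape:
        raise ValidationError("endplate grids must have matching shapes")
    ni, nj = cell_mask.shape
    used = np.zeros((ni + 1, nj + 1), dtype=bool)
    for i in range(ni):
        for j in range(nj):
            if cell_mask[i, j]:
                used[i : i + 2, j : j + 2] = True
    idx = -np.ones((ni + 1, nj + 1), dtype=int)
    idx[used] = np.arange(used.sum())
    n_cap = int(used.sum())
    b_cap, t_cap = bg[used], tg[used]
    # outward normal of the bottom endplate from the grid parameterization
    n_out = np.cross(bg[-1, 0] - bg[0, 0], bg[0, -1] - bg[0, 0])
    n_out = n_out / np.linalg.norm(n_out)
    if np.any((t_cap - b_cap) @ n_out <= 0):
        raise ValidationError("endplates intersect: non-positive inter-endplate gap")
    axis = t_cap.mean(axis=0) - b_cap.mean(axis=0)
    axis = axis / np.linalg.norm(axis)

    frac = np.linspace(0.0, 1.0, n_layers + 1)
    layers = b_cap[None] * (1 - frac)[:, None, None] + t_cap[None] * frac[:, None, None]
    nodes = layers.reshape(-1, 3)
    tets = []
    from .geometry import _HEX_CORNERS  # corner order: index = i + 2j + 4k

    for L in range(n_layers):
        for i in range(ni):
            for j in range(nj):
                if not cell_mask[i, j]:
                    continue
                corner_ids = np.array(
                    [idx[i + di, j + dj] + (L + dk) * n_cap for di, dj, dk in _HEX_CORNERS]
                )
                yc = np.mean([bg[i + di, j + dj][1] for di, dj, dk in _HEX_CORNERS])
                tets.extend(hex_cell_tets(corner_ids, mirrored=yc < -1e-9))
    tets = np.asarray(tets, dtype=int)
    vols = tet_volumes(nodes, tets)
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]

    mesh = TetMesh(nodes=nodes, tets=tets, provenance=f"disk:{level}")
    mesh.extras["n_cap_nodes"] = n_cap
    mesh.extras["n_layers"] = n_layers
    mesh.extras["perimeter_loop"] = _mask_perimeter_loop(cell_mask, idx)
    disk = DiskModel(
        mesh=mesh,
        level=level,
        axis=axis,
        nucleus_radius=0.0,
        nucleus_fraction_target=nucleus_fraction,
    )
    size_nucleus(disk, nucleus_fraction)
    if with_fibers:
        generate_annulus_fibers(
            disk, target_angle_deg=fiber_angle_deg, area_fraction=fiber_area_fraction
        )
    return disk


def _split_prism(bot, top) -> list[list[int]]:
    """Index-rule prism-to-3-tets split (diagonals through smallest ids),
    conforming across shared quad faces."""
    v = [bot[0], bot[1], bot[2], top[0], top[1], top[2]]
    # rotate so the smallest vertex sits at position 0 (mirror if on top)
    k = int(np.argmin(v))
    if k >= 3:
        v = [v[3], v[5], v[4], v[0], v[2], v[1]]  # flip, keep outward sense
        k = int(np.argmin(v))
    for _ in range(k):
        v = [v[1], v[2], v[0], v[4], v[5], v[3]]
    v0, v1, v2, v3, v4, v5 = v
    if min(v1, v5) < min(v2, v4):
        return [[v0, v1, v2, v5], [v0, v1, v5, v4], [v0, v4, v5, v3]]
    return [[v0, v1, v2, v4], [v0, v4, v2, v5], [v0, v4, v5, v3]]


def build_disk(
    bottom_cap: np.ndarray,
    top_cap: np.ndarray,
    cap_triangles: np.ndarray,
    *,
    level: str = "",
    n_layers: int = 3,
    nucleus_fraction: float = 0.5,
    table: MaterialTable | None = None,
    fiber_angle_deg: float = 30.0,
    fiber_area_fraction: float = 0.16,
    with_fibers: bool = True,
) -> DiskModel:
    """Build a disk between two matched endplate caps.

    The caps must have identical node counts with index correspondence; the
    bottom cap belongs to the superior endplate of the caudal vertebra, the
    top cap to the inferior endplate of the cranial vertebra.
    """
    table = table or MaterialTable()
    b = np.asarray(bottom_cap, dtype=float)
    t = np.asarray(top_cap, dtype=float)
    if b.shape != t.shape:
        raise ValidationError("endplate caps must have matching node layouts")
    # outward normal of the bottom cap (from the triangulation winding):
    # the top cap must lie strictly on its positive side
    tri = np.asarray(cap_triangles, dtype=int)
    n_out = np.cross(b[tri[:, 1]] - b[tri[:, 0]], b[tri[:, 2]] - b[tri[:, 0]]).sum(axis=0)
    n_out = n_out / np.linalg.norm(n_out)
    if np.any((t - b) @ n_out <= 0):
        raise ValidationError("endplates intersect: non-positive inter-endplate gap")
    axis = t.mean(axis=0) - b.mean(axis=0)
    axis = axis / np.linalg.norm(axis)

    n_cap = len(b)
    frac = np.linspace(0.0, 1.0, n_layers + 1)
    layers = b[None] * (1 - frac)[:, None, None] + t[None] * frac[:, None, None]
    nodes = layers.reshape(-1, 3)
    tets = []
    for L in range(n_layers):
        lo, hi = L * n_cap, (L + 1) * n_cap
        for tri in np.asarray(cap_triangles, dtype=int):
            tets.extend(_split_prism(list(lo + tri), list(hi + tri)))
    tets = np.asarray(tets, dtype=int)
    from .geometry import tet_volumes

    vols = tet_volumes(nodes, tets)
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]

    mesh = TetMesh(nodes=nodes, tets=tets, provenance=f"disk:{level}")
    mesh.extras["n_cap_nodes"] = n_cap
    mesh.extras["n_layers"] = n_layers
    mesh.extras["cap_triangles"] = np.asarray(cap_triangles, dtype=int)
    mesh.extras["perimeter_loop"] = _cap_perimeter_loop(np.asarray(cap_triangles, dtype=int))
    disk = DiskModel(
        mesh=mesh,
        level=level,
        axis=axis,
        nucleus_radius=0.0,
        nucleus_fraction_target=nucleus_fraction,
    )
    size_nucleus(disk, nucleus_fraction)
    if with_fibers:
        generate_annulus_fibers(
            disk,
            target_angle_deg=fiber_angle_deg,
            area_fraction=fiber_area_fraction,
        )
    return disk


def size_nucleus(disk: DiskModel, fraction: float) -> float:
    """Label the central cylindrical nucleus so its element volume is the
    requested share of the disk volume; returns the solved radius.

    The cylinder axis runs craniocaudally through the disk centroid; the
    radius is solved on the sorted element-centroid radial distances (the
    exact optimum of the discrete problem, equivalent to bisection refined
    to an element-width interval).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("nucleus fraction must be in [0, 1]")
    mesh = disk.mesh
    vols = np.abs(mesh.volumes())
    cent = mesh.centroids()
    c0 = (mesh.nodes * 1.0).mean(axis=0)
    rel = cent - c0
    radial = rel - np.outer(rel @ disk.axis, disk.axis)
    r = np.linalg.norm(radial, axis=1)
    order = np.argsort(r, kind="stable")
    cum = np.cumsum(vols[order]) / vols.sum()
    target = fraction
    if fraction <= 0:
        radius, n_in = 0.0, 0
    else:
        k = int(np.argmin(np.abs(cum - target)))
        n_in = k + 1
        r_in = r[order[k]]
        r_out = r[order[k + 1]] if k + 1 < len(r) else r_in * 1.05 + 1e-9
        radius = 0.5 * (r_in + r_out)
    labels = np.full(len(mesh.tets), "annulus", dtype=object)
    labels[order[:n_in]] = "nucleus"
    mesh.material_labels = labels.astype(str)
    disk.nucleus_radius = float(radius)
    disk.nucleus_fraction_target = fraction
    return float(radius)


# -- annulus fibers ----------------------------------------------------------


def _cap_perimeter_loop(cap_tris: np.ndarray) -> np.ndarray:
    """Cyclically ordered boundary node loop of a triangulated cap."""
    edges = np.sort(
        np.concatenate([cap_tris[:, [0, 1]], cap_tris[:, [1, 2]], cap_tris[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    border = uniq[counts == 1]
    nxt: dict[int, list[int]] = {}
    for a, b in border:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    start = min(nxt)
    loop = [start]
    prev = None
    while True:
        cands = [c for c in nxt[loop[-1]] if c != prev]
        prev = loop[-1]
        loop.append(cands[0])
        if loop[-1] == start:
            loop.pop()
            break
    return np.asarray(loop, dtype=int)


def _lateral_rings(mesh: TetMesh) -> list[np.ndarray]:
    """Cyclically ordered perimeter node ids per layer of a stacked disk."""
    n_cap = mesh.extras["n_cap_nodes"]
    n_layers = mesh.extras["n_layers"]
    loop = np.asarray(mesh.extras["perimeter_loop"], dtype=int)
    return [loop + L * n_cap for L in range(n_layers + 1)]


def generate_annulus_fibers(
    disk: DiskModel,
    target_angle_deg: float = 30.0,
    area_fraction: float = 0.16,
    tolerance_deg: float = 2.0,
) -> FiberSet:
    """Create two balanced criss-cross fiber families on the annulus wall.

    For each perimeter start node and family, candidate segments connect to
    higher rings at several (ring skip, circumferential offset) patterns; a
    deterministic greedy mix of the best candidate above and below the target
    keeps the running mean inclination at the target (discretization permits
    ±tolerance).  Fiber cross-sections are apportioned so the family total
    equals ``area_fraction`` of the annulus horizontal cross-section.
    """
    mesh = disk.mesh
    rings = _lateral_rings(mesh)
    if len(rings[0]) < 6:
        raise ValidationError("too few annulus boundary nodes to seed fibers")
    nodes = mesh.nodes
    axis = disk.axis
    n_ring = len(rings[0])
    patterns = [(m, k) for m in (1, 2, 3) for k in (1, 2, 3) if m < len(rings)]

    def angle_of(pa, pb) -> float:
        d = nodes[pb] - nodes[pa]
        L = np.linalg.norm(d)
        return float(np.degrees(np.arcsin(np.clip(abs(d @ axis) / L, -1, 1))))

    # bilateral symmetry check: if the disk nodes map onto themselves under
    # y -> -y, the minus family is built as the literal mirror image of the
    # plus family, so symmetric fixtures get exactly mirror-symmetric fibers
    from scipy.spatial import cKDTree

    tree = cKDTree(nodes)
    mirrored = nodes * np.array([1.0, -1.0, 1.0])
    d_mir, map_mir = tree.query(mirrored)
    is_symmetric = bool(np.max(d_mir) < 1e-9)

    def greedy_family(fam: int):
        out = []
        run_sum, run_n = 0.0, 0
        for Lr in range(len(rings) - 1):
            for p in range(n_ring):
                cands = []
                for m, k in patterns:
                    if Lr + m >= len(rings):
                        continue
                    a_id = rings[Lr][p]
                    b_id = rings[Lr + m][(p + fam * k) % n_ring]
                    ang = angle_of(a_id, b_id)
                    cands.append((ang, a_id, b_id))
                if not cands:
                    continue
                above = [c for c in cands if c[0] >= target_angle_deg]
                below = [c for c in cands if c[0] < target_angle_deg]
                hi = min(above, key=lambda c: c[0]) if above else None
                lo = max(below, key=lambda c: c[0]) if below else None
                if hi is None:
                    pick = lo
                elif lo is None:
                    pick = hi
                else:
                    mean_hi = (run_sum + hi[0]) / (run_n + 1)
                    mean_lo = (run_sum + lo[0]) / (run_n + 1)
                    pick = (
                        hi
                        if abs(mean_hi - target_angle_deg) <= abs(mean_lo - target_angle_deg)
                        else lo
                    )
                run_sum += pick[0]
                run_n += 1
                out.append(pick)
        return out

    pairs, fams, angles = [], [], []
    plus = greedy_family(+1)
    for ang, a_id, b_id in plus:
        pairs.append((a_id, b_id))
        fams.append(+1)
        angles.append(ang)
    if is_symmetric:
        for ang, a_id, b_id in plus:
            pairs.append((int(map_mir[a_id]), int(map_mir[b_id])))
            fams.append(-1)
            angles.append(ang)
    else:
        for ang, a_id, b_id in greedy_family(-1):
            pairs.append((a_id, b_id))
            fams.append(-1)
            angles.append(ang)

    pairs = np.asarray(pairs, dtype=int)
    fams = np.asarray(fams, dtype=int)
    angles = np.asarray(angles, dtype=float)
    rest = np.linalg.norm(nodes[pairs[:, 1]] - nodes[pairs[:, 0]], axis=1)

    vols = np.abs(mesh.volumes())
    annulus_vol = vols[mesh.material_labels == "annulus"].sum()
    a_cross = annulus_vol / max(disk.height(), 1e-9)
    area = np.full(len(pairs), area_fraction * a_cross / max(len(pairs), 1))
    disk.fibers = FiberSet(
        pairs=pairs, family=fams, rest_length=rest, area=area, inclination_deg=angles
    )
    return disk.fibers


# ---------------------------------------------------------------------------
# ligaments
# ---------------------------------------------------------------------------

_GROUP_SETS = {
    "ALL": "lig_all",
    "PLL": "lig_pll",
    "LF": "lig_lf",
    "ISL": "lig_isl",
    "SSL": "lig_ssl",
}


def build_ligaments(
    model: SpineModel, junction_name: str, table: MaterialTable | None = None
) -> LigamentSet:
    """Create the six ligament groups spanning one junction.

    Springs connect the inferior insertion sets of the cranial vertebra to
    the superior sets of the caudal one, paired in construction order; the
    capsular group pairs the 12 capsule nodes of each facet ring-wise from
    the joint outward.  Reference lengths are the assembled distances, so all
    ligament forces vanish in the reference state.
    """
    table = table or MaterialTable()
    j = model.junction_by_name(junction_name)
    hi, lo = model.vertebrae[j.cranial], model.vertebrae[j.caudal]
    hi_pose, lo_pose = model.poses[j.cranial], model.poses[j.caudal]
    out = LigamentSet(junction=junction_name)

    def ordered(surf, key):
        om = surf.extras.get("ordered_regions", {})
        if key not in om:
            raise ValidationError(f"missing insertion set {key!r}")
        return om[key]

    for group, base in _GROUP_SETS.items():
        top_ids = ordered(hi, f"{base}_inf")
        bot_ids = ordered(lo, f"{base}_sup")
        if len(top_ids) != len(bot_ids):
            raise ValidationError(f"insertion set size mismatch for group {group}")
        curve = table.ligament_curves[group]
        for a_id, b_id in zip(top_ids, bot_ids):
            a = hi_pose.apply(hi.vertices[a_id])
            b = lo_pose.apply(lo.vertices[b_id])
            out.springs.append(
                LigamentSpring(group, a, b, curve, float(np.linalg.norm(a - b)))
            )

    curve = table.ligament_curves["CL"]
    for side in ("left", "right"):
        top_ids = ordered(hi, f"capsule_{side}_inf")  # rings base->tip, 3x4
        bot_ids = ordered(lo, f"capsule_{side}_sup")
        # pair ring-from-tip with matching corner: tip ring to tip ring, etc.
        t_r = top_ids.reshape(3, 4)[::-1]
        b_r = bot_ids.reshape(3, 4)[::-1]
        for a_id, b_id in zip(t_r.ravel(), b_r.ravel()):
            a = hi_pose.apply(hi.vertices[a_id])
            b = lo_pose.apply(lo.vertices[b_id])
            out.springs.append(
                LigamentSpring("CL", a, b, curve, float(np.linalg.norm(a - b)))
            )
    return out


# ---------------------------------------------------------------------------
# facet contacts
# ---------------------------------------------------------------------------


def build_facet_contacts(model: SpineModel, junction_name: str) -> FacetContactSet:
    """Frictionless node-to-node gap elements across both facet joints.

    Tip nodes are matched one-to-one by nearest neighbour; the gap direction
    is the average facet-tip normal and the clearance the assembled projected
    distance (exactly the configured joint clearance for generated fixtures).
    """
    j = model.junction_by_name(junction_name)
    hi, lo = model.vertebrae[j.cranial], model.vertebrae[j.caudal]
    out = FacetContactSet(junction=junction_name)
    for side in ("left", "right"):
        ks, ki = f"{side}_facet_sup", f"{side}_facet_inf"
        if ks not in lo.extras.get("ordered_regions", {}) or ki not in hi.extras.get(
            "ordered_regions", {}
        ):
            raise ValidationError(f"missing facet sets on {side} side at {junction_name}")
        sup = model.poses[j.caudal].apply(lo.vertices[lo.extras["ordered_regions"][ks]])
        inf = model.poses[j.cranial].apply(hi.vertices[hi.extras["ordered_regions"][ki]])
        # one-to-one greedy nearest-neighbour matching
        from scipy.spatial import cKDTree

        remaining = list(range(len(inf)))
        pairs = []
        for si in range(len(sup)):
            tree = cKDTree(inf[remaining])
            _, k = tree.query(sup[si])
            pairs.append((si, remaining.pop(int(k))))
        if len(pairs) != len(sup):
            raise ValidationError(f"unmatched facet node sets at {junction_name} ({side})")
        # gap direction: the construction facet normal (average of the two
        # posed craniocaudal axes) when the generator recorded it — this
        # makes the assembled clearance exactly the configured value even at
        # subluxed (slipped) joints; averaged patch normals otherwise
        if j.facet_normal is not None:
            normal = np.asarray(j.facet_normal, dtype=float)
        else:
            n_sup, n_inf = _patch_normal(sup), _patch_normal(inf)
            if n_inf @ n_sup < 0:
                n_inf = -n_inf
            normal = n_sup + n_inf
        normal = normal / np.linalg.norm(normal)
        if normal[2] < 0:
            normal = -normal  # point from caudal toward cranial
        for si, ii in pairs:
            clearance = float((inf[ii] - sup[si]) @ normal)
            out.gaps.append(GapElement(a=sup[si], b=inf[ii], direction=normal, clearance=clearance))
    return out


def _patch_normal(pts: np.ndarray) -> np.ndarray:
    c = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - c)
    return vt[2]


# ---------------------------------------------------------------------------
# disk condition
# ---------------------------------------------------------------------------


def set_disk_condition(disk: DiskModel, condition: str) -> DiskModel:
    """Set the healthy / soft (unstable) / removed state of one disk.

    ``soft`` halves the annulus ground and fiber stiffness (nucleus
    unchanged); ``removed`` marks the disk for complete deactivation —
    the pipeline then also drops the ALL and PLL springs at that level and
    adds no endplate contact in their place.
    """
    if condition not in DISK_CONDITIONS:
        raise ValidationError(
            f"unknown disk condition {condition!r}; expected one of {DISK_CONDITIONS}"
        )
    disk.condition = condition
    return disk


def disk_elastics(disk: DiskModel, table: MaterialTable):
    """Per-element elastic constants for the disk under its condition."""
    if disk.condition == "removed":
        return None
    ground = table.annulus_ground if disk.condition == "healthy" else table.annulus_ground_soft
    fiber_E = table.fiber_modulus if disk.condition == "healthy" else table.fiber_modulus_soft
    return {"annulus": ground, "nucleus": table.nucleus, "fiber_modulus": fiber_E}
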