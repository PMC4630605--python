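"""Synthetic parametric vertebrae and spine fixtures with labeled regions.

The generator replaces a radiographic-reconstruction front-end: it emits
closed triangulated vertebral surfaces whose nodes carry named anatomical
region sets (endplates, pedicles, posterior elements, facet patches,
ligament insertions) and point landmarks, plus the conforming tetrahedral
volume mesh the surfaces are extracted from.

A synthetic vertebra is a union of conforming block meshes:

* an octagonal-footprint prismatic *body* (elliptical mask on a structured
  grid),
* a posterior *block* standing in for pedicles and lamina (solid, so the
  whole surface stays genus 0),
* a *spinous process* bar,
* four *articular processes* lofted from the posterior block; their tip
  faces are the facet contact patches.

Anatomical realism is deliberately coarse: every downstream operation keys
on the region sets and landmarks, not on surface fidelity.  Articular
process tips are junction-adapted so that, in the assembled (posed) spine,
every facet node pair sits at exactly the configured joint clearance.

Frame: X = anterior, Y = left, Z = cranial; units mm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    MeshBuilder,
    RigidTransform,
    boundary_edge_count,
    boundary_faces,
    box_grid,
    euler_characteristic,
    intrinsic_yxz,
    is_closed_manifold,
    surface_volume,
    tet_volumes,
)

__all__ = [
    "VertebraSpec",
    "VertebraSurface",
    "VolumeMesh",
    "FixtureConfig",
    "SpineModel",
    "Junction",
    "generate_vertebra_surface",
    "generate_spine_fixture",
    "track_landmark_nodes",
    "load_surface",
    "save_surface",
    "test_case_fixture_config",
]

FACET_CLEARANCE_MM = 0.4  # unloaded facet-joint gap, identical for all joints


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# specs and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VertebraSpec:
    """Per-level size parameters of the synthetic vertebra (mm).

    Pedicle cross-section is derived from the body dimensions (width/6 by
    height/2) so that all sub-blocks stay grid-conforming.
    """

    body_width: float = 42.0  # lateral (Y) extent of the body
    body_depth: float = 32.0  # anteroposterior (X) extent of the body
    body_height: float = 28.0  # craniocaudal (Z) extent of the body
    post_depth: float = 16.0  # anteroposterior depth of the posterior block
    spinous_length: float = 16.0  # length of the spinous bar behind the block
    process_extent: float = 10.0  # default articular-process length (standalone)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"vertebra dimension {f.name!r} must be > 0, got {v}")

    @property
    def pedicle_width(self) -> float:
        return self.body_width / 6.0

    @property
    def pedicle_height(self) -> float:
        return self.body_height / 2.0

    def scaled(self, factor: float) -> "VertebraSpec":
        return VertebraSpec(**{f.name: getattr(self, f.name) * factor for f in dataclasses.fields(self)})


@dataclass
class VolumeMesh:
    """Tetrahedral volume mesh a surface was extracted from."""

    nodes: np.ndarray  # (n, 3)
    tets: np.ndarray  # (m, 4), positive signed volume
    surface_to_volume: np.ndarray  # surface vertex index -> volume node index


@dataclass
class VertebraSurface:
    """Closed triangulated vertebral surface with labeled regions/landmarks."""

    vertices: np.ndarray
    triangles: np.ndarray
    region_sets: dict[str, np.ndarray] = field(default_factory=dict)
    landmarks: dict[str, int] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)  # auxiliary orderings, grids
    volume: VolumeMesh | None = None

    def enclosed_volume(self) -> float:
        return surface_volume(self.vertices, self.triangles)

    def euler_characteristic(self) -> int:
        return euler_characteristic(self.vertices, self.triangles)

    def validate(self) -> None:
        n = len(self.vertices)
        if not is_closed_manifold(self.triangles):
            raise ValidationError(
                f"surface is not a closed manifold ({boundary_edge_count(self.triangles)} boundary edges)"
            )
        if self.euler_characteristic() != 2:
            raise ValidationError("surface is not genus-0 (Euler characteristic != 2)")
        if self.enclosed_volume() <= 0:
            raise ValidationError("enclosed volume must be positive (check winding)")
        for name, idx in self.region_sets.items():
            idx = np.asarray(idx)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValidationError(f"region set {name!r} references invalid node indices")
        sup = set(np.asarray(self.region_sets.get("superior_endplate", [])).tolist())
        inf = set(np.asarray(self.region_sets.get("inferior_endplate", [])).tolist())
        if sup & inf:
            raise ValidationError("superior and inferior endplate sets overlap")


@dataclass
class Junction:
    """Adjacency metadata: which endplate pair faces each other."""

    cranial: str
    caudal: str
    gap: float  # unloaded disk height between the facing endplates (mm)
    facet_normal: np.ndarray | None = None  # unit contact direction (assembled)

    @property
    def name(self) -> str:
        return f"{self.cranial}-{self.caudal}"


@dataclass
class FixtureConfig:
    """Configuration of the synthetic multi-level spine fixture.

    ``levels`` are ordered cranial to caudal (e.g. L2..L5).  ``slip_mm`` maps
    junction names like ``"L3-L4"`` to an anterior translation applied to
    every vertebra cranial to that junction.  Coronal/axial asymmetry totals
    are distributed linearly across levels (zero at the caudal-most level).
    """

    levels: tuple[str, ...] = ("L2", "L3", "L4", "L5")
    specs: dict[str, VertebraSpec] = field(default_factory=dict)
    disk_gap: float = 10.0
    slip_mm: dict[str, float] = field(default_factory=dict)
    coronal_asymmetry_deg: float = 0.0
    axial_asymmetry_deg: float = 0.0
    jitter_amplitude: float = 0.0
    seed: int = 0

    def spec_for(self, level: str) -> VertebraSpec:
        return self.specs.get(level, VertebraSpec())

    def validate(self) -> None:
        if len(self.levels) < 2:
            raise ValidationError("a spine fixture needs at least 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValidationError("duplicate level labels")
        if self.disk_gap <= 0:
            raise ValidationError("endplates intersect: disk gap must be > 0")
        if self.jitter_amplitude < 0:
            raise ValidationError("jitter amplitude must be >= 0")
        for k, v in self.slip_mm.items():
            if not np.isfinite(v):
                raise ValidationError(f"slip at {k} must be finite")
            if k not in self.junction_names():
                raise ValidationError(f"unknown junction {k!r}")

    def junction_names(self) -> list[str]:
        return [f"{a}-{b}" for a, b in zip(self.levels[:-1], self.levels[1:])]


def test_case_fixture_config() -> FixtureConfig:
    """Baseline fixture emulating the benchmark patient: L2-L5 with a 14 mm
    anterior slip at L3-L4 and minor coronal (6 deg) / axial (3 deg)
    asymmetries."""
    return FixtureConfig(
        levels=("L2", "L3", "L4", "L5"),
        slip_mm={"L3-L4": 14.0},
        coronal_asymmetry_deg=6.0,
        axial_asymmetry_deg=3.0,
    )


@dataclass
class SpineModel:
    """Ordered vertebral surfaces + per-vertebra rigid pose + junctions."""

    levels: tuple[str, ...]
    vertebrae: dict[str, VertebraSurface]
    poses: dict[str, RigidTransform]
    junctions: list[Junction]
    config: FixtureConfig | None = None

    def posed_vertices(self, level: str) -> np.ndarray:
        return self.poses[level].apply(self.vertebrae[level].vertices)

    def posed_volume_nodes(self, level: str) -> np.ndarray:
        vol = self.vertebrae[level].volume
        if vol is None:
            raise ValidationError(f"vertebra {level} carries no volume mesh")
        return self.poses[level].apply(vol.nodes)

    def landmark_position(self, level: str, name: str) -> np.ndarray:
        surf = self.vertebrae[level]
        return self.poses[level].apply(surf.vertices[surf.landmarks[name]])

    def junction_by_name(self, name: str) -> Junction:
        for j in self.junctions:
            if j.name == name:
                return j
        raise ValidationError(f"unknown junction {name!r}")


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------


def _grid_1d(step: float, i0: int, i1: int) -> np.ndarray:
    return step * np.arange(i0, i1 + 1)


class _Template:
    """Grid bookkeeping for one vertebra spec (template frame, body centred
    at the origin)."""

    def __init__(self, spec: VertebraSpec):
        self.spec = spec
        self.cx = spec.body_depth / 4.0
        self.cy = spec.body_width / 6.0
        self.cz = spec.body_height / 4.0
        self.post_x0 = -2 * self.cx - spec.post_depth
        self.spin_x0 = self.post_x0 - spec.spinous_length

    # -- body -------------------------------------------------------------
    def body_grid(self) -> np.ndarray:
        return box_grid(
            _grid_1d(self.cx, -2, 2), _grid_1d(self.cy, -3, 3), _grid_1d(self.cz, -2, 2)
        )

    def body_mask(self) -> np.ndarray:
        # drop cells whose centre lies outside the body ellipse -> octagon
        a, b = 2 * self.cx, 3 * self.cy
        xc = self.cx * (np.arange(4) - 1.5)
        yc = self.cy * (np.arange(6) - 2.5)
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        inside = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
        return np.repeat(inside[:, :, None], 4, axis=2)

    def endplate_grid(self, which: str) -> np.ndarray:
        """Full 5x7 node grid of the superior/inferior body face (template)."""
        z = 2 * self.cz if which == "superior" else -2 * self.cz
        g = box_grid(_grid_1d(self.cx, -2, 2), _grid_1d(self.cy, -3, 3), np.array([z]))
        return g[:, :, 0, :]

    def endplate_cell_mask(self) -> np.ndarray:
        return self.body_mask()[:, :, 0]

    # -- posterior block / spinous ----------------------------------------
    def block_grid(self) -> np.ndarray:
        P = self.spec.post_depth
        x = np.array([self.post_x0, self.post_x0 + P / 2.0, -2 * self.cx])
        return box_grid(x, _grid_1d(self.cy, -2, 2), _grid_1d(self.cz, -1, 1))

    def spinous_grid(self) -> np.ndarray:
        S = self.spec.spinous_length
        x = np.array([self.spin_x0, self.spin_x0 + S / 2.0, self.post_x0])
        return box_grid(x, _grid_1d(self.cy, -1, 1), _grid_1d(self.cz, -1, 1))

    # -- articular processes ----------------------------------------------
    def process_base_grid(self, side: str, which: str) -> np.ndarray:
        """(2,2,3) node grid of a process root on the posterior block face."""
        P = self.spec.post_depth
        x = np.array([self.post_x0, self.post_x0 + P / 2.0])
        y = _grid_1d(self.cy, 1, 2) if side == "left" else _grid_1d(self.cy, -2, -1)
        z = self.cz if which == "sup" else -self.cz
        g = box_grid(x, y, np.array([z]))
        return g[:, :, 0, :]

    def default_process_tip(self, side: str, which: str, extent: float) -> np.ndarray:
        base = self.process_base_grid(side, which)
        dz = extent if which == "sup" else -extent
        return base + np.array([0.0, 0.0, dz])


def _build_vertebra(
    spec: VertebraSpec,
    process_tips: dict[tuple[str, str], np.ndarray] | None = None,
    jitter_amplitude: float = 0.0,
    rng: np.random.Generator | None = None,
) -> VertebraSurface:
    """Assemble the conforming vertebra tet mesh and extract its surface.

    ``process_tips`` optionally overrides the (2,2,3) tip grid of each
    articular process, keyed by (side, 'sup'|'inf'); used by the spine
    generator to realise exact facet clearances in the assembled state.
    """
    t = _Template(spec)
    builder = MeshBuilder()
    body_elems = builder.add_hex_grid(t.body_grid(), t.body_mask())
    builder.add_hex_grid(t.block_grid())
    builder.add_hex_grid(t.spinous_grid())

    tip_nodes: dict[tuple[str, str], np.ndarray] = {}
    process_nodes: dict[tuple[str, str], np.ndarray] = {}
    for side in ("left", "right"):
        for which in ("sup", "inf"):
            base = t.process_base_grid(side, which)
            if process_tips and (side, which) in process_tips:
                tip = np.asarray(process_tips[(side, which)], dtype=float)
            else:
                tip = t.default_process_tip(side, which, spec.process_extent)
            bottom, top = (base, tip) if which == "sup" else (tip, base)
            builder.add_loft(bottom, top, 2)
            tip_nodes[(side, which)] = np.array(
                [[builder.node_id(tip[i, j]) for j in range(2)] for i in range(2)]
            )
            # all 12 nodes (3 rings of 4) of the lofted process, by the same
            # interpolation arithmetic the loft used
            frac = np.linspace(0.0, 1.0, 3)
            rings = base[None] * (1 - frac)[:, None, None, None] + tip[None] * frac[:, None, None, None]
            process_nodes[(side, which)] = np.array(
                [builder.node_id(p) for p in rings.reshape(-1, 3)]
            )

    nodes, tets = builder.build()
    n_body_tets = len(body_elems)
    body_tet_ids = np.asarray(body_elems, dtype=int)

    if jitter_amplitude > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        nodes = _apply_jitter(nodes, tets, t, jitter_amplitude, rng)

    tris = boundary_faces(tets)
    surf_nodes = np.unique(tris)
    remap = -np.ones(len(nodes), dtype=int)
    remap[surf_nodes] = np.arange(len(surf_nodes))
    surface = VertebraSurface(
        vertices=nodes[surf_nodes],
        triangles=remap[tris],
        volume=VolumeMesh(nodes=nodes, tets=tets, surface_to_volume=surf_nodes),
    )
    _label_regions(surface, t, remap, tip_nodes, process_nodes)
    surface.extras["n_body_tets"] = n_body_tets
    surface.extras["body_tet_ids"] = body_tet_ids
    surface.extras["template"] = t
    return surface


def _apply_jitter(nodes, tets, t: _Template, amplitude: float, rng) -> np.ndarray:
    """Perturb lateral body-surface nodes only (endplates, posterior elements,
    landmarks and interfaces stay exact)."""
    tris = boundary_faces(tets)
    on_surface = np.zeros(len(nodes), dtype=bool)
    on_surface[np.unique(tris)] = True
    x, y, z = nodes[:, 0], nodes[:, 1], nodes[:, 2]
    eps = 1e-9
    lateral = (
        on_surface
        & (x > -2 * t.cx + eps)
        & (np.abs(z) < 2 * t.cz - eps)
        & (np.abs(np.abs(y) - 3 * t.cy) < 10 * t.cy)  # body region only
    )
    # exclude the anterior mid-column which hosts the body_center landmark
    lateral &= ~((np.abs(y) < eps) & (x > 2 * t.cx - eps))
    out = nodes.copy()
    out[lateral] += amplitude * rng.uniform(-1.0, 1.0, size=(int(lateral.sum()), 3))
    if np.any(tet_volumes(out, tets) <= 0):
        raise ValidationError("jitter amplitude too large: it inverts elements")
    return out


def _select(vertices: np.ndarray, predicate) -> np.ndarray:
    return np.nonzero(predicate(vertices[:, 0], vertices[:, 1], vertices[:, 2]))[0]


def _label_regions(surface: VertebraSurface, t: _Template, vol_to_surf, tip_nodes, process_nodes) -> None:
    v = surface.vertices
    cx, cy, cz = t.cx, t.cy, t.cz
    eps = 1e-6
    regions: dict[str, np.ndarray] = {}

    body = _select(v, lambda x, y, z: x >= -2 * cx - eps)
    regions["vertebral_body"] = body
    regions["superior_endplate"] = _select(v, lambda x, y, z: (x >= -2 * cx - eps) & (np.abs(z - 2 * cz) < eps))
    regions["inferior_endplate"] = _select(v, lambda x, y, z: (x >= -2 * cx - eps) & (np.abs(z + 2 * cz) < eps))
    post = _select(v, lambda x, y, z: x < -2 * cx - eps)
    in_block_x = lambda x: (x >= t.post_x0 - eps) & (x <= -2 * cx + eps)
    regions["left_pedicle"] = _select(
        v, lambda x, y, z: in_block_x(x) & (y >= cy - eps) & (np.abs(z) <= cz + eps)
    )
    regions["right_pedicle"] = _select(
        v, lambda x, y, z: in_block_x(x) & (y <= -cy + eps) & (np.abs(z) <= cz + eps)
    )
    # lamina, spinous and articular processes carry the single posterior
    # material; pedicles classify cortical/trabecular like the body, so the
    # zones are kept disjoint
    pedicles = set(regions["left_pedicle"].tolist()) | set(regions["right_pedicle"].tolist())
    regions["posterior_elements"] = np.array(
        [i for i in post if i not in pedicles], dtype=int
    )

    for side in ("left", "right"):
        for which in ("sup", "inf"):
            regions[f"{side}_facet_{which}"] = vol_to_surf[tip_nodes[(side, which)].ravel()]

    # ligament insertion sets (template-symmetric node triples / singletons)
    def nodes_at(pts) -> np.ndarray:
        idx = []
        for p in np.atleast_2d(pts):
            d = np.linalg.norm(v - p, axis=1)
            k = int(np.argmin(d))
            if d[k] > 1e-6:
                raise ValidationError(f"expected insertion node at {p}, nearest is {d[k]:.3g} mm away")
            idx.append(k)
        return np.asarray(idx, dtype=int)

    ys3 = np.array([-cy, 0.0, cy])
    for which, zs in (("sup", 2 * cz), ("inf", -2 * cz)):
        regions[f"lig_all_{which}"] = nodes_at([[2 * cx, yy, zs] for yy in ys3])
        regions[f"lig_pll_{which}"] = nodes_at([[-2 * cx, yy, zs] for yy in ys3])
    for which, zb in (("sup", cz), ("inf", -cz)):
        regions[f"lig_lf_{which}"] = nodes_at([[t.post_x0 + t.spec.post_depth / 2.0, yy, zb] for yy in ys3])
        xs3 = np.array([t.spin_x0, t.spin_x0 + t.spec.spinous_length / 2.0, t.post_x0])
        regions[f"lig_isl_{which}"] = nodes_at([[xx, 0.0, zb] for xx in xs3])
        regions[f"lig_ssl_{which}"] = nodes_at([[t.spin_x0, 0.0, zb]])

    # capsular insertions: all 12 nodes (3 rings of 4) of each articular process
    for side in ("left", "right"):
        for which in ("sup", "inf"):
            regions[f"capsule_{side}_{which}"] = vol_to_surf[process_nodes[(side, which)]]

    # construction-ordered copies (pairing of ligament insertions across a
    # junction relies on this order; region_sets themselves stay sorted)
    surface.extras["ordered_regions"] = {
        k: np.asarray(ix, dtype=int).copy()
        for k, ix in regions.items()
        if k.startswith(("lig_", "capsule_")) or "facet" in k
    }
    surface.region_sets = {k: np.asarray(sorted(set(np.asarray(ix).tolist())), dtype=int) for k, ix in regions.items()}

    lm = {}
    lm["body_center"] = int(nodes_at([[2 * cx, 0.0, 0.0]])[0])
    lm["spinous_tip"] = int(nodes_at([[t.spin_x0, 0.0, 0.0]])[0])
    lm["left_pedicle_entry"] = int(nodes_at([[t.post_x0, 2 * cy, 0.0]])[0])
    lm["right_pedicle_entry"] = int(nodes_at([[t.post_x0, -2 * cy, 0.0]])[0])
    surface.landmarks = lm

    # endplate grid orderings used for disk extrusion
    for which in ("superior", "inferior"):
        g = t.endplate_grid(which)
        surface.extras[f"{which}_endplate_grid"] = g
    surface.extras["endplate_cell_mask"] = t.endplate_cell_mask()


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def generate_vertebra_surface(spec: VertebraSpec | None = None) -> VertebraSurface:
    """Generate a standalone labeled synthetic vertebra surface."""
    spec = spec or VertebraSpec()
    surface = _build_vertebra(spec)
    surface.validate()
    return surface


def generate_spine_fixture(config: FixtureConfig | None = None) -> SpineModel:
    """Generate the posed multi-level synthetic spine fixture.

    Slip is applied as a rigid anterior translation of every vertebra cranial
    to the slipped junction.  Asymmetry angles are distributed linearly from
    the caudal-most level (0) to the cranial-most (full value); rotations
    pivot about each vertebra's ``body_center`` landmark so that configured
    slips stay exactly measurable from the landmarks.
    """
    config = config or FixtureConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    levels = list(config.levels)  # cranial -> caudal
    caudal_first = levels[::-1]
    n = len(levels)

    # per-level pose parameters, accumulated caudal -> cranial
    specs = {lv: config.spec_for(lv) for lv in levels}
    z_off: dict[str, float] = {}
    z = 0.0
    for i, lv in enumerate(caudal_first):
        if i > 0:
            lower = caudal_first[i - 1]
            z += specs[lower].body_height / 2.0 + config.disk_gap + specs[lv].body_height / 2.0
        z_off[lv] = z

    frac = {lv: (i / (n - 1) if n > 1 else 0.0) for i, lv in enumerate(caudal_first)}
    rotations = {
        lv: intrinsic_yxz(
            0.0,
            config.coronal_asymmetry_deg * frac[lv],
            config.axial_asymmetry_deg * frac[lv],
        )
        for lv in levels
    }
    pivots = {
        lv: np.array([2 * _Template(specs[lv]).cx, 0.0, 0.0]) for lv in levels
    }
    # Slip is a rigid translation of all vertebrae cranial to the slipped
    # junction, applied along the caudal vertebra's anteroposterior axis and
    # compensated so the landmark-based slip measurement returns exactly the
    # configured value (with asymmetry rotations, a naive global-X shift
    # would leak part of the craniocaudal stack offset into the measurement).
    poses: dict[str, RigidTransform] = {}
    T = np.zeros(3)
    for i, lv in enumerate(caudal_first):
        if i > 0:
            lower = caudal_first[i - 1]
            jname = f"{lv}-{lower}"
            if jname in config.slip_mm:
                ap_axis = rotations[lower][:, 0]
                c_lo = poses[lower].apply(pivots[lower])  # body_center = pivot
                c_hi0 = pivots[lv] + np.array([0.0, 0.0, z_off[lv]]) + T
                delta = config.slip_mm[jname] - float((c_hi0 - c_lo) @ ap_axis)
                T = T + delta * ap_axis
        poses[lv] = RigidTransform.about_point(
            rotations[lv], pivots[lv], np.array([0.0, 0.0, z_off[lv]]) + T
        )

    junctions = [
        Junction(cranial=a, caudal=b, gap=config.disk_gap)
        for a, b in zip(levels[:-1], levels[1:])
    ]

    # Articular process tip grids: sup tips reach half a clearance below the
    # mid-disk plane.  Inf tips of the vertebra above sit exactly one
    # clearance along the average facet normal from the posed sup tips, plus
    # the in-plane component of the junction slip: at a slipped junction the
    # facets are subluxed in the assembled state (anatomically faithful) and
    # realign when the listhesis is reduced, while the unloaded joint
    # clearance along the facet normal stays exactly the configured value.
    tips: dict[str, dict[tuple[str, str], np.ndarray]] = {lv: {} for lv in levels}
    for j in junctions:
        tc, tk = _Template(specs[j.caudal]), _Template(specs[j.cranial])
        ext_sup = specs[j.caudal].body_height / 2.0 + j.gap / 2.0 - tc.cz - FACET_CLEARANCE_MM / 2.0
        if ext_sup <= 0:
            raise ValidationError(f"disk gap at {j.name} too small for facet geometry")
        n_dir = _facet_normal(poses[j.caudal], poses[j.cranial])
        j.facet_normal = n_dir
        slip_vec = config.slip_mm.get(j.name, 0.0) * rotations[j.caudal][:, 0]
        slip_in_plane = slip_vec - (slip_vec @ n_dir) * n_dir
        for side in ("left", "right"):
            sup_tip = tc.default_process_tip(side, "sup", ext_sup)
            tips[j.caudal][(side, "sup")] = sup_tip
            sup_tip_global = poses[j.caudal].apply(sup_tip.reshape(-1, 3))
            inf_tip_global = sup_tip_global + slip_in_plane + FACET_CLEARANCE_MM * n_dir
            inf_tip = poses[j.cranial].inverse().apply(inf_tip_global).reshape(sup_tip.shape)
            tips[j.cranial][(side, "inf")] = inf_tip

    vertebrae: dict[str, VertebraSurface] = {}
    for lv in levels:
        vertebrae[lv] = _build_vertebra(
            specs[lv],
            process_tips=tips[lv] or None,
            jitter_amplitude=config.jitter_amplitude,
            rng=rng,
        )
        vertebrae[lv].validate()

    model = SpineModel(
        levels=tuple(levels), vertebrae=vertebrae, poses=poses, junctions=junctions, config=config
    )
    _check_no_interpenetration(model)
    return model


def _facet_normal(pose_caudal: RigidTransform, pose_cranial: RigidTransform) -> np.ndarray:
    zc = pose_caudal.rotation[:, 2]
    zk = pose_cranial.rotation[:, 2]
    n = zc + zk
    return n / np.linalg.norm(n)


def _check_no_interpenetration(model: SpineModel) -> None:
    for j in model.junctions:
        lo = model.vertebrae[j.caudal]
        hi = model.vertebrae[j.cranial]
        sup = model.poses[j.caudal].apply(
            lo.vertices[lo.region_sets["superior_endplate"]]
        )
        inf = model.poses[j.cranial].apply(
            hi.vertices[hi.region_sets["inferior_endplate"]]
        )
        if inf[:, 2].min() <= sup[:, 2].max():
            raise ValidationError(f"vertebrae interpenetrate at junction {j.name}")


# ---------------------------------------------------------------------------
# landmark tracking
# ---------------------------------------------------------------------------


def track_landmark_nodes(
    template: VertebraSurface,
    morphed_vertices: np.ndarray,
    morphed_triangles: np.ndarray,
    coarsened: VertebraSurface | None = None,
) -> tuple[dict[str, int], dict[str, np.ndarray]]:
    """Carry landmark/region node indices from a template to a morphed surface.

    When the morphed surface preserves the template connectivity the indices
    transfer unchanged (the morph only moves nodes).  If a ``coarsened``
    surface is supplied, each tracked node is additionally mapped to its
    nearest node (Euclidean) on the coarsened surface and the returned sets
    refer to coarsened indices.
    """
    morphed_triangles = np.asarray(morphed_triangles, dtype=int)
    same_connectivity = morphed_triangles.shape == np.asarray(template.triangles).shape and np.array_equal(
        morphed_triangles, template.triangles
    )
    if not same_connectivity and coarsened is None:
        raise ValidationError(
            "morphed surface connectivity differs from template; supply a coarsened surface to remap"
        )
    landmarks = dict(template.landmarks)
    regions = {k: np.asarray(v, dtype=int).copy() for k, v in template.region_sets.items()}
    if coarsened is None:
        return landmarks, regions
    from scipy.spatial import cKDTree

    tree = cKDTree(np.asarray(coarsened.vertices, dtype=float))
    src = np.asarray(morphed_vertices, dtype=float)
    landmarks = {k: int(tree.query(src[i])[1]) for k, i in landmarks.items()}
    regions = {k: np.unique(tree.query(src[v])[1]) for k, v in regions.items()}
    return landmarks, regions


# ---------------------------------------------------------------------------
# surface I/O (STL / PLY / OFF + JSON sidecar)
# ---------------------------------------------------------------------------

_SIDE_SUFFIX = ".regions.json"


def _sidecar_path(path) -> str:
    import os

    base, _ = os.path.splitext(str(path))
    return base + _SIDE_SUFFIX


def save_surface(surface: VertebraSurface, path) -> None:
    """Write a surface as STL/PLY/OFF (ASCII) plus a JSON region sidecar.

    STL stores a triangle soup, so before export the vertex array is put in
    first-occurrence-in-face-order canonical form; reloading with
    :func:`load_surface` then reproduces indices exactly.
    """
    import json
    import os

    import trimesh

    path = str(path)
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext not in ("stl", "ply", "off"):
        raise ValidationError(f"unsupported surface format {ext!r}")
    surf = surface
    if ext == "stl":
        surf = _canonicalize_face_order(surface)
    mesh = trimesh.Trimesh(vertices=surf.vertices, faces=surf.triangles, process=False)
    if ext == "stl":
        data = mesh.export(file_type="stl_ascii")
        with open(path, "w") as fh:
            fh.write(data)
    elif ext == "ply":
        mesh.export(path, encoding="ascii")
    else:
        mesh.export(path)
    sidecar = {
        "landmarks": {k: int(v) for k, v in surf.landmarks.items()},
        "regions": {k: [int(i) for i in v] for k, v in surf.region_sets.items()},
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def load_surface(path, require_sidecar: bool = False) -> VertebraSurface:
    """Load a triangulated surface and its JSON region sidecar.

    Raises a validation error (with the open boundary-edge count) for
    non-watertight input.  A missing sidecar yields empty region sets and a
    warning.
    """
    import json
    import os
    import warnings

    import trimesh

    path = str(path)
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    mesh = trimesh.load(path, process=False, force="mesh")
    vertices = np.asarray(mesh.vertices, dtype=float)
    triangles = np.asarray(mesh.faces, dtype=int)
    if ext == "stl":
        vertices, triangles = _weld_first_occurrence(vertices, triangles)
    if not is_closed_manifold(triangles):
        raise ValidationError(
            f"surface {os.path.basename(path)} is not watertight: "
            f"{boundary_edge_count(triangles)} boundary edges"
        )
    surf = VertebraSurface(vertices=vertices, triangles=triangles)
    sc = _sidecar_path(path)
    if os.path.exists(sc):
        with open(sc) as fh:
            data = json.load(fh)
        surf.landmarks = {k: int(v) for k, v in data.get("landmarks", {}).items()}
        surf.region_sets = {
            k: np.asarray(v, dtype=int) for k, v in data.get("regions", {}).items()
        }
    elif require_sidecar:
        raise ValidationError(f"missing sidecar {sc}")
    else:
        warnings.warn(f"no region sidecar found at {sc}; surface loads with empty region sets")
    return surf


def _canonicalize_face_order(surface: VertebraSurface) -> VertebraSurface:
    order = []
    seen = np.zeros(len(surface.vertices), dtype=bool)
    for idx in np.asarray(surface.triangles).ravel():
        if not seen[idx]:
            seen[idx] = True
            order.append(idx)
    order = np.asarray(order, dtype=int)
    remap = np.empty(len(surface.vertices), dtype=int)
    remap[order] = np.arange(len(order))
    return VertebraSurface(
        vertices=surface.vertices[order],
        triangles=remap[np.asarray(surface.triangles)],
        region_sets={k: np.sort(remap[v]) for k, v in surface.region_sets.items()},
        landmarks={k: int(remap[v]) for k, v in surface.landmarks.items()},
    )


def _weld_first_occurrence(vertices: np.ndarray, triangles: np.ndarray):
    """Weld exactly-equal vertices keeping first-occurrence-in-face order."""
    index: dict[tuple, int] = {}
    out_v: list[np.ndarray] = []
    remap = np.empty(len(vertices), dtype=int)
    for face in triangles:
        for vi in face:
            key = tuple(vertices[vi])
            k = index.get(key)
            if k is None:
                k = len(out_v)
                index[key] = k
                out_v.append(vertices[vi])
            remap[vi] = k
    return np.asarray(out_v, dtype=float), remap[triangles]
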