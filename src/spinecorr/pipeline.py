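"""Assembly of the instrumented finite-element model.

Welds the posed vertebral volume meshes, the disks (conforming by shared
endplate nodes), ligament and fiber springs, facet gap elements, embedded
screws and — per correction plan — the posterior rods into one
:class:`~spinecorr.fe.FEModel`, keeping an index of every part for
postprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import SpineModel, ValidationError
from .fe.model import FEModel
from .geometry import MeshBuilder
from .instrumentation import (
    RodModel,
    RodSection,
    Screw,
    connect_screws_to_rod,
    default_screw_layout,
    embed_screw,
    fit_rod_curve,
    mesh_rod,
)
from .materials import LigamentCurve, MaterialTable
from .meshing import TetMesh, assign_materials
from .planning import CorrectionPlan
from .soft_tissue import (
    DiskModel,
    build_disk_grid,
    build_facet_contacts,
    build_ligaments,
    disk_elastics,
    set_disk_condition,
)

__all__ = ["ModelIndex", "build_instrumented_model", "add_rods"]


@dataclass
class ModelIndex:
    """Bookkeeping of what went where in the assembled FE model."""

    spine: SpineModel
    table: MaterialTable
    node_ids: dict[str, np.ndarray] = field(default_factory=dict)  # level -> global ids
    tet_ids: dict[str, np.ndarray] = field(default_factory=dict)  # level/junction -> elem ids
    disks: dict[str, DiskModel] = field(default_factory=dict)
    disk_states: dict[str, str] = field(default_factory=dict)
    spring_ids: dict[str, list[int]] = field(default_factory=dict)  # tag -> spring ids
    gap_ids: dict[str, list[int]] = field(default_factory=dict)  # junction -> gap ids
    screws: list[Screw] = field(default_factory=list)
    screw_refs: dict[str, int] = field(default_factory=dict)  # screw name -> ref node
    screw_couplings: dict[str, int] = field(default_factory=dict)  # name -> coupling index
    rods: dict[str, dict] = field(default_factory=dict)  # side -> rod info
    screw_ties: dict[str, int] = field(default_factory=dict)  # name -> tie index

    def landmark_node(self, level: str, name: str) -> int:
        surf = self.spine.vertebrae[level]
        vol_idx = surf.volume.surface_to_volume[surf.landmarks[name]]
        return int(self.node_ids[level][vol_idx])

    def surface_nodes(self, level: str, region: str) -> np.ndarray:
        surf = self.spine.vertebrae[level]
        vol_idx = surf.volume.surface_to_volume[surf.region_sets[region]]
        return self.node_ids[level][vol_idx]


def _linear_curve(k: float) -> LigamentCurve:
    return LigamentCurve(((0.0, 0.0), (1.0, float(k))))


def build_instrumented_model(
    spine: SpineModel,
    *,
    table: MaterialTable | None = None,
    screws: list[Screw] | None = None,
    disk_states: dict[str, str] | None = None,
    discectomy_levels: list[str] | None = None,
    n_disk_layers: int = 3,
    nucleus_fraction: float = 0.5,
    capture_radius: float | None = None,
) -> tuple[FEModel, ModelIndex]:
    """Assemble the instrumented spine (without rods; see :func:`add_rods`)."""
    table = table or MaterialTable()
    disk_states = dict(disk_states or {})
    discectomy = set(discectomy_levels or [])
    for j in spine.junctions:
        disk_states.setdefault(j.name, "healthy")
        if j.name in discectomy:
            disk_states[j.name] = "removed"

    fe = FEModel()
    index = ModelIndex(spine=spine, table=table)
    weld = MeshBuilder()

    def global_ids(points: np.ndarray, must_exist: bool = False) -> np.ndarray:
        known = len(weld.nodes)
        ids = np.array([weld.node_id(p) for p in np.atleast_2d(points)], dtype=int)
        if must_exist and ids.max(initial=-1) >= known:
            raise ValidationError("expected coordinates to weld onto existing nodes")
        return ids

    # -- vertebrae ---------------------------------------------------------
    for lv in spine.levels:
        surf = spine.vertebrae[lv]
        vol = surf.volume
        posed = spine.poses[lv].apply(vol.nodes)
        ids = global_ids(posed)
        _sync_nodes(fe, weld)
        index.node_ids[lv] = ids
        # material labels on the template mesh (cortical shell criterion uses
        # the vertebra's own boundary, before disks cover the endplates)
        tm = TetMesh(nodes=vol.nodes, tets=vol.tets, provenance=f"vertebra:{lv}")
        regions = {
            k: vol.surface_to_volume[surf.region_sets[k]]
            for k in ("vertebral_body", "left_pedicle", "right_pedicle", "posterior_elements")
        }
        assign_materials(tm, regions, table)
        lam = np.empty(len(vol.tets))
        mu = np.empty(len(vol.tets))
        for label in np.unique(tm.material_labels):
            m = tm.material_labels == label
            la, m_u = table.bone(str(label)).lame()
            lam[m], mu[m] = la, m_u
        index.tet_ids[lv] = fe.add_tet_block(ids[vol.tets], lam, mu, tag=f"vertebra:{lv}")
        index.tet_ids[f"{lv}:labels"] = tm.material_labels

    # -- disks -------------------------------------------------------------
    for j in spine.junctions:
        state = disk_states[j.name]
        index.disk_states[j.name] = state
        if state == "removed":
            continue
        lo, hi = spine.vertebrae[j.caudal], spine.vertebrae[j.cranial]
        bg = lo.extras["superior_endplate_grid"]
        tg = hi.extras["inferior_endplate_grid"]
        mask = lo.extras["endplate_cell_mask"]
        disk = build_disk_grid(
            spine.poses[j.caudal].apply(bg.reshape(-1, 3)).reshape(bg.shape),
            spine.poses[j.cranial].apply(tg.reshape(-1, 3)).reshape(tg.shape),
            mask,
            level=j.name,
            n_layers=n_disk_layers,
            nucleus_fraction=nucleus_fraction,
            table=table,
        )
        set_disk_condition(disk, state)
        index.disks[j.name] = disk
        ela = disk_elastics(disk, table)
        dids = global_ids(disk.mesh.nodes)
        _sync_nodes(fe, weld)
        lam = np.empty(len(disk.mesh.tets))
        mu = np.empty(len(disk.mesh.tets))
        for label in ("annulus", "nucleus"):
            m = disk.mesh.material_labels == label
            la, m_u = ela[label].lame()
            lam[m], mu[m] = la, m_u
        index.tet_ids[j.name] = fe.add_tet_block(
            dids[disk.mesh.tets], lam, mu, tag=f"disk:{j.name}"
        )
        # annulus fibers: tension-only linear springs
        fib = disk.fibers
        tagf = f"fiber:{j.name}"
        index.spring_ids[tagf] = []
        for i in range(len(fib)):
            a, b = dids[fib.pairs[i]]
            k = ela["fiber_modulus"] * fib.area[i] / max(fib.rest_length[i], 1e-9)
            sid = fe.add_spring(
                int(a), int(b), _linear_curve(k), rest_length=fib.rest_length[i], tag=tagf
            )
            index.spring_ids[tagf].append(sid)

    # -- ligaments ---------------------------------------------------------
    for j in spine.junctions:
        ligs = build_ligaments(spine, j.name, table)
        removed = disk_states[j.name] == "removed"
        for s in ligs.springs:
            if removed and s.group in ("ALL", "PLL"):
                continue  # discectomy takes the longitudinal ligaments with it
            a = int(global_ids(s.a, must_exist=True)[0])
            b = int(global_ids(s.b, must_exist=True)[0])
            tag = f"lig:{s.group}:{j.name}"
            sid = fe.add_spring(a, b, s.curve, rest_length=s.rest_length, tag=tag)
            index.spring_ids.setdefault(tag, []).append(sid)

    # -- facet contacts ----------------------------------------------------
    for j in spine.junctions:
        contacts = build_facet_contacts(spine, j.name)
        index.gap_ids[j.name] = []
        for g in contacts.gaps:
            a = int(global_ids(g.a, must_exist=True)[0])
            b = int(global_ids(g.b, must_exist=True)[0])
            gid = fe.add_gap(a, b, g.direction, g.clearance, tag=f"facet:{j.name}")
            index.gap_ids[j.name].append(gid)

    # -- screws ------------------------------------------------------------
    # capture sets are made disjoint per vertebra (a node within reach of
    # both shafts goes to the nearer one): shared followers would make the
    # coupling constraint rows linearly dependent
    screws = screws if screws is not None else default_screw_layout(spine)
    from .instrumentation import _segment_distance

    embedded: list[tuple[Screw, np.ndarray, np.ndarray]] = []
    claimed: dict[str, dict[int, tuple[int, float]]] = {lv: {} for lv in spine.levels}
    tied: dict[str, set[int]] = {lv: set() for lv in spine.levels}
    for si, s in enumerate(screws):
        posed_nodes = spine.poses[s.vertebra].apply(spine.vertebrae[s.vertebra].volume.nodes)
        emb = embed_screw(s, posed_nodes, capture_radius=capture_radius)
        dist = _segment_distance(posed_nodes[emb.captured_nodes], s.entry, s.tip)
        for n, d in zip(emb.captured_nodes, dist):
            prev = claimed[s.vertebra].get(int(n))
            if prev is None or d < prev[1] - 1e-9:
                claimed[s.vertebra][int(n)] = (si, float(d))
            elif prev is not None and prev[0] != si and abs(d - prev[1]) <= 1e-9:
                # equidistant from two shafts (midline nodes): exclude from
                # both so symmetric fixtures keep symmetric couplings
                tied[s.vertebra].add(int(n))
        embedded.append((s, emb.captured_nodes, dist))
    for si, (s, captured, dist) in enumerate(embedded):
        mine = np.array(
            [
                n
                for n in captured
                if int(n) not in tied[s.vertebra]
                and claimed[s.vertebra][int(n)][0] == si
            ],
            dtype=int,
        )
        if len(mine) == 0:
            raise ValidationError(f"screw {s.name}: all captured nodes claimed elsewhere")
        ref = fe.add_node(s.head, ndof=6)
        followers = index.node_ids[s.vertebra][mine]
        weights = np.full(len(mine), 1.0 / len(mine))
        fe.add_rigid_coupling(ref, followers, weights=weights, tag=s.name)
        index.screws.append(s)
        index.screw_refs[s.name] = ref
        index.screw_couplings[s.name] = len(fe.couplings) - 1

    return fe, index


def _sync_nodes(fe: FEModel, weld: MeshBuilder) -> None:
    """Mirror newly welded coordinates into the FE node table (3-DOF)."""
    while fe.n_nodes < len(weld.nodes):
        fe.add_node(weld.nodes[fe.n_nodes], ndof=3)


def add_rods(
    fe: FEModel,
    index: ModelIndex,
    plan: CorrectionPlan,
    *,
    section: RodSection | None = None,
    n_elements_per_rod: int = 24,
) -> None:
    """Fit, mesh and register the two posterior rods for a given plan.

    Rod curves interpolate the *planned* screw-head positions (caudal to
    cranial); the beam nodes carry 6 DOF and the caudal-most node of each rod
    is flagged for full fixation during the correction steps.  Screw-rod
    couplings are resolved to the nearest rod node and stored for activation
    in the coupling step.
    """
    section = section or RodSection()
    spine = index.spine
    if isinstance(plan.connected_screws, str) and plan.connected_screws == "all":
        selected = [s.name for s in index.screws]
    else:
        selected = list(plan.connected_screws)
    for side in ("left", "right"):
        side_screws = [s for s in index.screws if s.side == side]
        if not side_screws:
            continue
        order = [lv for lv in spine.levels[::-1]]  # caudal -> cranial
        side_screws.sort(key=lambda s: order.index(s.vertebra))
        heads_planned = np.array(
            [plan.transform(s.vertebra).apply(s.head) for s in side_screws]
        )
        curve = fit_rod_curve(heads_planned)
        rod = mesh_rod(curve, n_elements_per_rod, section=section, side=side)
        node_ids = fe.add_nodes(rod.nodes, ndof=6)
        conn = node_ids[rod.elements]
        beam_ids = fe.add_beam_block(
            conn,
            section.elastic.E,
            section.elastic.nu,
            section.area,
            section.I,
            section.J,
            tag=f"rod:{side}",
        )
        connections = {}
        sel_side = [s for s in side_screws if s.name in selected]
        for name, rn in connect_screws_to_rod(rod, sel_side):
            connections[name] = int(node_ids[rn])
        index.rods[side] = {
            "model": rod,
            "node_ids": node_ids,
            "beam_ids": beam_ids,
            "fixed_node": int(node_ids[0]),
            "connections": connections,
            "planned_heads": heads_planned,
        }
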