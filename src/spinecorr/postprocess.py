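"""Derived mechanical outputs: vertebral orientations, screw-bone interface
forces, rod internal-action profiles and element stresses, plus report
export (CSV / JSON / VTK).

Angle convention: intrinsic Y-X-Z (sagittal, coronal, axial), degrees; the
original (assembled) state is the zero reference.  Pull-out is positive
along the shaft axis pointing out of the bone (posteriorly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import ValidationError
from .fe.correction import ResultsBundle
from .fe.model import FEModel
from .fe.solver import SolveResult, gap_forces, screw_interface_forces
from .geometry import extract_yxz_angles, kabsch_rotation

__all__ = [
    "OrientationReport",
    "ScrewForceReport",
    "RodActionProfile",
    "compute_vertebral_orientations",
    "compute_screw_forces",
    "compute_rod_internal_actions",
    "compute_element_stresses",
    "von_mises",
    "export_results",
]


@dataclass
class OrientationReport:
    """Per-vertebra planar angles for planned and achieved states (deg)."""

    rows: pd.DataFrame  # columns: level, plane, planned, achieved, discrepancy

    def discrepancy(self, level: str, plane: str) -> float:
        m = (self.rows.level == level) & (self.rows.plane == plane)
        return float(self.rows.loc[m, "discrepancy"].iloc[0])

    def max_abs_discrepancy(self, planes=("sagittal", "coronal", "axial")) -> float:
        m = self.rows.plane.isin(planes)
        return float(self.rows.loc[m, "discrepancy"].abs().max())


@dataclass
class ScrewForceReport:
    rows: pd.DataFrame  # screw, side, level, Fx, Fy, Fz, magnitude, pullout, kind

    def peak_force(self) -> float:
        return float(self.rows.magnitude.max())

    def by_screw(self, name: str) -> pd.Series:
        return self.rows.set_index("screw").loc[name]


@dataclass
class RodActionProfile:
    """Internal actions along one rod.

    Stations are element midpoints (arc length from the caudal end).  The
    internal action at a station is the force/moment exerted by the cranial
    part on the caudal part, expressed in the rod frame: tangent (axial,
    + = toward cranial), anteroposterior (+ = anterior) and laterolateral
    (+ = left) transverse axes obtained by projecting the global X and Y
    directions onto the section plane.
    """

    side: str
    rows: pd.DataFrame  # s, axial, shear_ap, shear_ll, m_sag, m_cor, m_tor

    def peak(self, column: str) -> float:
        return float(self.rows[column].abs().max())


# ---------------------------------------------------------------------------
# orientations
# ---------------------------------------------------------------------------


def _landmark_points(index, level: str) -> tuple[np.ndarray, np.ndarray]:
    """(global node ids, reference positions) of the orientation markers."""
    spine = index.spine
    surf = spine.vertebrae[level]
    marker_sets = ["superior_endplate", "inferior_endplate"]
    ids = np.unique(
        np.concatenate(
            [surf.volume.surface_to_volume[surf.region_sets[k]] for k in marker_sets]
            + [
                surf.volume.surface_to_volume[[surf.landmarks[n]]]
                for n in ("body_center", "spinous_tip")
            ]
        )
    )
    gids = index.node_ids[level][ids]
    ref = spine.poses[level].apply(surf.volume.nodes[ids])
    return gids, ref


def compute_vertebral_orientations(
    fe: FEModel, index, bundle: ResultsBundle, step: str = "ii"
) -> OrientationReport:
    """Best-fit rigid rotations of each vertebra vs the planned rotations."""
    u = bundle.steps[step].u
    off = fe.dof_offsets()
    recs = []
    for lv in index.spine.levels:
        gids, ref = _landmark_points(index, lv)
        if len(gids) < 3:
            raise ValidationError(f"not enough landmarks on {lv} for a rigid fit")
        if np.linalg.matrix_rank(ref - ref.mean(axis=0), tol=1e-6) < 2:
            raise ValidationError(f"landmarks on {lv} are collinear")
        disp = u[off[gids][:, None] + np.arange(3)]
        R_ach, _ = kabsch_rotation(ref, ref + disp)
        ach = extract_yxz_angles(R_ach)
        plan_R = bundle.plan.transform(lv).rotation
        pln = extract_yxz_angles(plan_R)
        for plane, a, p in zip(("sagittal", "coronal", "axial"), ach, pln):
            recs.append(
                {
                    "level": lv,
                    "plane": plane,
                    "planned": p,
                    "achieved": a,
                    "discrepancy": a - p,
                }
            )
    return OrientationReport(rows=pd.DataFrame.from_records(recs))


# ---------------------------------------------------------------------------
# screw forces
# ---------------------------------------------------------------------------


def compute_screw_forces(
    fe: FEModel, index, bundle: ResultsBundle, step: str = "ii"
) -> ScrewForceReport:
    """Screw-bone interface force resultants (on the vertebra side)."""
    res = bundle.steps[step]
    by_coupling = screw_interface_forces(fe, res)
    if not by_coupling and fe.couplings:
        raise ValidationError("no coupling constraint forces in the solution")
    recs = []
    for s in index.screws:
        ci = index.screw_couplings[s.name]
        F = by_coupling.get(ci, np.zeros(3))
        outward = -s.axis  # out of the bone, posteriorly
        pullout = float(F @ outward)
        recs.append(
            {
                "screw": s.name,
                "level": s.vertebra,
                "side": s.side,
                "Fx": F[0],
                "Fy": F[1],
                "Fz": F[2],
                "magnitude": float(np.linalg.norm(F)),
                "pullout": pullout,
                "kind": "pull-out" if pullout > 0 else "push-in",
            }
        )
    return ScrewForceReport(rows=pd.DataFrame.from_records(recs))


def screw_force_balance(fe: FEModel, index, bundle: ResultsBundle, step: str = "ii"):
    """Newton's-third-law check: force on screw ref node vs vertebra side."""
    res = bundle.steps[step]
    on_vertebra = screw_interface_forces(fe, res)
    on_ref: dict[int, np.ndarray] = {}
    for r_i, tag in enumerate(res.row_meta):
        if tag[0] != "coupling":
            continue
        _, ci, fi, k = tag
        c = fe.couplings[ci]
        on_ref.setdefault(ci, np.zeros(3))
        # row has -1 on the reference translation DOF k
        on_ref[ci][k] += res.lam[r_i]
    return {ci: (on_vertebra[ci], on_ref.get(ci, np.zeros(3))) for ci in on_vertebra}


# ---------------------------------------------------------------------------
# rod internal actions
# ---------------------------------------------------------------------------


def compute_rod_internal_actions(
    fe: FEModel, index, bundle: ResultsBundle, side: str, step: str = "ii"
) -> RodActionProfile:
    res = bundle.steps[step]
    if side not in index.rods:
        raise ValidationError(f"no rod on side {side!r}")
    info = index.rods[side]
    beam_ids = set(int(b) for b in info["beam_ids"])
    end_forces = fe.beam_end_forces(res.u)
    lengths = []
    recs = []
    s_accum = 0.0
    for e in sorted(beam_ids):
        ef = end_forces[e]
        R = ef["R"]  # local = R @ global
        tangent = R[0]
        if np.linalg.norm(tangent) < 1e-12:
            raise ValidationError("degenerate rod tangent")
        # rod frame: tangent + projected anatomical axes
        e_ap = _project_unit(np.array([1.0, 0.0, 0.0]), tangent)
        e_ll = _project_unit(np.array([0.0, 1.0, 0.0]), tangent, fallback=np.cross(tangent, e_ap))
        f_b_local = ef["f_local"][6:9]
        m_b_local = ef["f_local"][9:12]
        F = R.T @ f_b_local  # internal force at the cranial cut (global)
        M = R.T @ m_b_local
        s_mid = s_accum + ef["L"] / 2.0
        recs.append(
            {
                "s": s_mid,
                "axial": float(F @ tangent),
                "shear_ap": float(F @ e_ap),
                "shear_ll": float(F @ e_ll),
                "m_sag": float(M @ e_ll),  # flexion-extension: about laterolateral
                "m_cor": float(M @ e_ap),  # lateral bending: about anteroposterior
                "m_tor": float(M @ tangent),
            }
        )
        s_accum += ef["L"]
        lengths.append(ef["L"])
    return RodActionProfile(side=side, rows=pd.DataFrame.from_records(recs))


def _project_unit(v: np.ndarray, tangent: np.ndarray, fallback: np.ndarray | None = None) -> np.ndarray:
    p = v - (v @ tangent) * tangent
    n = np.linalg.norm(p)
    if n < 1e-8:
        if fallback is None:
            raise ValidationError("cannot build rod section frame (tangent parallel)")
        p, n = fallback, np.linalg.norm(fallback)
    return p / n


# ---------------------------------------------------------------------------
# element stresses
# ---------------------------------------------------------------------------


def compute_element_stresses(fe: FEModel, bundle: ResultsBundle, step: str = "ii") -> np.ndarray:
    """Per-tet Voigt stress tensors (xx, yy, zz, xy, yz, zx), MPa."""
    return fe.tet_stresses(bundle.steps[step].u)


def von_mises(stress_voigt: np.ndarray) -> np.ndarray:
    s = np.asarray(stress_voigt, dtype=float)
    sx, sy, sz, sxy, syz, szx = (s[:, k] for k in range(6))
    return np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_results(
    out_dir,
    fe: FEModel,
    index,
    bundle: ResultsBundle,
    orientations: OrientationReport | None = None,
    screw_forces: ScrewForceReport | None = None,
    rod_profiles: dict[str, RodActionProfile] | None = None,
    step: str = "ii",
) -> dict[str, str]:
    """Write CSV tables, a JSON summary, and VTK field files.

    Raises if a requested report was not computed; returns the file map.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    files: dict[str, str] = {}
    if orientations is None or screw_forces is None or rod_profiles is None:
        raise ValidationError("missing report: compute orientations, screw forces and rod profiles first")

    p = os.path.join(out_dir, "orientations.csv")
    orientations.rows.to_csv(p, index=False, float_format="%.12g")
    files["orientations"] = p
    p = os.path.join(out_dir, "screw_forces.csv")
    screw_forces.rows.to_csv(p, index=False, float_format="%.12g")
    files["screw_forces"] = p
    for side, prof in rod_profiles.items():
        p = os.path.join(out_dir, f"rod_actions_{side}.csv")
        prof.rows.to_csv(p, index=False, float_format="%.12g")
        files[f"rod_actions_{side}"] = p

    summary = {
        "final_step": bundle.final_step(),
        "peak_screw_force_N": screw_forces.peak_force(),
        "max_abs_orientation_discrepancy_deg": orientations.max_abs_discrepancy(),
        "rod_peaks": {
            side: {c: prof.peak(c) for c in ("axial", "shear_ap", "shear_ll", "m_sag", "m_cor", "m_tor")}
            for side, prof in rod_profiles.items()
        },
        "residuals": {k: r.residual for k, r in bundle.steps.items()},
    }
    p = os.path.join(out_dir, "summary.json")
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    files["summary"] = p

    # VTK: displacement on all 3-DOF solid nodes + von Mises per tet
    from .vtkio import write_vtk_unstructured

    u = bundle.steps[step].u
    off = fe.dof_offsets()
    solid = np.nonzero(np.asarray(fe.ndof_per_node) == 3)[0]
    remap = -np.ones(fe.n_nodes, dtype=int)
    remap[solid] = np.arange(len(solid))
    disp = u[off[solid][:, None] + np.arange(3)]
    vm = von_mises(fe.tet_stresses(u))
    p = os.path.join(out_dir, "fields.vtk")
    write_vtk_unstructured(
        p,
        fe.nodes[solid],
        remap[fe.tets],
        point_vectors={"displacement": disp},
        cell_scalars={"von_mises": vm, "active": fe.tet_active.astype(float)},
    )
    files["fields"] = p
    return files
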