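"""Three-step simulation of the correction maneuver.

Step i (impose correction): the rods — already shaped to the planned
configuration — are fixed in space and unloaded; every screw head is driven
by prescribed 6-DOF displacements to its position on the rod, straining the
spine.

Step ii (couple and release): kinematic couplings lock each screw head to
its nearest rod node at the engaged relative position, the head boundary
conditions are removed (their reaction forces are ramped down as external
loads), and the strain energy of the spine redistributes into the rods.  The
caudal end of each rod stays fully fixed, which also removes the global
rigid modes.

Step iii (optional external load): a force and/or moment is distributed over
a vertebral endplate with the couplings active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..anatomy import ValidationError
from ..planning import CorrectionPlan
from .model import FEModel, Tie6
from .solver import (
    SolveResult,
    SolverOptions,
    StepDefinition,
    solve_static,
)

__all__ = ["ResultsBundle", "run_three_step_correction", "distribute_load"]


@dataclass
class ResultsBundle:
    """Converged states and derived forces of the three-step simulation."""

    plan: CorrectionPlan
    steps: dict[str, SolveResult] = field(default_factory=dict)
    head_reactions: dict[str, np.ndarray] = field(default_factory=dict)  # screw -> 6-vector
    log: list[str] = field(default_factory=list)

    def displacements(self, step: str = "ii") -> np.ndarray:
        return self.steps[step].u

    def final_step(self) -> str:
        return "iii" if "iii" in self.steps else "ii"


def _rotation_vector(R: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_matrix(R).as_rotvec()


def run_three_step_correction(
    fe: FEModel,
    index,
    plan: CorrectionPlan,
    external_load: dict | None = None,
    options: SolverOptions | None = None,
) -> ResultsBundle:
    """Run steps i-iii on an assembled, rodded model (see pipeline docs)."""
    options = options or SolverOptions()
    if not index.rods:
        raise ValidationError("no rods registered; call add_rods first")
    bundle = ResultsBundle(plan=plan)

    rod_nodes = np.concatenate([info["node_ids"] for info in index.rods.values()])

    # ---- step i: impose the correction ----------------------------------
    fixed = [(int(n), k) for n in rod_nodes for k in range(6)]
    prescribed = []
    for s in index.screws:
        ref = index.screw_refs[s.name]
        T = plan.transform(s.vertebra)
        d_t = T.apply(s.head) - s.head
        d_r = _rotation_vector(T.rotation)
        for k in range(3):
            prescribed.append((ref, k, float(d_t[k])))
        for k in range(3):
            prescribed.append((ref, 3 + k, float(d_r[k])))
    step_i = StepDefinition(
        kind="impose_correction", fixed=fixed, prescribed=prescribed, options=options
    )
    res_i = solve_static(fe, step_i)
    bundle.steps["i"] = res_i
    bundle.log += res_i.log

    # head reactions: the forces the prescriptions exerted on the heads
    release = np.zeros(fe.n_dof)
    by_screw: dict[str, np.ndarray] = {s.name: np.zeros(6) for s in index.screws}
    ref_of = {index.screw_refs[s.name]: s.name for s in index.screws}
    for r_i, tag in enumerate(res_i.row_meta):
        if tag[0] == "presc":
            _, node, comp = tag
            force = -res_i.lam[r_i]
            release[fe.dof(node, comp)] += force
            if node in ref_of:
                by_screw[ref_of[node]][comp] += force
    bundle.head_reactions = by_screw

    # ---- step ii: couple heads to rods, release head BCs -----------------
    fe.ties = []
    index.screw_ties = {}
    u_i = res_i.u
    for side, info in index.rods.items():
        for name, rod_node in info["connections"].items():
            ref = index.screw_refs[name]
            xa = fe.coords[ref] + u_i[fe.dofs(ref)[:3]]
            xb = fe.coords[rod_node] + u_i[fe.dofs(rod_node)[:3]]
            lever = xa - xb
            rhs = np.zeros(6)
            ua, ub = u_i[fe.dofs(ref)], u_i[fe.dofs(rod_node)]
            S = np.array(
                [
                    [0, -lever[2], lever[1]],
                    [lever[2], 0, -lever[0]],
                    [-lever[1], lever[0], 0.0],
                ]
            )
            rhs[:3] = ua[:3] - ub[:3] + S @ ub[3:]
            rhs[3:] = ua[3:] - ub[3:]
            fe.ties.append(Tie6(node_a=ref, node_b=rod_node, lever=lever, rhs=rhs, tag=name))
            index.screw_ties[name] = len(fe.ties) - 1

    fixed_ii = [
        (info["fixed_node"], k) for info in index.rods.values() for k in range(6)
    ]
    step_ii = StepDefinition(
        kind="couple_and_release",
        fixed=fixed_ii,
        release_forces=release,
        include_ties=True,
        options=options,
    )
    res_ii = solve_static(fe, step_ii, u0=res_i.u, active_gaps0=res_i.active_gaps)
    bundle.steps["ii"] = res_ii
    bundle.log += res_ii.log

    # ---- step iii: optional external load --------------------------------
    if external_load is not None:
        forces = distribute_load(fe, index, external_load)
        step_iii = StepDefinition(
            kind="external_load",
            fixed=fixed_ii,
            forces=forces,
            include_ties=True,
            options=options,
        )
        res_iii = solve_static(fe, step_iii, u0=res_ii.u, active_gaps0=res_ii.active_gaps)
        bundle.steps["iii"] = res_iii
        bundle.log += res_iii.log

    return bundle


def distribute_load(fe: FEModel, index, spec: dict) -> np.ndarray:
    """Turn a {'level', 'force', 'moment', 'region'} spec into nodal forces.

    The resultant force/moment (about the node-set centroid) is realized by
    the minimum-norm nodal force distribution over the chosen region
    (default: the superior endplate of the given level).
    """
    level = spec.get("level")
    if level not in index.spine.levels:
        raise ValidationError(f"external load on unknown vertebra {level!r}")
    region = spec.get("region", "superior_endplate")
    nodes = index.surface_nodes(level, region)
    F = np.asarray(spec.get("force", (0.0, 0.0, 0.0)), dtype=float)
    M = np.asarray(spec.get("moment", (0.0, 0.0, 0.0)), dtype=float)
    X = fe.nodes[nodes]
    r = X - X.mean(axis=0)
    n = len(nodes)
    # constraint matrix: sum f_i = F, sum r_i x f_i = M; minimum-norm solve
    C = np.zeros((6, 3 * n))
    for i in range(n):
        C[0:3, 3 * i : 3 * i + 3] = np.eye(3)
        rx, ry, rz = r[i]
        C[3:6, 3 * i : 3 * i + 3] = np.array([[0, -rz, ry], [rz, 0, -rx], [-ry, rx, 0]])
    rhs = np.concatenate([F, M])
    f = C.T @ np.linalg.solve(C @ C.T + 1e-12 * np.eye(6), rhs)
    out = np.zeros(fe.n_dof)
    for i, node in enumerate(nodes):
        out[fe.dofs(int(node))[:3]] += f[3 * i : 3 * i + 3]
    return out
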