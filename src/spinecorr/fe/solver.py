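"""Nonlinear static solve: Newton iteration with Lagrange-multiplier
constraints, incremental load application and an active set for the gaps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..anatomy import ValidationError
from .model import FEModel

__all__ = ["StepDefinition", "SolverOptions", "SolveResult", "solve_static", "NonConvergenceError"]


class NonConvergenceError(RuntimeError):
    pass


@dataclass
class SolverOptions:
    increments: int = 10
    max_iterations: int = 25
    rel_tol: float = 1e-6
    abs_tol: float = 1e-4  # N
    constraint_tol: float = 1e-8  # mm
    gap_penetration_tol: float = 1e-9  # mm
    max_active_set_loops: int = 12


@dataclass
class StepDefinition:
    """One loading step of the simulation.

    ``fixed`` pins (node, component) pairs at zero; ``prescribed`` drives
    (node, component) to a target value, ramped over the increments;
    ``forces`` is an external nodal force vector ramped 0 -> 1; the optional
    ``release_forces`` vector is ramped 1 -> 0 (used to hand loads over from
    a released boundary condition to the rest of the structure).
    """

    kind: str = "generic"  # impose_correction | couple_and_release | external_load
    fixed: list[tuple[int, int]] = field(default_factory=list)
    prescribed: list[tuple[int, int, float]] = field(default_factory=list)
    forces: np.ndarray | None = None
    release_forces: np.ndarray | None = None
    include_ties: bool = False
    options: SolverOptions = field(default_factory=SolverOptions)

    def validate(self, model: FEModel) -> None:
        seen = set()
        for node, comp in self.fixed:
            model.dof(node, comp)
            seen.add((node, comp))
        for node, comp, _ in self.prescribed:
            model.dof(node, comp)
            if (node, comp) in seen:
                raise ValidationError(
                    f"DOF (node {node}, comp {comp}) is both fixed and prescribed"
                )


@dataclass
class SolveResult:
    u: np.ndarray
    lam: np.ndarray
    row_meta: list[tuple]
    active_gaps: np.ndarray
    log: list[str]
    residual: float


def _skew(d: np.ndarray) -> np.ndarray:
    return np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0.0]])


def build_constraints(
    model: FEModel,
    step: StepDefinition,
    active_gaps: np.ndarray,
    alpha: float,
):
    """Assemble the constraint matrix C, rhs b, and per-row metadata."""
    rows, cols, vals, b, meta = [], [], [], [], []

    def add_row(entries, rhs, tag):
        r = len(b)
        for dof, coeff in entries:
            rows.append(r)
            cols.append(dof)
            vals.append(coeff)
        b.append(rhs)
        meta.append(tag)

    for node, comp in step.fixed:
        add_row([(model.dof(node, comp), 1.0)], 0.0, ("fix", node, comp))
    for node, comp, target in step.prescribed:
        add_row([(model.dof(node, comp), 1.0)], alpha * target, ("presc", node, comp))

    for ci, c in enumerate(model.couplings):
        ref_t = [model.dof(c.ref_node, k) for k in range(3)]
        ref_r = [model.dof(c.ref_node, k) for k in range(3, 6)]
        for fi, fnode in enumerate(c.followers):
            S = _skew(c.offsets[fi])
            for k in range(3):
                entries = [(model.dof(int(fnode), k), 1.0), (ref_t[k], -1.0)]
                for p in range(3):
                    if S[k, p] != 0.0:
                        entries.append((ref_r[p], S[k, p]))
                add_row(entries, 0.0, ("coupling", ci, fi, k))

    if step.include_ties:
        for ti, t in enumerate(model.ties):
            S = _skew(t.lever)
            for k in range(3):
                entries = [
                    (model.dof(t.node_a, k), 1.0),
                    (model.dof(t.node_b, k), -1.0),
                ]
                for p in range(3):
                    if S[k, p] != 0.0:
                        entries.append((model.dof(t.node_b, 3 + p), S[k, p]))
                add_row(entries, t.rhs[k], ("tie", ti, k))
            for k in range(3):
                add_row(
                    [(model.dof(t.node_a, 3 + k), 1.0), (model.dof(t.node_b, 3 + k), -1.0)],
                    t.rhs[3 + k],
                    ("tie", ti, 3 + k),
                )

    g = model.gaps
    for gi in np.nonzero(active_gaps)[0]:
        a, bnode = g.pairs[gi]
        n = g.directions[gi]
        entries = []
        for k in range(3):
            entries.append((model.dof(int(bnode), k), n[k]))
            entries.append((model.dof(int(a), k), -n[k]))
        add_row(entries, -g.clearances[gi], ("gap", int(gi)))

    C = sp.coo_matrix((vals, (rows, cols)), shape=(len(b), model.n_dof)).tocsr()
    return C, np.asarray(b), meta


def gap_openings(model: FEModel, u: np.ndarray) -> np.ndarray:
    g = model.gaps
    if len(g.clearances) == 0:
        return np.zeros(0)
    off = model.dof_offsets()
    ua = u[off[g.pairs[:, 0]][:, None] + np.arange(3)]
    ub = u[off[g.pairs[:, 1]][:, None] + np.arange(3)]
    return g.clearances + np.einsum("ij,ij->i", g.directions, ub - ua)


def solve_static(
    model: FEModel,
    step: StepDefinition,
    u0: np.ndarray | None = None,
    active_gaps0: np.ndarray | None = None,
) -> SolveResult:
    """Incremental Newton solve of one step.

    Prescribed displacements and external forces ramp linearly over the
    increments; tension-only springs and the contact active set are resolved
    within each increment.  Convergence requires the force residual
    inf-norm below max(rel_tol * reference force, abs_tol) and constraint
    violation below the constraint tolerance.
    """
    step.validate(model)
    opt = step.options
    n = model.n_dof
    u = np.zeros(n) if u0 is None else u0.copy()
    n_gaps = len(model.gaps.clearances)
    if active_gaps0 is None:
        active = gap_openings(model, u) <= opt.gap_penetration_tol
        active &= model.gaps.active
    else:
        active = active_gaps0.copy() & model.gaps.active
    log: list[str] = []
    lam = np.zeros(0)
    meta: list[tuple] = []
    residual = np.inf

    for inc in range(1, opt.increments + 1):
        alpha = inc / opt.increments
        f_ext = np.zeros(n)
        if step.forces is not None:
            f_ext += alpha * step.forces
        if step.release_forces is not None:
            f_ext += (1.0 - alpha) * step.release_forces
        for as_loop in range(opt.max_active_set_loops):
            C, b, meta = build_constraints(model, step, active, alpha)
            converged = False
            for it in range(opt.max_iterations):
                f_int, K = model.internal_force_and_tangent(u)
                r = f_ext - f_int
                if C.shape[0]:
                    rhs = np.concatenate([r, b - C @ u])
                    KKT = sp.bmat([[K, C.T], [C, None]], format="csc")
                else:
                    rhs = r
                    KKT = K.tocsc()
                sol = spla.spsolve(KKT, rhs)
                if not np.all(np.isfinite(sol)):
                    raise NonConvergenceError(
                        f"singular system in step '{step.kind}' increment {inc}: "
                        "an unconstrained component remains"
                    )
                du = sol[:n]
                lam = sol[n:]
                u = u + du
                f_int, _ = model.internal_force_and_tangent(u)
                res_vec = f_ext - f_int - C.T @ lam if C.shape[0] else f_ext - f_int
                ref = max(
                    float(np.abs(f_int).max(initial=0.0)),
                    float(np.abs(f_ext).max(initial=0.0)),
                )
                residual = float(np.abs(res_vec).max(initial=0.0))
                cviol = float(np.abs(C @ u - b).max(initial=0.0)) if C.shape[0] else 0.0
                if residual <= max(opt.rel_tol * ref, opt.abs_tol) and cviol <= max(
                    opt.constraint_tol, 1e-12 * max(1.0, float(np.abs(u).max(initial=0.0)))
                ):
                    converged = True
                    break
            if not converged:
                worst = int(np.argmax(np.abs(res_vec)))
                raise NonConvergenceError(
                    f"step '{step.kind}' increment {inc} did not converge in "
                    f"{opt.max_iterations} iterations (residual {residual:.3g} N "
                    f"at DOF {worst})"
                )
            # active-set update
            changed = False
            if n_gaps:
                openings = gap_openings(model, u)
                lam_gap = np.zeros(n_gaps)
                for r_i, tag in enumerate(meta):
                    if tag[0] == "gap":
                        lam_gap[tag[1]] = lam[r_i]
                for gi in range(n_gaps):
                    if not model.gaps.active[gi]:
                        continue
                    if active[gi] and lam_gap[gi] > 1e-9:
                        active[gi] = False  # tensile multiplier: release
                        changed = True
                    elif not active[gi] and openings[gi] < -opt.gap_penetration_tol:
                        active[gi] = True
                        changed = True
            if not changed:
                break
        else:
            raise NonConvergenceError(
                f"contact active set did not settle in step '{step.kind}' increment {inc}"
            )
        log.append(
            f"{step.kind} inc {inc}/{opt.increments}: residual {residual:.3e} N, "
            f"active gaps {int(active.sum())}/{n_gaps}"
        )

    return SolveResult(u=u, lam=lam, row_meta=meta, active_gaps=active, log=log, residual=residual)


# -- force extraction helpers ------------------------------------------------


def constraint_forces(model: FEModel, result: SolveResult, step: StepDefinition, alpha: float = 1.0):
    """Recompute -C^T lam (force applied by constraints on the structure)."""
    C, _, _ = build_constraints(model, step, result.active_gaps, alpha)
    return -C.T @ result.lam


def reaction_on(model: FEModel, result: SolveResult, kind: str) -> dict:
    """Sum multiplier forces by metadata kind for reporting."""
    out: dict = {}
    for r_i, tag in enumerate(result.row_meta):
        if tag[0] != kind:
            continue
        out.setdefault(tag[1:], 0.0)
        out[tag[1:]] += -result.lam[r_i]
    return out


def screw_interface_forces(model: FEModel, result: SolveResult) -> dict[int, np.ndarray]:
    """Resultant coupling constraint force on the vertebra side per coupling.

    Row (coupling ci, follower fi, comp k) has +1 on the follower DOF, so the
    force applied on the follower (bone) node is -lam; the resultant over all
    followers is the screw-bone interface force on the vertebra.
    """
    out: dict[int, np.ndarray] = {}
    for r_i, tag in enumerate(result.row_meta):
        if tag[0] != "coupling":
            continue
        _, ci, fi, k = tag
        out.setdefault(ci, np.zeros(3))
        out[ci][k] += -result.lam[r_i]
    return out


def gap_forces(model: FEModel, result: SolveResult) -> np.ndarray:
    """Compressive contact force per gap element (>= 0; 0 when open)."""
    n_gaps = len(model.gaps.clearances)
    out = np.zeros(n_gaps)
    for r_i, tag in enumerate(result.row_meta):
        if tag[0] == "gap":
            out[tag[1]] = -result.lam[r_i]
    return np.maximum(out, 0.0)
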