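"""FE core verification: elements, solver, constraints, three-step driver."""

from __future__ import annotations

import numpy as np
import pytest

from spinecorr.fe.model import FEModel
from spinecorr.fe.solver import (
    SolverOptions,
    StepDefinition,
    build_constraints,
    gap_forces,
    gap_openings,
    solve_static,
)
from spinecorr.geometry import MeshBuilder, box_grid
from spinecorr.materials import Elastic, LigamentCurve


def _linear(k):
    return LigamentCurve(((0.0, 0.0), (1.0, float(k))))


# ---------------------------------------------------------------------------
# independent dense oracle (shape functions fitted from nodal data, dense
# Newton with constraint elimination) - used for small models only
# ---------------------------------------------------------------------------


def dense_tet_stiffness(X, tet, E, nu):
    """Tet4 stiffness via polynomial shape-function fitting (independent of
    the package's Jacobian-inverse assembly)."""
    P = np.column_stack([np.ones(4), X[tet]])  # rows [1, x, y, z]
    C = np.linalg.inv(P)  # coeffs: N_a(x) = C[0,a] + C[1,a] x + ...
    grads = C[1:, :].T  # (4, 3) dN_a/dx_j
    V = abs(np.linalg.det(P)) / 6.0
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[:3, :3] += 2 * mu * np.eye(3)
    D[3:, 3:] = mu * np.eye(3)
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c], B[1, c + 1], B[2, c + 2] = gx, gy, gz
        B[3, c], B[3, c + 1] = gy, gx
        B[4, c + 1], B[4, c + 2] = gz, gy
        B[5, c], B[5, c + 2] = gz, gx
    return V * B.T @ D @ B, B, D, V


def dense_solve(X, tets, E, nu, springs, fixed, prescribed, forces, n_iter=40):
    """Dense Newton with constraint elimination; springs are tension-only."""
    n = 3 * len(X)
    K_lin = np.zeros((n, n))
    for tet in tets:
        Ke, _, _, _ = dense_tet_stiffness(X, tet, E, nu)
        dofs = np.concatenate([3 * tet[a] + np.arange(3) for a in range(4)])
        K_lin[np.ix_(dofs, dofs)] += Ke

    u = np.zeros(n)
    fixed_dofs = {3 * node + c: val for node, c, val in prescribed}
    fixed_dofs.update({3 * node + c: 0.0 for node, c in fixed})
    free = np.array([d for d in range(n) if d not in fixed_dofs])
    for d, v in fixed_dofs.items():
        u[d] = v
    f_ext = np.zeros(n)
    for node, c, v in forces:
        f_ext[3 * node + c] += v
    for _ in range(n_iter):
        f_int = K_lin @ u
        K = K_lin.copy()
        for a, b, k, L0 in springs:
            xa = X[a] + u[3 * a : 3 * a + 3]
            xb = X[b] + u[3 * b : 3 * b + 3]
            d = xb - xa
            L = np.linalg.norm(d)
            e = L - L0
            dn = d / L
            f = k * e if e > 0 else 0.0
            kt = k if e > 0 else 0.0
            f_int[3 * a : 3 * a + 3] += -f * dn
            f_int[3 * b : 3 * b + 3] += f * dn
            km = kt * np.outer(dn, dn) + (f / L) * (np.eye(3) - np.outer(dn, dn))
            for (r1, r2, s) in ((a, a, 1), (b, b, 1), (a, b, -1), (b, a, -1)):
                K[3 * r1 : 3 * r1 + 3, 3 * r2 : 3 * r2 + 3] += s * km
        r = (f_ext - f_int)[free]
        du = np.linalg.solve(K[np.ix_(free, free)], r)
        u[free] += du
        if np.abs(r).max() < 1e-12 * max(1.0, np.abs(f_int).max()):
            break
    return u


def make_small_model():
    """~100-DOF cube of tets with two tension-only springs."""
    mb = MeshBuilder()
    g = box_grid(np.linspace(0, 20, 3), np.linspace(0, 20, 3), np.linspace(0, 20, 3))
    mb.add_hex_grid(g)
    X, tets = mb.build()
    E, nu = 500.0, 0.3
    springs = [(0, len(X) - 1, 12.0, 10.0), (2, len(X) - 3, 8.0, 5.0)]
    return X, tets, E, nu, springs


@pytest.fixture(scope="module")
def small_model():
    return make_small_model()


class TestAssembly:
    def test_single_tet_has_six_rigid_modes(self):
        fe = FEModel()
        for p in ([0, 0, 0], [2, 0, 0], [0, 3, 0], [0, 0, 4]):
            fe.add_node(p)
        lam, mu = Elastic(1200.0, 0.3).lame()
        fe.add_tet_block([[0, 1, 2, 3]], lam, mu)
        w = np.linalg.eigvalsh(fe.linear_stiffness().toarray())
        assert (np.abs(w) < 1e-8 * w.max()).sum() == 6

    def test_tangent_symmetric(self, small_model):
        X, tets, E, nu, springs = small_model
        fe = FEModel()
        fe.add_nodes(X)
        lam, mu = Elastic(E, nu).lame()
        fe.add_tet_block(tets, lam, mu)
        for a, b, k, L0 in springs:
            fe.add_spring(a, b, _linear(k), rest_length=L0)
        u = np.linspace(0, 0.5, fe.n_dof)
        _, K = fe.internal_force_and_tangent(u)
        K = K.toarray()
        assert np.abs(K - K.T).max() <= 1e-9 * np.abs(K).max()

    def test_matches_dense_reference_assembly(self, small_model):
        X, tets, E, nu, _ = small_model
        fe = FEModel()
        fe.add_nodes(X)
        lam, mu = Elastic(E, nu).lame()
        fe.add_tet_block(tets, lam, mu)
        K_pkg = fe.linear_stiffness().toarray()
        n = 3 * len(X)
        K_ref = np.zeros((n, n))
        for tet in tets:
            Ke, _, _, _ = dense_tet_stiffness(X, tet, E, nu)
            dofs = np.concatenate([3 * tet[a] + np.arange(3) for a in range(4)])
            K_ref[np.ix_(dofs, dofs)] += Ke
        assert np.abs(K_pkg - K_ref).max() <= 1e-9 * np.abs(K_ref).max()

    def test_uniform_strain_patch(self):
        """Linear boundary displacement on a 2x2x2-cell cube reproduces the
        constant strain/stress state exactly (interior node solved)."""
        mb = MeshBuilder()
        g = box_grid(np.linspace(0, 2, 3), np.linspace(0, 2, 3), np.linspace(0, 2, 3))
        mb.add_hex_grid(g)
        X, tets = mb.build()
        fe = FEModel()
        fe.add_nodes(X)
        el = Elastic(900.0, 0.25)
        lam, mu = el.lame()
        fe.add_tet_block(tets, lam, mu)
        A = np.array([[0.002, 0.001, 0.0], [0.001, -0.001, 0.0005], [0.0, 0.0005, 0.003]])
        boundary = [
            i
            for i, p in enumerate(X)
            if np.any(np.isclose(p, 0.0)) or np.any(np.isclose(p, 2.0))
        ]
        prescribed = []
        for i in boundary:
            t = A @ X[i]
            for c in range(3):
                prescribed.append((i, c, float(t[c])))
        res = solve_static(
            fe,
            StepDefinition(kind="patch", prescribed=prescribed, options=SolverOptions(increments=1)),
        )
        stresses = fe.tet_stresses(res.u)
        assert np.abs(stresses - stresses[0]).max() < 1e-9 * max(1.0, np.abs(stresses[0]).max())
        # against the closed-form constant field
        eps = 0.5 * (A + A.T)
        voigt = np.array(
            [eps[0, 0], eps[1, 1], eps[2, 2], 2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[2, 0]]
        )
        lam_, mu_ = el.lame()
        D = np.zeros((6, 6))
        D[:3, :3] = lam_
        D[:3, :3] += 2 * mu_ * np.eye(3)
        D[3:, 3:] = mu_ * np.eye(3)
        assert np.abs(stresses[0] - D @ voigt).max() < 1e-9


class TestSolver:
    def test_hooke_spring_force(self):
        fe = FEModel()
        a = fe.add_node([0, 0, 0])
        b = fe.add_node([10, 0, 0])
        fe.add_spring(a, b, _linear(100.0))
        step = StepDefinition(
            kind="stretch",
            fixed=[(a, 0), (a, 1), (a, 2), (b, 1), (b, 2)],
            prescribed=[(b, 0, 2.0)],
            options=SolverOptions(increments=2),
        )
        res = solve_static(fe, step)
        _, f, _, _ = fe.spring_state(res.u)
        assert f[0] == pytest.approx(200.0, abs=1e-9)

    def test_cantilever_tip_deflection(self):
        fe = FEModel()
        E, nu, A, I, J = 200000.0, 0.3, 100.0, 1000.0, 2000.0
        nodes = [fe.add_node([x, 0, 0], ndof=6) for x in np.linspace(0, 100, 21)]
        conn = np.stack([np.arange(20), np.arange(1, 21)], axis=1)
        fe.add_beam_block(conn, E, nu, A, I, J)
        f = np.zeros(fe.n_dof)
        f[fe.dof(nodes[-1], 2)] = 10.0
        res = solve_static(
            fe,
            StepDefinition(
                kind="cant",
                fixed=[(nodes[0], k) for k in range(6)],
                forces=f,
                options=SolverOptions(increments=1),
            ),
        )
        tip = res.u[fe.dof(nodes[-1], 2)]
        oracle = 10.0 * 100.0**3 / (3 * E * I)  # Euler-Bernoulli closed form
        assert abs(tip - oracle) / oracle < 0.01

    def test_solution_matches_dense_newton_oracle(self, small_model):
        X, tets, E, nu, springs = small_model
        fe = FEModel()
        fe.add_nodes(X)
        lam, mu = Elastic(E, nu).lame()
        fe.add_tet_block(tets, lam, mu)
        for a, b, k, L0 in springs:
            fe.add_spring(a, b, _linear(k), rest_length=L0)
        base = [i for i, p in enumerate(X) if np.isclose(p[2], 0.0)]
        fixed = [(i, c) for i in base for c in range(3)]
        top = [i for i, p in enumerate(X) if np.isclose(p[2], 20.0)]
        prescribed = [(i, 0, 1.5) for i in top]
        forces = [(len(X) - 1, 2, -40.0)]
        fvec = np.zeros(fe.n_dof)
        for node, c, v in forces:
            fvec[fe.dof(node, c)] += v
        res = solve_static(
            fe,
            StepDefinition(
                kind="oracle",
                fixed=fixed,
                prescribed=prescribed,
                forces=fvec,
                options=SolverOptions(increments=4),
            ),
        )
        u_ref = dense_solve(X, tets, E, nu, springs, fixed, prescribed, forces)
        scale = np.abs(u_ref).max()
        assert fe.n_dof <= 300
        assert np.abs(res.u - u_ref).max() <= 1e-8 * scale

    def test_singular_system_reported(self):
        import warnings

        fe = FEModel()
        fe.add_node([0, 0, 0])
        fe.add_node([1, 0, 0])
        fe.add_spring(0, 1, _linear(10.0))
        from spinecorr.fe.solver import NonConvergenceError

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # SuperLU rank warning is the point
            with pytest.raises(NonConvergenceError, match="unconstrained|singular"):
                solve_static(
                    fe, StepDefinition(kind="loose", options=SolverOptions(increments=1))
                )

    def test_dof_fixed_and_prescribed_rejected(self):
        fe = FEModel()
        a = fe.add_node([0, 0, 0])
        step = StepDefinition(kind="bad", fixed=[(a, 0)], prescribed=[(a, 0, 1.0)])
        from spinecorr.anatomy import ValidationError

        with pytest.raises(ValidationError):
            step.validate(fe)


class TestThreeStepSimulation:
    def test_null_plan_produces_no_response(self, test_case_spine):
        from spinecorr.fe.correction import run_three_step_correction
        from spinecorr.pipeline import add_rods, build_instrumented_model
        from spinecorr.planning import CorrectionPlan

        plan = CorrectionPlan(levels=tuple(test_case_spine.levels))
        fe, idx = build_instrumented_model(test_case_spine)
        add_rods(fe, idx, plan)
        bundle = run_three_step_correction(fe, idx, plan)
        for res in bundle.steps.values():
            assert np.abs(res.u).max() < 1e-9

    def test_step_i_reaches_prescribed_head_positions(self, suite_results):
        r = suite_results["C-H"]
        fe, idx, bundle, plan = r["fe"], r["index"], r["bundle"], r["plan"]
        u_i = bundle.steps["i"].u
        for s in idx.screws:
            ref = idx.screw_refs[s.name]
            target = plan.transform(s.vertebra).apply(s.head) - s.head
            got = u_i[fe.dofs(ref)[:3]]
            assert np.abs(got - target).max() < 1e-8

    def test_equilibrium_every_converged_step(self, suite_results):
        for name, r in suite_results.items():
            for step_name, res in r["bundle"].steps.items():
                assert res.residual <= 1e-3, (name, step_name)

    def test_coupling_rigidity_head_follows_rod(self, suite_results):
        r = suite_results["C-H"]
        fe, idx, bundle = r["fe"], r["index"], r["bundle"]
        u = bundle.steps["ii"].u
        for tie in fe.ties:
            ua = u[fe.dofs(tie.node_a)]
            ub = u[fe.dofs(tie.node_b)]
            S = np.array(
                [
                    [0, -tie.lever[2], tie.lever[1]],
                    [tie.lever[2], 0, -tie.lever[0]],
                    [-tie.lever[1], tie.lever[0], 0.0],
                ]
            )
            gap_t = ua[:3] - ub[:3] + S @ ub[3:] - tie.rhs[:3]
            gap_r = ua[3:] - ub[3:] - tie.rhs[3:]
            assert np.abs(gap_t).max() < 1e-8
            assert np.abs(gap_r).max() < 1e-8

    def test_gap_complementarity_all_configurations(self, suite_results):
        for name, r in suite_results.items():
            fe = r["fe"]
            res = r["bundle"].steps["ii"]
            op = gap_openings(fe, res.u)
            gf = gap_forces(fe, res)
            assert np.all(op >= -1e-6), name  # penetration bound
            assert np.abs(gf * op).max() < 1e-6, name  # f * g = 0
            assert np.all(gf >= 0.0), name  # no tensile gap force

    def test_step_ii_energy_bookkeeping(self, suite_results):
        """Coupling releases spine strain energy into the rods."""
        r = suite_results["C-H"]
        fe, bundle = r["fe"], r["bundle"]
        e_i = fe.element_energies(bundle.steps["i"].u)
        e_ii = fe.element_energies(bundle.steps["ii"].u)
        assert e_i["beam"] == pytest.approx(0.0, abs=1e-9)  # rods unloaded in step i
        assert e_ii["beam"] > 0.0
        spine_i = e_i["tet"] + e_i["spring"]
        spine_ii = e_ii["tet"] + e_ii["spring"]
        assert spine_ii <= spine_i * (1 + 1e-9)

    def test_global_force_balance(self, suite_results):
        """With no external load in the final state, all constraint forces
        (supports, couplings, contacts) sum to zero by component."""
        from spinecorr.fe.solver import build_constraints

        r = suite_results["C-H"]
        fe, bundle = r["fe"], r["bundle"]
        res = bundle.steps["ii"]
        fixed = [
            (info["fixed_node"], k) for info in r["index"].rods.values() for k in range(6)
        ]
        step = StepDefinition(kind="couple_and_release", fixed=fixed, include_ties=True)
        C, _, _ = build_constraints(fe, step, res.active_gaps, 1.0)
        f_con = -C.T @ res.lam
        off = fe.dof_offsets()
        by_comp = np.zeros(3)
        for n in range(fe.n_nodes):
            by_comp += f_con[off[n] : off[n] + 3]
        assert np.abs(by_comp).max() <= 1e-3
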