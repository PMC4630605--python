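"""Finite-element model container and element-level assembly."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ..anatomy import ValidationError
from ..materials import LigamentCurve

__all__ = ["FEModel", "SpringBlock", "GapBlock", "RigidCoupling", "Tie6"]

# Voigt order: xx, yy, zz, xy, yz, zx
_VOIGT = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0)]


def _elastic_D(lam: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Batched 6x6 isotropic elasticity matrices (engineering shear strain)."""
    n = len(lam)
    D = np.zeros((n, 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
    for i in range(3, 6):
        D[:, i, i] = mu
    return D


@dataclass
class SpringBlock:
    """Tension-only springs with per-spring force-deflection curves."""

    pairs: np.ndarray  # (n, 2) node ids
    curves: list[LigamentCurve]
    rest_lengths: np.ndarray
    active: np.ndarray  # bool
    tag: list[str]  # provenance label per spring


@dataclass
class GapBlock:
    """Node-to-node compression-only gaps with fixed direction."""

    pairs: np.ndarray  # (n, 2): (a, b); direction points a -> b
    directions: np.ndarray  # (n, 3) unit
    clearances: np.ndarray  # (n,)
    active: np.ndarray  # participation flag (element exists in the model)
    tag: list[str]


@dataclass
class RigidCoupling:
    """Follower nodes move rigidly with a 6-DOF reference node."""

    ref_node: int
    followers: np.ndarray  # node ids (3-DOF nodes)
    offsets: np.ndarray  # (n, 3) follower position - ref position (reference state)
    weights: np.ndarray  # (n,), sum to 1 (bookkeeping for force reporting)
    tag: str = ""


@dataclass
class Tie6:
    """Rigid 6-DOF tie between two 6-DOF nodes with a fixed lever arm.

    u_a = u_b + theta_b x d, theta_a = theta_b, with an affine offset frozen
    at activation so the relative position at engagement is preserved.
    """

    node_a: int
    node_b: int
    lever: np.ndarray  # d = x_a - x_b at activation
    rhs: np.ndarray  # (6,) frozen activation offset
    tag: str = ""


class FEModel:
    """Node/element/constraint container with vectorized assembly."""

    def __init__(self) -> None:
        self.coords: list[np.ndarray] = []
        self.ndof_per_node: list[int] = []
        # tets
        self.tets = np.zeros((0, 4), dtype=int)
        self.tet_lam = np.zeros(0)
        self.tet_mu = np.zeros(0)
        self.tet_active = np.zeros(0, dtype=bool)
        self.tet_tags: list[str] = []
        # beams
        self.beams = np.zeros((0, 2), dtype=int)
        self.beam_props = np.zeros((0, 5))  # E, G, A, I, J
        self.beam_tags: list[str] = []
        self.springs = SpringBlock(
            np.zeros((0, 2), int), [], np.zeros(0), np.zeros(0, bool), []
        )
        self.gaps = GapBlock(
            np.zeros((0, 2), int), np.zeros((0, 3)), np.zeros(0), np.zeros(0, bool), []
        )
        self.couplings: list[RigidCoupling] = []
        self.ties: list[Tie6] = []
        self._dof_offsets: np.ndarray | None = None
        self._K0: sp.csr_matrix | None = None
        self._tet_cache: dict | None = None

    # -- nodes -------------------------------------------------------------
    def add_node(self, xyz, ndof: int = 3) -> int:
        self.coords.append(np.asarray(xyz, dtype=float))
        self.ndof_per_node.append(int(ndof))
        self._dof_offsets = None
        return len(self.coords) - 1

    def add_nodes(self, xyz: np.ndarray, ndof: int = 3) -> np.ndarray:
        return np.array([self.add_node(p, ndof) for p in np.asarray(xyz, dtype=float)])

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def nodes(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    def dof_offsets(self) -> np.ndarray:
        if self._dof_offsets is None:
            self._dof_offsets = np.concatenate(
                [[0], np.cumsum(np.asarray(self.ndof_per_node, dtype=int))]
            )
        return self._dof_offsets

    @property
    def n_dof(self) -> int:
        return int(self.dof_offsets()[-1])

    def dof(self, node: int, comp: int) -> int:
        off = self.dof_offsets()
        if comp >= self.ndof_per_node[node]:
            raise ValidationError(f"node {node} has no DOF component {comp}")
        return int(off[node] + comp)

    def dofs(self, node: int) -> np.ndarray:
        off = self.dof_offsets()
        return np.arange(off[node], off[node + 1])

    # -- elements ----------------------------------------------------------
    def add_tet_block(self, conn: np.ndarray, lam, mu, tag: str = "") -> np.ndarray:
        conn = np.asarray(conn, dtype=int)
        n = len(conn)
        ids = np.arange(len(self.tets), len(self.tets) + n)
        self.tets = np.vstack([self.tets, conn])
        self.tet_lam = np.concatenate([self.tet_lam, np.broadcast_to(lam, (n,))])
        self.tet_mu = np.concatenate([self.tet_mu, np.broadcast_to(mu, (n,))])
        self.tet_active = np.concatenate([self.tet_active, np.ones(n, dtype=bool)])
        self.tet_tags.extend([tag] * n)
        self._K0 = None
        self._tet_cache = None
        return ids

    def add_beam_block(self, conn: np.ndarray, E: float, nu: float, A: float, I: float, J: float, tag: str = "") -> np.ndarray:
        conn = np.asarray(conn, dtype=int)
        G = E / (2 * (1 + nu))
        n = len(conn)
        ids = np.arange(len(self.beams), len(self.beams) + n)
        self.beams = np.vstack([self.beams, conn])
        self.beam_props = np.vstack(
            [self.beam_props, np.tile([E, G, A, I, J], (n, 1))]
        )
        self.beam_tags.extend([tag] * n)
        self._K0 = None
        return ids

    def add_spring(self, a: int, b: int, curve: LigamentCurve, rest_length: float | None = None, tag: str = "") -> int:
        if a == b:
            raise ValidationError("spring must connect distinct nodes")
        L0 = (
            float(np.linalg.norm(self.coords[b] - self.coords[a]))
            if rest_length is None
            else float(rest_length)
        )
        s = self.springs
        s.pairs = np.vstack([s.pairs, [a, b]])
        s.curves.append(curve)
        s.rest_lengths = np.concatenate([s.rest_lengths, [L0]])
        s.active = np.concatenate([s.active, [True]])
        s.tag.append(tag)
        return len(s.curves) - 1

    def add_gap(self, a: int, b: int, direction, clearance: float, tag: str = "") -> int:
        g = self.gaps
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        g.pairs = np.vstack([g.pairs, [a, b]])
        g.directions = np.vstack([g.directions, d])
        g.clearances = np.concatenate([g.clearances, [float(clearance)]])
        g.active = np.concatenate([g.active, [True]])
        g.tag.append(tag)
        return len(g.clearances) - 1

    def add_rigid_coupling(self, ref_node: int, followers, weights=None, tag: str = "") -> RigidCoupling:
        followers = np.asarray(followers, dtype=int)
        if len(followers) == 0:
            raise ValidationError("rigid coupling needs at least one follower node")
        if self.ndof_per_node[ref_node] != 6:
            raise ValidationError("coupling reference node must carry 6 DOF")
        offsets = self.nodes[followers] - self.coords[ref_node]
        if weights is None:
            weights = np.full(len(followers), 1.0 / len(followers))
        c = RigidCoupling(ref_node, followers, offsets, np.asarray(weights, float), tag)
        self.couplings.append(c)
        return c

    # -- assembly ----------------------------------------------------------
    def _tet_setup(self):
        if self._tet_cache is not None:
            return self._tet_cache
        X = self.nodes
        t = self.tets
        x0 = X[t[:, 0]]
        Jm = np.stack([X[t[:, k]] - x0 for k in (1, 2, 3)], axis=2)  # (n,3,3)
        detJ = np.linalg.det(Jm)
        if np.any(detJ <= 0):
            raise ValidationError("tet element with non-positive volume")
        Ji = np.linalg.inv(Jm)
        grads = np.zeros((len(t), 4, 3))
        grads[:, 1:, :] = Ji  # row j of inv(J) = grad N_{j+1}
        grads[:, 0, :] = -Ji.sum(axis=1)
        vol = detJ / 6.0
        B = np.zeros((len(t), 6, 12))
        for a in range(4):
            gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
            c = 3 * a
            B[:, 0, c] = gx
            B[:, 1, c + 1] = gy
            B[:, 2, c + 2] = gz
            B[:, 3, c] = gy
            B[:, 3, c + 1] = gx
            B[:, 4, c + 1] = gz
            B[:, 4, c + 2] = gy
            B[:, 5, c] = gz
            B[:, 5, c + 2] = gx
        D = _elastic_D(self.tet_lam, self.tet_mu)
        Ke = np.einsum("nji,njk,nkl,n->nil", B, D, B, vol)
        off = self.dof_offsets()
        edofs = np.concatenate(
            [off[t[:, a], None] + np.arange(3)[None, :] for a in range(4)], axis=1
        )  # (n, 12)
        self._tet_cache = {"Ke": Ke, "B": B, "D": D, "vol": vol, "edofs": edofs}
        return self._tet_cache

    def _beam_elements(self):
        X = self.nodes
        out = []
        off = self.dof_offsets()
        for e, (a, b) in enumerate(self.beams):
            E, G, A, I, J = self.beam_props[e]
            d = X[b] - X[a]
            L = float(np.linalg.norm(d))
            if L < 1e-12:
                raise ValidationError("beam element with zero length")
            ex = d / L
            ref = np.array([0.0, 0.0, 1.0]) if abs(ex[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            ey = np.cross(ref, ex)
            ey /= np.linalg.norm(ey)
            ez = np.cross(ex, ey)
            R = np.stack([ex, ey, ez])  # local = R @ global
            Kl = _beam_local_stiffness(E, G, A, I, I, J, L)
            T = np.zeros((12, 12))
            for blk in range(4):
                T[3 * blk : 3 * blk + 3, 3 * blk : 3 * blk + 3] = R
            Kg = T.T @ Kl @ T
            edofs = np.concatenate([self.dofs(a), self.dofs(b)])
            if len(edofs) != 12:
                raise ValidationError("beam nodes must carry 6 DOF")
            out.append((Kg, Kl, T, edofs, L, R))
        return out

    def linear_stiffness(self) -> sp.csr_matrix:
        """Constant part of the tangent: tets + beams."""
        if self._K0 is not None:
            return self._K0
        n = self.n_dof
        rows, cols, vals = [], [], []
        if len(self.tets):
            c = self._tet_setup()
            act = self.tet_active
            Ke = c["Ke"][act]
            ed = c["edofs"][act]
            r = np.repeat(ed, 12, axis=1).ravel()
            cjj = np.tile(ed, (1, 12)).ravel()
            rows.append(r)
            cols.append(cjj)
            vals.append(Ke.ravel())
        for Kg, _, _, edofs, _, _ in self._beam_elements():
            r = np.repeat(edofs, 12)
            cjj = np.tile(edofs, 12)
            rows.append(r)
            cols.append(cjj)
            vals.append(Kg.ravel())
        if rows:
            K = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(n, n),
            ).tocsr()
        else:
            K = sp.csr_matrix((n, n))
        self._K0 = K
        return K

    # -- nonlinear springs -------------------------------------------------
    def spring_state(self, u: np.ndarray):
        """Per-spring (elongation, force, direction, current length)."""
        s = self.springs
        if len(s.curves) == 0:
            z = np.zeros(0)
            return z, z, np.zeros((0, 3)), z
        off = self.dof_offsets()
        X = self.nodes
        a, b = s.pairs[:, 0], s.pairs[:, 1]
        ua = u[off[a][:, None] + np.arange(3)]
        ub = u[off[b][:, None] + np.arange(3)]
        xa = X[a] + ua
        xb = X[b] + ub
        d = xb - xa
        L = np.linalg.norm(d, axis=1)
        L = np.maximum(L, 1e-12)
        dirs = d / L[:, None]
        e = L - s.rest_lengths
        f = np.array([c.force(e[i]) for i, c in enumerate(s.curves)], dtype=float)
        f[~s.active] = 0.0
        return e, f, dirs, L

    def spring_forces_tangent(self, u: np.ndarray):
        """Internal force vector and tangent triplets from the springs."""
        s = self.springs
        n = self.n_dof
        f_int = np.zeros(n)
        rows, cols, vals = [], [], []
        if len(s.curves) == 0:
            return f_int, (rows, cols, vals)
        e, f, dirs, L = self.spring_state(u)
        k_t = np.array([c.stiffness(e[i]) for i, c in enumerate(s.curves)], dtype=float)
        k_t[~s.active] = 0.0
        off = self.dof_offsets()
        for i in range(len(s.curves)):
            if not s.active[i]:
                continue
            a, b = s.pairs[i]
            d = dirs[i]
            da = off[a] + np.arange(3)
            db = off[b] + np.arange(3)
            # dPi/du_a = -f*d, dPi/du_b = +f*d (taut spring pulls ends together)
            f_int[da] += -f[i] * d
            f_int[db] += f[i] * d
            if f[i] == 0.0 and k_t[i] == 0.0:
                continue
            km = k_t[i] * np.outer(d, d) + (f[i] / L[i]) * (np.eye(3) - np.outer(d, d))
            for (r1, r2, sgn) in ((da, da, 1.0), (db, db, 1.0), (da, db, -1.0), (db, da, -1.0)):
                rows.append(np.repeat(r1, 3))
                cols.append(np.tile(r2, 3))
                vals.append((sgn * km).ravel())
        return f_int, (rows, cols, vals)

    def internal_force_and_tangent(self, u: np.ndarray):
        K0 = self.linear_stiffness()
        f_int = K0 @ u
        fs, (rows, cols, vals) = self.spring_forces_tangent(u)
        f_int = f_int + fs
        if rows:
            Ks = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=K0.shape,
            ).tocsr()
            K = K0 + Ks
        else:
            K = K0
        return f_int, K

    # -- energies ----------------------------------------------------------
    def element_energies(self, u: np.ndarray) -> dict[str, float]:
        """Elastic energy by element family (N mm)."""
        out = {"tet": 0.0, "beam": 0.0, "spring": 0.0}
        if len(self.tets):
            c = self._tet_setup()
            act = self.tet_active
            ue = u[c["edofs"][act]]
            out["tet"] = float(0.5 * np.einsum("ni,nij,nj->", ue, c["Ke"][act], ue))
        for Kg, _, _, edofs, _, _ in self._beam_elements():
            ue = u[edofs]
            out["beam"] += float(0.5 * ue @ Kg @ ue)
        e, f, _, _ = self.spring_state(u)
        for i, c in enumerate(self.springs.curves):
            if not self.springs.active[i] or e[i] <= 0:
                continue
            xs = np.linspace(0.0, e[i], 64)
            out["spring"] += float(np.trapezoid(c.force(xs), xs))
        return out

    def tet_energy_by_tag(self, u: np.ndarray) -> dict[str, float]:
        c = self._tet_setup()
        ue = u[c["edofs"]]
        per = 0.5 * np.einsum("ni,nij,nj->n", ue, c["Ke"], ue)
        per = np.where(self.tet_active, per, 0.0)
        out: dict[str, float] = {}
        for tag, val in zip(self.tet_tags, per):
            out[tag] = out.get(tag, 0.0) + float(val)
        return out

    # -- stresses ----------------------------------------------------------
    def tet_stresses(self, u: np.ndarray) -> np.ndarray:
        """Per-tet Voigt stress (xx, yy, zz, xy, yz, zx), MPa."""
        c = self._tet_setup()
        ue = u[c["edofs"]]
        eps = np.einsum("nij,nj->ni", c["B"], ue)
        return np.einsum("nij,nj->ni", c["D"], eps)

    def beam_end_forces(self, u: np.ndarray):
        """Local end-force vectors per beam element (12,) in the local frame.

        Local x runs along the element; entries are (F_a(3), M_a(3),
        F_b(3), M_b(3)) acting *on* the element at each end node.
        """
        out = []
        for Kg, Kl, T, edofs, L, R in self._beam_elements():
            ue = u[edofs]
            f_local = Kl @ (T @ ue)
            out.append({"f_local": f_local, "L": L, "R": R, "edofs": edofs})
        return out


def _beam_local_stiffness(E, G, A, Iy, Iz, J, L) -> np.ndarray:
    """Standard 12x12 Euler-Bernoulli space-beam stiffness (local frame).

    DOF order per node: ux, uy, uz, rx, ry, rz; local x along the axis.
    """
    K = np.zeros((12, 12))
    ax = E * A / L
    tr = G * J / L
    bz12 = 12 * E * Iz / L**3
    bz6 = 6 * E * Iz / L**2
    bz4 = 4 * E * Iz / L
    bz2 = 2 * E * Iz / L
    by12 = 12 * E * Iy / L**3
    by6 = 6 * E * Iy / L**2
    by4 = 4 * E * Iy / L
    by2 = 2 * E * Iy / L
    # axial
    K[0, 0] = K[6, 6] = ax
    K[0, 6] = K[6, 0] = -ax
    # torsion
    K[3, 3] = K[9, 9] = tr
    K[3, 9] = K[9, 3] = -tr
    # bending about local z (displacement y, rotation rz)
    K[1, 1] = K[7, 7] = bz12
    K[1, 7] = K[7, 1] = -bz12
    K[1, 5] = K[5, 1] = K[1, 11] = K[11, 1] = bz6
    K[5, 7] = K[7, 5] = K[7, 11] = K[11, 7] = -bz6
    K[5, 5] = K[11, 11] = bz4
    K[5, 11] = K[11, 5] = bz2
    # bending about local y (displacement z, rotation ry)
    K[2, 2] = K[8, 8] = by12
    K[2, 8] = K[8, 2] = -by12
    K[2, 4] = K[4, 2] = K[2, 10] = K[10, 2] = -by6
    K[4, 8] = K[8, 4] = K[8, 10] = K[10, 8] = by6
    K[4, 4] = K[10, 10] = by4
    K[4, 10] = K[10, 4] = by2
    return K
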