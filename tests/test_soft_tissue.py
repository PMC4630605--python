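"""Disks (nucleus sizing, fibers), ligaments, facet gap contacts."""

from __future__ import annotations

import numpy as np
import pytest

from spinecorr import soft_tissue as st
from spinecorr.anatomy import ValidationError
from spinecorr.materials import MaterialTable


class TestDiskConstruction:
    def test_cylinder_volume_matches_closed_form(self, cylinder_disk):
        oracle = np.pi * 20.0**2 * 10.0
        assert abs(cylinder_disk.mesh.total_volume() - oracle) / oracle < 0.05

    def test_volume_partition_exact(self, cylinder_disk):
        vols = np.abs(cylinder_disk.mesh.volumes())
        nuc = vols[cylinder_disk.mesh.material_labels == "nucleus"].sum()
        ann = vols[cylinder_disk.mesh.material_labels == "annulus"].sum()
        assert nuc + ann == pytest.approx(vols.sum(), rel=1e-12)

    def test_intersecting_endplates_rejected(self):
        b, t, tris = st.make_circular_endplates(20.0, 10.0)
        with pytest.raises(ValidationError, match="intersect"):
            st.build_disk(b, b - np.array([0, 0, 1.0]), tris)

    def test_symmetric_fixture_disk_mirror_symmetric(self, symmetric_spine):
        from scipy.spatial import cKDTree

        m = symmetric_spine
        lo = m.vertebrae["L5"]
        bg = lo.extras["superior_endplate_grid"]
        tg = m.vertebrae["L4"].extras["inferior_endplate_grid"]
        mask = lo.extras["endplate_cell_mask"]
        disk = st.build_disk_grid(
            m.poses["L5"].apply(bg.reshape(-1, 3)).reshape(bg.shape),
            m.poses["L4"].apply(tg.reshape(-1, 3)).reshape(tg.shape),
            mask,
        )
        v = disk.mesh.nodes
        d, _ = cKDTree(v).query(v * np.array([1.0, -1.0, 1.0]))
        assert d.max() < 1e-9


class TestNucleusSizing:
    def test_cylinder_half_volume_radius(self, cylinder_disk):
        frac = cylinder_disk.nucleus_fraction()
        assert abs(frac - 0.5) <= 0.02
        # element-centroid criterion biases the solved radius slightly above
        # the continuum value R/sqrt(2)
        assert cylinder_disk.nucleus_radius == pytest.approx(20.0 / np.sqrt(2), rel=0.08)

    @pytest.mark.parametrize("frac,expected", [(0.0, 0), (1.0, None)])
    def test_degenerate_fractions(self, frac, expected):
        b, t, tris = st.make_circular_endplates(15.0, 8.0)
        d = st.build_disk(b, t, tris, nucleus_fraction=frac, with_fibers=False)
        n_nuc = int((d.mesh.material_labels == "nucleus").sum())
        if expected == 0:
            assert n_nuc == 0
        else:
            assert n_nuc == len(d.mesh.tets)

    def test_fixture_disk_fraction_within_tolerance(self, suite_results):
        for disk in suite_results["C-H"]["index"].disks.values():
            assert abs(disk.nucleus_fraction() - 0.5) <= 0.02


class TestAnnulusFibers:
    def test_mean_inclination_and_family_balance(self, cylinder_disk):
        f = cylinder_disk.fibers
        assert abs(np.abs(f.inclination_deg).mean() - 30.0) <= 2.0
        n_plus = int((f.family == 1).sum())
        n_minus = int((f.family == -1).sum())
        assert abs(n_plus - n_minus) <= 1
        assert np.all(f.pairs[:, 0] != f.pairs[:, 1])

    def test_fibers_attach_to_annulus_boundary(self, cylinder_disk):
        from spinecorr.geometry import boundary_faces

        boundary = set(np.unique(boundary_faces(cylinder_disk.mesh.tets)).tolist())
        assert set(cylinder_disk.fibers.pairs.ravel().tolist()) <= boundary

    def test_axial_compression_slackens_all_fibers(self, cylinder_disk):
        # kinematic uniform compression along the disk axis
        d = cylinder_disk
        z = d.mesh.nodes @ d.axis
        strain = -0.05
        disp = (z - z.min())[:, None] * strain * d.axis
        moved = d.mesh.nodes + disp
        L0 = d.fibers.rest_length
        L1 = np.linalg.norm(moved[d.fibers.pairs[:, 1]] - moved[d.fibers.pairs[:, 0]], axis=1)
        assert np.all(L1 <= L0 + 1e-12)  # all shorten -> zero tension-only force

    def test_axial_torsion_loads_one_family_only(self, cylinder_disk):
        d = cylinder_disk
        z = d.mesh.nodes @ d.axis
        theta = np.deg2rad(4.0) * (z - z.min()) / (z.max() - z.min())
        c, s = np.cos(theta), np.sin(theta)
        x, y = d.mesh.nodes[:, 0], d.mesh.nodes[:, 1]
        moved = np.stack([c * x - s * y, s * x + c * y, d.mesh.nodes[:, 2]], axis=1)
        L0 = d.fibers.rest_length
        L1 = np.linalg.norm(moved[d.fibers.pairs[:, 1]] - moved[d.fibers.pairs[:, 0]], axis=1)
        elong = L1 - L0
        plus = d.fibers.family == 1
        # per-fiber length change oracle: one family lengthens, the other shortens
        assert np.all(elong[plus] * elong[~plus][0] <= 1e-12) or (
            np.median(elong[plus]) * np.median(elong[~plus]) < 0
        )
        assert (np.median(elong[plus]) > 0) != (np.median(elong[~plus]) > 0)


class TestLigaments:
    def test_spring_counts_per_group(self, test_case_spine):
        ls = st.build_ligaments(test_case_spine, "L3-L4")
        for group, n in st.LIGAMENT_COUNTS.items():
            assert ls.count(group) == n, group
        assert ls.count("CL") == 2 * st.CAPSULE_SPRINGS_PER_FACET

    def test_zero_force_at_assembly(self, test_case_spine):
        ls = st.build_ligaments(test_case_spine, "L3-L4")
        for s in ls.springs:
            assert np.linalg.norm(s.a - s.b) == pytest.approx(s.rest_length, abs=1e-9)
            assert s.curve.force(0.0) == 0.0

    def test_curve_sweep_matches_configuration_pointwise(self):
        table = MaterialTable()
        curve = table.ligament_curves["ALL"]
        xs = np.linspace(-2.0, 12.0, 141)
        forces = curve.force(xs)
        assert np.all(forces[xs <= 0] == 0.0)
        assert np.all(np.diff(forces) >= -1e-12)  # monotone non-decreasing
        pts = np.asarray(curve.points)
        for x, f in pts:
            assert curve.force(x) == pytest.approx(f, abs=1e-12)

    def test_missing_insertion_set_names_group(self, test_case_spine):
        import copy

        m = copy.deepcopy(test_case_spine)
        del m.vertebrae["L3"].extras["ordered_regions"]["lig_ssl_inf"]
        with pytest.raises(ValidationError, match="lig_ssl"):
            st.build_ligaments(m, "L3-L4")


class TestFacetContacts:
    def test_unloaded_clearance(self, test_case_spine):
        fc = st.build_facet_contacts(test_case_spine, "L2-L3")
        assert all(g.clearance == pytest.approx(0.4, abs=1e-12) for g in fc.gaps)

    def test_gap_closing_gives_compression_without_penetration(self):
        # single gap element driven shut: active-set constraint oracle
        from spinecorr.fe.model import FEModel
        from spinecorr.fe.solver import (
            StepDefinition,
            SolverOptions,
            gap_forces,
            gap_openings,
            solve_static,
        )

        fe = FEModel()
        a = fe.add_node([0, 0, 0.0])
        b = fe.add_node([0, 0, 0.4], ndof=6)
        c = fe.add_node([0, 0, 10.0], ndof=6)
        # elastic support column behind the contact surface
        fe.add_beam_block([[b, c]], E=1000.0, nu=0.3, A=10.0, I=100.0, J=200.0)
        fe.add_gap(a, b, [0, 0, 1.0], 0.4)
        step = StepDefinition(
            kind="close",
            fixed=[(a, 0), (a, 1)] + [(c, k) for k in range(6)] + [(b, k) for k in (0, 1, 3, 4, 5)],
            prescribed=[(a, 2, 0.5)],
            options=SolverOptions(increments=5),
        )
        res = solve_static(fe, step)
        op = gap_openings(fe, res.u)
        gf = gap_forces(fe, res)
        assert gf[0] > 0.0  # compressive
        assert op[0] >= -1e-6  # penetration bounded
        assert abs(gf[0] * op[0]) < 1e-6  # complementarity

    def test_gap_opening_gives_zero_force(self):
        from spinecorr.fe.model import FEModel
        from spinecorr.fe.solver import (
            StepDefinition,
            SolverOptions,
            gap_forces,
            solve_static,
        )
        fe = FEModel()
        a = fe.add_node([0, 0, 0.0])
        b = fe.add_node([0, 0, 0.4], ndof=6)
        c = fe.add_node([0, 0, 10.0], ndof=6)
        fe.add_beam_block([[b, c]], E=1000.0, nu=0.3, A=10.0, I=100.0, J=200.0)
        fe.add_gap(a, b, [0, 0, 1.0], 0.4)
        step = StepDefinition(
            kind="open",
            fixed=[(a, 0), (a, 1)] + [(c, k) for k in range(6)] + [(b, k) for k in (0, 1, 3, 4, 5)],
            prescribed=[(a, 2, -0.5)],
            options=SolverOptions(increments=2),
        )
        res = solve_static(fe, step)
        assert gap_forces(fe, res)[0] == 0.0


class TestDiskCondition:
    def test_condition_moduli(self):
        table = MaterialTable()
        b, t, tris = st.make_circular_endplates(15.0, 8.0)
        d = st.build_disk(b, t, tris, with_fibers=False)
        st.set_disk_condition(d, "healthy")
        ela = st.disk_elastics(d, table)
        assert ela["annulus"].E == 4.2 and ela["annulus"].nu == 0.45
        assert ela["nucleus"].E == 1.0 and ela["nucleus"].nu == 0.499
        assert ela["fiber_modulus"] == 25.0
        st.set_disk_condition(d, "soft")
        ela = st.disk_elastics(d, table)
        assert ela["annulus"].E == 2.1 and ela["fiber_modulus"] == 12.5
        assert ela["nucleus"].E == 1.0
        st.set_disk_condition(d, "removed")
        assert st.disk_elastics(d, table) is None

    def test_unknown_condition_rejected(self, cylinder_disk):
        with pytest.raises(ValidationError):
            st.set_disk_condition(cylinder_disk, "mushy")

    def test_removed_disk_deactivates_elements_and_longitudinal_ligaments(
        self, suite_results
    ):
        fe = suite_results["C-D"]["fe"]
        index = suite_results["C-D"]["index"]
        assert "L3-L4" not in index.disks  # no disk elements at the level
        tags = fe.springs.tag
        assert not any(t == "lig:ALL:L3-L4" or t == "lig:PLL:L3-L4" for t in tags)
        assert not any(t == "fiber:L3-L4" for t in tags)
        # other levels untouched
        assert any(t == "lig:ALL:L2-L3" for t in tags)
        assert "L2-L3" in index.disks and "L4-L5" in index.disks
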