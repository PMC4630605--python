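"""Synthetic vertebra/spine generator, landmark tracking and surface I/O."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.spatial import cKDTree

from spinecorr import anatomy
from spinecorr.anatomy import (
    FixtureConfig,
    ValidationError,
    VertebraSpec,
    generate_spine_fixture,
    generate_vertebra_surface,
    load_surface,
    save_surface,
    track_landmark_nodes,
)
from spinecorr.geometry import RigidTransform, rot_z, tet_volumes
from spinecorr.planning import measure_slip

REQUIRED_REGIONS = [
    "superior_endplate",
    "inferior_endplate",
    "left_pedicle",
    "right_pedicle",
    "posterior_elements",
    "vertebral_body",
    "left_facet_sup",
    "left_facet_inf",
    "right_facet_sup",
    "right_facet_inf",
]


class TestVertebraSurface:
    def test_closed_genus0_surface_with_labels(self, default_vertebra):
        s = default_vertebra
        assert s.euler_characteristic() == 2
        assert s.enclosed_volume() > 0
        for r in REQUIRED_REGIONS:
            assert len(s.region_sets[r]) > 0, r
        s.validate()

    def test_endplate_sets_disjoint_and_planar(self, default_vertebra):
        s = default_vertebra
        sup = set(s.region_sets["superior_endplate"].tolist())
        inf = set(s.region_sets["inferior_endplate"].tolist())
        assert not (sup & inf)
        spec = VertebraSpec()
        z_sup = s.vertices[sorted(sup), 2]
        assert np.allclose(z_sup, spec.body_height / 2, atol=1e-9)

    def test_volume_scaling_law(self, default_vertebra):
        doubled = generate_vertebra_surface(VertebraSpec().scaled(2.0))
        ratio = doubled.enclosed_volume() / default_vertebra.enclosed_volume()
        assert abs(ratio - 8.0) < 8.0 * 1e-6

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(k=hst.floats(min_value=0.5, max_value=2.5))
    def test_volume_scaling_law_any_factor(self, k):
        base = generate_vertebra_surface(VertebraSpec())
        scaled = generate_vertebra_surface(VertebraSpec().scaled(k))
        assert abs(scaled.enclosed_volume() / base.enclosed_volume() - k**3) < k**3 * 1e-6

    def test_surface_volume_equals_tet_volume(self, default_vertebra):
        v = default_vertebra
        tot = tet_volumes(v.volume.nodes, v.volume.tets).sum()
        assert abs(tot - v.enclosed_volume()) < 1e-6 * v.enclosed_volume()

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValidationError):
            VertebraSpec(body_width=-1.0)
        with pytest.raises(ValidationError):
            VertebraSpec(post_depth=0.0)


class TestSpineFixture:
    def test_vertebra_count_matches_levels(self, test_case_spine):
        assert len(test_case_spine.vertebrae) == len(test_case_spine.levels) == 4

    def test_configured_slip_measurable(self, test_case_spine):
        assert measure_slip(test_case_spine, "L3-L4") == pytest.approx(14.0, abs=0.01)

    def test_symmetric_fixture_mirror_symmetry(self):
        m = generate_spine_fixture(FixtureConfig())
        for lv in m.levels:
            v = m.posed_vertices(lv)
            d, _ = cKDTree(v).query(v * np.array([1.0, -1.0, 1.0]))
            assert d.max() < 1e-9

    def test_aligned_fixture_zero_slip(self):
        m = generate_spine_fixture(FixtureConfig())
        assert measure_slip(m, "L3-L4") == pytest.approx(0.0, abs=1e-9)

    def test_coronal_asymmetry_between_end_levels(self, test_case_spine):
        def coronal_tilt(m, lv):
            s = m.vertebrae[lv]
            ep = m.poses[lv].apply(s.vertices[s.region_sets["superior_endplate"]])
            slope = np.polyfit(ep[:, 1], ep[:, 2], 1)[0]
            return np.degrees(np.arctan(slope))

        a = coronal_tilt(test_case_spine, "L2") - coronal_tilt(test_case_spine, "L5")
        assert a == pytest.approx(6.0, abs=0.1)

    def test_generator_determinism_bit_identical(self):
        cfg = anatomy.test_case_fixture_config()
        m1 = generate_spine_fixture(cfg)
        m2 = generate_spine_fixture(anatomy.test_case_fixture_config())
        for lv in m1.levels:
            assert np.array_equal(m1.vertebrae[lv].vertices, m2.vertebrae[lv].vertices)
            assert np.array_equal(m1.vertebrae[lv].triangles, m2.vertebrae[lv].triangles)

    def test_jitter_seeded_and_bounded(self):
        c1 = FixtureConfig(jitter_amplitude=0.3, seed=11)
        c2 = FixtureConfig(jitter_amplitude=0.3, seed=11)
        c3 = FixtureConfig(jitter_amplitude=0.3, seed=12)
        m1, m2, m3 = map(generate_spine_fixture, (c1, c2, c3))
        v1 = m1.vertebrae["L3"].vertices
        assert np.array_equal(v1, m2.vertebrae["L3"].vertices)
        assert not np.array_equal(v1, m3.vertebrae["L3"].vertices)
        m1.vertebrae["L3"].validate()

    def test_single_level_rejected(self):
        with pytest.raises(ValidationError):
            generate_spine_fixture(FixtureConfig(levels=("L3",)))

    def test_nonpositive_disk_gap_rejected(self):
        with pytest.raises(ValidationError):
            generate_spine_fixture(FixtureConfig(disk_gap=0.0))


class TestLandmarkTracking:
    def test_identity_and_rigid_morph_preserve_indices(self, default_vertebra):
        s = default_vertebra
        lm, regions = track_landmark_nodes(s, s.vertices, s.triangles)
        assert lm == s.landmarks
        T = RigidTransform.about_point(rot_z(17.0), [5.0, -3.0, 2.0], [4.0, 1.0, -2.0])
        moved = T.apply(s.vertices)
        lm2, _ = track_landmark_nodes(s, moved, s.triangles)
        for name, idx in lm2.items():
            ref = T.apply(s.vertices[s.landmarks[name]])
            assert np.linalg.norm(moved[idx] - ref) < 1e-9

    def test_coarsened_mapping_matches_brute_force(self, default_vertebra):
        from spinecorr.meshing import remesh_surface

        s = default_vertebra
        coarse = remesh_surface(s, 12.0)
        lm, regions = track_landmark_nodes(s, s.vertices, s.triangles, coarsened=coarse)
        for name, idx in lm.items():
            p = s.vertices[s.landmarks[name]]
            d = np.linalg.norm(np.asarray(coarse.vertices) - p, axis=1)
            assert idx == int(np.argmin(d))  # exhaustive nearest-node oracle

    def test_connectivity_mismatch_without_coarse_target_errors(self, default_vertebra):
        s = default_vertebra
        with pytest.raises(ValidationError):
            track_landmark_nodes(s, s.vertices[: len(s.vertices) // 2], s.triangles[:10])


class TestSurfaceIO:
    @pytest.mark.parametrize("ext", ["stl", "ply", "off"])
    def test_round_trip_preserves_geometry_and_regions(self, default_vertebra, tmp_path, ext):
        path = tmp_path / f"vert.{ext}"
        save_surface(default_vertebra, path)
        back = load_surface(path)
        assert len(back.triangles) == len(default_vertebra.triangles)
        if ext == "stl":
            # canonical re-ordering: compare as sets of coordinates
            d, _ = cKDTree(back.vertices).query(default_vertebra.vertices)
            assert d.max() < 1e-6
        else:
            assert np.abs(back.vertices - default_vertebra.vertices).max() < 1e-6
        # region sets preserved exactly relative to the written file
        again = load_surface(path)
        for k, v in back.region_sets.items():
            assert np.array_equal(v, again.region_sets[k])
        assert back.landmarks.keys() == default_vertebra.landmarks.keys()

    def test_regions_follow_canonical_stl_order(self, default_vertebra, tmp_path):
        path = tmp_path / "vert.stl"
        save_surface(default_vertebra, path)
        back = load_surface(path)
        src = default_vertebra
        for k in ("superior_endplate", "left_pedicle"):
            a = np.sort(src.vertices[src.region_sets[k]], axis=0)
            b = np.sort(back.vertices[back.region_sets[k]], axis=0)
            assert np.abs(a - b).max() < 1e-6

    def test_open_surface_reports_boundary_edges(self, default_vertebra, tmp_path):
        import trimesh

        s = default_vertebra
        open_mesh = trimesh.Trimesh(vertices=s.vertices, faces=s.triangles[1:], process=False)
        p = tmp_path / "open.ply"
        open_mesh.export(p, encoding="ascii")
        with pytest.raises(ValidationError, match="3 boundary edges"):
            load_surface(p)

    def test_missing_sidecar_warns_and_loads_empty(self, default_vertebra, tmp_path):
        import os

        path = tmp_path / "vert.ply"
        save_surface(default_vertebra, path)
        os.remove(str(path).replace(".ply", ".regions.json"))
        with pytest.warns(UserWarning, match="sidecar"):
            back = load_surface(path)
        assert back.region_sets == {}


class TestFacetConstruction:
    def test_unloaded_clearance_exact(self, test_case_spine):
        from spinecorr.soft_tissue import build_facet_contacts

        for j in test_case_spine.junctions:
            fc = build_facet_contacts(test_case_spine, j.name)
            assert len(fc.gaps) == 8
            for g in fc.gaps:
                assert g.clearance == pytest.approx(0.4, abs=1e-12)
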