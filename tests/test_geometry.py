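import numpy as np
import pytest

import perifem as pf
from perifem import geometry as G


class TestThreadAndImplant:
    def test_catalogue_has_eleven_labelled_implants(self, catalogue):
        assert len(catalogue) == 11
        assert set(catalogue) == {str(i) for i in range(1, 11)} | {"A"}

    def test_reference_implant_dimensions(self, catalogue):
        a = catalogue["A"]
        assert a.D_mm == 3.5 and a.L_mm == 11.0
        assert a.milling.kind is G.MillingKind.NONE
        assert not a.has_lead_in_bevel

    def test_platform_switching_invariant(self, catalogue):
        for spec in catalogue.values():
            assert spec.abutment_connection_diameter_mm < spec.D_mm

    def test_implant_8_matches_its_designation(self, catalogue):
        s = catalogue["8"]
        assert (s.D_mm, s.L_mm) == (3.6, 9.0)
        assert s.thread.profile_kind is G.ThreadProfile.T10_30
        assert s.thread.truncation is G.Truncation.DT
        assert s.thread.depth_secondary_mm == pytest.approx(0.19)

    def test_thread_geometry_constants(self):
        t0 = pf.thread_T0_30()
        t10 = pf.thread_T10_30()
        assert t0.free_thickness_mm == pytest.approx(0.33)
        assert t10.free_thickness_mm == pytest.approx(0.25)
        assert t0.lower_flank_angle_deg == 90.0
        assert t10.lower_flank_angle_deg == 100.0
        assert t0.effective_pitch_mm == t10.effective_pitch_mm == 1.2
        assert t0.fin_spacing_mm == pytest.approx(0.6)

    def test_st_requires_equal_depths(self):
        with pytest.raises(G.GeometryError):
            G.ThreadSpec(truncation=G.Truncation.ST, depth_secondary_mm=0.19)

    def test_degenerate_thread_gives_smooth_cylinder(self):
        spec = pf.ImplantSpec("x", 3.6, 9.0,
                              G.ThreadSpec(truncation=G.Truncation.ST,
                                           depth_primary_mm=0.0,
                                           depth_secondary_mm=0.0))
        vol = pf.build_implant_solid(spec).body_volume()
        # cylinder of the outer diameter minus the elliptic apex dome cap
        r, L = 1.8, 9.0
        dome = G.dome_height(spec)
        expected = np.pi * r ** 2 * L - np.pi * r ** 2 * dome / 3.0
        assert vol == pytest.approx(expected, rel=0.02)

    def test_solid_volume_monotone_in_diameter(self):
        v36 = pf.build_implant_solid(
            pf.ImplantSpec("a", 3.6, 9.0, pf.thread_T10_30())).body_volume()
        v43 = pf.build_implant_solid(
            pf.ImplantSpec("b", 4.3, 9.0, pf.thread_T10_30())).body_volume()
        assert v43 > v36

    def test_thread_volume_st_exceeds_dt(self):
        """Uniform full-depth fins carry strictly more thread volume than the
        mixed 0.38/0.19 truncation."""
        st = pf.ImplantSpec("s", 3.6, 9.0, pf.thread_T10_30(G.Truncation.ST))
        dt = pf.ImplantSpec("d", 3.6, 9.0, pf.thread_T10_30(G.Truncation.DT))
        core = pf.ImplantSpec("c", 3.6, 9.0,
                              G.ThreadSpec(truncation=G.Truncation.ST,
                                           depth_primary_mm=0.0,
                                           depth_secondary_mm=0.0))
        v_c = np.pi * pf.build_implant_solid(core).spec.core_radius_mm  # noqa
        thread_st = pf.build_implant_solid(st).body_volume()
        thread_dt = pf.build_implant_solid(dt).body_volume()
        assert thread_st > thread_dt

    def test_milling_reduces_volume_and_lm_more_than_sm(self):
        base = pf.ImplantSpec("a", 3.6, 9.0, pf.thread_T10_30())
        sm = pf.ImplantSpec("b", 3.6, 9.0, pf.thread_T10_30(),
                            G.MillingSpec.small())
        lm = pf.ImplantSpec("c", 3.6, 9.0, pf.thread_T10_30(),
                            G.MillingSpec.large())
        v0 = pf.build_implant_solid(base).volume()
        v1 = pf.build_implant_solid(sm).volume()
        v2 = pf.build_implant_solid(lm).volume()
        assert v0 > v1 > v2

    def test_infeasible_thread_raises(self):
        with pytest.raises(G.GeometryError):
            # flanks so shallow they overrun the fin root width
            G.implant_profile(pf.ImplantSpec(
                "x", 3.6, 9.0,
                G.ThreadSpec(upper_flank_angle_deg=160.0,
                             truncation=G.Truncation.ST,
                             depth_secondary_mm=0.38)))

    def test_out_of_range_dimensions_raise(self):
        with pytest.raises(G.GeometryError):
            pf.ImplantSpec("x", 2.0, 9.0, pf.thread_T10_30())
        with pytest.raises(G.GeometryError):
            pf.ImplantSpec("x", 3.6, 20.0, pf.thread_T10_30())


class TestBoneSegment:
    def test_cortical_thickness_along_normals(self):
        cort, trab = pf.build_bone_segment(pf.BoneSegmentSpec())
        outer = cort.section.exterior
        inner = trab.section.exterior
        ts = np.linspace(0, 1, 200, endpoint=False)
        d = [inner.distance(outer.interpolate(t, normalized=True))
             for t in ts]
        assert np.mean(d) == pytest.approx(2.0, abs=0.1)

    def test_volume_partition(self):
        spec = pf.BoneSegmentSpec()
        cort, trab = pf.build_bone_segment(spec)
        outer_area = G._section_polygon(spec).area
        assert cort.section.area + trab.section.area == pytest.approx(
            outer_area, rel=1e-9)

    def test_excessive_shell_raises(self):
        with pytest.raises(G.GeometryError):
            pf.BoneSegmentSpec(cortical_thickness_mm=8.0)

    def test_thin_core_limiting_case(self):
        spec = pf.BoneSegmentSpec(cortical_thickness_mm=5.0)
        cort, trab = pf.build_bone_segment(spec)
        assert trab.section.area > 0


class TestScenario:
    def test_placement_depth_recovered_by_measurement(self, catalogue):
        for code, depth in (("P0", 0.0), ("P05", 0.5), ("P1", 1.0)):
            sc = pf.build_scenario(catalogue["8"], code)
            assert sc.platform_z == pytest.approx(-depth)
            # far from the implant the outer surface is the crest plane z=0
            assert sc.top_surface(np.array([6.0]))[0] == pytest.approx(0.0)

    def test_apposition_collar_covers_platform(self, scenario8_p1):
        # bone directly above the platform ledge, 0.25 mm collar
        pts = np.array([[1.65, 0.0, -0.9], [1.65, 0.0, -0.80]])
        assert (scenario8_p1.region_of(pts) == G.REGION_CORTICAL).all()
        # no bone above the collar top nor against the abutment wall
        pts = np.array([[1.65, 0.0, -0.5], [1.38, 0.0, -0.85]])
        assert (scenario8_p1.region_of(pts) == G.REGION_OUTSIDE).all()

    def test_crater_depth_probe(self, catalogue):
        morph = G.CrestalMorphology(G.MorphologyKind.BONE_LOSS,
                                    bone_loss_fraction=0.5)
        sc = pf.build_scenario(catalogue["8"], "P0", morph)
        # crater bottom at the implant wall: 50% of the 2 mm shell
        assert sc.top_surface(np.array([1.8]))[0] == pytest.approx(-1.0)
        # 45-degree wall recovers the crest one depth away
        assert sc.top_surface(np.array([2.8]))[0] == pytest.approx(0.0)

    def test_pristine_crest_flush(self, catalogue):
        sc = pf.build_scenario(catalogue["8"], "P0",
                               G.CrestalMorphology(G.MorphologyKind.PRISTINE))
        assert sc.top_surface(np.array([1.9]))[0] == pytest.approx(0.0)

    def test_regions_partition_no_overlap(self, scenario8_p1):
        r = rng_points()
        labels = scenario8_p1.region_of(r)
        assert set(np.unique(labels)) <= {0, 1, 2, 3, 4}
        metal_local = r.copy()
        metal_local[:, 2] -= scenario8_p1.platform_z
        inside_metal = scenario8_p1.implant.contains(metal_local) \
            & (r[:, 2] <= scenario8_p1.load_z)
        assert np.array_equal(np.isin(labels, (1, 2)), inside_metal)

    def test_deep_implant_exits_floor(self, catalogue):
        bone = pf.BoneSegmentSpec(crest_height_mm=11.0)
        with pytest.raises(G.GeometryError):
            pf.build_scenario(catalogue["A"], "P1", bone_spec=bone)

    def test_mismatched_morphology_raises(self, catalogue):
        with pytest.raises(G.GeometryError):
            pf.build_scenario(catalogue["8"], "P0",
                              G.CrestalMorphology(G.MorphologyKind.APPOSITION))

    def test_geometry_deterministic(self, catalogue):
        a = G.implant_profile(catalogue["8"])
        b = G.implant_profile(catalogue["8"])
        assert np.array_equal(a, b)


class TestSerialization:
    def test_yaml_round_trip_bit_exact(self, catalogue):
        spec = G.ScenarioSpec(catalogue["8"], G.PlacementSpec.from_code("P1"),
                              G.CrestalMorphology())
        text = spec.to_yaml()
        again = G.ScenarioSpec.from_yaml(text)
        assert again == spec
        assert again.to_yaml() == text

    def test_mechanical_signature_ignores_milling(self, catalogue):
        pl = G.PlacementSpec.from_code("P1")
        mo = G.CrestalMorphology()
        s8 = G.ScenarioSpec(catalogue["8"], pl, mo)
        s9 = G.ScenarioSpec(catalogue["9"], pl, mo)
        s7 = G.ScenarioSpec(catalogue["7"], pl, mo)
        assert s8.mechanical_signature() == s9.mechanical_signature()
        assert s8.mechanical_signature() != s7.mechanical_signature()


def rng_points(n=4000, seed=7):
    r = np.random.default_rng(seed)
    pts = r.uniform([-9, -21, -17], [9, 21, 8], size=(n, 3))
    return pts
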