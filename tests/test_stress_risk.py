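import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import perifem.stress_risk as SR
import perifem.fem as F
from perifem import geometry as G


def sym(vals):
    a, b, c, d, e, f = vals
    return np.array([[a, d, f], [d, b, e], [f, e, c]])


def cubic_roots_oracle(t):
    """Principal stresses via the characteristic polynomial roots."""
    i1 = np.trace(t)
    i2 = 0.5 * (i1 ** 2 - np.trace(t @ t))
    i3 = np.linalg.det(t)
    roots = np.roots([1.0, -i1, i2, -i3])
    return np.sort(roots.real)[::-1]


class TestPrincipalStresses:
    def test_diagonal_tensor(self):
        s = SR.principal_stresses(np.diag([3.0, 1.0, -2.0]))
        assert np.allclose(s, [3.0, 1.0, -2.0])

    def test_pure_shear(self):
        tau = 2.5
        t = np.zeros((3, 3))
        t[0, 1] = t[1, 0] = tau
        assert np.allclose(SR.principal_stresses(t), [tau, 0.0, -tau])

    def test_nonsymmetric_rejected(self):
        t = np.zeros((3, 3))
        t[0, 1] = 1.0
        with pytest.raises(SR.RiskError):
            SR.principal_stresses(t)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=6))
    def test_matches_characteristic_polynomial_oracle(self, vals):
        t = sym(vals)
        ours = SR.principal_stresses(t)
        oracle = cubic_roots_oracle(t)
        assert np.allclose(ours, oracle, atol=1e-6 * max(1, np.abs(t).max()))


class TestSigmaCT:
    @pytest.mark.parametrize("s,exp_c,exp_t", [
        ((3, 1, -2), -2, 3),
        ((5, 5, 5), 0, 5),
        ((-5, -5, -5), -5, 0),
        ((0, 0, 0), 0, 0)])
    def test_clamping(self, s, exp_c, exp_t):
        sC, sT = SR.sigma_C_T(*s)
        assert sC == exp_c and sT == exp_t

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    def test_signs_and_exclusivity(self, s):
        sC, sT = SR.sigma_C_T(*s)
        assert sC <= 0 <= sT
        if all(x >= 0 for x in s) or all(x <= 0 for x in s):
            assert sT * (-sC) == 0.0


class TestVonMises:
    def test_uniaxial(self):
        assert SR.von_mises(np.diag([7.0, 0, 0])) == pytest.approx(7.0)
        assert SR.von_mises(np.diag([-7.0, 0, 0])) == pytest.approx(7.0)

    def test_hydrostatic_invariance(self):
        t = sym([10, -4, 2, 3, 1, -2])
        shifted = t + 123.0 * np.eye(3)
        assert SR.von_mises(t) == pytest.approx(SR.von_mises(shifted))
        assert SR.von_mises(50.0 * np.eye(3)) == pytest.approx(0.0, abs=1e-9)

    def test_pure_shear_sqrt3(self):
        tau = 4.0
        t = np.zeros((3, 3))
        t[0, 1] = t[1, 0] = tau
        assert SR.von_mises(t) == pytest.approx(np.sqrt(3) * tau)

    def test_voigt_variant_agrees(self):
        t = sym([10, -4, 2, 3, 1, -2])
        v = np.array([10, -4, 2, 3, 1, -2.0])
        assert SR.von_mises_voigt(v) == pytest.approx(SR.von_mises(t))


class TestRiskIndex:
    def test_admissible_compression_is_unity(self):
        assert SR.risk_index(-115.0, 0.0, SR.CORTICAL_LIMITS) == 1.0

    def test_zero_state(self):
        assert SR.risk_index(0.0, 0.0, SR.CORTICAL_LIMITS) == 0.0

    def test_trabecular_mixed_state(self):
        assert SR.risk_index(-2.5, 2.5, SR.TRABECULAR_LIMITS) == 1.0

    def test_default_limits(self):
        lims = SR.default_strength_limits()
        assert lims[G.REGION_CORTICAL].sigma_T0_MPa == 180.0
        assert lims[G.REGION_CORTICAL].sigma_C0_MPa == 115.0
        assert lims[G.REGION_TRABECULAR].sigma_T0_MPa == 5.0
        assert lims[G.REGION_TRABECULAR].sigma_C0_MPa == 5.0

    def test_nonpositive_limits_rejected(self):
        with pytest.raises(SR.RiskError):
            SR.StrengthLimits(0.0, 5.0)

    def test_positively_homogeneous_in_load(self):
        r = np.random.default_rng(2)
        s = r.standard_normal((50, 3)) * 40
        sC, sT = SR.sigma_C_T(s[:, 0], s[:, 1], s[:, 2])
        R1 = SR.risk_index(sC, sT, SR.CORTICAL_LIMITS)
        k = 3.7
        sCk, sTk = SR.sigma_C_T(*(k * s).T)
        Rk = SR.risk_index(sCk, sTk, SR.CORTICAL_LIMITS)
        assert np.allclose(Rk, k * R1)


class TestControlRegions:
    def test_delta_arithmetic(self, regions8):
        assert regions8.delta_mm == pytest.approx(0.25 * 3.6)

    def test_axial_thirds_equal(self, regions8):
        z1, z2 = regions8.z_splits
        z_hi, z_lo = regions8.trab_span
        assert (z_hi - z1) == pytest.approx(z1 - z2, abs=1e-9)
        assert (z1 - z2) == pytest.approx(z2 - z_lo, abs=1e-9)

    def test_no_member_farther_than_delta(self, regions8, scenario8_p1,
                                          solved8):
        _, _, sig = solved8
        xg = sig.gauss_points.reshape(-1, 3)
        member = regions8.membership.reshape(-1)
        prof = SR._implant_surface_profile(scenario8_p1)
        inside = member > 0
        # brute-force distance oracle on a dense resampled profile
        dense = []
        for a, b in zip(prof[:-1], prof[1:]):
            for t in np.linspace(0, 1, 24):
                dense.append(a + t * (b - a))
        dense = np.array(dense)
        rz = np.column_stack([np.hypot(xg[inside, 0], xg[inside, 1]),
                              xg[inside, 2]])
        d = np.min(np.linalg.norm(rz[:, None, :] - dense[None], axis=2),
                   axis=1)
        assert d.max() <= regions8.delta_mm + 0.01

    def test_membership_tags_match_mesh_regions(self, regions8, mesh8_coarse):
        member = regions8.membership
        reg = mesh8_coarse.region
        for e in range(0, len(reg), 37):
            tags = member[e][member[e] > 0]
            if reg[e] == G.REGION_CORTICAL:
                assert set(tags) <= {1}
            elif reg[e] == G.REGION_TRABECULAR:
                assert set(tags) <= {2, 3, 4}
            else:
                assert len(tags) == 0

    def test_all_four_regions_populated(self, regions8):
        assert regions8.empty_regions == ()


class TestRegionStats:
    def _uniform_stress(self, mesh, value):
        E = len(mesh.elements)
        vals = np.tile(value, (E, 4, 1))
        vol, _ = F.bmatrices(mesh)
        xg = np.einsum("ga,eak->egk", F._GP4, mesh.nodes[mesh.elements[:, :4]])
        return F.StressField(mesh, vals, xg, np.outer(vol, F._GW4))

    def test_uniform_field_mean_equals_peak(self, mesh8_coarse, scenario8_p1,
                                            regions8):
        sig = self._uniform_stress(mesh8_coarse,
                                   np.array([-3.0, -3.0, -3.0, 0, 0, 0]))
        rep = SR.region_stats(sig, regions8)
        for region in SR.OMEGA_NAMES.values():
            assert rep.value(region, "sigma_c_abs", "mean") == \
                pytest.approx(3.0)
            assert rep.value(region, "sigma_c_abs", "peak") == \
                pytest.approx(3.0)
            assert rep.value(region, "sigma_vm", "peak") == \
                pytest.approx(0.0, abs=1e-9)

    def test_peak_dominates_mean(self, solved8, regions8):
        _, _, sig = solved8
        rep = SR.region_stats(sig, regions8)
        t = rep.table
        assert (t["peak"] + 1e-12 >= t["mean"]).all()
        assert (t["mean"] >= 0).all()

    def test_pointwise_risk_mean_dominates_risk_of_means(self, solved8,
                                                         regions8):
        """Aggregating R pointwise bounds R of the aggregated stresses."""
        _, _, sig = solved8
        rep = SR.region_stats(sig, regions8)
        for region, key in (("cortical", SR.CORTICAL_LIMITS),
                            ("trab_mid", SR.TRABECULAR_LIMITS)):
            mean_R = rep.value(region, "risk", "mean")
            lower = rep.value(region, "sigma_c_abs", "mean") / key.sigma_C0_MPa
            assert mean_R + 1e-12 >= lower

    def test_plain_vs_volume_weighting_differ(self, solved8, regions8):
        _, _, sig = solved8
        a = SR.region_stats(sig, regions8, weighting="volume")
        b = SR.region_stats(sig, regions8, weighting="plain")
        assert not np.allclose(a.table["mean"], b.table["mean"])
        assert np.allclose(a.table["peak"], b.table["peak"])

    def test_report_reproducible(self, solved8, regions8):
        _, _, sig = solved8
        a = SR.region_stats(sig, regions8).table
        b = SR.region_stats(sig, regions8).table
        assert a.equals(b)
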