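import numpy as np
import pytest

import perifem.fem as F
import perifem.geometry as G
from perifem import meshing as M
from perifem.benchmarks import bar_extension, patch_test


def exact_tet10_stiffness(x, D):
    """Independent assembly oracle via exact barycentric monomial integration.

    B(lambda) is linear in the barycentric coordinates, so every entry of
    B^T D B is a quadratic polynomial in lambda; these are integrated with
    the closed form  int prod(lam_i^a_i) dV = V * 6 * prod(a_i!) / (sum+3)!.
    """
    from math import factorial
    J = x[1:] - x[:1]
    V = np.linalg.det(J) / 6.0
    invJ = np.linalg.inv(J)
    dlam = np.zeros((4, 3))
    dlam[1:] = invJ.T
    dlam[0] = -dlam[1:].sum(axis=0)

    # dN_i/dx = sum_a c[i][a] * lam_a  (vector coefficients)
    pairs = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
    coeff = np.zeros((10, 4, 3))
    for i in range(4):
        coeff[i, i] = 4 * dlam[i]
        for a in range(4):
            if a != i:
                coeff[i, a] -= 0.0
        coeff[i, i] -= 0.0
    # corner N_i = lam_i(2 lam_i - 1): grad = (4 lam_i - 1) dlam_i
    # represent -1 * dlam_i via the partition of unity sum lam_a = 1
    for i in range(4):
        coeff[i] = np.zeros((4, 3))
        coeff[i][i] = 4 * dlam[i]
        for a in range(4):
            coeff[i][a] -= dlam[i]
    for e, (a, b) in enumerate(pairs):
        coeff[4 + e][a] += 4 * dlam[b]
        coeff[4 + e][b] += 4 * dlam[a]

    def bmat(c):  # c: (3,) gradient -> (6, 3) strain rows for one node
        return np.array([[c[0], 0, 0], [0, c[1], 0], [0, 0, c[2]],
                         [c[1], c[0], 0], [0, c[2], c[1]], [c[2], 0, c[0]]])

    def moment(a):  # integral of prod lam^a over the tet, divided by V
        s = sum(a)
        num = 6 * np.prod([factorial(k) for k in a])
        return num / factorial(s + 3)

    K = np.zeros((30, 30))
    for i in range(10):
        for j in range(10):
            blk = np.zeros((3, 3))
            for a in range(4):
                for b in range(4):
                    e = [0, 0, 0, 0]
                    e[a] += 1
                    e[b] += 1
                    w = moment(e) * V
                    Bi = bmat(coeff[i][a])
                    Bj = bmat(coeff[j][b])
                    blk += w * (Bi.T @ D @ Bj)
            K[3 * i:3 * i + 3, 3 * j:3 * j + 3] = blk
    return K


class TestElement:
    def test_single_tet_stiffness_matches_integration_oracle(self):
        r = np.random.default_rng(1)
        x = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        x += 0.15 * r.standard_normal(x.shape)
        corners = x
        mids = np.array([(corners[a] + corners[b]) / 2
                         for a, b in M.TET_EDGES])
        nodes = np.vstack([corners, mids])
        mesh = M.Tet10Mesh(nodes, np.arange(10)[None, :],
                           np.array([G.REGION_CORTICAL], np.int8),
                           {}, n_corner_nodes=4)
        mat = F.MaterialModel(1.0, 0.0, "o")
        system = F.assemble(mesh, {G.REGION_CORTICAL: mat})
        K_or = exact_tet10_stiffness(x, mat.stiffness_matrix())
        assert np.allclose(system.K.toarray(), K_or, atol=1e-10)

    def test_rigid_motions_have_zero_energy(self, mesh8_coarse):
        system = F.assemble(mesh8_coarse, F.default_materials())
        n = len(mesh8_coarse.nodes)
        for vec in (np.tile([1.0, 0, 0], n), np.tile([0, 1.0, -2.0], n)):
            assert abs(vec @ (system.K @ vec)) < 1e-6 * abs(system.K).sum() / n
        # infinitesimal rotation about z
        rot = np.zeros((n, 3))
        rot[:, 0] = -mesh8_coarse.nodes[:, 1]
        rot[:, 1] = mesh8_coarse.nodes[:, 0]
        r = rot.reshape(-1)
        assert r @ (system.K @ r) < 1e-8 * r @ r * 1e3

    def test_stiffness_linear_in_youngs_modulus(self):
        mesh = M.build_box_mesh((1, 1, 1), (2, 2, 2))
        K1 = F.assemble(mesh, {G.REGION_CORTICAL:
                               F.MaterialModel(100.0, 0.3, "a")}).K
        K2 = F.assemble(mesh, {G.REGION_CORTICAL:
                               F.MaterialModel(200.0, 0.3, "a")}).K
        assert np.allclose((K2 - K1 * 2).data, 0.0, atol=1e-9)


class TestMaterialsAndLoad:
    def test_default_material_constants(self):
        mats = F.default_materials()
        assert mats[G.REGION_CORTICAL].E_MPa == 13700.0
        assert mats[G.REGION_CORTICAL].nu == 0.30
        assert mats[G.REGION_TRABECULAR].E_MPa == 500.0
        assert mats[G.REGION_IMPLANT].E_MPa == 114000.0
        assert mats[G.REGION_IMPLANT].nu == 0.34

    def test_load_resultant_and_angle(self):
        lc = F.LoadCase()
        assert lc.resultant_N == pytest.approx(np.hypot(100.0, 250.0))
        assert lc.occlusal_angle_deg == pytest.approx(68.2, abs=0.05)

    def test_invalid_material_rejected(self):
        with pytest.raises(F.FEMError):
            F.MaterialModel(-1.0, 0.3, "bad")
        with pytest.raises(F.FEMError):
            F.MaterialModel(100.0, 0.5, "bad")

    def test_applied_force_exact(self, mesh8_coarse):
        system = F.assemble(mesh8_coarse, F.default_materials())
        F.apply_bcs_and_load(system, mesh8_coarse, F.LoadCase())
        tot = system.F.reshape(-1, 3).sum(axis=0)
        # half model carries half of the x and z components exactly
        assert np.allclose(tot, [50.0, 0.0, -125.0], atol=1e-10)

    def test_zero_load_zero_displacement(self, mesh8_coarse):
        system = F.assemble(mesh8_coarse, F.default_materials())
        F.apply_bcs_and_load(system, mesh8_coarse,
                             F.LoadCase(F_lateral_N=0.0, F_vertical_N=0.0))
        u = F.solve(system)
        assert np.abs(u.values).max() == 0.0

    def test_missing_material_raises(self, mesh8_coarse):
        mats = F.default_materials()
        del mats[G.REGION_TRABECULAR]
        with pytest.raises(F.FEMError):
            F.assemble(mesh8_coarse, mats)


class TestSolution:
    def test_patch_test_exact_to_machine_precision(self):
        err, spread, _, _ = patch_test()
        assert err < 1e-12
        assert spread < 1e-9

    def test_bar_tip_displacement(self):
        tip, exact, _ = bar_extension()
        assert tip == pytest.approx(exact, rel=5e-3)

    def test_global_equilibrium(self, solved8):
        system, u, _ = solved8
        R = F.reaction_forces(system, u)
        applied = np.array([50.0, 0.0, -125.0])
        assert np.allclose(R, -applied, rtol=1e-6, atol=1e-6)

    def test_energy_consistency(self, solved8):
        system, u, _ = solved8
        assert F.strain_energy(system, u) == pytest.approx(
            F.external_work(system, u), rel=1e-8)

    def test_stress_constitutive_identity(self):
        mesh = M.build_box_mesh((1, 1, 1), (1, 1, 1))
        mats = {G.REGION_CORTICAL: F.MaterialModel(200.0, 0.0, "c")}
        e = 1e-3
        u = F.DisplacementField(mesh, np.column_stack(
            [e * mesh.nodes[:, 0], np.zeros(len(mesh.nodes)),
             np.zeros(len(mesh.nodes))]))
        sig = F.stress_at_gauss(mesh, mats, u)
        v = sig.values.reshape(-1, 6)
        assert np.allclose(v[:, 0], 200.0 * e, atol=1e-12)
        assert np.allclose(v[:, 1:], 0.0, atol=1e-12)

    def test_pure_shear_stress(self):
        mesh = M.build_box_mesh((1, 1, 1), (1, 1, 1))
        E_mod, nu, gam = 200.0, 0.25, 1e-3
        mats = {G.REGION_CORTICAL: F.MaterialModel(E_mod, nu, "c")}
        u = F.DisplacementField(mesh, np.column_stack(
            [gam * mesh.nodes[:, 1], np.zeros(len(mesh.nodes)),
             np.zeros(len(mesh.nodes))]))
        sig = F.stress_at_gauss(mesh, mats, u)
        v = sig.values.reshape(-1, 6)
        mu = E_mod / (2 * (1 + nu))
        assert np.allclose(v[:, 3], mu * gam, atol=1e-12)

    def test_solver_rejects_unconstrained_system(self, mesh8_coarse):
        system = F.assemble(mesh8_coarse, F.default_materials())
        with pytest.raises(F.FEMError):
            F.solve(system)
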