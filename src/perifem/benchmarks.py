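"""Analytic verification benchmarks for the elasticity solver.

These drive the solver against closed-form solutions: the linear patch test
(quadratic tetrahedra reproduce affine displacement fields exactly), the
end-loaded prismatic bar, and the Lame thick-walled cylinder under internal
pressure in plane strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from . import geometry as G
from .fem import (DisplacementField, MaterialModel, assemble, stress_at_gauss)
from .meshing import Tet10Mesh, build_box_mesh, build_hollow_cylinder_mesh


def _solve_with_dirichlet(mesh: Tet10Mesh, materials, fixed_dofs: np.ndarray,
                          fixed_values: np.ndarray, F: np.ndarray | None = None):
    system = assemble(mesh, materials)
    n = system.ndof
    u = np.zeros(n)
    u[fixed_dofs] = fixed_values
    free = np.ones(n, dtype=bool)
    free[fixed_dofs] = False
    K = system.K
    rhs = (F if F is not None else np.zeros(n))[free] - K[free][:, ~free] @ u[~free]
    u[free] = spla.splu(K[free][:, free].tocsc()).solve(rhs)
    return system, DisplacementField(mesh, u.reshape(-1, 3))


def patch_test(n: int = 2, E: float = 1000.0, nu: float = 0.3,
               A: np.ndarray | None = None):
    """Impose an affine displacement on the box boundary; return the maximum
    interior displacement error and the Gauss-point stress spread."""
    if A is None:
        A = np.array([[1.0, 0.4, 0.2], [0.0, 0.7, 0.3], [0.5, 0.1, 0.9]]) * 1e-3
    mesh = build_box_mesh((1, 1, 1), (n, n, n))
    mats = {G.REGION_CORTICAL: MaterialModel(E, nu, "patch")}
    exact = mesh.nodes @ A.T
    bnodes = np.unique(np.concatenate(
        [v.ravel() for k, v in mesh.face_groups.items() if len(v)]))
    dofs = (3 * bnodes[:, None] + np.arange(3)).ravel()
    system, u = _solve_with_dirichlet(mesh, mats, dofs,
                                      exact[bnodes].reshape(-1))
    err = np.abs(u.values - exact).max()
    sig = stress_at_gauss(mesh, mats, u)
    spread = float(np.ptp(sig.values.reshape(-1, 6), axis=0).max())
    return err, spread, u, sig


def bar_extension(L: float = 10.0, a: float = 1.0, F: float = 100.0,
                  E: float = 1000.0, n: tuple = (2, 2, 10)):
    """End-loaded bar (nu = 0): tip displacement vs FL/EA."""
    mesh = build_box_mesh((a, a, L), (n[0], n[1], n[2]))
    mats = {G.REGION_CORTICAL: MaterialModel(E, 0.0, "bar")}
    fixed_nodes = np.unique(mesh.face_groups["zmin"])
    dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    # uniform traction F/a^2 on the top face, integrated on tri6 faces
    top = mesh.face_groups["zmax"]
    p = mesh.nodes[top[:, :3]]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    Fv = np.zeros(3 * len(mesh.nodes))
    for m in range(3, 6):
        np.add.at(Fv, 3 * top[:, m] + 2, areas / 3.0 * (F / a ** 2))
    system, u = _solve_with_dirichlet(mesh, mats, dofs,
                                      np.zeros(len(dofs)), Fv)
    tip = u.values[np.isclose(mesh.nodes[:, 2], L)][:, 2].mean()
    return tip, F * L / (E * a ** 2), u


@dataclass
class LameResult:
    mesh: Tet10Mesh
    u: DisplacementField
    stress: object
    max_rel_err_radial: float
    max_rel_err_hoop: float
    p: float
    r_in: float
    r_out: float


def lame_sigma(r: np.ndarray, p: float, a: float, b: float):
    """Plane-strain Lame solution for internal pressure p, radii a < b."""
    c = p * a ** 2 / (b ** 2 - a ** 2)
    sr = c * (1 - b ** 2 / r ** 2)
    st = c * (1 + b ** 2 / r ** 2)
    return sr, st


def lame_cylinder(nr: int = 6, ntheta: int = 24, nz: int = 2,
                  r_in: float = 1.0, r_out: float = 2.0, height: float = 0.5,
                  p: float = 10.0, E: float = 1000.0, nu: float = 0.3,
                  sample_band: tuple = (0.25, 0.75)) -> LameResult:
    """Thick-walled cylinder under internal pressure, plane strain.

    Plane strain is enforced by fixing u_z on both end faces; rigid rotation
    about z is removed by the discrete symmetry of the load.  The returned
    errors compare FE Gauss stresses with the closed form in an interior
    radial band (away from the pressurised surface where the polygonal
    approximation of the circle perturbs the local field).
    """
    mesh = build_hollow_cylinder_mesh(r_in, r_out, height, nr, ntheta, nz)
    mats = {G.REGION_CORTICAL: MaterialModel(E, nu, "lame")}
    n = len(mesh.nodes)
    # u_z = 0 on end faces; pin u_theta via two nodes to kill rotation
    zdofs = 3 * np.unique(np.concatenate([mesh.face_groups["zmin"].ravel(),
                                          mesh.face_groups["zmax"].ravel()])) + 2
    th = np.arctan2(mesh.nodes[:, 1], mesh.nodes[:, 0])
    on_x = np.isclose(th, 0.0, atol=1e-9)
    on_y = np.isclose(th, np.pi / 2, atol=1e-9)
    pins = np.concatenate([3 * np.where(on_x)[0] + 1, 3 * np.where(on_y)[0]])
    fixed = np.unique(np.concatenate([zdofs, pins]))

    # pressure on the inner surface: traction p * (-n), n outward of the solid
    inner = mesh.face_groups["inner"]
    pts = mesh.nodes[inner[:, :3]]
    nvec = np.cross(pts[:, 1] - pts[:, 0], pts[:, 2] - pts[:, 0])
    areas = 0.5 * np.linalg.norm(nvec, axis=1)
    nhat = nvec / np.linalg.norm(nvec, axis=1, keepdims=True)
    # orient outward of the cylinder solid (towards the axis is -radial)
    cent = pts.mean(axis=1)
    radial = cent[:, :2] / np.linalg.norm(cent[:, :2], axis=1, keepdims=True)
    sign = np.sign(np.einsum("ij,ij->i", nhat[:, :2], radial))
    nhat[sign > 0] *= -1.0          # boundary normal points out of the solid
    traction = -p * nhat            # pressure pushes into the solid
    F = np.zeros(3 * n)
    for m in range(3, 6):
        np.add.at(F, (3 * inner[:, m][:, None] + np.arange(3)),
                  areas[:, None] / 3.0 * traction)
    system, u = _solve_with_dirichlet(mesh, mats, fixed,
                                      np.zeros(len(fixed)), F)
    sig = stress_at_gauss(mesh, mats, u)

    xg = sig.gauss_points.reshape(-1, 3)
    r = np.hypot(xg[:, 0], xg[:, 1])
    band = (r > r_in + sample_band[0] * (r_out - r_in)) \
        & (r < r_in + sample_band[1] * (r_out - r_in))
    t = sig.tensors().reshape(-1, 3, 3)
    er = np.stack([xg[:, 0] / r, xg[:, 1] / r, np.zeros_like(r)], axis=1)
    et = np.stack([-xg[:, 1] / r, xg[:, 0] / r, np.zeros_like(r)], axis=1)
    srr = np.einsum("pi,pij,pj->p", er, t, er)
    stt = np.einsum("pi,pij,pj->p", et, t, et)
    sr_ex, st_ex = lame_sigma(r, p, r_in, r_out)
    scale = p * r_in ** 2 / (r_out ** 2 - r_in ** 2) * (1 + r_out ** 2 / r_in ** 2)
    err_r = np.abs(srr[band] - sr_ex[band]).max() / scale
    err_t = np.abs(stt[band] - st_ex[band]).max() / scale
    return LameResult(mesh, u, sig, float(err_r), float(err_t), p, r_in, r_out)
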