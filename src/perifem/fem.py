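"""Linear isotropic elasticity on 10-node tetrahedra.

Pure displacement formulation, quadratic shape functions, three displacement
degrees of freedom per node, 4-point Gauss quadrature (exact for the straight-
edged elements used here).  All quantities are in mm-N-MPa units.

The functional load case is a resultant of 100 N along the buccolingual x
axis and 250 N of intrusive force along -z (about 68 degrees to the occlusal
plane), introduced as a statically equivalent uniform traction on the
abutment top faces; comparisons in bone are made far from the load patch, so
the local introduction detail is immaterial there (Saint-Venant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import geometry as G
from .meshing import Tet10Mesh

VOIGT = ["xx", "yy", "zz", "xy", "yz", "zx"]


class FEMError(RuntimeError):
    pass


@dataclass(frozen=True)
class MaterialModel:
    E_MPa: float
    nu: float
    region: str

    def __post_init__(self):
        if self.E_MPa <= 0 or not (0 <= self.nu < 0.5):
            raise FEMError(f"invalid elastic constants ({self.E_MPa}, {self.nu})")

    def stiffness_matrix(self) -> np.ndarray:
        lam = self.E_MPa * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E_MPa / (2 * (1 + self.nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2 * mu
        D[3:, 3:] = mu * np.eye(3)
        return D


def default_materials() -> dict[int, MaterialModel]:
    """Titanium alloy implant/abutment, type-II bone elastic constants."""
    ti = dict(E_MPa=114000.0, nu=0.34)
    return {
        G.REGION_IMPLANT: MaterialModel(**ti, region="implant"),
        G.REGION_ABUTMENT: MaterialModel(**ti, region="abutment"),
        G.REGION_CORTICAL: MaterialModel(13700.0, 0.30, "cortical"),
        G.REGION_TRABECULAR: MaterialModel(500.0, 0.30, "trabecular"),
    }


@dataclass(frozen=True)
class LoadCase:
    F_lateral_N: float = 100.0
    F_vertical_N: float = 250.0        # intrusive, applied along -z
    application_height_mm: float = 7.0
    patch_radius_mm: float | None = None   # None: whole abutment top

    @property
    def force_vector(self) -> np.ndarray:
        return np.array([self.F_lateral_N, 0.0, -self.F_vertical_N])

    @property
    def resultant_N(self) -> float:
        return float(np.linalg.norm(self.force_vector))

    @property
    def occlusal_angle_deg(self) -> float:
        """Angle of the resultant to the occlusal (horizontal) plane."""
        return float(np.degrees(np.arctan2(self.F_vertical_N,
                                           abs(self.F_lateral_N))))


# --------------------------------------------------------------------------- #
# tet10 reference element
# --------------------------------------------------------------------------- #

_GP4 = np.array([  # 4-point degree-2 rule in barycentric coordinates
    [0.58541020, 0.13819660, 0.13819660, 0.13819660],
    [0.13819660, 0.58541020, 0.13819660, 0.13819660],
    [0.13819660, 0.13819660, 0.58541020, 0.13819660],
    [0.13819660, 0.13819660, 0.13819660, 0.58541020]])
_GW4 = np.full(4, 0.25)


def shape_functions(lam: np.ndarray) -> np.ndarray:
    """Tet10 shape functions at barycentric points lam (..., 4) -> (..., 10)."""
    l0, l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2], lam[..., 3]
    corners = [l * (2 * l - 1) for l in (l0, l1, l2, l3)]
    edges = [4 * l0 * l1, 4 * l1 * l2, 4 * l2 * l0,
             4 * l0 * l3, 4 * l1 * l3, 4 * l2 * l3]
    return np.stack(corners + edges, axis=-1)


def shape_gradients_bary(lam: np.ndarray) -> np.ndarray:
    """d N / d lambda at points (..., 4) -> (..., 10, 4)."""
    out = np.zeros(lam.shape[:-1] + (10, 4))
    for i in range(4):
        out[..., i, i] = 4 * lam[..., i] - 1
    pairs = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
    for e, (a, b) in enumerate(pairs):
        out[..., 4 + e, a] = 4 * lam[..., b]
        out[..., 4 + e, b] = 4 * lam[..., a]
    return out


def element_geometry(mesh: Tet10Mesh):
    """Per-element corner Jacobians: volumes and barycentric gradients."""
    x = mesh.nodes[mesh.elements[:, :4]]        # (E, 4, 3)
    J = x[:, 1:] - x[:, :1]                     # (E, 3, 3)
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    if np.any(vol <= 0):
        raise FEMError(f"inverted element {int(np.argmin(vol))}")
    invJ = np.linalg.inv(J)                     # d(xi)/dx
    # gradients of the 4 barycentric coordinates wrt x: (E, 4, 3)
    dlam = np.empty((len(x), 4, 3))
    dlam[:, 1:] = invJ.transpose(0, 2, 1)
    dlam[:, 0] = -dlam[:, 1:].sum(axis=1)
    return vol, dlam


def bmatrices(mesh: Tet10Mesh):
    """Strain-displacement matrices at the 4 Gauss points: (E, 4, 6, 30)."""
    vol, dlam = element_geometry(mesh)
    dN_dl = shape_gradients_bary(_GP4)          # (4gp, 10, 4)
    # dN/dx (E, gp, 10, 3)
    dN = np.einsum("gna,eak->egnk", dN_dl, dlam)
    E = len(vol)
    B = np.zeros((E, 4, 6, 30))
    dx, dy, dz = dN[..., 0], dN[..., 1], dN[..., 2]
    cols = np.arange(10) * 3
    B[:, :, 0, cols] = dx
    B[:, :, 1, cols + 1] = dy
    B[:, :, 2, cols + 2] = dz
    B[:, :, 3, cols] = dy
    B[:, :, 3, cols + 1] = dx
    B[:, :, 4, cols + 1] = dz
    B[:, :, 4, cols + 2] = dy
    B[:, :, 5, cols] = dz
    B[:, :, 5, cols + 2] = dx
    return vol, B


def material_table(mesh: Tet10Mesh,
                   materials: dict[int, MaterialModel]) -> np.ndarray:
    """Per-element 6x6 stiffness matrices."""
    for tag in np.unique(mesh.region):
        if int(tag) not in materials:
            raise FEMError(f"no material for region {G.REGION_NAMES[int(tag)]}")
    Ds = {tag: m.stiffness_matrix() for tag, m in materials.items()}
    D = np.empty((len(mesh.elements), 6, 6))
    for tag, d in Ds.items():
        D[mesh.region == tag] = d
    return D


# --------------------------------------------------------------------------- #
# assembly, boundary conditions, solve
# --------------------------------------------------------------------------- #

@dataclass
class LinearSystem:
    mesh: Tet10Mesh
    K: sp.csr_matrix                     # full (unconstrained) stiffness
    F: np.ndarray = None                 # load vector, set by apply_bcs_and_load
    fixed: np.ndarray = None             # boolean dof mask
    load: LoadCase | None = None

    @property
    def ndof(self) -> int:
        return self.K.shape[0]


@dataclass
class DisplacementField:
    mesh: Tet10Mesh
    values: np.ndarray                   # (N, 3) mm

    def flat(self) -> np.ndarray:
        return self.values.reshape(-1)


@dataclass
class StressField:
    """Cauchy stress (Voigt xx, yy, zz, xy, yz, zx) at the 4 Gauss points."""

    mesh: Tet10Mesh
    values: np.ndarray                   # (E, 4, 6) MPa
    gauss_points: np.ndarray             # (E, 4, 3) mm
    gauss_weights: np.ndarray            # (E, 4) mm^3 (quadrature x |J|)
    quadrature: str = "tet4pt"

    def tensors(self) -> np.ndarray:
        """(E, 4, 3, 3) symmetric tensor form."""
        s = self.values
        t = np.empty(s.shape[:-1] + (3, 3))
        t[..., 0, 0], t[..., 1, 1], t[..., 2, 2] = s[..., 0], s[..., 1], s[..., 2]
        t[..., 0, 1] = t[..., 1, 0] = s[..., 3]
        t[..., 1, 2] = t[..., 2, 1] = s[..., 4]
        t[..., 0, 2] = t[..., 2, 0] = s[..., 5]
        return t


def assemble(mesh: Tet10Mesh,
             materials: dict[int, MaterialModel]) -> LinearSystem:
    """Assemble the global stiffness matrix (symmetric positive semidefinite
    with the six rigid-body modes before constraints)."""
    vol, B = bmatrices(mesh)
    D = material_table(mesh, materials)
    Ke = np.zeros((len(vol), 30, 30))
    for g in range(4):
        Bg = B[:, g]
        Ke += np.einsum("eji,ejk,ekl->eil", Bg, D, Bg, optimize=True) \
            * (_GW4[g] * vol)[:, None, None]
    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(len(vol), 30)
    rows = np.repeat(dofs, 30, axis=1).ravel()
    cols = np.tile(dofs, (1, 30)).ravel()
    n = 3 * len(mesh.nodes)
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return LinearSystem(mesh, K)


def _face_areas_normals(mesh: Tet10Mesh, faces: np.ndarray):
    p = mesh.nodes[faces[:, :3]]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    a = 0.5 * np.linalg.norm(n, axis=1)
    return a, n


def apply_bcs_and_load(system: LinearSystem, mesh: Tet10Mesh,
                       load: LoadCase) -> LinearSystem:
    """Fix all dofs on the coronal cuts, u_y on the symmetry plane if present,
    and distribute the load as a uniform traction on the load patch.

    The traction resultant equals the prescribed force vector exactly; on the
    symmetric half-model the half resultant is applied.
    """
    cuts = mesh.face_groups.get("coronal_cuts")
    patch = mesh.face_groups.get("load_patch")
    if cuts is None or len(cuts) == 0:
        raise FEMError("empty coronal_cuts face group")
    if patch is None or len(patch) == 0:
        raise FEMError("empty load_patch face group")

    ndof = system.ndof
    fixed = np.zeros(ndof, dtype=bool)
    cut_nodes = np.unique(cuts)
    fixed[(3 * cut_nodes[:, None] + np.arange(3)).ravel()] = True

    sym = mesh.face_groups.get("symmetry")
    symmetric = sym is not None and len(sym) > 0
    if symmetric:
        sn = np.unique(sym)
        fixed[3 * sn + 1] = True         # u_y = 0 on the mirror plane

    if load.patch_radius_mm is not None:
        c = mesh.nodes[patch[:, :3]].mean(axis=1)
        keep = np.hypot(c[:, 0], c[:, 1]) <= load.patch_radius_mm
        if keep.any():
            patch = patch[keep]
    areas, _ = _face_areas_normals(mesh, patch)
    total_area = areas.sum()
    Fvec = load.force_vector.copy()
    if symmetric:
        Fvec = Fvec / 2.0                # mirror half carries the other half
        Fvec[1] = 0.0
    traction = Fvec / total_area
    F = np.zeros(ndof)
    # exact integration of quadratic shape functions on straight tri6 faces:
    # corner weights vanish, each mid-side node carries A/3
    for m in range(3, 6):
        np.add.at(F, 3 * patch[:, m][:, None] + np.arange(3),
                  (areas[:, None] / 3.0) * traction[None, :])
    system.F = F
    system.fixed = fixed
    system.load = load
    return system


def solve(system: LinearSystem, check_residual: bool = True) -> DisplacementField:
    """Direct sparse solve of the constrained system (deterministic)."""
    if system.F is None or system.fixed is None:
        raise FEMError("apply_bcs_and_load must run before solve")
    free = ~system.fixed
    if not free.any() or not system.fixed.any():
        raise FEMError("system is fully constrained or fully unconstrained")
    K = system.K
    Kff = K[free][:, free].tocsc()
    Ff = system.F[free]
    u = np.zeros(system.ndof)
    if np.any(Ff) or np.any(system.F):
        lu = spla.splu(Kff, permc_spec="MMD_AT_PLUS_A",
                       options=dict(SymmetricMode=True))
        uf = lu.solve(Ff)
        u[free] = uf
        if check_residual:
            r = np.linalg.norm(Kff @ uf - Ff)
            nf = np.linalg.norm(Ff)
            if nf > 0 and r / nf > 1e-8:
                raise FEMError(f"poor solver residual {r / nf:.2e}")
    return DisplacementField(system.mesh, u.reshape(-1, 3))


def stress_at_gauss(mesh: Tet10Mesh, materials: dict[int, MaterialModel],
                    u: DisplacementField) -> StressField:
    """sigma = D : eps(u) at the 4 Gauss points of every element."""
    vol, B = bmatrices(mesh)
    D = material_table(mesh, materials)
    ue = u.values[mesh.elements].reshape(len(vol), 30)
    eps = np.einsum("egij,ej->egi", B, ue)
    sig = np.einsum("eik,egk->egi", D, eps)
    xg = np.einsum("ga,eak->egk", _GP4, mesh.nodes[mesh.elements[:, :4]])
    wg = np.outer(vol, _GW4)
    return StressField(mesh, sig, xg, wg)


# --------------------------------------------------------------------------- #
# diagnostics
# --------------------------------------------------------------------------- #

def strain_energy(system: LinearSystem, u: DisplacementField) -> float:
    uu = u.flat()
    return float(0.5 * uu @ (system.K @ uu))


def external_work(system: LinearSystem, u: DisplacementField) -> float:
    return float(0.5 * system.F @ u.flat())


def reaction_forces(system: LinearSystem, u: DisplacementField) -> np.ndarray:
    """Resultant reaction on the constrained dofs, by direction."""
    R = system.K @ u.flat() - system.F
    R = np.where(system.fixed, R, 0.0)
    return R.reshape(-1, 3).sum(axis=0)


def solve_scenario(mesh: Tet10Mesh,
                   materials: dict[int, MaterialModel] | None = None,
                   load: LoadCase | None = None):
    """Convenience: assemble, constrain, solve, and evaluate stresses."""
    materials = materials or default_materials()
    load = load or LoadCase()
    system = assemble(mesh, materials)
    apply_bcs_and_load(system, mesh, load)
    u = solve(system)
    sig = stress_at_gauss(mesh, materials, u)
    return system, u, sig
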