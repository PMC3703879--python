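"""Zienkiewicz-Zhu stress recovery and mesh-convergence indicators.

Two error measures certify mesh adequacy:

* the global relative energy error norm, estimated from the difference
  between the raw Gauss-point stresses and a smoothed (recovered) nodal
  stress field,

      e_en = 100 * sqrt( ||sigma* - sigma_h||_E^2
                         / (||sigma*||_E^2 + ||sigma* - sigma_h||_E^2) )  [%]

  with ||s||_E^2 = integral s^T C^-1 s dV, accepted when <= 5 %;

* the relative L2 displacement change between successive refinements,

      e_u = 100 * ||u_fine - Pi u_coarse||_L2 / ||u_fine||_L2  [%],

  accepted when <= 0.5 %.  (A single-mesh "displacement error norm" is not
  well defined; pairing it with the refinement walk matches the convergence
  analysis the thresholds belong to.)

Recovery never averages across material interfaces: nodal values are kept
separately per region, because the true stress is discontinuous there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import geometry as G
from .fem import (DisplacementField, MaterialModel, StressField, _GP4,
                  default_materials, material_table, shape_functions,
                  solve_scenario)
from .meshing import (Tet10Mesh, SizeField, make_size_field, mesh_scenario,
                      refine_uniform)


class RecoveryError(RuntimeError):
    pass


# barycentric coordinates of the 10 local nodes
_LAM_NODES = np.array(
    [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1],
     [.5, .5, 0, 0], [0, .5, .5, 0], [.5, 0, .5, 0],
     [.5, 0, 0, .5], [0, .5, 0, .5], [0, 0, .5, .5]], float)
# linear extrapolation from the 4 Gauss points to the 10 nodes
_EXTRAP = _LAM_NODES @ np.linalg.inv(_GP4)


@dataclass
class RecoveredStress:
    """Nodal stress field, kept per material region (no cross averaging)."""

    mesh: Tet10Mesh
    nodal: dict[int, np.ndarray]          # region tag -> (N, 6), NaN off-region
    mode: str = "average"

    def at_gauss(self) -> np.ndarray:
        """Interpolate the recovered field back to Gauss points: (E, 4, 6)."""
        N = shape_functions(_GP4)         # (4, 10)
        out = np.empty((len(self.mesh.elements), 4, 6))
        for tag, vals in self.nodal.items():
            sel = self.mesh.region == tag
            nod = vals[self.mesh.elements[sel]]          # (e, 10, 6)
            out[sel] = np.einsum("gn,enc->egc", N, nod)
        return out


def recover_stress(mesh: Tet10Mesh, stress: StressField,
                   mode: str = "average") -> RecoveredStress:
    """Nodal recovery of the Gauss stress field, region by region.

    ``average``: volume-weighted average of the per-element nodal
    extrapolations over the elements of the same region sharing a node
    (exact for fields that are linear inside every element patch).
    ``spr``: superconvergent patch recovery -- a linear least-squares fit to
    the Gauss values of the elements sharing each node, evaluated at the
    node; falls back to averaging on under-determined patches.
    """
    if mode not in ("average", "spr"):
        raise RecoveryError(f"unknown recovery mode {mode!r}")
    n_nodes = len(mesh.nodes)
    counts = np.bincount(mesh.elements.ravel(), minlength=n_nodes)
    if np.any(counts == 0):
        raise RecoveryError("orphan node with no adjacent element")

    vol = np.abs(mesh.volumes())
    nodal_elem = np.einsum("ng,egc->enc", _EXTRAP, stress.values)  # (E,10,6)
    out: dict[int, np.ndarray] = {}
    for tag in np.unique(mesh.region):
        sel = np.where(mesh.region == tag)[0]
        acc = np.zeros((n_nodes, 6))
        wacc = np.zeros(n_nodes)
        ids = mesh.elements[sel].ravel()
        w = np.repeat(vol[sel], 10)
        np.add.at(acc, ids, nodal_elem[sel].reshape(-1, 6) * w[:, None])
        np.add.at(wacc, ids, w)
        vals = np.full((n_nodes, 6), np.nan)
        has = wacc > 0
        vals[has] = acc[has] / wacc[has, None]
        if mode == "spr":
            vals = _spr_patch_fit(mesh, stress, sel, vals, has)
        out[int(tag)] = vals
    return RecoveredStress(mesh, out, mode)


def _spr_patch_fit(mesh, stress, elem_sel, vals, has):
    """Least-squares linear polynomial fit over each nodal element patch."""
    # build node -> element adjacency for the selected region
    ids = mesh.elements[elem_sel, :4]
    node_elems: dict[int, list[int]] = {}
    for e_loc, row in zip(elem_sel, ids):
        for n in row:
            node_elems.setdefault(int(n), []).append(int(e_loc))
    # mid-edge nodes inherit the union of their corner patches afterwards
    xg = stress.gauss_points
    sg = stress.values
    fitted = vals.copy()
    for n, elems in node_elems.items():
        pts = xg[elems].reshape(-1, 3)
        if len(pts) < 8:
            continue                      # keep averaged value
        A = np.hstack([np.ones((len(pts), 1)), pts - mesh.nodes[n]])
        y = sg[elems].reshape(-1, 6)
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        fitted[n] = coef[0]
    # mid-edge nodes: average of the fitted end values where both exist
    edge = mesh.elements[elem_sel][:, 4:]
    ends = mesh.elements[elem_sel][:, [[0, 1], [1, 2], [2, 0],
                                       [0, 3], [1, 3], [2, 3]]]
    em = edge.ravel()
    e0 = ends[..., 0].ravel()
    e1 = ends[..., 1].ravel()
    fitted[em] = 0.5 * (fitted[e0] + fitted[e1])
    fitted[~has] = np.nan
    return fitted


# --------------------------------------------------------------------------- #
# error norms
# --------------------------------------------------------------------------- #

@dataclass
class ErrorReport:
    energy_error_norm_pct: float
    displacement_error_norm_pct: float | None = None
    per_region_energy_pct: dict[str, float] = field(default_factory=dict)
    converged: bool | None = None
    hi_ratio: float | None = None

    def to_dict(self) -> dict:
        return {"energy_error_norm_pct": self.energy_error_norm_pct,
                "displacement_error_norm_pct": self.displacement_error_norm_pct,
                "per_region_energy_pct": self.per_region_energy_pct,
                "converged": self.converged, "hi_ratio": self.hi_ratio}


def _compliance_table(mesh, materials) -> np.ndarray:
    D = material_table(mesh, materials)
    return np.linalg.inv(D)


def energy_error_norm(mesh: Tet10Mesh, materials: dict[int, MaterialModel],
                      raw: StressField, rec: RecoveredStress,
                      per_region: bool = False):
    """Global ZZ estimate of the relative energy error, in percent."""
    Cinv = _compliance_table(mesh, materials)
    # engineering-shear Voigt compliance: shear entries integrate as
    # 2 * s_ij C^-1 s_ij; C^-1 of the stiffness in this convention already
    # returns engineering shear strain, so s^T C^-1 s is the energy density
    srec = rec.at_gauss()
    diff = srec - raw.values
    w = raw.gauss_weights
    e_den = np.einsum("egi,eij,egj->eg", diff, Cinv, diff)
    u_den = np.einsum("egi,eij,egj->eg", srec, Cinv, srec)
    e2 = float((e_den * w).sum())
    u2 = float((u_den * w).sum())
    if u2 <= 0:
        raise RecoveryError("zero strain energy: nothing is loaded")
    total = 100.0 * np.sqrt(e2 / (u2 + e2))
    if not per_region:
        return total
    per = {}
    for tag in np.unique(mesh.region):
        m = mesh.region == tag
        e2r = float((e_den[m] * w[m]).sum())
        u2r = float((u_den[m] * w[m]).sum())
        per[G.REGION_NAMES[int(tag)]] = 100.0 * np.sqrt(e2r / (u2r + e2r)) \
            if (u2r + e2r) > 0 else 0.0
    return total, per


def interpolate_displacement(u_coarse: DisplacementField,
                             fine_mesh: Tet10Mesh) -> np.ndarray:
    """Evaluate a coarse FE displacement field at the fine-mesh nodes."""
    cm = u_coarse.mesh
    x = cm.nodes[cm.elements[:, :4]]
    origin = x[:, 0]
    T = (x[:, 1:] - x[:, :1]).transpose(0, 2, 1)     # columns = edge vectors
    Tinv = np.linalg.inv(T)
    cent = x.mean(axis=1)
    tree = cKDTree(cent)
    p = fine_mesh.nodes
    k = min(32, len(cent))
    _, cand = tree.query(p, k=k)
    cand = np.atleast_2d(cand)
    d = p[:, None, :] - origin[cand]
    lam123 = np.einsum("pkij,pkj->pki", Tinv[cand], d)
    lam0 = 1.0 - lam123.sum(axis=-1)
    lam = np.concatenate([lam0[..., None], lam123], axis=-1)
    feas = lam.min(axis=-1)
    best = np.argmax(feas, axis=1)
    rows = np.arange(len(p))
    elem = cand[rows, best]
    lam_b = np.clip(lam[rows, best], 0.0, 1.0)
    lam_b /= lam_b.sum(axis=1, keepdims=True)
    N = shape_functions(lam_b)                       # (P, 10)
    return np.einsum("pn,pnc->pc", N, u_coarse.values[cm.elements[elem]])


def displacement_error_norm(u_coarse: DisplacementField,
                            u_fine: DisplacementField) -> float:
    """Relative L2 change between successive refinements, in percent."""
    fm = u_fine.mesh
    if u_coarse.mesh is fm or len(u_coarse.values) == len(u_fine.values):
        du = u_fine.values - u_coarse.values
        proj = None
    else:
        proj = interpolate_displacement(u_coarse, fm)
        du = u_fine.values - proj
    w = np.abs(fm.volumes())
    N = shape_functions(_GP4)
    ue = u_fine.values[fm.elements]
    de = du[fm.elements]
    num = np.einsum("gn,enc->egc", N, de)
    den = np.einsum("gn,enc->egc", N, ue)
    num2 = float(((num ** 2).sum(axis=2) * w[:, None] * 0.25).sum())
    den2 = float(((den ** 2).sum(axis=2) * w[:, None] * 0.25).sum())
    if den2 <= 0:
        raise RecoveryError("zero displacement norm on the fine mesh")
    return 100.0 * np.sqrt(num2 / den2)


# --------------------------------------------------------------------------- #
# convergence walk
# --------------------------------------------------------------------------- #

@dataclass
class ConvergenceResult:
    mesh: Tet10Mesh
    displacement: DisplacementField
    stress: StressField
    report: ErrorReport
    history: list[ErrorReport]
    accepted_index: int


def converge_mesh(sc: G.ScenarioSolid,
                  hi_ratio_schedule=(0.2, 0.1, 0.05),
                  energy_max_pct: float = 5.0,
                  displacement_max_pct: float = 0.5,
                  materials=None, load=None, symmetric: bool = True,
                  recovery_mode: str = "average") -> ConvergenceResult:
    """Walk a decreasing hi/D schedule until both error norms pass.

    Returns the first mesh meeting ``energy <= energy_max_pct`` and
    ``displacement change vs the next refinement <= displacement_max_pct``;
    if none passes, the finest mesh is returned flagged not-converged.
    """
    sched = list(hi_ratio_schedule)
    if any(b >= a for a, b in zip(sched, sched[1:])):
        raise RecoveryError("hi ratio schedule must be strictly decreasing")
    D = sc.implant_spec.D_mm
    solves = []
    history: list[ErrorReport] = []
    base_mesh = None
    for ratio in sched:
        if base_mesh is None:
            size = make_size_field(D, h0_ratio=max(0.1, sched[0]),
                                   hi_ratio=sched[0])
            mesh = mesh_scenario(sc, size, symmetric=symmetric)
        else:
            # successive entries refine the same discrete geometry so the
            # indicators measure pure discretisation error
            mesh = refine_uniform(base_mesh)
        base_mesh = mesh
        system, u, sig = solve_scenario(mesh, materials, load)
        rec = recover_stress(mesh, sig, mode=recovery_mode)
        mats = materials or default_materials()
        een, per = energy_error_norm(mesh, mats, sig, rec, per_region=True)
        history.append(ErrorReport(een, None, per, None, ratio))
        solves.append((mesh, u, sig))
        if len(solves) >= 2:
            k = len(solves) - 2
            dun = displacement_error_norm(solves[k][1], solves[k + 1][1])
            history[k].displacement_error_norm_pct = dun
            ok = (history[k].energy_error_norm_pct <= energy_max_pct
                  and dun <= displacement_max_pct)
            history[k].converged = ok
            if ok:
                mesh, u, sig = solves[k]
                return ConvergenceResult(mesh, u, sig, history[k], history, k)
    last = len(solves) - 1
    if len(solves) == 1:
        history[0].converged = history[0].energy_error_norm_pct <= energy_max_pct
    else:
        history[last].converged = False
    mesh, u, sig = solves[last]
    return ConvergenceResult(mesh, u, sig, history[last], history, last)
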