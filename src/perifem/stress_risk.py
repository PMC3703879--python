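"""Principal-stress measures, the overloading risk index, and control-volume
statistics at the peri-implant bone.

At every bone material point the maximum compressive and maximum tensile
principal stresses are

    sigma_C = min(sigma_1, sigma_2, sigma_3, 0) <= 0
    sigma_T = max(sigma_1, sigma_2, sigma_3, 0) >= 0

and the dimensionless overloading risk index combines them against
tissue-specific admissible levels:

    R = |sigma_C| / sigma_C0 + sigma_T / sigma_T0,

with R > 1 flagging a locally critical state.  Admissible levels default to
ultimate strengths: 115 MPa compression / 180 MPa traction for cortical bone
and 5 MPa for trabecular bone in both signs.

Statistics are taken over a control volume: the bone shell of mean thickness
delta = 0.25 D around the implant surface, split into the cortical part and
three trabecular subregions (crestal / intermediate / apical) of equal length
along the implant axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry as G
from .fem import StressField

OMEGA_NAMES = {1: "cortical", 2: "trab_crest", 3: "trab_mid", 4: "trab_apex"}
MEASURES = ("sigma_vm", "sigma_t", "sigma_c_abs", "risk")


class RiskError(ValueError):
    pass


@dataclass(frozen=True)
class StrengthLimits:
    sigma_T0_MPa: float
    sigma_C0_MPa: float
    tissue: str = ""

    def __post_init__(self):
        if self.sigma_T0_MPa <= 0 or self.sigma_C0_MPa <= 0:
            raise RiskError("admissible stress levels must be positive")


CORTICAL_LIMITS = StrengthLimits(180.0, 115.0, "cortical")
TRABECULAR_LIMITS = StrengthLimits(5.0, 5.0, "trabecular")


def default_strength_limits() -> dict[int, StrengthLimits]:
    return {G.REGION_CORTICAL: CORTICAL_LIMITS,
            G.REGION_TRABECULAR: TRABECULAR_LIMITS}


# --------------------------------------------------------------------------- #
# pointwise measures
# --------------------------------------------------------------------------- #

def principal_stresses(tensor: np.ndarray) -> np.ndarray:
    """Principal stresses of symmetric 3x3 tensors, sorted descending.

    Accepts a single tensor or any (..., 3, 3) stack.
    """
    t = np.asarray(tensor, float)
    if t.shape[-2:] != (3, 3):
        raise RiskError("expected (..., 3, 3) tensors")
    if not np.allclose(t, np.swapaxes(t, -1, -2), atol=1e-8 * max(1.0, float(np.abs(t).max()))):
        raise RiskError("stress tensor is not symmetric")
    ev = np.linalg.eigvalsh(t)          # ascending
    return ev[..., ::-1]


def sigma_C_T(s1, s2, s3) -> tuple[np.ndarray, np.ndarray]:
    """Maximum compressive (clamped <= 0) and tensile (>= 0) principal stress."""
    s = np.stack(np.broadcast_arrays(s1, s2, s3), axis=-1)
    sC = np.minimum(s.min(axis=-1), 0.0)
    sT = np.maximum(s.max(axis=-1), 0.0)
    return sC, sT


def von_mises(tensor: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress of (..., 3, 3) tensors."""
    t = np.asarray(tensor, float)
    s1, s2, s3 = (principal_stresses(t)[..., i] for i in range(3))
    return np.sqrt(0.5 * ((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2))


def von_mises_voigt(v: np.ndarray) -> np.ndarray:
    """Von Mises stress from Voigt components (xx, yy, zz, xy, yz, zx)."""
    xx, yy, zz, xy, yz, zx = (v[..., i] for i in range(6))
    return np.sqrt(0.5 * ((xx - yy) ** 2 + (yy - zz) ** 2 + (zz - xx) ** 2)
                   + 3.0 * (xy ** 2 + yz ** 2 + zx ** 2))


def risk_index(sigma_C, sigma_T, limits: StrengthLimits) -> np.ndarray:
    """Overloading risk index R = |sigma_C|/sigma_C0 + sigma_T/sigma_T0."""
    return (np.abs(sigma_C) / limits.sigma_C0_MPa
            + np.asarray(sigma_T) / limits.sigma_T0_MPa)


# --------------------------------------------------------------------------- #
# control regions
# --------------------------------------------------------------------------- #

def _implant_surface_profile(sc: G.ScenarioSolid) -> np.ndarray:
    """(r, z) polyline of the in-bone metal surface in global coordinates."""
    prof = sc.implant.profile.copy()
    prof[:, 1] += sc.platform_z
    keep = prof[:, 1] <= sc.platform_z + 1e-9
    first = int(np.argmax(keep))
    return prof[max(first - 1, 0):]      # include the segment crossing z_pl


def distance_to_profile(points_rz: np.ndarray, prof: np.ndarray) -> np.ndarray:
    """Exact distance of (rho, z) points to a piecewise-linear profile."""
    p = np.asarray(points_rz, float)[:, None, :]        # (P, 1, 2)
    a = prof[None, :-1, :]
    b = prof[None, 1:, :]
    ab = b - a
    denom = np.einsum("pij,pij->pi", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(np.einsum("pij,pij->pi", p - a, ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    d = np.linalg.norm(p - proj, axis=-1)
    return d.min(axis=1)


@dataclass
class ControlRegions:
    """Per-Gauss-point membership of the peri-implant control volume."""

    delta_mm: float
    membership: np.ndarray        # (E, 4) int8: 0 outside, else OMEGA_NAMES key
    z_splits: tuple[float, float]
    trab_span: tuple[float, float]
    empty_regions: tuple[str, ...] = ()


def build_control_regions(mesh, sc: G.ScenarioSolid, stress: StressField,
                          delta_ratio: float = 0.25) -> ControlRegions:
    """Assign bone Gauss points within delta = delta_ratio * D of the implant
    surface to the cortical region or one of three equal-length trabecular
    subregions along the implant axis."""
    D = sc.implant_spec.D_mm
    delta = delta_ratio * D
    prof = _implant_surface_profile(sc)

    xg = stress.gauss_points.reshape(-1, 3)
    region = np.repeat(mesh.region, stress.gauss_points.shape[1])
    bone = np.isin(region, (G.REGION_CORTICAL, G.REGION_TRABECULAR))
    rz = np.column_stack([np.hypot(xg[:, 0], xg[:, 1]), xg[:, 2]])
    dist = np.full(len(xg), np.inf)
    # cheap prefilter: only points whose bounding-annulus distance can be
    # within delta are measured exactly
    rough = (rz[:, 0] <= prof[:, 0].max() + delta + 0.5) \
        & (rz[:, 1] >= prof[:, 1].min() - delta - 0.5) & bone
    dist[rough] = distance_to_profile(rz[rough], prof)

    member = np.zeros(len(xg), dtype=np.int8)
    inside = bone & (dist <= delta)
    member[inside & (region == G.REGION_CORTICAL)] = 1

    trab = inside & (region == G.REGION_TRABECULAR)
    if trab.any():
        z_hi = float(rz[trab, 1].max())
        z_lo = float(sc.apex_z)
        if z_lo > z_hi:
            z_lo = float(rz[trab, 1].min())
        z1 = z_hi - (z_hi - z_lo) / 3.0
        z2 = z_hi - 2.0 * (z_hi - z_lo) / 3.0
        zt = rz[trab, 1]
        code = np.where(zt >= z1, 2, np.where(zt >= z2, 3, 4))
        member[trab] = code
    else:
        z_hi = z_lo = sc.apex_z
        z1 = z2 = sc.apex_z
    empty = tuple(name for key, name in OMEGA_NAMES.items()
                  if not np.any(member == key))
    return ControlRegions(delta, member.reshape(stress.gauss_points.shape[:2]),
                          (z1, z2), (z_hi, z_lo), empty)


# --------------------------------------------------------------------------- #
# statistics
# --------------------------------------------------------------------------- #

@dataclass
class RegionReport:
    """Mean and peak stress measures per control region.

    Means are volume-weighted over member Gauss points (quadrature weights
    times Jacobians); peaks are extrema over the same points; the risk index
    is evaluated pointwise before aggregation.  sigma_c_abs is the magnitude
    of the most compressive principal stress.
    """

    table: pd.DataFrame
    delta_mm: float
    empty_regions: tuple[str, ...]

    def value(self, region: str, measure: str, statistic: str) -> float:
        row = self.table[(self.table.region == region)
                         & (self.table.measure == measure)]
        if row.empty:
            raise KeyError(f"no entry for {region}/{measure}")
        return float(row.iloc[0][statistic])

    def max_risk(self, regions=("cortical", "trab_crest", "trab_mid",
                                "trab_apex")) -> float:
        t = self.table[(self.table.measure == "risk")
                       & self.table.region.isin(regions)]
        return float(t["peak"].max())

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g",
                          lineterminator="\n")


def region_stats(stress: StressField, regions: ControlRegions,
                 limits: dict[int, StrengthLimits] | None = None,
                 weighting: str = "volume") -> RegionReport:
    if limits is None:
        limits = default_strength_limits()
    if weighting not in ("volume", "plain"):
        raise RiskError("weighting must be 'volume' or 'plain'")
    tens = stress.tensors().reshape(-1, 3, 3)
    w = stress.gauss_weights.reshape(-1)
    if weighting == "plain":
        w = np.ones_like(w)
    member = regions.membership.reshape(-1)

    s = principal_stresses(tens)
    sC, sT = sigma_C_T(s[:, 0], s[:, 1], s[:, 2])
    svm = von_mises_voigt(stress.values.reshape(-1, 6))

    rows = []
    for key, name in OMEGA_NAMES.items():
        m = member == key
        lim = limits[G.REGION_CORTICAL] if key == 1 \
            else limits[G.REGION_TRABECULAR]
        if not m.any():
            for meas in MEASURES:
                rows.append((name, meas, np.nan, np.nan, 0, 0.0))
            continue
        R = risk_index(sC[m], sT[m], lim)
        ww = w[m]
        wsum = ww.sum()
        for meas, vals in (("sigma_vm", svm[m]), ("sigma_t", sT[m]),
                           ("sigma_c_abs", np.abs(sC[m])), ("risk", R)):
            rows.append((name, meas, float((vals * ww).sum() / wsum),
                         float(vals.max()), int(m.sum()), float(wsum)))
    table = pd.DataFrame(rows, columns=["region", "measure", "mean", "peak",
                                        "n_points", "volume"])
    return RegionReport(table, regions.delta_mm, regions.empty_regions)
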