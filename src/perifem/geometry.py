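"""Parametric implant, abutment and bone-segment geometry.

Solids are represented implicitly (vectorised point-membership plus an exact
axisymmetric outer profile polyline) rather than as boundary CAD models: every
downstream consumer -- the mesher, the synthetic CT generator and the control
volume construction -- needs fast point classification and the exact (r, z)
profile, not a BREP.  Units are mm throughout; the implant axis is z (the
intrusive direction), x is buccolingual, y is mesiodistal.  The outer cortical
crest surface lies at z = 0 and bone occupies z < 0.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon


class GeometryError(ValueError):
    """Raised when a geometric specification is inconsistent or infeasible."""


# --------------------------------------------------------------------------- #
# specs
# --------------------------------------------------------------------------- #

class ThreadProfile(str, enum.Enum):
    T0_30 = "T0/30"    # saw-tooth: flanks at 120deg / 90deg from the axis
    T10_30 = "T10/30"  # trapezoid: flanks at 120deg / 100deg from the axis


class Truncation(str, enum.Enum):
    ST = "ST"  # same truncation on both starts
    DT = "DT"  # different truncation: 0.38 mm and 0.19 mm starts


class MillingKind(str, enum.Enum):
    NONE = "none"
    SM = "SM"
    LM = "LM"


@dataclass(frozen=True)
class ThreadSpec:
    """Two-start thread pattern of the implant body.

    Angles are measured from the implant axis, so 120 deg means a flank tilted
    30 deg from the horizontal plane; the saw-tooth lower flank at 90 deg is a
    flat annular face.  ``free_thickness_mm`` is the axial gap between
    successive fin roots at the internal (core) diameter.
    """

    profile_kind: ThreadProfile = ThreadProfile.T10_30
    truncation: Truncation = Truncation.DT
    upper_flank_angle_deg: float = 120.0
    lower_flank_angle_deg: float = 100.0   # 90.0 for the saw-tooth kind
    free_thickness_mm: float = 0.25        # 0.33 for T0/30
    n_starts: int = 2
    effective_pitch_mm: float = 1.2
    depth_primary_mm: float = 0.38
    depth_secondary_mm: float = 0.19       # equals primary for ST

    def __post_init__(self):
        if self.n_starts != 2:
            raise GeometryError("thread pattern is defined for two starts")
        if self.effective_pitch_mm <= 0:
            raise GeometryError("effective pitch must be positive")
        if not (0 <= self.depth_secondary_mm <= self.depth_primary_mm):
            raise GeometryError("0 <= depth_secondary <= depth_primary violated")
        if self.truncation is Truncation.ST and \
                self.depth_secondary_mm != self.depth_primary_mm:
            raise GeometryError("ST requires equal depths on both starts")

    @property
    def fin_spacing_mm(self) -> float:
        """Axial distance between successive fin roots (alternating starts)."""
        return self.effective_pitch_mm / self.n_starts

    def flank_extents(self, depth: float) -> tuple[float, float]:
        """Axial extents (upper, lower) of the two flanks for a fin of ``depth``."""
        au = depth * np.tan(np.radians(self.upper_flank_angle_deg - 90.0))
        al = depth * np.tan(np.radians(self.lower_flank_angle_deg - 90.0))
        return float(au), float(al)


def thread_T0_30(truncation: Truncation = Truncation.DT) -> ThreadSpec:
    d2 = 0.38 if truncation is Truncation.ST else 0.19
    return ThreadSpec(ThreadProfile.T0_30, truncation,
                      lower_flank_angle_deg=90.0, free_thickness_mm=0.33,
                      depth_secondary_mm=d2)


def thread_T10_30(truncation: Truncation = Truncation.DT) -> ThreadSpec:
    d2 = 0.38 if truncation is Truncation.ST else 0.19
    return ThreadSpec(ThreadProfile.T10_30, truncation,
                      lower_flank_angle_deg=100.0, free_thickness_mm=0.25,
                      depth_secondary_mm=d2)


@dataclass(frozen=True)
class MillingSpec:
    """Helical milling groove; pitch equals the implant threaded length."""

    kind: MillingKind = MillingKind.NONE
    width_mm: float = 0.0
    depth_mm: float = 0.0

    def __post_init__(self):
        if self.kind is MillingKind.NONE and (self.width_mm or self.depth_mm):
            raise GeometryError("milling 'none' must have zero dimensions")

    @staticmethod
    def small() -> "MillingSpec":
        return MillingSpec(MillingKind.SM, 0.3, 0.15)

    @staticmethod
    def large() -> "MillingSpec":
        return MillingSpec(MillingKind.LM, 0.6, 0.30)


@dataclass(frozen=True)
class ImplantSpec:
    label: str
    D_mm: float
    L_mm: float
    thread: ThreadSpec
    milling: MillingSpec = field(default_factory=MillingSpec)
    has_lead_in_bevel: bool = True
    abutment_connection_ratio: float = 0.75   # connection diameter / D
    load_height_mm: float = 7.0               # load point above bone surface
    bevel_ledge_mm: float = 0.3
    neck_len_mm: float = 0.15                 # plain collar below the bevel
    apex_chamfer_mm: float = 0.3

    def __post_init__(self):
        if not (3.0 <= self.D_mm <= 6.0):
            raise GeometryError(f"implant diameter {self.D_mm} outside [3, 6] mm")
        if not (4.0 <= self.L_mm <= 14.0):
            raise GeometryError(f"implant length {self.L_mm} outside [4, 14] mm")
        if self.abutment_connection_ratio >= 1.0:
            raise GeometryError("platform switching requires connection < D")
        if self.thread.depth_primary_mm >= self.D_mm / 2:
            raise GeometryError("thread depth exceeds implant radius")

    @property
    def abutment_connection_diameter_mm(self) -> float:
        return self.abutment_connection_ratio * self.D_mm

    @property
    def core_radius_mm(self) -> float:
        return self.D_mm / 2 - self.thread.depth_primary_mm


class CrossSectionKind(str, enum.Enum):
    ROUNDED_TRAPEZOID = "rounded_trapezoid"


@dataclass(frozen=True)
class BoneSegmentSpec:
    """Idealised premolar bone segment: prism along y of a rounded trapezoid."""

    mesiodistal_length_mm: float = 40.0
    cortical_thickness_mm: float = 2.0
    crest_width_mm: float = 16.0
    crest_height_mm: float = 16.0
    base_width_mm: float = 14.0
    corner_radius_mm: float = 1.5
    cross_section_kind: CrossSectionKind = CrossSectionKind.ROUNDED_TRAPEZOID

    def __post_init__(self):
        if self.cortical_thickness_mm <= 0:
            raise GeometryError("cortical thickness must be positive")
        if self.cortical_thickness_mm >= min(self.crest_width_mm,
                                             self.base_width_mm) / 2:
            raise GeometryError("cortical shell would swallow the trabecular core")


class PlacementDepth(str, enum.Enum):
    P0 = "P0"
    P05 = "P05"
    P1 = "P1"


_DEPTH_MM = {PlacementDepth.P0: 0.0, PlacementDepth.P05: 0.5, PlacementDepth.P1: 1.0}


@dataclass(frozen=True)
class PlacementSpec:
    depth_code: PlacementDepth = PlacementDepth.P1
    depth_mm: float = 1.0

    def __post_init__(self):
        if abs(self.depth_mm - _DEPTH_MM[self.depth_code]) > 1e-12:
            raise GeometryError(
                f"placement {self.depth_code.value} requires depth "
                f"{_DEPTH_MM[self.depth_code]} mm, got {self.depth_mm}")

    @staticmethod
    def from_code(code: PlacementDepth | str) -> "PlacementSpec":
        code = PlacementDepth(code)
        return PlacementSpec(code, _DEPTH_MM[code])


class MorphologyKind(str, enum.Enum):
    PRISTINE = "pristine"
    APPOSITION = "apposition"
    BONE_LOSS = "bone_loss"


@dataclass(frozen=True)
class CrestalMorphology:
    kind: MorphologyKind = MorphologyKind.APPOSITION
    apposition_thickness_mm: float = 0.25
    bone_loss_fraction: float = 0.0
    crater_wall_angle_deg: float = 45.0

    def __post_init__(self):
        if not (0.0 <= self.bone_loss_fraction <= 0.5):
            raise GeometryError("bone loss fraction outside [0, 0.5]")
        if self.kind is MorphologyKind.BONE_LOSS and self.bone_loss_fraction == 0:
            # 0% loss is the pristine crest; keep the distinction explicit
            object.__setattr__(self, "kind", MorphologyKind.PRISTINE)

    @staticmethod
    def for_placement(placement: PlacementSpec,
                      bone_loss_fraction: float = 0.10) -> "CrestalMorphology":
        """Study-default morphology: apposition subcrestally, cratering at P0."""
        if placement.depth_code is PlacementDepth.P0:
            return CrestalMorphology(MorphologyKind.BONE_LOSS,
                                     bone_loss_fraction=bone_loss_fraction)
        return CrestalMorphology(MorphologyKind.APPOSITION)


# --------------------------------------------------------------------------- #
# implant profile and solid
# --------------------------------------------------------------------------- #

def dome_height(spec: ImplantSpec) -> float:
    """Axial height of the rounded apex dome."""
    return max(spec.apex_chamfer_mm, 0.7 * spec.core_radius_mm)


def implant_profile(spec: ImplantSpec) -> np.ndarray:
    """Outer (r, z) profile polyline of implant + abutment, implant frame.

    The platform plane is z = 0; the threaded body occupies z in [-L, 0]; the
    abutment extends upward.  Returned as an (n, 2) array ordered from the
    abutment top down to the apex centre (r = 0), with z non-increasing.
    """
    t = spec.thread
    R = spec.D_mm / 2
    r_core = spec.core_radius_mm
    r_ab = spec.abutment_connection_diameter_mm / 2
    bev = spec.bevel_ledge_mm if spec.has_lead_in_bevel else 0.0
    L = spec.L_mm

    pts: list[tuple[float, float]] = []
    # abutment top is placement-dependent; use a generous stub here (the
    # scenario clips it at the load plane)
    z_ab_top = spec.load_height_mm + 2.0
    pts += [(0.0, z_ab_top), (r_ab, z_ab_top), (r_ab, 0.0)]
    # platform ledge and lead-in bevel
    if bev > 0:
        pts += [(R - bev, 0.0), (R, -bev)]
    else:
        pts += [(R, 0.0)]
    z_neck_end = -(bev + spec.neck_len_mm)
    pts += [(R, z_neck_end)]
    # taper from the collar down to the thread core diameter
    lead = (R - r_core) * np.tan(np.radians(30.0))
    z = z_neck_end - lead
    pts += [(r_core, z)]

    # Thread band: circumferential fins protruding from the core, one per
    # start, alternating along the axis at fin_spacing.  The primary start
    # always reaches full depth (crest at the outer diameter); under DT the
    # secondary start's fin is truncated at half depth.  The fin root axial
    # width is the start spacing minus the free thickness at the internal
    # diameter; flanks follow the thread form's flank angles and the crest
    # is the truncation flat.
    spacing = t.fin_spacing_mm
    depths = [t.depth_primary_mm, t.depth_secondary_mm]
    z_stop = -L + dome_height(spec) + 0.1
    w_root = spacing - t.free_thickness_mm
    k = 0
    while True:
        d = depths[k % 2]
        au, al = t.flank_extents(d)
        crest = w_root - au - al
        if crest <= 0:
            raise GeometryError(
                "thread profile self-intersects: flank extents "
                f"{au + al:.3f} mm exceed the fin root width {w_root:.3f} mm")
        if z - spacing < z_stop:
            break
        if d > 0:
            pts += [(r_core, z),
                    (r_core + d, z - au),
                    (r_core + d, z - au - crest),
                    (r_core, z - w_root)]
        z -= spacing
        k += 1
    # rounded (dome) apex: quarter-ellipse from the core radius to the tip
    dome_h = dome_height(spec)
    pts += [(r_core, -L + dome_h)]
    for phi in np.linspace(0.25, 1.0, 4) * (np.pi / 2):
        pts += [(r_core * np.cos(phi), -L + dome_h * (1 - np.sin(phi)))]

    prof = np.asarray(pts, float)
    assert np.all(np.diff(prof[:, 1]) <= 1e-12), "profile z must be non-increasing"
    return prof


def profile_radius(prof: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Outer radius of the surface of revolution at heights ``z``.

    At a horizontal step (two profile points sharing one z) the larger radius
    is taken, which is the correct convention for membership tests.
    """
    z = np.asarray(z, float)
    zs = prof[::-1, 1].copy()          # ascending
    rs = prof[::-1, 0].copy()
    # nudge exact duplicates so interp keeps both branches; max-r at the tie
    eps = 1e-9
    for i in range(1, len(zs)):
        if zs[i] <= zs[i - 1]:
            zs[i] = zs[i - 1] + eps
    r = np.interp(z, zs, rs, left=0.0, right=0.0)
    return r


@dataclass
class ImplantSolid:
    """Implicit solid of revolution for one implant + abutment."""

    spec: ImplantSpec
    profile: np.ndarray          # (n, 2) r, z in the implant frame
    thread_mode: str = "annular_rings"

    def radius_at(self, z: np.ndarray, theta: np.ndarray | None = None) -> np.ndarray:
        r = profile_radius(self.profile, z)
        if self.thread_mode == "helical" and theta is not None:
            # two-start helix: shift the fin pattern axially with theta; both
            # starts advance together (equal phase offset between starts).
            # Only the fin band is shifted; collar and apex stay axisymmetric.
            t = self.spec.thread
            z = np.asarray(z, float)
            shift = np.mod((np.asarray(theta) / (2 * np.pi))
                           * t.effective_pitch_mm, t.fin_spacing_mm)
            r_shifted = profile_radius(self.profile, z + shift)
            in_band = (z < -1.0) & (z > -self.spec.L_mm + 0.8)
            r = np.where(in_band, r_shifted, r)
        return r

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        rho = np.hypot(pts[:, 0], pts[:, 1])
        theta = np.arctan2(pts[:, 1], pts[:, 0])
        rsurf = self.radius_at(pts[:, 2], theta)
        inside = rho <= rsurf
        m = self.spec.milling
        if m.kind is not MillingKind.NONE:
            inside &= ~self._in_milling(rho, theta, pts[:, 2], rsurf)
        return inside

    def _in_milling(self, rho, theta, z, rsurf) -> np.ndarray:
        """Single helical groove over the threaded length, one full turn."""
        m, L = self.spec.milling, self.spec.L_mm
        frac = np.mod(theta, 2 * np.pi) / (2 * np.pi)
        z_groove = -frac * L
        dz = np.abs(np.mod(z - z_groove + L / 2, L) - L / 2)
        in_band = (z < 0) & (z > -L) & (dz < m.width_mm / 2)
        return in_band & (rho > rsurf - m.depth_mm)

    def volume(self) -> float:
        """Exact volume of the solid of revolution minus the milling groove."""
        v = _revolved_volume(self.profile)
        m = self.spec.milling
        if m.kind is not MillingKind.NONE:
            r_mean = self.spec.D_mm / 2 - m.depth_mm / 2
            helix_len = float(np.hypot(2 * np.pi * r_mean, self.spec.L_mm))
            v -= helix_len * m.width_mm * m.depth_mm
        return v

    def body_volume(self) -> float:
        """Volume of the in-bone part only (z <= platform plane).

        The milling groove, when present, lies entirely below the platform, so
        its volume is removed here in full.
        """
        prof = self.profile[self.profile[:, 1] <= 1e-12]
        groove = _revolved_volume(self.profile) - self.volume()
        return _revolved_volume(prof) - groove


def _revolved_volume(prof: np.ndarray) -> float:
    """pi * integral r(z)^2 dz over a piecewise-linear (r, z) profile."""
    r, z = prof[:, 0], prof[:, 1]
    dz = z[:-1] - z[1:]
    r0, r1 = r[:-1], r[1:]
    return float(np.pi * np.sum(dz * (r0 * r0 + r0 * r1 + r1 * r1) / 3.0))


def build_implant_solid(spec: ImplantSpec,
                        thread_mode: str = "annular_rings") -> ImplantSolid:
    if thread_mode not in ("annular_rings", "helical"):
        raise ValueError(f"unknown thread mode {thread_mode!r}")
    return ImplantSolid(spec, implant_profile(spec), thread_mode)


# --------------------------------------------------------------------------- #
# bone segment
# --------------------------------------------------------------------------- #

def _section_polygon(spec: BoneSegmentSpec) -> Polygon:
    w0, w1, h = spec.crest_width_mm, spec.base_width_mm, spec.crest_height_mm
    poly = Polygon([(-w0 / 2, 0.0), (w0 / 2, 0.0),
                    (w1 / 2, -h), (-w1 / 2, -h)])
    r = spec.corner_radius_mm
    if r > 0:
        # round the lower corners; keep the crest line exactly at z = 0
        poly = poly.buffer(-r, join_style="mitre").buffer(r, join_style="round",
                                                          quad_segs=16)
        poly = poly.intersection(
            Polygon([(-w0, 0.0), (w0, 0.0), (w0, -2 * h), (-w0, -2 * h)]))
    return poly


@dataclass
class BoneSolid:
    """Prismatic bone region: a cross-section polygon extruded along y."""

    spec: BoneSegmentSpec
    section: Polygon             # (x, z) polygon of this region
    name: str

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        half = self.spec.mesiodistal_length_mm / 2
        in_y = np.abs(pts[:, 1]) <= half
        in_xz = shapely.contains_xy(self.section, pts[:, 0], pts[:, 2])
        return in_y & in_xz

    def volume(self) -> float:
        return self.section.area * self.spec.mesiodistal_length_mm


def build_bone_segment(spec: BoneSegmentSpec) -> tuple[BoneSolid, BoneSolid]:
    """Cortical shell and trabecular core as a conforming solid pair."""
    outer = _section_polygon(spec)
    inner = outer.buffer(-spec.cortical_thickness_mm, join_style="round",
                         quad_segs=16)
    if inner.is_empty or inner.area <= 0:
        raise GeometryError("cortical thickness leaves no trabecular core")
    shell = outer.difference(inner)
    return (BoneSolid(spec, shell, "cortical"),
            BoneSolid(spec, inner, "trabecular"))


# --------------------------------------------------------------------------- #
# scenario composition
# --------------------------------------------------------------------------- #

REGION_OUTSIDE, REGION_IMPLANT, REGION_ABUTMENT = 0, 1, 2
REGION_CORTICAL, REGION_TRABECULAR = 3, 4
REGION_NAMES = {REGION_OUTSIDE: "outside", REGION_IMPLANT: "implant",
                REGION_ABUTMENT: "abutment", REGION_CORTICAL: "cortical",
                REGION_TRABECULAR: "trabecular"}


@dataclass
class ScenarioSolid:
    """Placed, morphology-adjusted bone-implant assembly (implicit CSG).

    The implant frame is shifted so its platform plane sits ``depth_mm`` below
    the outer bone surface z = 0; the abutment is clipped at the load plane
    ``z = load_height_mm``.
    """

    implant_spec: ImplantSpec
    bone_spec: BoneSegmentSpec
    placement: PlacementSpec
    morphology: CrestalMorphology
    implant: ImplantSolid
    cortical: BoneSolid
    trabecular: BoneSolid
    # transmucosal seam: apposed crestal bone bonds to the horizontal
    # platform ledge but not to the abutment wall; a thin free gap separates
    # bone from the abutment above the platform plane
    abutment_gap_mm: float = 0.1

    # -- frames -------------------------------------------------------------
    @property
    def platform_z(self) -> float:
        return -self.placement.depth_mm

    @property
    def apex_z(self) -> float:
        return self.platform_z - self.implant_spec.L_mm

    @property
    def load_z(self) -> float:
        return self.implant_spec.load_height_mm

    @property
    def abutment_radius(self) -> float:
        return self.implant_spec.abutment_connection_diameter_mm / 2

    def inner_radius(self, z: np.ndarray) -> np.ndarray:
        """Outer radius of the metal (implant+abutment) at global height z."""
        z = np.asarray(z, float)
        r = profile_radius(self.implant.profile, z - self.platform_z)
        return np.where(z > self.load_z, 0.0, r)

    # -- morphology top surface ---------------------------------------------
    def top_surface(self, rho: np.ndarray) -> np.ndarray:
        """Bone top surface height near the implant vs distance from the axis.

        Far from the implant this is the pristine crest z = 0; subcrestal
        placements carry an apposition collar over the platform ledge and a
        conical rise back to the crest; crestal placement with bone loss digs
        a conical crater of depth ``bone_loss_fraction * cortical thickness``.
        """
        rho = np.asarray(rho, float)
        slope = np.tan(np.radians(self.morphology.crater_wall_angle_deg))
        R = self.implant_spec.D_mm / 2
        if self.morphology.kind is MorphologyKind.APPOSITION:
            z_col = self.platform_z + self.morphology.apposition_thickness_mm
            z = np.minimum(0.0, z_col + np.maximum(0.0, rho - R) * slope)
            return z
        if self.morphology.kind is MorphologyKind.BONE_LOSS:
            depth = (self.morphology.bone_loss_fraction
                     * self.bone_spec.cortical_thickness_mm)
            z = np.minimum(0.0, -depth + np.maximum(0.0, rho - R) * slope)
            return z
        return np.zeros_like(rho)

    # -- classification ------------------------------------------------------
    def region_of(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        out = np.full(len(pts), REGION_OUTSIDE, dtype=np.int8)
        local = pts.copy()
        local[:, 2] -= self.platform_z
        metal = self.implant.contains(local) & (pts[:, 2] <= self.load_z)
        out[metal & (local[:, 2] > 0)] = REGION_ABUTMENT
        out[metal & (local[:, 2] <= 0)] = REGION_IMPLANT

        rho = np.hypot(pts[:, 0], pts[:, 1])
        ztop = self.top_surface(rho)
        bone = (~metal) & (pts[:, 2] <= ztop + 1e-12)
        bone &= self.cortical.contains(pts) | self.trabecular.contains(pts)
        # no osseous bond on the abutment wall above the platform
        bone &= ~((pts[:, 2] > self.platform_z)
                  & (rho < self.abutment_radius + self.abutment_gap_mm))
        # the cortical shell is anatomically fixed (the pristine shell):
        # cratering carves into it and thins it, apposition adds to it
        shellish = self.cortical.contains(pts)
        out[bone & shellish] = REGION_CORTICAL
        out[bone & ~shellish] = REGION_TRABECULAR
        return out


def apply_placement_and_morphology(bone: tuple[BoneSolid, BoneSolid],
                                   implant: ImplantSolid,
                                   placement: PlacementSpec,
                                   morph: CrestalMorphology) -> ScenarioSolid:
    cortical, trabecular = bone
    spec = implant.spec
    bspec = cortical.spec
    apex = -placement.depth_mm - spec.L_mm
    if apex < -(bspec.crest_height_mm - bspec.cortical_thickness_mm):
        raise GeometryError(
            f"implant apex at z={apex:.1f} exits the cortical floor of the "
            f"{bspec.crest_height_mm:.1f} mm segment")
    if morph.kind is MorphologyKind.APPOSITION and \
            placement.depth_code is PlacementDepth.P0:
        raise GeometryError("apposition collar requires a subcrestal placement")
    if morph.kind is MorphologyKind.BONE_LOSS and \
            placement.depth_code is not PlacementDepth.P0:
        raise GeometryError("cratering morphology is defined for P0 placement")
    if 4 * spec.D_mm > bspec.mesiodistal_length_mm / 2:
        raise GeometryError("bone segment too short for far-field boundaries")
    return ScenarioSolid(spec, bspec, placement, morph, implant,
                         cortical, trabecular)


def build_scenario(implant_spec: ImplantSpec,
                   placement: PlacementSpec | str = "P1",
                   morphology: CrestalMorphology | None = None,
                   bone_spec: BoneSegmentSpec | None = None,
                   thread_mode: str = "annular_rings") -> ScenarioSolid:
    """One-call composition of the full scenario geometry."""
    if isinstance(placement, str):
        placement = PlacementSpec.from_code(placement)
    if morphology is None:
        morphology = CrestalMorphology.for_placement(placement)
    bone_spec = bone_spec or BoneSegmentSpec()
    return apply_placement_and_morphology(
        build_bone_segment(bone_spec),
        build_implant_solid(implant_spec, thread_mode),
        placement, morphology)


# --------------------------------------------------------------------------- #
# catalogue
# --------------------------------------------------------------------------- #

def implant_catalogue() -> dict[str, ImplantSpec]:
    """The eleven implants of the comparative study.

    Labels 1-10 are the parametric platform-switched designs (D, L, thread
    shape, truncation and milling per the notation D{d}-L{l}-T../30-{ST,DT}-
    {SM,LM}); label "A" is a D3.5/L11 stand-in for the commercial reference
    implant, modelled with a trapezoid thread, no milling and no bevel.
    """
    SM, LM = MillingSpec.small(), MillingSpec.large()
    ST, DT = Truncation.ST, Truncation.DT
    cat = {
        "1": ImplantSpec("1", 3.6, 5.5, thread_T0_30(DT), SM),
        "2": ImplantSpec("2", 3.6, 5.5, thread_T10_30(DT), SM),
        "3": ImplantSpec("3", 4.3, 5.5, thread_T10_30(DT), SM),
        "4": ImplantSpec("4", 4.3, 9.0, thread_T10_30(DT), SM),
        "5": ImplantSpec("5", 4.3, 9.0, thread_T10_30(DT), LM),
        "6": ImplantSpec("6", 4.3, 9.0, thread_T10_30(ST), LM),
        "7": ImplantSpec("7", 3.6, 9.0, thread_T0_30(DT), SM),
        "8": ImplantSpec("8", 3.6, 9.0, thread_T10_30(DT), SM),
        "9": ImplantSpec("9", 3.6, 9.0, thread_T10_30(DT), LM),
        "10": ImplantSpec("10", 3.6, 9.0, thread_T10_30(ST), LM),
        "A": ImplantSpec("A", 3.5, 11.0, thread_T10_30(ST),
                         MillingSpec(), has_lead_in_bevel=False),
    }
    return cat


# --------------------------------------------------------------------------- #
# scenario spec serialization
# --------------------------------------------------------------------------- #

def _enum_to_str(obj):
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, dict):
        return {k: _enum_to_str(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_enum_to_str(v) for v in obj]
    return obj


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete serialisable description of one FE run."""

    implant: ImplantSpec
    placement: PlacementSpec
    morphology: CrestalMorphology
    bone: BoneSegmentSpec = field(default_factory=BoneSegmentSpec)
    thread_mode: str = "annular_rings"

    def to_dict(self) -> dict:
        return _enum_to_str({
            "implant": asdict(self.implant),
            "placement": asdict(self.placement),
            "morphology": asdict(self.morphology),
            "bone": asdict(self.bone),
            "thread_mode": self.thread_mode,
        })

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @staticmethod
    def from_dict(d: dict) -> "ScenarioSpec":
        imp = dict(d["implant"])
        th = dict(imp.pop("thread"))
        th["profile_kind"] = ThreadProfile(th["profile_kind"])
        th["truncation"] = Truncation(th["truncation"])
        mill = dict(imp.pop("milling"))
        mill["kind"] = MillingKind(mill["kind"])
        imp["thread"] = ThreadSpec(**th)
        imp["milling"] = MillingSpec(**mill)
        pl = dict(d["placement"])
        pl["depth_code"] = PlacementDepth(pl["depth_code"])
        mo = dict(d["morphology"])
        mo["kind"] = MorphologyKind(mo["kind"])
        bo = dict(d["bone"])
        bo["cross_section_kind"] = CrossSectionKind(bo["cross_section_kind"])
        return ScenarioSpec(ImplantSpec(**imp), PlacementSpec(**pl),
                            CrestalMorphology(**mo), BoneSegmentSpec(**bo),
                            d.get("thread_mode", "annular_rings"))

    @staticmethod
    def from_yaml(text: str) -> "ScenarioSpec":
        return ScenarioSpec.from_dict(yaml.safe_load(io.StringIO(text)))

    def build(self) -> ScenarioSolid:
        return build_scenario(self.implant, self.placement, self.morphology,
                              self.bone, self.thread_mode)

    def mechanical_signature(self) -> str:
        """Key identifying mechanically distinct models.

        The milling groove is carried by the solid model but not by the
        axisymmetric FE mesh, so two specs differing only in milling map to
        the same signature.
        """
        imp = replace(self.implant, milling=MillingSpec(), label="-")
        return yaml.safe_dump(_enum_to_str({
            "implant": asdict(imp), "placement": asdict(self.placement),
            "morphology": asdict(self.morphology), "bone": asdict(self.bone),
        }), sort_keys=True)
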