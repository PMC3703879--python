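"""Synthetic Hounsfield-unit volumes and threshold segmentation.

A stand-in for a multislice-CT pipeline: the bone-segment cross-section is
rasterised into a voxel volume with class-mean attenuation values (soft
tissue ~0 HU, trabecular ~400 HU, cortical ~1200 HU) plus Gaussian noise,
and segmented back into tissue classes with the standard thresholds:
soft <= 150 HU < trabecular <= 750 HU < cortical.  Only the thresholds are
anatomically calibrated constants; the class means are generator choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import BoneSegmentSpec, build_bone_segment

SOFT, TRABECULAR, CORTICAL = 0, 1, 2
LABEL_NAMES = {SOFT: "soft", TRABECULAR: "trabecular", CORTICAL: "cortical"}

SOFT_MAX_HU = 150.0
TRABECULAR_MAX_HU = 750.0


@dataclass
class HUVolume:
    voxels: np.ndarray                   # (nx, ny, nz) HU
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")

    def to_nifti(self, path: str) -> None:
        import nibabel as nib
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), aff), path)


@dataclass
class TissueLabelVolume:
    labels: np.ndarray                   # int8 over {SOFT, TRABECULAR, CORTICAL}
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    thresholds: dict = field(default_factory=lambda: {
        "soft_max": SOFT_MAX_HU, "trabecular_max": TRABECULAR_MAX_HU})

    def fraction(self, label: int) -> float:
        return float(np.mean(self.labels == label))


def _class_masks(bone: BoneSegmentSpec, vol_shape, spacing, origin):
    """Voxel-centre masks of the cortical shell and trabecular core."""
    import shapely
    cortical, trabecular = build_bone_segment(bone)
    nx, ny, nz = vol_shape
    x = origin[0] + spacing[0] * np.arange(nx)
    y = origin[1] + spacing[1] * np.arange(ny)
    z = origin[2] + spacing[2] * np.arange(nz)
    X, Z = np.meshgrid(x, z, indexing="ij")
    in_cort2d = shapely.contains_xy(cortical.section, X.ravel(), Z.ravel())
    in_trab2d = shapely.contains_xy(trabecular.section, X.ravel(), Z.ravel())
    in_cort2d = in_cort2d.reshape(nx, nz)
    in_trab2d = in_trab2d.reshape(nx, nz)
    in_y = np.abs(y) <= bone.mesiodistal_length_mm / 2
    cort = in_cort2d[:, None, :] & in_y[None, :, None]
    trab = in_trab2d[:, None, :] & in_y[None, :, None]
    return cort, trab


def generate_hu_volume(bone: BoneSegmentSpec | None = None,
                       noise_sd: float = 50.0, seed: int = 0,
                       spacing_mm: float | tuple = 0.5,
                       margin_mm: float = 2.0,
                       means_hu=(0.0, 400.0, 1200.0)) -> HUVolume:
    """Rasterise the bone segment into a noisy three-class HU volume.

    Deterministic for a given seed; ``means_hu`` are the class means for
    (exterior soft tissue, trabecular core, cortical shell).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    bone = bone or BoneSegmentSpec()
    if np.isscalar(spacing_mm):
        spacing = (float(spacing_mm),) * 3
    else:
        spacing = tuple(float(s) for s in spacing_mm)
    if max(spacing) > bone.cortical_thickness_mm:
        warnings.warn("voxel spacing exceeds the cortical thickness; the "
                      "shell may alias", stacklevel=2)
    hx = bone.crest_width_mm / 2 + margin_mm
    hy = bone.mesiodistal_length_mm / 2 + margin_mm
    z0, z1 = -bone.crest_height_mm - margin_mm, margin_mm
    origin = (-hx, -hy, z0)
    shape = (int(np.ceil(2 * hx / spacing[0])),
             int(np.ceil(2 * hy / spacing[1])),
             int(np.ceil((z1 - z0) / spacing[2])))
    cort, trab = _class_masks(bone, shape, spacing, origin)
    vox = np.full(shape, means_hu[0])
    vox[trab] = means_hu[1]
    vox[cort] = means_hu[2]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vox = vox + rng.normal(0.0, noise_sd, size=shape)
    return HUVolume(vox, spacing, origin)


def segment_hu(vol: HUVolume, soft_max: float = SOFT_MAX_HU,
               trabecular_max: float = TRABECULAR_MAX_HU) -> TissueLabelVolume:
    """Threshold segmentation: soft iff HU <= soft_max, trabecular iff
    soft_max < HU <= trabecular_max, cortical iff HU > trabecular_max."""
    if soft_max >= trabecular_max:
        raise ValueError("soft_max must be below trabecular_max")
    labels = np.full(vol.voxels.shape, SOFT, dtype=np.int8)
    labels[vol.voxels > soft_max] = TRABECULAR
    labels[vol.voxels > trabecular_max] = CORTICAL
    return TissueLabelVolume(labels, vol.spacing_mm, vol.origin_mm,
                             {"soft_max": soft_max,
                              "trabecular_max": trabecular_max})


def analytic_volume_fractions(bone: BoneSegmentSpec, vol: HUVolume) -> dict:
    """Exact tissue volume fractions of the bounding box, from the solids."""
    cortical, trabecular = build_bone_segment(bone)
    nx, ny, nz = vol.voxels.shape
    box = nx * vol.spacing_mm[0] * ny * vol.spacing_mm[1] * nz * vol.spacing_mm[2]
    return {"cortical": cortical.volume() / box,
            "trabecular": trabecular.volume() / box}
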