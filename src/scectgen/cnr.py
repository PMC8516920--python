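"""Lesion contrast-to-noise ratio (CNR) evaluation.

For each annotated node, a circular ROI of 90% of its short-axis diameter is
drawn on the slice where the diameter was measured; same-size ROIs go in the
descending thoracic aorta (DTA) and the subcutaneous fat of both chest
walls, and all ROIs are copied verbatim across modalities.  Then

    background noise = sqrt((SD_right_fat^2 + SD_left_fat^2) / 2)
    CNR_lesion      = |HU_DTA - HU_lesion| / background noise

so CNR is invariant to global HU shifts and scales inversely with noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from . import phantom as ph
from .phantom import LesionAnnotation, PhantomPair
from .volume import CTVolume


@dataclass(frozen=True)
class ROISpec:
    """A circular ROI on one axial slice: center (x, y, slice), diameter in voxels."""

    center: tuple[int, int, int]
    diameter: float
    role: str  # 'lesion' | 'dta' | 'right_fat' | 'left_fat'

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be > 0")


@dataclass
class CNRMeasurement:
    lesion_id: int
    modality: str  # 'ncct' | 'scect' | 'cect'
    hu_lesion: float
    hu_dta: float
    sd_right_fat: float
    sd_left_fat: float
    background_noise: float
    cnr: float  # nan when background noise is zero
    error: str | None = None


def circular_roi_mask(shape: tuple[int, int], center: tuple[float, float],
                      diameter: float) -> np.ndarray:
    """Boolean in-plane disk: voxels whose center lies within diameter/2.

    The circle must lie fully inside the image.
    """
    cx, cy = center
    r = diameter / 2.0
    if cx - r < -0.5 or cy - r < -0.5 or cx + r > shape[0] - 0.5 or cy + r > shape[1] - 0.5:
        raise ValueError(
            f"ROI (center {center}, diameter {diameter}) extends outside {shape}")
    xx, yy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def lesion_roi_from_annotation(
    annotation: LesionAnnotation, in_plane_spacing_mm: float
) -> ROISpec:
    """ROI measuring 90% of the short-axis diameter, at the measuring slice.

    The millimeter diameter converts to voxels by the in-plane spacing,
    rounded half-up, with a floor of one voxel.
    """
    d_vox = math.floor(0.9 * annotation.short_axis_diameter_mm / in_plane_spacing_mm + 0.5)
    return ROISpec(center=annotation.center, diameter=max(d_vox, 1.0), role="lesion")


def background_noise(sd_right: float, sd_left: float) -> float:
    """Root mean square of the two fat-ROI standard deviations."""
    if sd_right < 0 or sd_left < 0:
        raise ValueError("standard deviations must be >= 0")
    return math.sqrt((sd_right**2 + sd_left**2) / 2.0)


def lesion_cnr(hu_dta: float, hu_lesion: float, noise: float) -> float:
    """|HU_DTA - HU_lesion| / background noise; undefined for zero noise."""
    if noise <= 0:
        raise ZeroDivisionError(
            "background noise is zero; CNR is undefined (noiseless fat ROIs)")
    return abs(hu_dta - hu_lesion) / noise


def _roi_stats(volume: CTVolume, roi: ROISpec) -> tuple[float, float]:
    x, y, z = roi.center
    mask = circular_roi_mask(volume.shape[:2], (x, y), roi.diameter)
    values = volume.hu[:, :, z][mask]
    return float(values.mean()), float(values.std())


def _largest_inscribed_center(mask2d: np.ndarray) -> tuple[int, int, float]:
    """Center and diameter (voxels) of the largest inscribed circle of a mask."""
    if not mask2d.any():
        raise ValueError("empty mask; cannot place an ROI")
    dist = distance_transform_edt(mask2d)
    idx = np.unravel_index(np.argmax(dist), dist.shape)
    return int(idx[0]), int(idx[1]), float(2.0 * dist[idx] - 1.0)


def auto_reference_rois(masks: np.ndarray, slice_index: int,
                        diameter: float) -> dict[str, ROISpec]:
    """Place DTA and bilateral fat ROIs from ground-truth masks on one slice.

    Each ROI is centered on the largest inscribed circle of its region; the
    requested (lesion-size) diameter is capped by what fits in the region,
    mirroring how a reader would shrink an ROI inside a thin fat rim.
    """
    rois = {}
    aorta2d = masks[:, :, slice_index] == ph.AORTA
    ax, ay, amax = _largest_inscribed_center(aorta2d)
    rois["dta"] = ROISpec((ax, ay, slice_index), max(1.0, min(diameter, amax)), "dta")
    fat2d = masks[:, :, slice_index] == ph.FAT
    mid = masks.shape[0] // 2
    for role, half in (("right_fat", slice(0, mid)), ("left_fat", slice(mid, None))):
        region = np.zeros_like(fat2d)
        region[half, :] = fat2d[half, :]
        fx, fy, fmax = _largest_inscribed_center(region)
        rois[role] = ROISpec((fx, fy, slice_index), max(1.0, min(diameter, fmax)), role)
    return rois


def measure_cnr(
    volumes: dict[str, CTVolume],
    annotations: list[LesionAnnotation],
    masks: np.ndarray,
    in_plane_spacing_mm: float | None = None,
) -> list[CNRMeasurement]:
    """One CNR measurement per lesion per modality with shared ROI geometry.

    ``volumes`` maps modality labels (e.g. 'ncct', 'scect', 'cect') to
    co-registered volumes; reference ROIs are placed automatically from the
    mask volume.  A zero background noise is surfaced per lesion as a
    measurement with ``cnr = nan`` and an error message.
    """
    if not volumes:
        raise ValueError("no modalities supplied")
    shapes = {v.shape for v in volumes.values()}
    if len(shapes) != 1:
        raise ValueError(f"modalities are not co-registered: {shapes}")
    if in_plane_spacing_mm is None:
        in_plane_spacing_mm = next(iter(volumes.values())).spacing[0]

    results: list[CNRMeasurement] = []
    for ann in annotations:
        lesion_roi = lesion_roi_from_annotation(ann, in_plane_spacing_mm)
        refs = auto_reference_rois(masks, ann.slice_index, lesion_roi.diameter)
        for modality, vol in volumes.items():
            hu_lesion, _ = _roi_stats(vol, lesion_roi)
            hu_dta, _ = _roi_stats(vol, refs["dta"])
            _, sd_r = _roi_stats(vol, refs["right_fat"])
            _, sd_l = _roi_stats(vol, refs["left_fat"])
            noise = background_noise(sd_r, sd_l)
            if noise > 0:
                cnr_value, err = lesion_cnr(hu_dta, hu_lesion, noise), None
            else:
                cnr_value = float("nan")
                err = f"lesion {ann.lesion_id}/{modality}: zero background noise"
            results.append(CNRMeasurement(
                lesion_id=ann.lesion_id, modality=modality,
                hu_lesion=hu_lesion, hu_dta=hu_dta,
                sd_right_fat=sd_r, sd_left_fat=sd_l,
                background_noise=noise, cnr=cnr_value, error=err,
            ))
    return results


def measurements_to_frame(measurements: list[CNRMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in measurements])


def cnr_for_pair(
    pair: PhantomPair, scect: CTVolume | None = None
) -> list[CNRMeasurement]:
    """Convenience wrapper: measure CNR on a phantom pair (plus optional sCECT)."""
    volumes = {"ncct": pair.ncct, "cect": pair.cect}
    if scect is not None:
        volumes["scect"] = scect
    return measure_cnr(volumes, pair.annotations, pair.masks)
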