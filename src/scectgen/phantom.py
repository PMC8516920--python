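"""Synthetic paired NCCT/CECT chest phantoms with ground-truth masks.

The phantom is schematic, not anatomical: an elliptical soft-tissue body with
a subcutaneous fat rim, two lung fields, a descending-aorta cylinder, tubular
pulmonary vessels, and spherical mediastinal lymph nodes.  What matters for
training and evaluating the contrast-synthesis model is the data contract of
a perfectly registered pre/post-contrast pair: between NCCT and CECT only the
vascular structures and nodes change HU (by a known enhancement), each volume
carries its own independent Gaussian noise, and every structure has an exact
mask, so every downstream stage is testable without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .volume import CTVolume, HU_MIN, HU_MAX, write_volume, read_volume

# Mask labels shared by all modules.
AIR, BODY, LUNG, FAT, AORTA, VESSEL, HEART = 0, 1, 2, 3, 4, 5, 6
NODE_BASE = 10  # node k is labeled NODE_BASE + k


@dataclass
class PhantomSpec:
    """Geometry, tissue HU, enhancement, and noise of one phantom pair.

    HU defaults are conventional textbook tissue values: soft tissue ~40,
    lung ~-800, subcutaneous fat ~-100; arterial enhancement takes the aorta
    from 45 to 250 HU (+205) while nodes enhance mildly (45 to 90).
    """

    shape: tuple[int, int, int] = (128, 128, 32)
    spacing: tuple[float, float, float] = (2.5, 2.5, 5.0)
    body_hu: float = 40.0
    lung_hu: float = -800.0
    fat_hu: float = -100.0
    aorta_hu_pre: float = 45.0
    aorta_hu_post: float = 250.0
    node_hu_pre: float = 45.0
    node_hu_post: float = 90.0
    n_nodes: int = 3
    node_diameter_range: tuple[float, float] = (5.0, 15.0)
    n_vessels: int = 6
    vessel_radius_range: tuple[float, float] = (2.0, 5.0)
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(v) for v in self.shape)
        self.spacing = tuple(float(v) for v in self.spacing)
        if len(self.shape) != 3 or any(v < 8 for v in self.shape):
            raise ValueError(f"shape too small for a chest phantom: {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive: {self.spacing}")
        if self.aorta_hu_post <= self.aorta_hu_pre:
            raise ValueError("aorta_hu_post must exceed aorta_hu_pre")
        if self.node_hu_post < self.node_hu_pre:
            raise ValueError("node_hu_post must be >= node_hu_pre")
        lo, hi = self.node_diameter_range
        body_extent = min(self.shape[0] * self.spacing[0], self.shape[1] * self.spacing[1])
        if not (0 < lo <= hi < body_extent):
            raise ValueError(f"node_diameter_range {self.node_diameter_range} outside (0, body extent)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_nodes < 0 or self.n_vessels < 0:
            raise ValueError("structure counts must be >= 0")


@dataclass
class LesionAnnotation:
    """One annotated node: center voxel, short-axis diameter, measuring slice."""

    lesion_id: int
    center: tuple[int, int, int]
    short_axis_diameter_mm: float
    slice_index: int

    def __post_init__(self) -> None:
        if self.short_axis_diameter_mm <= 0:
            raise ValueError("short_axis_diameter_mm must be > 0")


@dataclass
class PhantomPair:
    """A registered NCCT/CECT pair with a label volume and node annotations."""

    ncct: CTVolume
    cect: CTVolume
    masks: np.ndarray
    annotations: list[LesionAnnotation]
    spec: PhantomSpec | None = None

    def __post_init__(self) -> None:
        if self.ncct.shape != self.cect.shape:
            raise ValueError("NCCT and CECT shapes differ")
        if self.ncct.spacing != self.cect.spacing:
            raise ValueError("NCCT and CECT spacings differ")
        if self.masks.shape != self.ncct.shape:
            raise ValueError("mask volume shape differs from images")
        labels = set(np.unique(self.masks).tolist())
        for ann in self.annotations:
            if NODE_BASE + ann.lesion_id not in labels:
                raise ValueError(f"annotation {ann.lesion_id} has no mask label")
            if not (0 <= ann.slice_index < self.ncct.n_slices):
                raise ValueError(f"annotation {ann.lesion_id} slice out of range")


def _grids_mm(shape, spacing):
    x = np.arange(shape[0], dtype=np.float64) * spacing[0]
    y = np.arange(shape[1], dtype=np.float64) * spacing[1]
    z = np.arange(shape[2], dtype=np.float64) * spacing[2]
    return np.meshgrid(x, y, z, indexing="ij")


def generate_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate one registered NCCT/CECT pair, deterministic for a fixed seed.

    Noiseless CECT equals noiseless NCCT plus the vascular enhancement inside
    the aorta/vessel masks and the nodal enhancement inside node masks;
    independent Gaussian noise (sd = noise_sd) is then added to each volume,
    values are rounded to integer HU and clipped to [-1024, 3071].
    """
    rng = np.random.default_rng(spec.seed)
    X, Y, Z = spec.shape
    sx, sy, sz = spec.spacing
    gx, gy, gz = _grids_mm(spec.shape, spec.spacing)
    cx, cy, cz = (X - 1) * sx / 2, (Y - 1) * sy / 2, (Z - 1) * sz / 2

    labels = np.zeros(spec.shape, dtype=np.uint16)

    # Body: elliptical cylinder through all slices, with a fat rim shell.
    ax = 0.45 * X * sx
    ay = 0.38 * Y * sy
    r2_body = ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2
    body = r2_body <= 1.0
    inner = r2_body <= 0.88**2
    labels[body] = FAT
    labels[inner] = BODY
    ax_in, ay_in = 0.88 * ax, 0.88 * ay

    # Lungs: two ellipsoids inside the body, leaving a mediastinal corridor.
    z_mm = Z * sz
    lung = np.zeros(spec.shape, dtype=bool)
    for side in (-1.0, 1.0):
        lcx = cx + side * 0.55 * ax_in
        d2 = (
            ((gx - lcx) / (0.38 * ax_in)) ** 2
            + ((gy - cy) / (0.62 * ay_in)) ** 2
            + ((gz - cz) / (0.48 * z_mm)) ** 2
        )
        lung |= (d2 <= 1.0) & inner
    labels[lung] = LUNG

    # Cardiac blood pool: a left-anterior ellipsoid indenting the lungs
    # (cardiac notch).  In contrast-enhanced chest CT the opacified cardiac
    # chambers dominate the post-contrast HU change of the mediastinum, so the
    # pool enhances with the vascular delta.
    heart_c = (cx - 0.05 * ax_in, cy - 0.20 * ay_in, cz + 0.10 * z_mm)
    heart = (
        ((gx - heart_c[0]) / (0.28 * ax_in)) ** 2
        + ((gy - heart_c[1]) / (0.32 * ay_in)) ** 2
        + ((gz - heart_c[2]) / (0.38 * z_mm)) ** 2
    ) <= 1.0
    heart &= inner
    lung &= ~heart
    labels[heart] = HEART
    labels[lung] = LUNG

    # Descending aorta: left para-vertebral cylinder over most of the z range.
    aorta_radius = 11.0
    aorta_x = cx - 0.06 * ax_in
    aorta_y = cy + 0.38 * ay_in
    z_lo = min(2, Z - 1)
    z_hi = max(Z - 3, z_lo)  # inclusive
    aorta = (
        ((gx - aorta_x) ** 2 + (gy - aorta_y) ** 2 <= aorta_radius**2)
        & (gz >= z_lo * sz - 1e-9)
        & (gz <= z_hi * sz + 1e-9)
        & inner
        & ~lung
        & ~heart
    )
    if not aorta.any():
        raise ValueError(f"phantom shape {spec.shape} too small to contain the aorta")
    labels[aorta] = AORTA

    # Pulmonary vessels: tubes radiating from each hilum into the lung.
    vessels = np.zeros(spec.shape, dtype=bool)
    for k in range(spec.n_vessels):
        side = -1.0 if k % 2 == 0 else 1.0
        p0 = np.array([cx + side * 0.20 * ax_in, cy, cz])
        theta = rng.uniform(-0.45 * np.pi, 0.45 * np.pi)
        direction = np.array(
            [side * np.cos(theta), np.sin(theta), rng.uniform(-0.5, 0.5)]
        )
        direction /= np.linalg.norm(direction)
        length = rng.uniform(0.5, 0.9) * 0.76 * ax_in
        radius = rng.uniform(*spec.vessel_radius_range)
        # distance from each voxel center to the segment p0 + t*d, t in [0, L]
        px, py, pz = gx - p0[0], gy - p0[1], gz - p0[2]
        t = np.clip(px * direction[0] + py * direction[1] + pz * direction[2], 0, length)
        d2 = (px - t * direction[0]) ** 2 + (py - t * direction[1]) ** 2 + (pz - t * direction[2]) ** 2
        vessels |= (d2 <= radius**2) & (lung | (inner & ~aorta))
    vessels &= ~aorta & ~heart
    labels[vessels] = VESSEL

    # Mediastinal lymph nodes: spheres in the corridor between the lungs.
    annotations: list[LesionAnnotation] = []
    occupied = lung | aorta | vessels | heart | ~inner
    for k in range(spec.n_nodes):
        diameter = rng.uniform(*spec.node_diameter_range)
        placed = False
        for _ in range(200):
            ix = int(rng.integers(int(X * 0.38), int(X * 0.62) + 1))
            iy = int(rng.integers(int(Y * 0.25), int(Y * 0.70) + 1))
            iz = int(rng.integers(int(Z * 0.20), int(Z * 0.80) + 1))
            ccx, ccy, ccz = ix * sx, iy * sy, iz * sz
            d2 = (gx - ccx) ** 2 + (gy - ccy) ** 2 + (gz - ccz) ** 2
            sphere = d2 <= (diameter / 2.0) ** 2
            if not sphere.any():
                sphere = np.zeros(spec.shape, dtype=bool)
                sphere[ix, iy, iz] = True
            if (sphere & occupied).any() or labels[ix, iy, iz] != BODY:
                continue
            labels[sphere] = NODE_BASE + k
            occupied |= sphere
            annotations.append(
                LesionAnnotation(
                    lesion_id=k,
                    center=(ix, iy, iz),
                    short_axis_diameter_mm=float(diameter),
                    slice_index=iz,
                )
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                f"phantom shape {spec.shape} too small to place node {k} "
                f"({diameter:.1f} mm) in the mediastinum"
            )

    # Compose HU: pre- and post-contrast share all non-enhancing tissue.
    hu_pre = np.full(spec.shape, -1000.0, dtype=np.float64)
    hu_pre[labels == BODY] = spec.body_hu
    hu_pre[labels == FAT] = spec.fat_hu
    hu_pre[labels == LUNG] = spec.lung_hu
    vascular = (labels == AORTA) | (labels == VESSEL) | (labels == HEART)
    hu_pre[vascular] = spec.aorta_hu_pre
    hu_pre[labels >= NODE_BASE] = spec.node_hu_pre

    hu_post = hu_pre.copy()
    hu_post[vascular] = spec.aorta_hu_post
    hu_post[labels >= NODE_BASE] = spec.node_hu_post

    def finalize(hu):
        if spec.noise_sd > 0:
            hu = hu + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        return np.clip(np.rint(hu), HU_MIN, HU_MAX).astype(np.float32)

    ncct = CTVolume(hu=finalize(hu_pre), spacing=spec.spacing)
    cect = CTVolume(hu=finalize(hu_post), spacing=spec.spacing)
    return PhantomPair(ncct=ncct, cect=cect, masks=labels, annotations=annotations, spec=spec)


def vascular_mask(pair: PhantomPair) -> np.ndarray:
    """All structures receiving the vascular enhancement (incl. blood pool)."""
    return (pair.masks == AORTA) | (pair.masks == VESSEL) | (pair.masks == HEART)


def node_mask(pair: PhantomPair, lesion_id: int) -> np.ndarray:
    return pair.masks == NODE_BASE + lesion_id


def aorta_slice_range(masks: np.ndarray) -> tuple[int, int]:
    """Inclusive axial slice range spanned by the aorta mask (evaluation range)."""
    zs = np.flatnonzero((masks == AORTA).any(axis=(0, 1)))
    if zs.size == 0:
        raise ValueError("no aorta voxels in the mask volume")
    return int(zs[0]), int(zs[-1])


def annotate_significant_nodes(
    pair: PhantomPair, threshold_mm: float = 5.0
) -> list[LesionAnnotation]:
    """Annotations with short-axis diameter strictly greater than threshold.

    5 mm is the per-lesion annotation cutoff; 10 mm flags significant
    lymphadenopathy.
    """
    return [a for a in pair.annotations if a.short_axis_diameter_mm > threshold_mm]


def write_phantom(pair: PhantomPair, directory) -> dict[str, str]:
    """Write NCCT/CECT/masks as NIfTI plus the annotation CSV; returns paths."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {
        "ncct": os.path.join(directory, "ncct.nii.gz"),
        "cect": os.path.join(directory, "cect.nii.gz"),
        "masks": os.path.join(directory, "masks.nii.gz"),
        "annotations": os.path.join(directory, "annotations.csv"),
    }
    write_volume(pair.ncct, paths["ncct"])
    write_volume(pair.cect, paths["cect"])
    mask_vol = CTVolume(hu=pair.masks.astype(np.float32), spacing=pair.ncct.spacing)
    write_volume(mask_vol, paths["masks"], dtype=np.uint16)
    rows = [
        {
            "lesion_id": a.lesion_id,
            "x": a.center[0],
            "y": a.center[1],
            "z": a.center[2],
            "short_axis_mm": a.short_axis_diameter_mm,
        }
        for a in pair.annotations
    ]
    pd.DataFrame(rows, columns=["lesion_id", "x", "y", "z", "short_axis_mm"]).to_csv(
        paths["annotations"], index=False
    )
    return paths


def read_phantom(directory) -> PhantomPair:
    """Read back a phantom pair written by :func:`write_phantom`."""
    import os

    ncct = read_volume(os.path.join(directory, "ncct.nii.gz"))
    cect = read_volume(os.path.join(directory, "cect.nii.gz"))
    masks = read_volume(os.path.join(directory, "masks.nii.gz")).hu.astype(np.uint16)
    df = pd.read_csv(os.path.join(directory, "annotations.csv"))
    annotations = [
        LesionAnnotation(
            lesion_id=int(r.lesion_id),
            center=(int(r.x), int(r.y), int(r.z)),
            short_axis_diameter_mm=float(r.short_axis_mm),
            slice_index=int(r.z),
        )
        for r in df.itertuples()
    ]
    return PhantomPair(ncct=ncct, cect=cect, masks=masks, annotations=annotations)
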