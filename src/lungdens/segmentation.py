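"""Rule-based lung extraction and upper/lower regional partitioning.

The extraction pipeline is a classic threshold-and-morphology chain:

1. candidate air voxels below the air threshold (default -320 HU);
2. connected components touching the in-plane volume border are discarded
   as outside air (the body separates lungs from the border);
3. components at or above the minimum volume (default 200 mL) are kept,
   up to the two largest;
4. optional coarse trachea/main-bronchus removal (a narrow cranial air
   column near the midline, region-grown caudally while its cross-section
   stays small);
5. per-slice 2-D hole filling (recovers vessels and dense lesions inside
   the lung), then morphological closing (default 2 mm radius).

A single fused component spanning both lungs is split at the midsagittal
plane of the body bounding box.  The pipeline is fully deterministic for
fixed parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import RegionError, SegmentationError, ValidationError
from .volume_io import CTVolume, LungMask

RIGHT_UPPER, RIGHT_LOWER, LEFT_UPPER, LEFT_LOWER = 1, 2, 3, 4
SPLIT_REGION_MAP = {
    RIGHT_UPPER: "right_upper",
    RIGHT_LOWER: "right_lower",
    LEFT_UPPER: "left_upper",
    LEFT_LOWER: "left_lower",
}

#: lobe names recognized by the lobe-label grouping, mapped to the four
#: output regions: upper lungs = RUL + upper part of LUL; lower lungs =
#: middle lobe + lingula + both lower lobes.
LOBE_GROUPING = {
    "rul": RIGHT_UPPER,
    "rml": RIGHT_LOWER,
    "rll": RIGHT_LOWER,
    "lul_upper": LEFT_UPPER,
    "lingula": LEFT_LOWER,
    "lll": LEFT_LOWER,
}


@dataclass
class SegmentationParams:
    air_threshold_hu: float = -320.0
    closing_radius_mm: float = 2.0
    min_volume_ml: float = 200.0
    remove_trachea: bool = True
    body_threshold_hu: float = -200.0  # voxels above this count as body
    #: trachea candidate: per-slice cross-section below this area
    max_airway_area_mm2: float = 400.0

    def __post_init__(self) -> None:
        if not (-1000.0 < self.air_threshold_hu < 0.0):
            raise ValidationError(f"air threshold must be in (-1000, 0) HU, got {self.air_threshold_hu}")
        if self.closing_radius_mm < 0:
            raise ValidationError("closing radius must be >= 0")
        if self.min_volume_ml <= 0:
            raise ValidationError("minimum lung-component volume must be > 0")


def _closing_structure(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray | None:
    radii = [int(round(radius_mm / s)) for s in spacing]
    if max(radii) < 1:
        return None
    xx, yy, zz = np.meshgrid(*(np.arange(-r, r + 1) for r in radii), indexing="ij")
    rx, ry, rz = (max(r, 1e-9) for r in radii)
    return (xx / rx) ** 2 + (yy / ry) ** 2 + (zz / rz) ** 2 <= 1.0


def _remove_trachea(air: np.ndarray, params: SegmentationParams, spacing) -> np.ndarray:
    """Remove a narrow cranial air column (trachea/main bronchi) in place."""
    nx, ny, nz = air.shape
    area_per_vox = spacing[0] * spacing[1]
    max_vox = params.max_airway_area_mm2 / area_per_vox
    # most cranial occupied slice
    occupied = np.flatnonzero(air.any(axis=(0, 1)))
    if occupied.size == 0:
        return air
    top = occupied[-1]
    lab, n = ndimage.label(air[:, :, top])
    seed = None
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() <= max_vox:
            cx = ndimage.center_of_mass(comp)[0]
            if abs(cx - nx / 2) < nx / 6:  # near midline
                seed = comp
                break
    if seed is None:
        return air
    current = seed
    for z in range(top, -1, -1):
        sl = air[:, :, z]
        grown = ndimage.binary_dilation(current, iterations=2) & sl
        lab2, n2 = ndimage.label(grown)
        keep = np.zeros_like(grown)
        for i in range(1, n2 + 1):
            comp = lab2 == i
            if comp.sum() <= max_vox:
                keep |= comp
        if not keep.any():
            break
        air[:, :, z] &= ~keep
        current = keep
    return air


def segment_lungs(vol: CTVolume, params: SegmentationParams | None = None) -> LungMask:
    """Isolate the lungs from the mediastinum, chest wall and outside air.

    Returns a mask with labels ``{1: right_lung, 2: left_lung}``.
    """
    params = params or SegmentationParams()
    voxels = vol.voxels
    if not np.any(voxels > params.body_threshold_hu):
        raise SegmentationError("no body detected: no voxels above the body threshold")

    air = voxels < params.air_threshold_hu

    # discard air connected to the in-plane volume border (outside air)
    border = np.zeros_like(air)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    lab, _ = ndimage.label(air)
    border_labels = np.unique(lab[border & air])
    if border_labels.size:
        air &= ~np.isin(lab, border_labels)

    if params.remove_trachea:
        air = _remove_trachea(air, params, vol.spacing)

    lab, n = ndimage.label(air)
    if n == 0:
        raise SegmentationError("no lung found: no interior air component")
    sizes = ndimage.sum_labels(np.ones_like(lab, dtype=np.int64), lab, index=np.arange(1, n + 1))
    min_vox = params.min_volume_ml * 1000.0 / vol.voxel_volume_mm3
    keep = np.argsort(sizes)[::-1][:2] + 1
    keep = [int(i) for i in keep if sizes[i - 1] >= min_vox]
    if not keep:
        raise SegmentationError(
            f"no lung found: largest air component is "
            f"{sizes.max() * vol.voxel_volume_ml:.0f} mL < {params.min_volume_ml:.0f} mL"
        )
    lung = np.isin(lab, keep)

    # 2-D hole filling per axial slice, then closing
    for z in range(lung.shape[2]):
        lung[:, :, z] = ndimage.binary_fill_holes(lung[:, :, z])
    struct = _closing_structure(params.closing_radius_mm, vol.spacing)
    if struct is not None:
        lung = ndimage.binary_closing(lung, structure=struct)

    labels = np.zeros(lung.shape, dtype=np.int32)
    lab2, n2 = ndimage.label(lung)
    sizes2 = ndimage.sum_labels(np.ones_like(lab2, dtype=np.int64), lab2, index=np.arange(1, n2 + 1))
    order = np.argsort(sizes2)[::-1][: min(2, n2)] + 1
    comps = [lab2 == int(i) for i in order]

    if len(comps) == 1:
        # fused lungs: split at the body's midsagittal plane
        body = voxels > params.body_threshold_hu
        xs = np.flatnonzero(body.any(axis=(1, 2)))
        mid = (xs[0] + xs[-1]) / 2.0 if xs.size else lung.shape[0] / 2.0
        xgrid = np.arange(lung.shape[0])[:, None, None]
        right = comps[0] & (xgrid >= mid)
        left = comps[0] & (xgrid < mid)
    else:
        c0 = ndimage.center_of_mass(comps[0])[0]
        c1 = ndimage.center_of_mass(comps[1])[0]
        right, left = (comps[0], comps[1]) if c0 >= c1 else (comps[1], comps[0])
    labels[right] = 1
    labels[left] = 2
    return LungMask(labels, {1: "right_lung", 2: "left_lung"}, vol.spacing)


def _axial_split_one_lung(sel: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean selector of the *upper* part: whole axial slices are assigned
    cranially until the requested fraction of the lung's voxels is reached."""
    per_slice = sel.sum(axis=(0, 1))
    total = per_slice.sum()
    target = fraction * total
    upper = np.zeros_like(sel)
    acc = 0
    last = None
    for z in range(sel.shape[2] - 1, -1, -1):  # cranial = high index
        if acc >= target:
            break
        upper[:, :, z] = sel[:, :, z]
        acc += per_slice[z]
        last = z
    # drop the boundary slice if that lands closer to the target fraction,
    # so the imbalance stays below one slice's voxels
    if last is not None and (acc - target) > (target - (acc - per_slice[last])):
        upper[:, :, last] = False
    return upper


def split_upper_lower(
    mask: LungMask,
    method: str = "axial_fraction",
    fraction: float = 0.5,
    lobe_mask: LungMask | None = None,
) -> LungMask:
    """Partition a lung mask into upper/lower regions per lung.

    ``axial_fraction`` places, per lung, the given fraction of that lung's
    voxels cranially of the cut plane.  ``lobe_labels`` groups a supplied
    lobe map: upper = right upper lobe + upper part of the left upper lobe;
    lower = middle lobe, lingula and both lower lobes.
    """
    if not np.any(mask.labels):
        raise RegionError("cannot split an empty lung mask")
    out = np.zeros(mask.shape, dtype=np.int32)

    if method == "axial_fraction":
        if not (0.0 < fraction < 1.0):
            raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
        sides = _lung_sides(mask)
        for side, (upper_lab, lower_lab) in (
            ("right", (RIGHT_UPPER, RIGHT_LOWER)),
            ("left", (LEFT_UPPER, LEFT_LOWER)),
        ):
            sel = sides[side]
            if not sel.any():
                continue
            upper = _axial_split_one_lung(sel, fraction)
            out[upper] = upper_lab
            out[sel & ~upper] = lower_lab
    elif method == "lobe_labels":
        if lobe_mask is None:
            raise ValidationError("lobe_labels split requires a lobe label mask")
        if lobe_mask.shape != mask.shape:
            raise ValidationError("lobe mask shape does not match lung mask shape")
        for lab, name in lobe_mask.region_map.items():
            key = name.lower().replace("-", "_").replace(" ", "_")
            if key not in LOBE_GROUPING:
                raise ValidationError(f"unrecognized lobe name '{name}'; known: {sorted(LOBE_GROUPING)}")
            out[(lobe_mask.labels == lab) & (mask.labels > 0)] = LOBE_GROUPING[key]
    else:
        raise ValidationError(f"unknown split method '{method}'")

    present = set(np.unique(out).tolist()) - {0}
    region_map = {k: v for k, v in SPLIT_REGION_MAP.items() if k in present}
    return LungMask(out, region_map, mask.spacing)


def _lung_sides(mask: LungMask) -> dict[str, np.ndarray]:
    """Right/left selectors from explicit labels when present, else by the
    mask's midsagittal centroid split."""
    names = {v.lower(): k for k, v in mask.region_map.items()}
    if "right_lung" in names and "left_lung" in names:
        return {
            "right": mask.labels == names["right_lung"],
            "left": mask.labels == names["left_lung"],
        }
    sel = mask.labels > 0
    xs = np.flatnonzero(sel.any(axis=(1, 2)))
    mid = (xs[0] + xs[-1]) / 2.0
    xgrid = np.arange(mask.shape[0])[:, None, None]
    return {"right": sel & (xgrid >= mid), "left": sel & (xgrid < mid)}


def mask_volume_ml(mask: LungMask, region: int | str = "whole") -> float:
    """Physical volume of a mask region: voxel count x voxel volume, in mL."""
    sel = mask.select(region)
    voxel_ml = float(np.prod(mask.spacing)) / 1000.0
    return float(np.count_nonzero(sel)) * voxel_ml
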