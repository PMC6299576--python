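"""CT volume and lung-mask containers with NIfTI/DICOM I/O.

The in-memory convention is a right-handed RAS+ grid: ``voxels[i, j, k]``
with *i* increasing toward the patient's right-to-left... strictly, toward
+x (patient left in DICOM is flipped on load so that +x = patient right),
*j* toward anterior, and *k* toward superior.  Axial slices therefore lie
along the last axis and the craniocaudal direction is fixed, which the
upper/lower regional split relies on.

HU semantics: DICOM stored values are rescaled with the slope/intercept
from the headers on read; NIfTI volumes are assumed to already hold HU.
Values below -1024 HU are physically implausible for calibrated chest CT
and are logged, but retained (no clipping by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import AlignmentError, ValidationError, VolumeIOError

log = logging.getLogger(__name__)

AXIS_CONVENTION = "RAS"  # +x right->left flipped to right, +y anterior, +z superior

#: spacing agreement required when binding a mask to a volume, in mm
GRID_TOLERANCE_MM = 1e-3


@dataclass
class CTVolume:
    """A 3-D attenuation field in Hounsfield units on a regular grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_convention: str = AXIS_CONVENTION

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(f"volume must be 3-D, got shape {self.voxels.shape}")
        if self.voxels.size == 0:
            raise ValidationError("volume has zero voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing components must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("volume contains non-finite HU values")
        n_low = int(np.count_nonzero(self.voxels < -1024))
        if n_low:
            log.warning("volume contains %d voxels below -1024 HU (retained, not clipped)", n_low)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def clipped(self, lo: float, hi: float) -> "CTVolume":
        """Return a copy with HU clipped to ``[lo, hi]`` (opt-in only)."""
        return CTVolume(np.clip(self.voxels, lo, hi), self.spacing, self.origin, self.axis_convention)


@dataclass
class LungMask:
    """Integer label volume aligned to a :class:`CTVolume`.

    Label 0 is background; labels 1..K are regions named by ``region_map``.
    The derived regions ``"whole"``, ``"upper"`` and ``"lower"`` select,
    respectively, all labelled voxels and the union of labels whose name
    contains ``upper`` / ``lower``.
    """

    labels: np.ndarray
    region_map: dict[int, str] = field(default_factory=lambda: {1: "lung"})
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.allclose(self.labels, np.round(self.labels)):
                self.labels = self.labels.astype(np.int32)
            else:
                raise ValidationError("mask contains non-integer label values")
        present = set(np.unique(self.labels).tolist()) - {0}
        declared = set(self.region_map)
        if not present <= declared:
            raise ValidationError(
                f"mask contains labels {sorted(present - declared)} not in region map {sorted(declared)}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def select(self, region: int | str = "whole") -> np.ndarray:
        """Boolean voxel selector for a region label, name, or derived region."""
        from .errors import RegionError

        if isinstance(region, (int, np.integer)):
            if int(region) not in self.region_map:
                raise RegionError(f"unknown region label {region}; known: {self.region_map}")
            return self.labels == int(region)
        name = str(region).lower()
        if name in ("whole", "lung", "all"):
            return self.labels > 0
        if name in ("upper", "lower"):
            labels = [lab for lab, nm in self.region_map.items() if name in nm.lower()]
            if not labels:
                raise RegionError(f"no labels matching region '{name}' in {self.region_map}")
            return np.isin(self.labels, labels)
        for lab, nm in self.region_map.items():
            if nm.lower() == name:
                return self.labels == lab
        raise RegionError(f"unknown region '{region}'; known: {sorted(self.region_map.values())}")

    def region_names(self) -> list[str]:
        return [self.region_map[k] for k in sorted(self.region_map)]


def _affine(vol_spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(vol_spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a volume as NIfTI, preserving voxels, spacing and origin."""
    path = Path(path)
    img = nib.Nifti1Image(np.asanyarray(vol.voxels), _affine(vol.spacing, vol.origin))
    img.header.set_data_dtype(vol.voxels.dtype)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise VolumeIOError(f"cannot write volume to {path}: {exc}") from exc


def write_mask(mask: LungMask, path: str | Path, sidecar: bool = True) -> None:
    """Write a label mask as unsigned-integer NIfTI plus a JSON region-map sidecar."""
    path = Path(path)
    labels = mask.labels.astype(np.uint16)
    img = nib.Nifti1Image(labels, _affine(mask.spacing, (0.0, 0.0, 0.0)))
    img.header.set_data_dtype(np.uint16)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise VolumeIOError(f"cannot write mask to {path}: {exc}") from exc
    if sidecar:
        sc = _sidecar_path(path)
        sc.write_text(json.dumps({str(k): v for k, v in mask.region_map.items()}, indent=1))


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(path: str | Path, format_hint: str = "auto") -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    DICOM slices are sorted by physical position along the slice normal and
    rescaled to HU with the per-slice RescaleSlope/RescaleIntercept.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such path: {path}")
    if format_hint == "auto":
        format_hint = "dicom_dir" if path.is_dir() else "nifti"
    if format_hint == "nifti":
        return _read_nifti(path)
    if format_hint == "dicom_dir":
        return _read_dicom_dir(path)
    raise ValidationError(f"unknown format hint '{format_hint}'")


def _read_nifti(path: Path) -> CTVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeIOError(f"cannot read NIfTI {path}: {exc}") from exc
    voxels = np.asanyarray(img.dataobj)
    if voxels.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3-D volume, got shape {voxels.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return CTVolume(voxels, tuple(float(z) for z in zooms), origin)


def _read_dicom_dir(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and not p.name.startswith("."))
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # skip non-DICOM files (e.g. DICOMDIR, reports)
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise VolumeIOError(f"no DICOM image files found in {path}")

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise VolumeIOError(f"mixed DICOM series in {path}: {len(uids)} SeriesInstanceUIDs found")

    for name in ("RescaleSlope", "RescaleIntercept"):
        for ds in datasets:
            if not hasattr(ds, name):
                raise VolumeIOError(f"DICOM slice {ds.filename} is missing required tag {name}")

    first = datasets[0]
    orient = np.array(getattr(first, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float)
    normal = np.cross(orient[:3], orient[3:])

    def slice_pos(ds) -> float:
        ipp = np.array(getattr(ds, "ImagePositionPatient", [0, 0, getattr(ds, "InstanceNumber", 0)]), float)
        return float(np.dot(ipp, normal))

    datasets.sort(key=slice_pos)
    positions = [slice_pos(ds) for ds in datasets]

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float32)
        arr = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        slices.append(arr)
    # pydicom arrays are (row, col) = (y, x); rearrange to (x, y, z)
    voxels = np.stack(slices, axis=-1).transpose(1, 0, 2)
    # DICOM LPS -> internal RAS-style handedness: flip the first two axes
    voxels = voxels[::-1, ::-1, :].copy()

    row_spacing, col_spacing = (float(v) for v in first.PixelSpacing)
    if len(positions) > 1:
        dz = float(np.median(np.diff(positions)))
        if dz <= 0:
            raise VolumeIOError(f"degenerate slice positions in {path}")
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    origin = tuple(float(x) for x in getattr(first, "ImagePositionPatient", (0.0, 0.0, 0.0)))
    thickness = float(getattr(first, "SliceThickness", dz))
    if abs(thickness - dz) > 1e-6:
        log.info("slice thickness %.3f mm differs from slice spacing %.3f mm", thickness, dz)
    return CTVolume(voxels, (col_spacing, row_spacing, dz), origin)


def read_mask(path: str | Path, vol: CTVolume) -> LungMask:
    """Load a NIfTI label mask and bind it to ``vol``, checking grid alignment."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such mask: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot read mask {path}: {exc}") from exc
    labels = np.asanyarray(img.dataobj)
    if labels.shape != vol.shape:
        raise AlignmentError(f"mask shape {labels.shape} does not match volume shape {vol.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(abs(a - b) > GRID_TOLERANCE_MM for a, b in zip(zooms, vol.spacing)):
        raise AlignmentError(f"mask spacing {zooms} does not match volume spacing {vol.spacing}")
    if not np.issubdtype(labels.dtype, np.integer) and not np.allclose(labels, np.round(labels)):
        raise ValidationError(f"mask {path} contains non-integer values")
    region_map: dict[int, str] | None = None
    sc = _sidecar_path(path)
    if sc.exists():
        region_map = {int(k): v for k, v in json.loads(sc.read_text()).items()}
    if region_map is None:
        present = sorted(set(np.unique(labels).tolist()) - {0})
        region_map = {int(k): f"region_{int(k)}" for k in present} or {1: "lung"}
    return LungMask(np.round(labels).astype(np.int32), region_map, vol.spacing)
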