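"""Synthetic chest-CT phantoms with ground truth.

The generator reproduces the *statistical* structure the density-scoring
method relies on, not anatomy: a soft-tissue body ellipsoid surrounded by
air, two lung ellipsoids whose parenchymal voxels follow a sharp Gaussian
peak near -850 HU, vessel-like tubes at soft-tissue attenuation that give
the histogram its right tail, and disease burden as mid-density lesion
blobs (bronchial wall thickening, mucus plugging, consolidation and
atelectasis all raise lung attenuation) replacing a prescribed fraction
*f* of lung voxels.  Inspiration level is modelled as an affine transform
of the lung densities about their mean: expiration shifts the histogram
toward higher HU and spreads it.

Lesions *replace* parenchymal voxels, so total lung volume is conserved
and the recorded per-region lesion fractions are exact voxel counts.  All
randomness flows from the single spec seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .segmentation import split_upper_lower
from .volume_io import CTVolume, LungMask


@dataclass
class PhantomSpec:
    """Parameters of the synthetic chest generator.

    HU defaults: body +40 (soft tissue), background -1000 (air),
    parenchyma N(-850, 60) resembling inspiratory adult lungs, vessels
    +30, lesions N(-150, 100) spanning mucus/consolidation densities.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    body_hu: float = 40.0
    background_hu: float = -1000.0
    parenchyma_mean_hu: float = -850.0
    parenchyma_sd_hu: float = 60.0
    vessel_fraction: float = 0.03
    vessel_hu: float = 30.0
    #: spread of vessel attenuation (partial volume, caliber); keeps the
    #: histogram mode at the parenchymal peak as in real lungs
    vessel_sd_hu: float = 25.0
    lesion_fraction: float = 0.0
    lesion_mean_hu: float = -150.0
    lesion_sd_hu: float = 100.0
    lesion_lower_bias: float = 0.5  # expected caudal share of lesion volume
    inspiration_shift_hu: float = 0.0
    inspiration_scale: float = 1.0
    noise_sd_hu: float = 0.0
    seed: int = 0
    #: lung semi-axes as fractions of the volume extent; the body ellipsoid
    #: is fixed at (0.42, 0.36, 0.46) of the extent
    lung_semiaxes: tuple[float, float, float] = (0.16, 0.25, 0.36)
    lung_offset_x: float = 0.21

    def __post_init__(self) -> None:
        if not (0.0 <= self.lesion_fraction <= 0.3):
            raise ValidationError(f"lesion fraction must be in [0, 0.3], got {self.lesion_fraction}")
        if not (0.0 <= self.vessel_fraction < 1.0):
            raise ValidationError(f"vessel fraction must be in [0, 1), got {self.vessel_fraction}")
        if self.lesion_fraction + self.vessel_fraction >= 1.0:
            raise ValidationError("lesion fraction + vessel fraction must be < 1")
        if not (0.0 <= self.lesion_lower_bias <= 1.0):
            raise ValidationError("lesion lower bias must be in [0, 1]")
        if self.inspiration_scale <= 0:
            raise ValidationError("inspiration spread scale must be > 0")
        for hu in (self.body_hu, self.background_hu, self.parenchyma_mean_hu, self.vessel_hu, self.lesion_mean_hu):
            if not np.isfinite(hu):
                raise ValidationError("all HU parameters must be finite")


BODY_SEMIAXES = (0.42, 0.36, 0.46)


def _physical_grids(shape, spacing):
    coords = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*coords, indexing="ij")


def _ellipsoid(grids, center, semiaxes) -> np.ndarray:
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def _ball_offsets(radius_vox: int) -> np.ndarray:
    r = int(radius_vox)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = dx**2 + dy**2 + dz**2 <= r**2
    return np.stack([dx[inside], dy[inside], dz[inside]], axis=1)


def _paint_spheres(target: np.ndarray, centers: np.ndarray, radius_vox: int) -> None:
    """Set ``target`` True inside spheres at integer voxel ``centers`` (in place)."""
    offsets = _ball_offsets(radius_vox)
    pts = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    valid = np.all((pts >= 0) & (pts < np.array(target.shape)), axis=1)
    pts = pts[valid]
    target[pts[:, 0], pts[:, 1], pts[:, 2]] = True


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[CTVolume, LungMask, dict]:
    """Generate one phantom: HU volume, 4-region truth mask, truth metadata.

    The truth mask carries labels right/left x upper/lower (upper = the
    cranial half of each lung by voxel count), and the metadata records
    the exact lesion fraction overall and per region.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    shape, spacing = tuple(spec.shape), tuple(spec.spacing)
    extent = np.array(shape) * np.array(spacing)
    center = extent / 2.0
    grids = _physical_grids(shape, spacing)

    body = _ellipsoid(grids, center, extent * np.array(BODY_SEMIAXES))
    semi = extent * np.array(spec.lung_semiaxes)
    off = spec.lung_offset_x * extent[0]
    right = _ellipsoid(grids, center + np.array([off, 0, 0]), semi)
    left = _ellipsoid(grids, center - np.array([off, 0, 0]), semi)
    lung = right | left
    if np.any(lung & ~body):
        raise ValidationError("phantom spec error: lungs do not fit inside the body ellipsoid")

    voxels = np.full(shape, spec.background_hu, dtype=np.float32)
    voxels[body] = spec.body_hu
    n_lung = int(np.count_nonzero(lung))
    voxels[lung] = rng.normal(spec.parenchyma_mean_hu, spec.parenchyma_sd_hu, n_lung).astype(np.float32)

    lung_idx = np.argwhere(lung)
    vessel = np.zeros(shape, dtype=bool)
    target_vessel = int(round(spec.vessel_fraction * n_lung))
    attempts = 0
    while int(np.count_nonzero(vessel)) < target_vessel and attempts < 10_000:
        attempts += 1
        start = lung_idx[rng.integers(len(lung_idx))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length_mm = rng.uniform(20.0, 60.0)
        radius_vox = int(rng.integers(1, 4))
        n_steps = max(2, int(length_mm / min(spacing)))
        t = np.linspace(0.0, length_mm, n_steps)
        pts = np.round(start[None, :] + (t[:, None] * direction[None, :]) / np.array(spacing)).astype(int)
        tube = np.zeros(shape, dtype=bool)
        _paint_spheres(tube, pts, radius_vox)
        vessel |= tube & lung
    n_vessel = int(np.count_nonzero(vessel))
    if n_vessel:
        voxels[vessel] = rng.normal(spec.vessel_hu, spec.vessel_sd_hu, n_vessel).astype(np.float32)

    lesion = np.zeros(shape, dtype=bool)
    target_lesion = int(round(spec.lesion_fraction * n_lung))
    if target_lesion > 0:
        z_mid = np.median(lung_idx[:, 2])
        caudal = lung_idx[:, 2] < z_mid
        pools = {True: lung_idx[caudal], False: lung_idx[~caudal]}
        zgrid = np.arange(shape[2])[None, None, :]
        side_sel = {True: zgrid < z_mid, False: zgrid >= z_mid}
        available = lung & ~vessel
        attempts = 0
        while int(np.count_nonzero(lesion)) < target_lesion and attempts < 100_000:
            attempts += 1
            # each blob lands caudally with probability lesion_lower_bias and
            # is clipped to its side, so the bias is the expected caudal
            # share of lesion volume (bias 1.0 -> strictly lower lungs)
            go_lower = bool(rng.random() < spec.lesion_lower_bias)
            pool = pools[go_lower] if len(pools[go_lower]) else lung_idx
            c = pool[rng.integers(len(pool))]
            radius_vox = int(rng.integers(2, 6))
            blob = np.zeros(shape, dtype=bool)
            _paint_spheres(blob, c[None, :], radius_vox)
            new = blob & available & side_sel[go_lower] & ~lesion
            deficit = target_lesion - int(np.count_nonzero(lesion))
            new_idx = np.argwhere(new)
            if len(new_idx) > deficit:
                new_idx = new_idx[:deficit]  # trim the last blob for an exact count
            lesion[new_idx[:, 0], new_idx[:, 1], new_idx[:, 2]] = True
        n_les = int(np.count_nonzero(lesion))
        voxels[lesion] = rng.normal(spec.lesion_mean_hu, spec.lesion_sd_hu, n_les).astype(np.float32)

    if spec.noise_sd_hu > 0:
        voxels += rng.normal(0.0, spec.noise_sd_hu, shape).astype(np.float32)

    labels = np.zeros(shape, dtype=np.int32)
    labels[right] = 1
    labels[left] = 2
    binary = LungMask(labels, {1: "right_lung", 2: "left_lung"}, spacing)
    truth = split_upper_lower(binary, "axial_fraction", 0.5)

    vol = CTVolume(voxels, spacing)
    if spec.inspiration_shift_hu != 0.0 or spec.inspiration_scale != 1.0:
        vol = apply_inspiration(vol, truth, spec.inspiration_shift_hu, spec.inspiration_scale)

    meta = {
        "seed": int(spec.seed),
        "n_lung_voxels": n_lung,
        "lung_volume_ml": n_lung * float(np.prod(spacing)) / 1000.0,
        "vessel_fraction": int(np.count_nonzero(vessel)) / n_lung,
        "lesion_fraction": int(np.count_nonzero(lesion)) / n_lung,
        "lesion_fraction_by_region": {
            name: _region_fraction(lesion, truth, name) for name in ("upper", "lower", *truth.region_names())
        },
        "spec": asdict(spec),
    }
    return vol, truth, meta


def _region_fraction(lesion: np.ndarray, mask: LungMask, region: str) -> float:
    sel = mask.select(region)
    n = int(np.count_nonzero(sel))
    return int(np.count_nonzero(lesion & sel)) / n if n else 0.0


def apply_inspiration(vol: CTVolume, mask: LungMask, shift_hu: float, scale: float) -> CTVolume:
    """Affine inspiration-level transform of the lung densities.

    Masked voxels map ``v -> MLD + scale*(v - MLD) + shift_hu`` (about the
    lung mean); voxels outside the mask are unchanged.  A lower level of
    inspiration corresponds to ``shift_hu > 0`` (denser lung) and
    ``scale > 1`` (flatter, wider histogram).
    """
    if scale <= 0:
        raise ValidationError("spread scale must be > 0")
    sel = mask.select("whole")
    values = vol.voxels[sel].astype(np.float64)
    mld = values.mean()
    out = vol.voxels.astype(np.float64, copy=True)
    out[sel] = mld + scale * (values - mld) + shift_hu
    return CTVolume(out.astype(vol.voxels.dtype), vol.spacing, vol.origin, vol.axis_convention)


@dataclass
class CohortSpec:
    """A cohort of phantoms with surrogate spirometry.

    Surrogate FEV1/FVC (% predicted) follow
    ``intercept - slope * f + N(0, noise_sd)`` clamped to (0, 130], so a
    higher lesion burden f lowers lung function, as structural disease
    does in patients.
    """

    n: int = 30
    burden_range: tuple[float, float] = (0.0, 0.15)
    intercept: float = 100.0
    slope: float = 300.0
    noise_sd: float = 5.0
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError(f"cohort size must be >= 3, got {self.n}")
        lo, hi = self.burden_range
        if not (0.0 <= lo < hi <= 0.3):
            raise ValidationError(f"degenerate or out-of-range burden range {self.burden_range}")


def generate_cohort(spec: CohortSpec | None = None) -> tuple[pd.DataFrame, list[tuple[CTVolume, LungMask, dict]]]:
    """Generate ``n`` phantoms with lesion burdens sampled in the range and
    surrogate spirometry; fully reproducible from the cohort seed."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.burden_range
    rows, phantoms = [], []
    for i in range(spec.n):
        f = float(rng.uniform(lo, hi))
        fev1 = float(np.clip(spec.intercept - spec.slope * f + rng.normal(0.0, spec.noise_sd), 0.1, 130.0))
        fvc = float(np.clip(spec.intercept - spec.slope * f + rng.normal(0.0, spec.noise_sd), 0.1, 130.0))
        child_seed = int(rng.integers(0, 2**31 - 1))
        pspec = PhantomSpec(**{**asdict(spec.phantom), "lesion_fraction": f, "seed": child_seed})
        vol, mask, meta = generate_phantom(pspec)
        rows.append(
            {
                "patient_id": f"P{i + 1:03d}",
                "lesion_fraction": f,
                "fev1_pct": fev1,
                "fvc_pct": fvc,
                "phantom_seed": child_seed,
            }
        )
        phantoms.append((vol, mask, meta))
    return pd.DataFrame(rows), phantoms
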