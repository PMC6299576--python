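"""Fixed and histogram-adapted threshold resolution and CT-density scores.

The CT-density score of a lung region at a threshold *t* is the percentage
of the region's voxels with attenuation >= *t* (inclusive): a score of 10
means 10% of the lung is at or above the threshold.  High-attenuating
structural changes (bronchial wall thickening, mucus plugging,
consolidation, atelectasis) raise this percentage.

Thresholds are either fixed HU values or adapted to the patient's own
density histogram (base MLD or Mode, plus a fixed HU offset or a multiple
of the SD, e.g. MLD + 1*SD).  Because an adapted threshold moves with any
affine change of the lung density distribution, adapted scores are exactly
invariant under inspiration-level effects that shift and spread the
histogram, which fixed thresholds are not.

Scores are always computed from the raw voxel values, never from binned
histograms, so no bin-edge artifact can move mass across the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import RegionError, UndefinedStatisticError, ValidationError
from .histogram import HistogramFeatures, compute_features
from .volume_io import CTVolume, LungMask


@dataclass(frozen=True)
class ThresholdSpec:
    """Declarative threshold rule.

    ``fixed``: an absolute HU value.  ``adapted``: ``base + offset + k*SD``
    where base is the region's MLD or Mode; exactly one of ``offset`` and
    ``k`` must be nonzero.
    """

    kind: str  # "fixed" | "adapted"
    value: float | None = None  # fixed only
    base: str | None = None  # adapted only: "MLD" | "Mode"
    offset: float = 0.0  # adapted: additive HU offset
    k: float = 0.0  # adapted: multiplier of SD

    def __post_init__(self) -> None:
        if self.kind == "fixed":
            if self.value is None or not np.isfinite(self.value):
                raise ValidationError("fixed threshold requires a finite HU value")
        elif self.kind == "adapted":
            if self.base is None or self.base.lower() not in ("mld", "mode"):
                raise ValidationError("adapted threshold requires base 'MLD' or 'Mode'")
            if (self.offset != 0) == (self.k != 0):
                raise ValidationError(
                    "adapted threshold must use exactly one of a nonzero HU offset or a nonzero SD multiplier"
                )
        else:
            raise ValidationError(f"threshold kind must be 'fixed' or 'adapted', got '{self.kind}'")

    @property
    def name(self) -> str:
        if self.kind == "fixed":
            return f"{self.value:+.0f}HU".replace("+-", "-")
        base = "MLD" if self.base.lower() == "mld" else "Mode"
        if self.k != 0:
            kk = int(self.k) if float(self.k).is_integer() else self.k
            return f"{base}+{kk}SD" if self.k > 0 else f"{base}{kk}SD"
        return f"{base}{self.offset:+.0f}"


def fixed(value: float) -> ThresholdSpec:
    return ThresholdSpec("fixed", value=value)


def adapted(base: str, offset: float = 0.0, k: float = 0.0) -> ThresholdSpec:
    return ThresholdSpec("adapted", base=base, offset=offset, k=k)


#: the threshold suite evaluated by default: fixed values from both printed
#: variants of the fixed set, plus the eight adapted definitions.
DEFAULT_SUITE: tuple[ThresholdSpec, ...] = (
    fixed(-300),
    fixed(-400),
    fixed(-500),
    fixed(-600),
    adapted("MLD", k=2),
    adapted("MLD", k=1),
    adapted("Mode", offset=500),
    adapted("Mode", offset=400),
    adapted("Mode", offset=300),
    adapted("Mode", k=3),
    adapted("Mode", k=2),
    adapted("Mode", k=1),
)

#: the best-performing threshold (strongest negative spirometry correlation)
BEST_SPEC = adapted("MLD", k=1)


@dataclass
class DensityScore:
    """Score record: % of region voxels at/above the resolved threshold."""

    region: str
    spec_name: str
    threshold: float  # resolved, HU
    score: float  # percent, 0..100
    n: int  # voxels in the region

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 100.0):
            raise ValidationError(f"score {self.score} outside [0, 100]")


def resolve_threshold(spec: ThresholdSpec, feats: HistogramFeatures) -> float:
    """Resolve a threshold rule to an HU value using the region's features."""
    if spec.kind == "fixed":
        return float(spec.value)
    if spec.k != 0 and feats.sd is None:
        raise UndefinedStatisticError(f"cannot resolve {spec.name}: SD undefined")
    return float(feats.base_value(spec.base) + spec.offset + spec.k * feats.sd)


def compute_score(
    vol: CTVolume,
    mask: LungMask,
    region: int | str,
    threshold: float,
    spec_name: str = "",
) -> DensityScore:
    """CT-density score: 100 * #{voxels >= threshold} / #{region voxels}."""
    if mask.shape != vol.shape:
        raise ValidationError(f"mask shape {mask.shape} does not match volume shape {vol.shape}")
    sel = mask.select(region)
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise RegionError(f"region '{region}' is empty")
    above = int(np.count_nonzero(vol.voxels[sel] >= threshold))
    return DensityScore(str(region), spec_name, float(threshold), 100.0 * above / n, n)


def score_suite(
    vol: CTVolume,
    mask: LungMask,
    feats: HistogramFeatures | None = None,
    specs: tuple[ThresholdSpec, ...] | list[ThresholdSpec] = DEFAULT_SUITE,
    regions: list[int | str] = ("whole",),
) -> pd.DataFrame:
    """Evaluate a threshold suite over one or more regions.

    Adapted thresholds are resolved from ``feats`` (whole-lung features by
    default), so every region of a patient is scored against the same
    resolved threshold per spec.
    """
    if not specs:
        raise ValidationError("threshold suite is empty")
    if feats is None:
        feats = compute_features(vol, mask, "whole")
    rows = []
    for spec in specs:
        thr = resolve_threshold(spec, feats)
        for region in regions:
            s = compute_score(vol, mask, region, thr, spec.name)
            rows.append(
                {
                    "region": str(region),
                    "spec": spec.name,
                    "threshold_hu": s.threshold,
                    "score_pct": s.score,
                    "n_voxels": s.n,
                }
            )
    return pd.DataFrame(rows)


def regional_scores(
    vol: CTVolume, mask: LungMask, spec: ThresholdSpec = BEST_SPEC
) -> dict[str, DensityScore]:
    """Upper, lower and whole-lung scores at one threshold.

    The threshold is resolved once from whole-lung features so that the
    upper-vs-lower contrast reflects regional disease rather than regional
    histogram shifts.  The whole-lung score is then exactly the
    voxel-count-weighted mean of the regional scores.
    """
    feats = compute_features(vol, mask, "whole")
    thr = resolve_threshold(spec, feats)
    return {
        "upper": compute_score(vol, mask, "upper", thr, spec.name),
        "lower": compute_score(vol, mask, "lower", thr, spec.name),
        "whole": compute_score(vol, mask, "whole", thr, spec.name),
    }
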