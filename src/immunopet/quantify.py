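"""SUV quantification, lesion filtering, table summaries, and H-score."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .kinetics import LesionTimeActivity

__all__ = [
    "ImageVolume",
    "VOIMask",
    "LesionRecord",
    "HscoreInput",
    "suv_from_activity",
    "suv_mean",
    "suv_max",
    "suv_peak",
    "filter_lesions",
    "hscore",
    "suv_table_summary",
    "round_half_up",
]

MIN_LESION_DIAMETER_CM = 2.0  # below this, partial-volume effects dominate


@dataclass(frozen=True)
class ImageVolume:
    """Small voxel grid of SUV values with isotropic-or-not spacing."""

    voxel_values: np.ndarray  # 3D, SUV
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxel_values, dtype=float)
        object.__setattr__(self, "voxel_values", v)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError("voxel_values must be a non-empty 3D grid")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass(frozen=True)
class VOIMask:
    """Boolean membership grid matching a volume's shape."""

    mask: np.ndarray
    label: str = ""
    nominal_volume_ml: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 3:
            raise ValueError("mask must be 3D")
        if not m.any():
            raise ValueError("mask selects no voxels")


@dataclass(frozen=True)
class LesionRecord:
    lesion_id: str
    tissue_class: str  # bone | soft-tissue | lung | lymph-node
    diameter_cm: float
    patient_id: str

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0:
            raise ValueError("diameter_cm must be positive")


@dataclass(frozen=True)
class HscoreInput:
    """Percentages of cells staining weakly (1+), moderately (2+), strongly (3+)."""

    pct_weak: float
    pct_moderate: float
    pct_strong: float

    def __post_init__(self) -> None:
        for name in ("pct_weak", "pct_moderate", "pct_strong"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.pct_weak + self.pct_moderate + self.pct_strong > 100 + 1e-9:
            raise ValueError("staining percentages sum to more than 100")


def suv_from_activity(conc_kbq_ml: float, injected_activity_mbq: float, body_weight_kg: float) -> float:
    """Standardized uptake value from an activity concentration.

    Concentration divided by injected activity per gram of body mass,
    assuming 1 g/mL tissue density:
    SUV = conc / (activity*1000 / (weight*1000)).
    """
    if injected_activity_mbq <= 0 or body_weight_kg <= 0:
        raise ValueError("injected activity and body weight must be positive")
    conc = np.asarray(conc_kbq_ml, dtype=float)
    if np.any(conc < 0):
        raise ValueError("activity concentration must be non-negative")
    out = conc / (injected_activity_mbq * 1000.0 / (body_weight_kg * 1000.0))
    return float(out) if out.ndim == 0 else out


def suv_mean(volume: ImageVolume, mask: VOIMask) -> float:
    if mask.mask.shape != volume.voxel_values.shape:
        raise ValueError("mask shape does not match volume")
    return float(volume.voxel_values[mask.mask].mean())


def suv_max(volume: ImageVolume, mask: VOIMask) -> float:
    if mask.mask.shape != volume.voxel_values.shape:
        raise ValueError("mask shape does not match volume")
    return float(volume.voxel_values[mask.mask].max())


def _sphere_offsets(volume: ImageVolume, sphere_volume_ml: float) -> np.ndarray:
    """Integer voxel offsets covered by a sphere of the given volume."""
    radius_mm = (3.0 * sphere_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    sz = np.asarray(volume.voxel_size_mm, dtype=float)
    half = np.maximum(np.floor(radius_mm / sz).astype(int), 0)
    grids = np.meshgrid(*(np.arange(-h, h + 1) for h in half), indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    dist = np.sqrt(((offs * sz) ** 2).sum(axis=1))
    return offs[dist <= radius_mm + 1e-9]

def suv_peak(volume: ImageVolume, mask: VOIMask, sphere_volume_ml: float = 1.0) -> float:
    """EANM-style SUVpeak: the maximum, over sphere centers inside the
    mask, of the mean SUV within a sphere of ``sphere_volume_ml``.

    Sphere voxels falling outside the mask still contribute (the sphere
    is placed in the image, constrained only by the grid bounds).  If
    the mask is smaller than the sphere, falls back to the mask mean
    with a warning.
    """
    vals = volume.voxel_values
    if mask.mask.shape != vals.shape:
        raise ValueError("mask shape does not match volume")
    offs = _sphere_offsets(volume, sphere_volume_ml)
    if int(mask.mask.sum()) < offs.shape[0]:
        warnings.warn(
            f"VOI '{mask.label}' smaller than the {sphere_volume_ml} mL sphere; "
            "falling back to mask mean",
            stacklevel=2,
        )
        return suv_mean(volume, mask)
    centers = np.argwhere(mask.mask)
    shape = np.asarray(vals.shape)
    best = -np.inf
    for c in centers:
        pos = c + offs
        inside = np.all((pos >= 0) & (pos < shape), axis=1)
        pos = pos[inside]
        best = max(best, float(vals[pos[:, 0], pos[:, 1], pos[:, 2]].mean()))
    return best


def filter_lesions(records: list[LesionRecord], min_diameter_cm: float = MIN_LESION_DIAMETER_CM) -> list[LesionRecord]:
    """Keep lesions at least ``min_diameter_cm`` across (inclusive); order preserved."""
    return [r for r in records if r.diameter_cm >= min_diameter_cm]


def hscore(inp: HscoreInput) -> float:
    """Intensity-weighted staining score on the 0-300 scale:
    1*(% weak) + 2*(% moderate) + 3*(% strong)."""
    return 1.0 * inp.pct_weak + 2.0 * inp.pct_moderate + 3.0 * inp.pct_strong


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (15.66 -> 15.7), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def suv_table_summary(
    lesions: list[LesionTimeActivity], administration: str, *, decimals: int = 1
) -> dict[str, float]:
    """Min and max SUVpeak over all lesions and time points of one
    administration, excluding BLQ/NA entries, rounded half-up."""
    if administration not in ("first", "second"):
        raise ValueError("administration must be 'first' or 'second'")
    values: list[float] = []
    for tac in lesions:
        if tac.administration != administration:
            continue
        values.extend(v for v in tac.suv if np.isfinite(v))
    if not values:
        raise ValueError(f"no quantifiable SUV values for administration {administration!r}")
    return {
        "min": round_half_up(min(values), decimals),
        "max": round_half_up(max(values), decimals),
    }
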