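"""Per-scan lung densitometry: HAA%, LAA-950 emphysema %, and CT-derived TLC.

High attenuation areas (HAA) are lung voxels with HU in [-600, -250] —
hazy ground-glass and reticular material.  Low attenuation areas below
-950 HU (LAA-950) are the standard CT emphysema metric.  Total lung
capacity is the physical volume of the lung mask.  Intrapulmonary vessels
are kept *inside* the lung mask; blood attenuation (~+40 HU) lies far
above the HAA window, so vessels drop out of the numerator by the HU
window rather than by mask exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import ball

from .phantom import HAA_WINDOW, CTVolume

EMPH_THRESHOLD_HU = -950.0

#: HU below this are treated as air-like when seeding the lung mask.
AIR_THRESHOLD_HU = -320.0


class LungSegmentationError(RuntimeError):
    """Raised when no lung-like region can be found in a volume."""


class MaskError(ValueError):
    """Raised for empty or misaligned lung masks."""


@dataclass
class LungMask:
    """Binary lung labelling aligned to a CTVolume grid."""

    mask: np.ndarray
    provenance: str = "segmented"  # or "ground_truth"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise MaskError(f"lung mask must be 3-D, got ndim={self.mask.ndim}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class DensitometryResult:
    haa_fraction: float
    emph_fraction: float
    tlc_l: float
    lung_voxel_count: int
    hu_window: tuple[float, float] = HAA_WINDOW
    emph_threshold_hu: float = EMPH_THRESHOLD_HU

    @property
    def haa_pct(self) -> float:
        return 100.0 * self.haa_fraction

    @property
    def emph_pct(self) -> float:
        return 100.0 * self.emph_fraction


def _check_alignment(vol: CTVolume, mask: LungMask) -> np.ndarray:
    m = mask.mask
    if m.shape != vol.voxels.shape:
        raise MaskError(
            f"mask shape {m.shape} does not match volume shape {vol.voxels.shape}"
        )
    if not m.any():
        raise MaskError("empty lung mask")
    return m


def segment_lungs(
    vol: CTVolume,
    air_threshold_hu: float = AIR_THRESHOLD_HU,
    min_component_ratio: float = 0.3,
    closing_radius: int = 2,
) -> LungMask:
    """Segment the lung fields of a chest CT volume.

    Air-like voxels (HU below ``air_threshold_hu``) are grouped into
    connected components; components touching the grid border (outside
    air, trachea reaching the scan edge) are discarded, the largest one
    or two remaining components are kept, and morphological closing plus
    hole filling re-absorbs interior vessels and denser ground-glass that
    the air threshold missed.

    Raises :class:`LungSegmentationError` when nothing lung-like remains
    — never returns an empty mask silently.
    """
    air = vol.voxels < air_threshold_hu
    labels, n = ndi.label(air)
    if n == 0:
        raise LungSegmentationError("no lung detected: no sub-threshold voxels")

    border = np.zeros_like(air)
    for ax in range(3):
        sl = [slice(None)] * 3
        for end in (0, -1):
            sl[ax] = end
            border[tuple(sl)] = True
    border_labels = np.unique(labels[border & air])
    sizes = ndi.sum_labels(air, labels, index=np.arange(1, n + 1))
    keep = np.ones(n, dtype=bool)
    keep[border_labels[border_labels > 0] - 1] = False
    if not keep.any() or sizes[keep].max() == 0:
        raise LungSegmentationError(
            "no lung detected: every air component touches the volume border"
        )
    largest = sizes[keep].max()
    order = np.argsort(sizes)[::-1]
    selected = [i for i in order if keep[i] and sizes[i] >= min_component_ratio * largest]
    selected = selected[:2]
    mask = np.isin(labels, [i + 1 for i in selected])

    if closing_radius > 0:
        mask = ndi.binary_closing(mask, structure=ball(closing_radius))
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():  # pragma: no cover - defensive
        raise LungSegmentationError("no lung detected after morphology")
    return LungMask(mask=mask, provenance="segmented")


def compute_haa(
    vol: CTVolume, mask: LungMask, window: tuple[float, float] = HAA_WINDOW
) -> float:
    """Fraction of lung-mask voxels with HU in ``window`` (inclusive ends)."""
    low, high = window
    if low > high:
        raise ValueError(f"inverted HU window: low {low} > high {high}")
    m = _check_alignment(vol, mask)
    hu = vol.voxels[m]
    return float(((hu >= low) & (hu <= high)).mean())


def compute_emphysema(
    vol: CTVolume, mask: LungMask, threshold: float = EMPH_THRESHOLD_HU
) -> float:
    """Fraction of lung-mask voxels strictly below ``threshold`` HU (LAA)."""
    m = _check_alignment(vol, mask)
    return float((vol.voxels[m] < threshold).mean())


def compute_tlc(vol: CTVolume, mask: LungMask) -> float:
    """Lung volume in litres: mask voxel count times voxel volume."""
    if any(s <= 0 for s in vol.spacing_mm):
        raise ValueError(f"nonpositive voxel spacing {vol.spacing_mm}")
    m = _check_alignment(vol, mask)
    return float(m.sum()) * vol.voxel_volume_mm3 / 1e6


def run_densitometry(
    vol: CTVolume,
    mask: LungMask | None = None,
    window: tuple[float, float] = HAA_WINDOW,
    emph_threshold: float = EMPH_THRESHOLD_HU,
) -> DensitometryResult:
    """Full densitometry panel; segments the lungs if no mask is given."""
    if mask is None:
        mask = segment_lungs(vol)
    return DensitometryResult(
        haa_fraction=compute_haa(vol, mask, window),
        emph_fraction=compute_emphysema(vol, mask, emph_threshold),
        tlc_l=compute_tlc(vol, mask),
        lung_voxel_count=mask.voxel_count,
        hu_window=window,
        emph_threshold_hu=emph_threshold,
    )
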