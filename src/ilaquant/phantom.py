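"""Synthetic chest-CT phantoms with known ground-truth HU composition.

A phantom is a voxel grid of Hounsfield Units built from a small set of
materials: soft tissue filling the grid (~+40 HU), two ellipsoidal lung
fields of aerated parenchyma (~-850 HU), an airway (trachea) cylinder of
air reaching the top of the grid, and — inside the lungs — ground-glass
blobs placed in the high-attenuation window [-600, -250] HU, emphysema
blobs below -950 HU, and vessel cylinders at blood attenuation (~+40 HU).

The geometry is deliberately schematic: lung densitometry depends only on
the HU histogram inside the lung mask, so the contract of the generator is
the *composition* (which fraction of lung voxels each material occupies),
not anatomy.  Requested fractions are honoured exactly at the voxel level:
the last blob of each material is trimmed so the converted voxel count
matches the target, and the returned ground truth is obtained by counting
labelled voxels rather than echoing the request.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

HU_MIN = -1024
HU_MAX = 3071

#: HAA window used throughout: lung voxels with HU inside it count as
#: high attenuation areas.
HAA_WINDOW = (-600.0, -250.0)

# Label codes for PhantomTruth.label_map
BODY = 0
PARENCHYMA = 1
GGO = 2
EMPHYSEMA = 3
VESSEL = 4
AIRWAY = 5

LABEL_NAMES = {
    BODY: "body",
    PARENCHYMA: "parenchyma",
    GGO: "ggo",
    EMPHYSEMA: "emphysema",
    VESSEL: "vessel",
    AIRWAY: "airway",
}


class PhantomSpecError(ValueError):
    """Raised when a PhantomSpec violates its invariants."""


class VolumeFormatError(ValueError):
    """Raised when a volume file cannot be interpreted as a 3-D HU grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic chest-CT phantom.

    Fractions are fractions of *lung* voxels; their sum must not exceed 1.
    ``noise_sd`` is the SD of additive Gaussian HU noise, a stand-in for
    the image-noise effect of increased body mass.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body_hu: float = 40.0
    lung_base_hu: float = -850.0
    ggo_fraction: float = 0.0
    ggo_hu_range: tuple[float, float] = HAA_WINDOW
    emph_fraction: float = 0.0
    emph_hu_range: tuple[float, float] = (-1000.0, -960.0)
    vessel_fraction: float = 0.02
    vessel_hu: float = 40.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        shape = tuple(int(s) for s in self.grid_shape)
        if len(shape) != 3 or any(s < 16 for s in shape):
            raise PhantomSpecError(
                f"grid_shape {self.grid_shape} too small: need >= 16 voxels per axis "
                "to place a lung"
            )
        if any(s <= 0 for s in self.voxel_spacing):
            raise PhantomSpecError("voxel_spacing components must be > 0")
        fr = (self.ggo_fraction, self.emph_fraction, self.vessel_fraction)
        if any(f < 0 for f in fr):
            raise PhantomSpecError("material fractions must be >= 0")
        if sum(fr) > 1.0:
            raise PhantomSpecError(
                f"impossible fraction combination: ggo+emphysema+vessel = {sum(fr):.3f} > 1"
            )
        lo, hi = self.ggo_hu_range
        if not (HAA_WINDOW[0] <= lo <= hi <= HAA_WINDOW[1]):
            raise PhantomSpecError(
                f"ggo_hu_range {self.ggo_hu_range} must lie within {HAA_WINDOW}"
            )
        elo, ehi = self.emph_hu_range
        if not (HU_MIN <= elo <= ehi < -950.0):
            raise PhantomSpecError(
                f"emph_hu_range {self.emph_hu_range} must lie in [{HU_MIN}, -950)"
            )
        for hu in (self.body_hu, self.lung_base_hu, self.vessel_hu):
            if not (HU_MIN <= hu <= HU_MAX):
                raise PhantomSpecError(f"HU value {hu} outside [{HU_MIN}, {HU_MAX}]")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("grid_shape", "voxel_spacing", "ggo_hu_range", "emph_hu_range"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        kwargs = dict(d)
        for k in ("grid_shape", "voxel_spacing", "ggo_hu_range", "emph_hu_range"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


@dataclass
class CTVolume:
    """A calibrated HU voxel grid with physical spacing in mm."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"CTVolume requires a 3-D array, got ndim={self.voxels.ndim}"
            )
        if any(s <= 0 for s in self.spacing_mm):
            raise VolumeFormatError(f"spacing must be > 0, got {self.spacing_mm}")
        if self.voxels.size and (
            self.voxels.min() < HU_MIN or self.voxels.max() > HU_MAX
        ):
            raise VolumeFormatError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: "
                f"range [{self.voxels.min()}, {self.voxels.max()}]"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom.

    Fractions are obtained by counting labelled voxels, so rasterization
    effects of blob placement are already absorbed.
    """

    lung_mask: np.ndarray
    label_map: np.ndarray
    true_haa_fraction: float
    true_emph_fraction: float
    true_lung_volume_l: float


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _lung_masks(shape) -> tuple[np.ndarray, np.ndarray]:
    nx, ny, nz = shape
    semi = (0.15 * nx, 0.28 * ny, 0.38 * nz)
    left = _ellipsoid_mask(shape, (0.30 * nx, 0.50 * ny, 0.50 * nz), semi)
    right = _ellipsoid_mask(shape, (0.70 * nx, 0.50 * ny, 0.50 * nz), semi)
    return left, right


def _trachea_mask(shape) -> np.ndarray:
    nx, ny, nz = shape
    r = max(1.2, 0.02 * min(nx, ny))
    grids = np.ogrid[0:nx, 0:ny, 0:nz]
    dist2 = (grids[0] - 0.5 * nx) ** 2 + (grids[1] - 0.5 * ny) ** 2
    cyl = dist2 <= r**2
    zmask = np.zeros(nz, dtype=bool)
    zmask[int(0.55 * nz):] = True  # reaches the top z-face of the grid
    return cyl & zmask[None, None, :]


def _place_blobs(
    rng: np.random.Generator,
    label_map: np.ndarray,
    target_count: int,
    new_label: int,
    r_range: tuple[int, int],
) -> None:
    """Convert exactly ``target_count`` parenchyma voxels into ``new_label``
    by stamping random spheres centred on parenchyma voxels; the final
    sphere is trimmed (nearest voxels kept) to hit the count exactly."""
    if target_count <= 0:
        return
    shape = label_map.shape
    remaining = target_count
    while remaining > 0:
        candidates = np.flatnonzero(label_map == PARENCHYMA)
        if candidates.size == 0:
            break
        center = np.unravel_index(rng.choice(candidates), shape)
        r = int(rng.integers(r_range[0], r_range[1] + 1))
        sl = tuple(
            slice(max(0, c - r), min(s, c + r + 1)) for c, s in zip(center, shape)
        )
        grids = np.ogrid[sl]
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        sphere = (dist2 <= r**2) & (label_map[sl] == PARENCHYMA)
        idx = np.nonzero(sphere)
        n_new = idx[0].size
        if n_new > remaining:
            order = np.argsort(dist2[sphere], kind="stable")[:remaining]
            idx = tuple(ax[order] for ax in idx)
            n_new = remaining
        label_map[sl][idx] = new_label
        remaining -= n_new


def _place_vessels(
    rng: np.random.Generator,
    label_map: np.ndarray,
    lung: np.ndarray,
    target_count: int,
) -> None:
    """Cylindrical vessel segments between random interior points of one lung."""
    if target_count <= 0:
        return
    shape = label_map.shape
    coords = np.argwhere(lung)
    remaining = target_count
    guard = 0
    while remaining > 0 and guard < 10_000:
        guard += 1
        p0, p1 = coords[rng.integers(0, len(coords), size=2)].astype(float)
        if np.all(p0 == p1):
            continue
        r = float(rng.integers(1, 3))
        lo = np.maximum(np.floor(np.minimum(p0, p1)) - r - 1, 0).astype(int)
        hi = np.minimum(np.ceil(np.maximum(p0, p1)) + r + 2, shape).astype(int)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        grids = np.meshgrid(
            *[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij", sparse=True
        )
        d = p1 - p0
        # distance from voxel centre to the segment p0-p1
        ap = [g - c for g, c in zip(grids, p0)]
        t = sum(a * b for a, b in zip(ap, d)) / float(d @ d)
        t = np.clip(t, 0.0, 1.0)
        dist2 = sum((a - t * b) ** 2 for a, b in zip(ap, d))
        cyl = (dist2 <= r**2) & (label_map[sl] == PARENCHYMA)
        idx = np.nonzero(cyl)
        n_new = idx[0].size
        if n_new == 0:
            continue
        if n_new > remaining:
            order = np.argsort(dist2[cyl], kind="stable")[:remaining]
            idx = tuple(ax[order] for ax in idx)
            n_new = remaining
        label_map[sl][idx] = VESSEL
        remaining -= n_new


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Generate a phantom volume and its voxel-counted ground truth.

    Deterministic for a given ``spec.seed``; placement order is vessels,
    emphysema, ground-glass, then additive noise, all from one RNG stream.
    """
    spec.validate()
    shape = tuple(int(s) for s in spec.grid_shape)
    rng = np.random.default_rng(spec.seed)

    label_map = np.full(shape, BODY, dtype=np.uint8)
    left, right = _lung_masks(shape)
    lung = left | right
    label_map[lung] = PARENCHYMA
    trachea = _trachea_mask(shape) & ~lung
    label_map[trachea] = AIRWAY

    n_lung = int(lung.sum())
    _place_vessels(rng, label_map, lung, round(spec.vessel_fraction * n_lung))
    rmax = max(3, min(shape) // 16)
    _place_blobs(
        rng, label_map, round(spec.emph_fraction * n_lung), EMPHYSEMA, (2, rmax)
    )
    _place_blobs(rng, label_map, round(spec.ggo_fraction * n_lung), GGO, (2, rmax))

    hu = np.full(shape, spec.body_hu, dtype=np.float64)
    hu[label_map == PARENCHYMA] = spec.lung_base_hu
    hu[label_map == AIRWAY] = -1000.0
    hu[label_map == VESSEL] = spec.vessel_hu
    n_emph = int((label_map == EMPHYSEMA).sum())
    hu[label_map == EMPHYSEMA] = rng.uniform(*spec.emph_hu_range, size=n_emph)
    n_ggo = int((label_map == GGO).sum())
    hu[label_map == GGO] = rng.uniform(*spec.ggo_hu_range, size=n_ggo)
    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, size=shape)
    hu = np.clip(np.rint(hu), HU_MIN, HU_MAX).astype(np.int16)

    vol = CTVolume(voxels=hu, spacing_mm=tuple(float(s) for s in spec.voxel_spacing))
    voxel_l = vol.voxel_volume_mm3 / 1e6
    truth = PhantomTruth(
        lung_mask=lung,
        label_map=label_map,
        true_haa_fraction=n_ggo / n_lung,
        true_emph_fraction=n_emph / n_lung,
        true_lung_volume_l=n_lung * voxel_l,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a volume as int16 NIfTI with spacing in the affine."""
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.int16), affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))


def write_labels(labels: np.ndarray, spacing_mm, path: str | Path) -> None:
    """Write an integer label map as a companion NIfTI volume."""
    affine = np.diag(list(spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.uint8), affine)
    img.header.set_zooms(spacing_mm)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI volume, validating dimensionality and spacing metadata."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel's message is adequate
        raise VolumeFormatError(f"cannot read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3-D volume, got {data.ndim}-D data"
        )
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(
            f"{path}: missing or invalid spacing metadata (header zooms = {zooms})"
        )
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return CTVolume(
        voxels=data, spacing_mm=tuple(float(z) for z in zooms), origin=origin
    )
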