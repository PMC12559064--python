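"""Volume and mask I/O for the CTPA perfusion pipeline.

All downstream analyses operate on one coherent voxel grid: the CT volume
in Hounsfield units plus binary masks for the left lung, right lung and
pulmonary veins on exactly the same grid.  Nothing here reorients or
resamples — masks must come from the same geometry as the CT.

Physical coordinates use the voxel-center convention: the center of voxel
``(i, j, k)`` sits at ``(i + 0.5, j + 0.5, k + 0.5) * spacing`` mm.  All
distance computations in the package use these physical coordinates because
CTPA voxels are anisotropic (sub-millimetre in-plane, ~0.9 mm slices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "QCWarning",
    "CTVolume",
    "SegmentationSet",
    "LungSamples",
    "read_ct_volume",
    "read_segmentation",
    "write_volume",
    "write_labels",
    "extract_lung_samples",
    "voxel_centers_mm",
    "DEFAULT_CLIP_RANGE",
]

#: Default analysis window.  Retains hyperemic parenchyma and
#: intrapulmonary vessels; excludes bone/metal spill-in.
DEFAULT_CLIP_RANGE: tuple[float, float] = (-1024.0, 100.0)

#: Values outside this window are physically implausible for CT and are
#: flagged as suspect in the QC report.
_PLAUSIBLE_HU = (-1100.0, 3100.0)

_MIN_LUNG_VOXELS = 1000


class QCWarning(UserWarning):
    """Soft quality-control finding; recorded in patient reports, never fatal."""


@dataclass(frozen=True)
class CTVolume:
    """A 3-D attenuation grid in Hounsfield units.

    Parameters
    ----------
    data
        3-D array of HU values.
    spacing
        Per-axis voxel size in mm; strictly positive.
    orientation_tag
        Label identifying the axis convention (e.g. ``"RAS"``); purely
        informational, the grid is never reoriented.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    orientation_tag: str = "unknown"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(
                f"expected 3 spatial dimensions, got shape {data.shape}"
            )
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(data)):
            raise ValueError("CT volume contains non-finite values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def qc_flags(self) -> list[str]:
        """Return QC findings (suspect attenuation values) without raising."""
        flags = []
        lo, hi = _PLAUSIBLE_HU
        n_bad = int(np.count_nonzero((self.data < lo) | (self.data > hi)))
        if n_bad:
            flags.append(f"{n_bad} voxels outside plausible HU range [{lo}, {hi}]")
        return flags


@dataclass(frozen=True)
class SegmentationSet:
    """Binary masks for both lungs and the pulmonary veins on the CT grid."""

    lung_left: np.ndarray
    lung_right: np.ndarray
    veins: np.ndarray
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        for name in ("lung_left", "lung_right", "veins"):
            mask = np.asarray(getattr(self, name), dtype=bool)
            if mask.shape != tuple(self.grid_shape):
                raise ValueError(
                    f"mask grid differs from CT grid: {name} has shape "
                    f"{mask.shape}, CT grid is {tuple(self.grid_shape)}"
                )
            object.__setattr__(self, name, mask)
        if np.any(self.lung_left & self.lung_right):
            raise ValueError("lung masks overlap")
        for name in ("lung_left", "lung_right"):
            n = int(np.count_nonzero(getattr(self, name)))
            if n == 0:
                raise ValueError(f"empty lung mask: {name}")
            if n < _MIN_LUNG_VOXELS:
                warnings.warn(
                    f"{name} has only {n} voxels (< {_MIN_LUNG_VOXELS}); "
                    "analysis may be unreliable",
                    QCWarning,
                    stacklevel=2,
                )

    def lung(self, side: str) -> np.ndarray:
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return self.lung_left if side == "left" else self.lung_right

    @property
    def lungs(self) -> np.ndarray:
        """Union of both lung masks."""
        return self.lung_left | self.lung_right


@dataclass(frozen=True)
class LungSamples:
    """HU values and physical voxel-center coordinates for one lung."""

    side: str
    values: np.ndarray        # (n,) HU
    coords_mm: np.ndarray     # (n, 3) physical mm
    clip_range: tuple[float, float]
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if len(self.values) != len(self.coords_mm):
            raise ValueError("values and coords_mm length mismatch")

    def __len__(self) -> int:
        return len(self.values)


def voxel_centers_mm(indices: np.ndarray, spacing) -> np.ndarray:
    """Physical coordinates (mm) of voxel centers for an (n, 3) index array."""
    return (np.asarray(indices, dtype=float) + 0.5) * np.asarray(spacing, dtype=float)


def _default_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_ct_volume(path) -> CTVolume:
    """Read a NIfTI CT volume; values are taken as stored (assumed HU)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"CT volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3 spatial dimensions, got {data.ndim} in {path}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing {zooms} in {path}")
    try:
        tag = "".join(nib.aff2axcodes(img.affine))
    except Exception:  # pragma: no cover - malformed affine
        tag = "unknown"
    return CTVolume(data=np.asarray(data, dtype=np.float32), spacing=zooms,
                    orientation_tag=tag)


def write_volume(volume: CTVolume, path) -> None:
    """Write a CTVolume to NIfTI with a diagonal affine built from its spacing."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32),
                          _default_affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_labels(labels: np.ndarray, spacing, path) -> None:
    """Write an integer label volume (e.g. masks, compartment labels) to NIfTI."""
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.uint8), _default_affine(spacing))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def read_segmentation(paths, volume: CTVolume, label_map: dict | None = None
                      ) -> SegmentationSet:
    """Read segmentation masks and bind them to the CT grid.

    Parameters
    ----------
    paths
        Either a mapping ``{"lung_left": path, "lung_right": path,
        "veins": path}`` of binary-mask files, or a single path to a
        multi-label volume, in which case ``label_map`` gives the integer
        label of each structure.
    volume
        The CT volume whose grid the masks must match.
    label_map
        Required for multi-label input, e.g.
        ``{"lung_left": 1, "lung_right": 2, "veins": 3}``.
    """
    required = ("lung_left", "lung_right", "veins")
    masks: dict[str, np.ndarray] = {}
    if isinstance(paths, (str, Path)):
        if label_map is None:
            raise ValueError("label_map required for a multi-label segmentation file")
        missing = [k for k in required if k not in label_map]
        if missing:
            raise ValueError(f"label_map missing entries: {missing}")
        img = nib.load(str(paths))
        data = np.asanyarray(img.dataobj)
        if data.shape != volume.shape:
            raise ValueError(
                f"mask grid differs from CT grid: {data.shape} vs {volume.shape}"
            )
        for key in required:
            masks[key] = data == int(label_map[key])
    else:
        for key in required:
            if key not in paths:
                raise ValueError(f"missing segmentation for {key}")
            img = nib.load(str(paths[key]))
            data = np.asanyarray(img.dataobj)
            if data.shape != volume.shape:
                raise ValueError(
                    f"mask grid differs from CT grid: {key} has shape "
                    f"{data.shape}, CT grid is {volume.shape}"
                )
            masks[key] = data > 0
    return SegmentationSet(grid_shape=volume.shape, **masks)


def extract_lung_samples(volume: CTVolume, seg: SegmentationSet, side: str,
                         clip_range: tuple[float, float] = DEFAULT_CLIP_RANGE
                         ) -> LungSamples:
    """Extract HU values + physical coordinates of one lung's in-window voxels.

    Voxels with attenuation outside ``clip_range`` are dropped (their count
    is recorded); losing more than 20% of a lung this way suggests a
    mis-calibrated volume and raises a :class:`QCWarning`.
    """
    mask = seg.lung(side)
    if mask.shape != volume.shape:
        raise ValueError("segmentation grid differs from CT grid")
    idx = np.argwhere(mask)
    vals = volume.data[mask].astype(float)
    lo, hi = clip_range
    keep = (vals >= lo) & (vals <= hi)
    n_clipped = int(len(vals) - np.count_nonzero(keep))
    if len(vals) and n_clipped > 0.2 * len(vals):
        warnings.warn(
            f"clip range {clip_range} removes {n_clipped}/{len(vals)} voxels "
            f"of {side} lung — possible mis-calibrated volume",
            QCWarning,
            stacklevel=2,
        )
    coords = voxel_centers_mm(idx[keep], volume.spacing)
    return LungSamples(side=side, values=vals[keep], coords_mm=coords,
                       clip_range=(float(lo), float(hi)), n_clipped=n_clipped)
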