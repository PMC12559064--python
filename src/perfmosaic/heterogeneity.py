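"""Spatial heterogeneity of attenuation compartments.

Mosaic perfusion scatters hyperemic and oligemic patches through the lung.
This module quantifies that dispersion as the Shannon entropy (bits) of a
32 x 32 x 32 histogram of the physical coordinates of a compartment's
voxels, computed per lung over the lung's bounding box and averaged across
the two lungs.  A compact compartment concentrates its mass in few bins
(low entropy, at most 15 bits = log2(32^3)); a scattered one spreads it.

Only the hyperemic (high) and normal (medium) compartments are headline
metrics; oligemic entropy can be computed on request.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attenuation import CompartmentMask
from .imaging import SegmentationSet, voxel_centers_mm

__all__ = [
    "SpatialHistogram",
    "HeterogeneityResult",
    "spatial_histogram",
    "shannon_entropy",
    "heterogeneity_metrics",
    "DEFAULT_BINS",
]

DEFAULT_BINS = 32


@dataclass(frozen=True)
class SpatialHistogram:
    """3-D occupancy histogram of voxel coordinates inside a bounding box."""

    counts: np.ndarray            # (bins, bins, bins) integer
    bounds: np.ndarray            # (3, 2) per-axis [min, max] mm
    n_total: int

    @property
    def bins(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class HeterogeneityResult:
    entropy_high_left: float
    entropy_high_right: float
    entropy_high_mean: float
    entropy_medium_left: float
    entropy_medium_right: float
    entropy_medium_mean: float
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "entropy_high_left": self.entropy_high_left,
            "entropy_high_right": self.entropy_high_right,
            "entropy_high_mean": self.entropy_high_mean,
            "entropy_medium_left": self.entropy_medium_left,
            "entropy_medium_right": self.entropy_medium_right,
            "entropy_medium_mean": self.entropy_medium_mean,
        }


def spatial_histogram(coords_mm: np.ndarray, box: np.ndarray,
                      bins: int = DEFAULT_BINS) -> SpatialHistogram:
    """Bin 3-D coordinates into an equal-width per-axis histogram.

    Bins are half-open except the last, which includes the upper box
    boundary; coordinates outside the box are ignored.
    """
    box = np.asarray(box, dtype=float).reshape(3, 2)
    if np.any(box[:, 1] <= box[:, 0]):
        raise ValueError(f"binning box must have positive extent, got {box.tolist()}")
    coords = np.asarray(coords_mm, dtype=float).reshape(-1, 3)
    if len(coords) == 0:
        counts = np.zeros((bins, bins, bins), dtype=np.int64)
        return SpatialHistogram(counts=counts, bounds=box, n_total=0)
    counts, _ = np.histogramdd(coords, bins=bins, range=[tuple(b) for b in box])
    counts = counts.astype(np.int64)
    return SpatialHistogram(counts=counts, bounds=box, n_total=int(counts.sum()))


def shannon_entropy(hist: SpatialHistogram) -> float:
    """Shannon entropy of the histogram in bits; 0 for empty or single-bin."""
    if hist.n_total == 0:
        return 0.0
    c = hist.counts[hist.counts > 0].astype(float)
    p = c / hist.n_total
    return float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 avoids returning -0.0


def _lung_box_mm(lung_mask: np.ndarray, spacing) -> np.ndarray:
    """Axis-aligned bounding box (mm) of a lung mask: full voxel extents."""
    idx = np.argwhere(lung_mask)
    sp = np.asarray(spacing, dtype=float)
    lo = idx.min(axis=0) * sp
    hi = (idx.max(axis=0) + 1) * sp
    return np.stack([lo, hi], axis=1)


def heterogeneity_metrics(mask: CompartmentMask, seg: SegmentationSet,
                          spacing, bins: int = DEFAULT_BINS,
                          include_low: bool = False):
    """Per-lung compartment entropies and their across-lung means.

    For each lung the binning box is that lung's bounding box in physical
    mm, which makes the entropy invariant to where the lung sits in the
    scanner.  An empty compartment in a lung is maximally homogeneous:
    entropy 0 with a flag.

    Returns a :class:`HeterogeneityResult`; with ``include_low=True``, a
    ``(result, oligemic_entropies)`` pair where the second element maps
    ``{"left": H, "right": H, "mean": H}``.
    """
    spacing = np.asarray(spacing, dtype=float)
    per: dict[tuple[str, str], float] = {}
    flags: list[str] = []
    comps = {"high": 3, "medium": 2}
    if include_low:
        comps["low"] = 1
    for side in ("left", "right"):
        lung = seg.lung(side)
        box = _lung_box_mm(lung, spacing)
        for name, code in comps.items():
            sel = lung & (mask.labels == code)
            idx = np.argwhere(sel)
            if len(idx) == 0:
                per[(name, side)] = 0.0
                flags.append(f"{name} compartment empty in {side} lung")
                continue
            hist = spatial_histogram(voxel_centers_mm(idx, spacing), box, bins=bins)
            per[(name, side)] = shannon_entropy(hist)

    result = HeterogeneityResult(
        entropy_high_left=per[("high", "left")],
        entropy_high_right=per[("high", "right")],
        entropy_high_mean=(per[("high", "left")] + per[("high", "right")]) / 2.0,
        entropy_medium_left=per[("medium", "left")],
        entropy_medium_right=per[("medium", "right")],
        entropy_medium_mean=(per[("medium", "left")] + per[("medium", "right")]) / 2.0,
        flags=tuple(flags),
    )
    if include_low:
        low = {"left": per[("low", "left")], "right": per[("low", "right")]}
        low["mean"] = (low["left"] + low["right"]) / 2.0
        return result, low
    return result
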