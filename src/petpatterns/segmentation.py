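"""Lesion delineation on SUV volumes.

Implements the six delineation methods used for metabolic tumor volume
(MTV) quantification in FDG-PET of lymphoma:

* fixed SUV thresholds at 4.0 and 2.5 (``SUV4.0``, ``SUV2.5``);
* relative thresholds at 41% of the lesion maximum (``PC41MAX``) and 50%
  of the lesion SUVpeak (``PC50PEAK``);
* majority votes over the four base methods keeping voxels selected by at
  least 2 (``MV2``) or at least 3 (``MV3``) of them.

All thresholds are inclusive: a voxel whose SUV equals the threshold is
part of the lesion. Connected components use 26-neighborhood connectivity
by default (configurable to 6). SUVpeak is the maximum, over 1-mL spheres
centered at lesion voxels, of the mean SUV of voxels whose centers fall
inside the sphere — the common PERCIST-style convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import SuvVolume

__all__ = [
    "BASE_METHODS",
    "ALL_METHODS",
    "LesionMask",
    "LesionMetrics",
    "EmptySegmentationError",
    "RelativeThresholdUndefinedError",
    "apply_fixed_threshold",
    "compute_suv_peak",
    "segment_relative",
    "majority_vote",
    "exclude_regions",
    "compute_metrics",
    "segment_all_methods",
    "select_mask",
]

BASE_METHODS = ("SUV4.0", "SUV2.5", "PC41MAX", "PC50PEAK")
ALL_METHODS = BASE_METHODS + ("MV2", "MV3")


class EmptySegmentationError(ValueError):
    """The requested delineation contains no voxels."""


class RelativeThresholdUndefinedError(ValueError):
    """A relative threshold cannot be derived (no lesion region at the seed)."""


@dataclass
class LesionMask:
    """A boolean lesion delineation congruent with its SUV volume."""

    voxels: np.ndarray
    lesion_id: str = "lesion"
    method: str = "SUV4.0"
    fully_excluded: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("lesion mask must be a 3-D boolean grid")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not self.voxels.any()


@dataclass
class LesionMetrics:
    """Quantitative lesion summary: SUVmax, SUVpeak and MTV in millilitres."""

    suv_max: float
    suv_peak: float
    mtv_ml: float

    def __post_init__(self) -> None:
        if self.suv_peak > self.suv_max + 1e-12:
            raise ValueError("suv_peak cannot exceed suv_max")
        if self.mtv_ml < 0:
            raise ValueError("mtv_ml must be non-negative")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def _component_at(binary: np.ndarray, index, connectivity: int) -> np.ndarray:
    """Connected component of a boolean grid containing ``index`` (may be empty)."""
    labels, _ = ndimage.label(binary, structure=_structure(connectivity))
    lab = labels[tuple(index)]
    if lab == 0:
        return np.zeros_like(binary, dtype=bool)
    return labels == lab


def apply_fixed_threshold(
    volume: SuvVolume,
    threshold: float,
    seed_point,
    *,
    connectivity: int = 26,
    lesion_id: str = "lesion",
    method: str | None = None,
) -> LesionMask:
    """Grow the connected region with SUV >= ``threshold`` from ``seed_point``.

    Raises
    ------
    EmptySegmentationError
        If the seed voxel itself lies below the threshold.
    """
    seed_point = tuple(int(i) for i in seed_point)
    if not volume.contains_index(seed_point):
        raise IndexError(f"seed point {seed_point} outside grid {volume.shape}")
    if volume.values[seed_point] < threshold:
        raise EmptySegmentationError(
            f"empty segmentation: seed {seed_point} has SUV "
            f"{volume.values[seed_point]:.3g} below threshold {threshold:.3g}"
        )
    comp = _component_at(volume.values >= threshold, seed_point, connectivity)
    if method is None:
        method = f"SUV{threshold:g}"
    return LesionMask(comp, lesion_id=lesion_id, method=method)


def _sphere_offsets(spacing_mm, radius_mm: float) -> np.ndarray:
    """Integer voxel offsets whose centers lie within ``radius_mm`` of the origin."""
    spacing = np.asarray(spacing_mm, dtype=float)
    reach = np.floor(radius_mm / spacing).astype(int)
    axes = [np.arange(-r, r + 1) for r in reach]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(grid * spacing, axis=1)
    return grid[dist <= radius_mm + 1e-9]


def compute_suv_peak(
    volume: SuvVolume,
    lesion_mask: LesionMask | np.ndarray,
    *,
    sphere_volume_ml: float = 1.0,
) -> float:
    """SUVpeak: best 1-mL-sphere mean with the sphere centered at a lesion voxel.

    The sphere mean averages all in-grid voxels whose centers fall inside the
    sphere, whether or not they belong to the lesion mask; placements are
    exhaustive over lesion voxels and the maximum mean is returned.
    """
    mask = lesion_mask.voxels if isinstance(lesion_mask, LesionMask) else np.asarray(lesion_mask, bool)
    if not mask.any():
        raise EmptySegmentationError("SUVpeak undefined for an empty mask")
    if volume.voxel_volume_ml > sphere_volume_ml:
        raise ValueError(
            f"voxel volume {volume.voxel_volume_ml:.3g} mL exceeds the "
            f"{sphere_volume_ml:g} mL peak sphere"
        )
    radius_mm = (3.0 * sphere_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    offsets = _sphere_offsets(volume.spacing_mm, radius_mm)
    centers = np.argwhere(mask)
    shape = np.asarray(volume.shape)

    best = -np.inf
    # chunk placements to bound the (N_centers x N_offsets) intermediate
    for start in range(0, len(centers), 2048):
        chunk = centers[start : start + 2048]
        coords = chunk[:, None, :] + offsets[None, :, :]  # (n, k, 3)
        valid = np.all((coords >= 0) & (coords < shape), axis=2)
        flat = np.clip(coords, 0, shape - 1)
        vals = volume.values[flat[..., 0], flat[..., 1], flat[..., 2]]
        sums = np.where(valid, vals, 0.0).sum(axis=1)
        counts = valid.sum(axis=1)
        means = sums / counts
        best = max(best, float(means.max()))
    return best


def _local_peak(volume: SuvVolume, seed_point, connectivity: int):
    """Hill-climb (plateau-aware) from the seed to a strict local maximum.

    Returns ``(index, value)`` of a voxel on the terminal plateau. Raises
    RelativeThresholdUndefinedError when the climb terminates on a plateau
    with no strictly-lower neighbor (a flat volume has no lesion maximum).
    """
    struct = _structure(connectivity)
    current = tuple(int(i) for i in seed_point)
    while True:
        value = volume.values[current]
        plateau = _component_at(np.isclose(volume.values, value), current, connectivity)
        ring = ndimage.binary_dilation(plateau, structure=struct) & ~plateau
        ring_idx = np.argwhere(ring)
        if len(ring_idx) == 0:
            raise RelativeThresholdUndefinedError(
                "relative threshold undefined: volume is flat around the seed "
                f"{tuple(seed_point)} (no local maximum)"
            )
        ring_vals = volume.values[ring_idx[:, 0], ring_idx[:, 1], ring_idx[:, 2]]
        if ring_vals.max() <= value:
            return current, float(value)
        current = tuple(ring_idx[int(np.argmax(ring_vals))])


def segment_relative(
    volume: SuvVolume,
    seed_point,
    mode: str,
    *,
    provisional_threshold: float = 4.0,
    connectivity: int = 26,
    lesion_id: str = "lesion",
) -> LesionMask:
    """Relative-threshold delineation: 41% of lesion max or 50% of SUVpeak.

    ``PC41MAX`` thresholds at 0.41 x the lesion-local maximum — the maximum of
    the provisional SUV4.0 component at the seed, falling back to a
    hill-climbed local peak when that component is empty (lesion max below
    4.0). ``PC50PEAK`` thresholds at 0.50 x the SUVpeak of the provisional
    SUV4.0 component and requires that component to be non-empty. The returned
    mask is the connected region above threshold containing the lesion
    maximum.
    """
    seed_point = tuple(int(i) for i in seed_point)
    if not volume.contains_index(seed_point):
        raise IndexError(f"seed point {seed_point} outside grid {volume.shape}")

    provisional = None
    if volume.values[seed_point] >= provisional_threshold:
        provisional = _component_at(
            volume.values >= provisional_threshold, seed_point, connectivity
        )

    if mode == "PC41MAX":
        if provisional is not None:
            idx = np.argwhere(provisional)
            vals = volume.values[idx[:, 0], idx[:, 1], idx[:, 2]]
            peak_index = tuple(idx[int(np.argmax(vals))])
            ref_max = float(vals.max())
        else:
            peak_index, ref_max = _local_peak(volume, seed_point, connectivity)
        threshold = 0.41 * ref_max
    elif mode == "PC50PEAK":
        if provisional is None:
            raise RelativeThresholdUndefinedError(
                f"relative threshold undefined: no SUV{provisional_threshold:g} "
                f"region at seed {seed_point}"
            )
        idx = np.argwhere(provisional)
        vals = volume.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        peak_index = tuple(idx[int(np.argmax(vals))])
        suv_peak = compute_suv_peak(volume, provisional)
        threshold = 0.50 * suv_peak
    else:
        raise ValueError(f"unknown relative mode {mode!r}")

    comp = _component_at(volume.values >= threshold, peak_index, connectivity)
    return LesionMask(comp, lesion_id=lesion_id, method=mode)


def majority_vote(masks: list[LesionMask], k: int) -> LesionMask:
    """Keep voxels selected by >= ``k`` of the four base delineations (MV2/MV3)."""
    if len(masks) != 4:
        raise ValueError(f"majority vote requires exactly 4 base masks, got {len(masks)}")
    if k not in (2, 3):
        raise ValueError(f"k must be 2 or 3, got {k}")
    shapes = {m.voxels.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"input masks are not congruent: shapes {shapes}")
    votes = np.sum([m.voxels.astype(int) for m in masks], axis=0)
    return LesionMask(votes >= k, lesion_id=masks[0].lesion_id, method=f"MV{k}")


def exclude_regions(mask: LesionMask, exclusion: np.ndarray) -> LesionMask:
    """Remove non-tumor FDG-avid voxels (e.g., bladder, kidney) from a mask."""
    exclusion = np.asarray(exclusion, dtype=bool)
    if exclusion.shape != mask.voxels.shape:
        raise ValueError(
            f"exclusion grid {exclusion.shape} not congruent with mask {mask.voxels.shape}"
        )
    remaining = mask.voxels & ~exclusion
    return LesionMask(
        remaining,
        lesion_id=mask.lesion_id,
        method=mask.method,
        fully_excluded=bool(mask.voxels.any() and not remaining.any()),
    )


def compute_metrics(volume: SuvVolume, mask: LesionMask) -> LesionMetrics:
    """SUVmax, SUVpeak and MTV (mL) of a delineated lesion."""
    if mask.is_empty():
        raise EmptySegmentationError(
            f"metrics undefined for empty mask {mask.lesion_id!r} ({mask.method})"
        )
    suv_max = float(volume.values[mask.voxels].max())
    suv_peak = compute_suv_peak(volume, mask)
    mtv_ml = mask.n_voxels * volume.voxel_volume_mm3 / 1000.0
    return LesionMetrics(suv_max=suv_max, suv_peak=min(suv_peak, suv_max), mtv_ml=mtv_ml)


def segment_all_methods(
    volume: SuvVolume,
    seed_point,
    *,
    connectivity: int = 26,
    lesion_id: str = "lesion",
) -> dict[str, LesionMask]:
    """All six delineations (SUV4.0, SUV2.5, PC41MAX, PC50PEAK, MV2, MV3)."""
    masks = {
        "SUV4.0": apply_fixed_threshold(
            volume, 4.0, seed_point, connectivity=connectivity, lesion_id=lesion_id
        ),
        "SUV2.5": apply_fixed_threshold(
            volume, 2.5, seed_point, connectivity=connectivity, lesion_id=lesion_id
        ),
        "PC41MAX": segment_relative(
            volume, seed_point, "PC41MAX", connectivity=connectivity, lesion_id=lesion_id
        ),
        "PC50PEAK": segment_relative(
            volume, seed_point, "PC50PEAK", connectivity=connectivity, lesion_id=lesion_id
        ),
    }
    base = [masks[m] for m in BASE_METHODS]
    masks["MV2"] = majority_vote(base, 2)
    masks["MV3"] = majority_vote(base, 3)
    return masks


def select_mask(
    masks: dict[str, LesionMask],
    *,
    policy: str = "MV2",
) -> LesionMask:
    """Pick the delineation used for reporting.

    The trial protocol leaves "most complete segmentation without
    oversegmentation" to a supervising physician; here the choice is an
    explicit configuration. ``policy`` is either one of the six method names
    or ``"auto-smallest-covering"``: the smallest mask among those fully
    covering the SUV4.0 core (falls back to MV2 when none covers it).
    """
    if policy in masks:
        return masks[policy]
    if policy == "auto-smallest-covering":
        core = masks["SUV4.0"].voxels
        covering = [
            m for m in masks.values() if not (core & ~m.voxels).any()
        ]
        if not covering:
            return masks["MV2"]
        return min(covering, key=lambda m: m.n_voxels)
    raise ValueError(f"unknown mask-selection policy {policy!r}")
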