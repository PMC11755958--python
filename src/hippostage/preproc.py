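"""3D volume preprocessing and hippocampal volumetry.

Covers the imaging-side math of the staging pipeline: per-volume min-max
intensity normalization, nearest-neighbor resizing driven by per-axis
scale factors (desired / current dimension), small-angle rotation
augmentation, and conversion of a hippocampus probability mask into a
volume in mm^3.

Axis convention: arrays are indexed ``(r, c, h)`` = (row, column,
height), 0-based, with physical voxel spacing in mm per axis.  The
nearest-neighbor index map is ``source = floor(target / factor)``
clamped to the valid range, so downscaling by 1/2 keeps every other
voxel and upscaling by 2 repeats each voxel twice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Volume3D",
    "SegmentationMask",
    "ResizeSpec",
    "minmax_normalize",
    "compute_scale_factors",
    "resize_nearest",
    "rotate_augment",
    "quantify_hippocampal_volume",
    "DEFAULT_AUGMENT_ANGLES",
]

logger = logging.getLogger(__name__)

#: Default rotation-augmentation angle set: six small angles about the
#: height axis, excluding 0 (each input is replaced by its six rotations).
DEFAULT_AUGMENT_ANGLES = (-15.0, -10.0, -5.0, 5.0, 10.0, 15.0)

_AXIS_PLANES = {"r": (1, 2), "c": (0, 2), "h": (0, 1)}


@dataclass
class Volume3D:
    """A voxel grid with physical spacing (mm per axis)."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3-axis grid, got ndim={self.grid.ndim}")
        if min(self.grid.shape) < 1:
            raise ValueError(f"all dims must be >= 1, got shape {self.grid.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if not np.isfinite(self.grid).all():
            raise ValueError("grid contains non-finite intensities")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.grid.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


class SegmentationMask(Volume3D):
    """Per-voxel probability grid in [0, 1] with physical spacing."""

    def __post_init__(self):
        super().__post_init__()
        if self.grid.min() < 0 or self.grid.max() > 1:
            raise ValueError(
                f"mask probabilities must lie in [0, 1], got range "
                f"[{self.grid.min()}, {self.grid.max()}]"
            )


def minmax_normalize(v: Volume3D) -> Volume3D:
    """Rescale intensities to [0, 1]: (x - min) / (max - min).

    A constant volume (max == min) maps to all zeros with a logged
    warning, guarding the division by zero.
    """
    lo = float(v.grid.min())
    hi = float(v.grid.max())
    if hi == lo:
        logger.warning(
            "minmax_normalize: constant volume (all voxels %g); returning zeros", lo
        )
        return Volume3D(np.zeros_like(v.grid), v.spacing)
    return Volume3D((v.grid - lo) / (hi - lo), v.spacing)


def compute_scale_factors(
    current: tuple[int, int, int], desired: tuple[int, int, int]
) -> tuple[float, float, float]:
    """Per-axis scale factors desired / current (depth, width, height)."""
    if len(current) != 3 or len(desired) != 3:
        raise ValueError("current and desired must be dimension triples")
    for name, dims in (("current", current), ("desired", desired)):
        if any(int(d) != d or d <= 0 for d in dims):
            raise ValueError(f"{name} dims must be positive integers, got {dims}")
    return tuple(d / c for d, c in zip(desired, current))


@dataclass
class ResizeSpec:
    """Target dims plus the per-axis factors derived from the source dims."""

    desired: tuple[int, int, int]
    factors: tuple[float, float, float]

    @classmethod
    def from_dims(cls, current, desired) -> "ResizeSpec":
        return cls(tuple(int(d) for d in desired), compute_scale_factors(current, desired))


def resize_nearest(v: Volume3D, spec: ResizeSpec | tuple[int, int, int]) -> Volume3D:
    """Nearest-neighbor resize to ``spec.desired`` dims.

    Every output voxel is a copy of an input voxel (no interpolation, no
    new intensity values); output spacing is input spacing divided by the
    per-axis factor, preserving physical extent.
    """
    if not isinstance(spec, ResizeSpec):
        spec = ResizeSpec.from_dims(v.dims, spec)
    expected = compute_scale_factors(v.dims, spec.desired)
    if not np.allclose(spec.factors, expected, rtol=1e-12, atol=0):
        raise ValueError(
            f"spec factors {spec.factors} inconsistent with volume dims "
            f"{v.dims} and desired {spec.desired}"
        )
    idx = []
    for axis in range(3):
        n_src = v.dims[axis]
        f = spec.factors[axis]
        src = np.floor(np.arange(spec.desired[axis]) / f).astype(int)
        idx.append(np.clip(src, 0, n_src - 1))
    out = v.grid[np.ix_(*idx)]
    new_spacing = tuple(s / f for s, f in zip(v.spacing, spec.factors))
    return Volume3D(out, new_spacing)


def _rotate_plane_nearest(grid: np.ndarray, angle_deg: float, plane: tuple[int, int], fill: float) -> np.ndarray:
    """Rotate ``grid`` about the plane's center, nearest-neighbor resampled.

    Positive angles rotate counterclockwise in the (first, second) plane
    axes; target voxels whose source falls outside the grid get ``fill``.
    """
    moved = np.moveaxis(grid, plane, (0, 1))
    n0, n1 = moved.shape[:2]
    c0, c1 = (n0 - 1) / 2.0, (n1 - 1) / 2.0
    th = math.radians(angle_deg)
    cos, sin = math.cos(th), math.sin(th)
    i0, i1 = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    # inverse rotation of target coordinates gives the source location
    s0 = cos * (i0 - c0) + sin * (i1 - c1) + c0
    s1 = -sin * (i0 - c0) + cos * (i1 - c1) + c1
    s0r = np.rint(s0).astype(int)
    s1r = np.rint(s1).astype(int)
    valid = (s0r >= 0) & (s0r < n0) & (s1r >= 0) & (s1r < n1)
    sampled = moved[s0r.clip(0, n0 - 1), s1r.clip(0, n1 - 1)]
    extra = (1,) * (moved.ndim - 2)
    out = np.where(valid.reshape(valid.shape + extra), sampled, fill)
    return np.moveaxis(out, (0, 1), plane)


def rotate_augment(
    v: Volume3D,
    angles=DEFAULT_AUGMENT_ANGLES,
    axis: str = "h",
) -> list[Volume3D]:
    """Rotation augmentation: one output volume per angle (degrees).

    Rotations are in-plane about the chosen axis, nearest-neighbor
    resampled (so the intensity set is preserved up to cropping), with
    voxels rotated in from outside the grid set to the input minimum.
    Angle 0 reproduces the input exactly.
    """
    angles = list(angles)
    if not angles:
        raise ValueError("angles must be a nonempty list of degrees")
    if axis not in _AXIS_PLANES:
        raise ValueError(f"axis must be one of {sorted(_AXIS_PLANES)}, got {axis!r}")
    plane = _AXIS_PLANES[axis]
    fill = float(v.grid.min())
    return [
        Volume3D(_rotate_plane_nearest(v.grid, a, plane, fill), v.spacing) for a in angles
    ]


def _mask_volume_mm3(mask: SegmentationMask, threshold: float | None) -> float:
    voxel = mask.voxel_volume_mm3()
    if threshold is None:
        return float(mask.grid.sum()) * voxel
    return float((mask.grid >= threshold).sum()) * voxel


def quantify_hippocampal_volume(
    left: SegmentationMask,
    right: SegmentationMask,
    threshold: float | None = None,
) -> tuple[float, float, float]:
    """Hippocampal volume (left, right, total) in mm^3 from probability masks.

    With a threshold t, volume = (# voxels with p >= t) x voxel volume;
    without, volume = (sum of probabilities) x voxel volume (the
    expected-volume reading of the probability map).
    """
    if threshold is not None and not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if left.spacing != right.spacing:
        raise ValueError(
            f"left/right masks have mismatched spacing: {left.spacing} vs {right.spacing}"
        )
    vl = _mask_volume_mm3(left, threshold)
    vr = _mask_volume_mm3(right, threshold)
    return vl, vr, vl + vr
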