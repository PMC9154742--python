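"""Blastema isolation and background removal.

Real acquisitions are rotated and cropped distal to the zeugopod to exclude
the mature stump; per-HCR-channel background is then estimated as the mean
of several small (default 5 µm × 5 µm) in-plane ROIs placed in epidermis
devoid of HCR signal, and subtracted with clamping at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .stack import GeometryError, ImageStack

#: default in-plane background ROI edge length (µm)
ROI_SIZE_UM = 5.0


class ConfigError(ValueError):
    """Inconsistent experiment configuration."""


@dataclass(frozen=True)
class CropSpec:
    """Rigid rotation about the stack center followed by a half-open crop box.

    ``rotation_deg`` are Euler angles (about the z, y, x axes, applied in
    that order); ``crop_box_px`` is ``((z0, z1), (y0, y1), (x0, x1))`` or
    None for no crop.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    crop_box_px: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None


@dataclass
class BackgroundEstimate:
    """Per-HCR-channel background value and the ROIs it came from."""

    per_channel_value: dict[int, float]
    rois: list[tuple[int, int, int]] = field(default_factory=list)


# rotation axis pairs for Euler angles about (z, y, x) with arrays as (z,y,x)
_ROT_PLANES = {0: (1, 2), 1: (0, 2), 2: (0, 1)}


def crop_rotate(stack: ImageStack, spec: CropSpec) -> ImageStack:
    """Rotate every channel about the stack center, then crop.

    Intensity channels are interpolated linearly; the rotation keeps the
    array shape (``reshape=False``) so the crop box is stated in rotated
    coordinates. Negative interpolation overshoot is clamped at zero.
    """
    vol = stack.voxels
    for axis, angle in enumerate(spec.rotation_deg):
        if angle == 0.0:
            continue
        plane = tuple(a + 1 for a in _ROT_PLANES[axis])  # +1 for channel axis
        vol = ndimage.rotate(vol, angle, axes=plane, reshape=False,
                             order=1, mode="constant", cval=0.0)
    vol = np.maximum(vol, 0.0)
    if spec.crop_box_px is not None:
        (z0, z1), (y0, y1), (x0, x1) = spec.crop_box_px
        nz, ny, nx = stack.spatial_shape
        if not (0 <= z0 < z1 <= nz and 0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
            raise GeometryError(
                f"crop box {spec.crop_box_px} outside volume {stack.spatial_shape}"
            )
        vol = vol[:, z0:z1, y0:y1, x0:x1]
    return stack.with_voxels(vol)


def roi_shape_px(voxel_size_um: Sequence[float],
                 roi_size_um: float = ROI_SIZE_UM) -> tuple[int, int]:
    """µm → voxel conversion of the in-plane ROI edge (nearest count, min 1)."""
    _, vy, vx = voxel_size_um
    return max(1, round(roi_size_um / vy)), max(1, round(roi_size_um / vx))


def estimate_background(
    stack: ImageStack,
    channel: int | str,
    rois: Sequence[tuple[int, int, int]],
    roi_size_um: float = ROI_SIZE_UM,
) -> BackgroundEstimate:
    """Mean of per-ROI mean intensities in one channel.

    Each ROI is an in-plane square of ``roi_size_um`` per side on a single
    z plane, given by its ``(z, y0, x0)`` corner. ROIs are equal-sized, so
    the unweighted mean of ROI means is used.
    """
    if len(rois) == 0:
        raise ConfigError("at least one background ROI is required")
    c = stack.channel_index(channel)
    ky, kx = roi_shape_px(stack.voxel_size_um, roi_size_um)
    nz, ny, nx = stack.spatial_shape
    means = []
    for (z, y0, x0) in rois:
        if not (0 <= z < nz and 0 <= y0 and y0 + ky <= ny
                and 0 <= x0 and x0 + kx <= nx):
            raise GeometryError(
                f"background ROI {(z, y0, x0)} (size {ky}x{kx}) outside volume"
            )
        means.append(float(stack.voxels[c, z, y0:y0 + ky, x0:x0 + kx]
                           .mean(dtype=np.float64)))
    return BackgroundEstimate(
        per_channel_value={c: float(np.mean(means))},
        rois=[tuple(r) for r in rois],
    )


def subtract_background(stack: ImageStack,
                        estimates: BackgroundEstimate) -> ImageStack:
    """Clamp-at-zero subtraction of the per-channel background.

    Only the channels present in the estimate (the HCR channels) are
    touched; nuclei and autofluorescence channels pass through unchanged.
    """
    hcr = set(stack.hcr_channels())
    vol = stack.voxels.copy()
    for c, b in estimates.per_channel_value.items():
        if c not in hcr:
            raise ConfigError(
                f"background estimate given for non-HCR channel {c}"
            )
        if b < 0:
            raise ConfigError("background value must be nonnegative")
        vol[c] = np.maximum(vol[c] - b, 0.0)
    return stack.with_voxels(vol)
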