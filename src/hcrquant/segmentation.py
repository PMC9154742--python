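"""Expression-domain segmentation: anisotropic 3D blur, fixed thresholds,
and mask set algebra.

The segmentation path is: denoise one channel with a separable 3D Gaussian
whose physical width is isotropic (default 3.84 µm, which at the original
acquisition spacing corresponds to per-axis pixel sigmas x=6.0, y=6.0,
z=1.74); apply a fixed manual threshold shared by all samples of an
experiment; subtract the autofluorescence mask; and, for Axin2, split the
domain into epidermal and mesenchymal compartments by subtracting a
low-threshold Fgf8 mask that covers the whole mesenchyme. No hole filling,
size filtering or connected-component selection is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack import GeometryError, ImageStack, SegmentationMask


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class SmoothingParams:
    """Gaussian denoising width, in physical µm and/or per-axis pixels.

    ``sigma_um`` is the isotropic physical sigma; ``sigma_px`` (z, y, x)
    forces exact pixel sigmas. When both are given together with a voxel
    size, they must agree per axis within 5%.
    """

    sigma_um: float | None = 3.84
    sigma_px: tuple[float, float, float] | None = None

    def resolve(self, voxel_size_um: tuple[float, float, float] | None
                ) -> tuple[float, float, float]:
        """Per-axis pixel sigmas in (z, y, x) order."""
        if self.sigma_px is not None:
            px = tuple(float(s) for s in self.sigma_px)
            if any(s <= 0 for s in px):
                raise ParameterError(f"sigma_px must be positive, got {px}")
            if self.sigma_um is not None and voxel_size_um is not None:
                for s, v in zip(px, voxel_size_um):
                    if abs(s * v - self.sigma_um) > 0.05 * self.sigma_um:
                        raise ParameterError(
                            f"sigma_px {px} inconsistent with sigma_um "
                            f"{self.sigma_um} at voxel size {voxel_size_um}"
                        )
            return px
        if self.sigma_um is None or voxel_size_um is None:
            raise ParameterError(
                "need sigma_px, or sigma_um together with a voxel size"
            )
        if self.sigma_um <= 0:
            raise ParameterError("sigma_um must be positive")
        return tuple(self.sigma_um / v for v in voxel_size_um)


@dataclass(frozen=True)
class ThresholdSet:
    """Named intensity thresholds shared by all samples of one experiment."""

    per_channel_threshold: dict[str, float]
    experiment_id: str = ""

    def __getitem__(self, key: str) -> float:
        try:
            return self.per_channel_threshold[key]
        except KeyError:
            raise KeyError(
                f"no threshold {key!r} in experiment {self.experiment_id!r}"
            ) from None


def gaussian_blur_3d(
    stack: ImageStack,
    channel: int | str,
    params: SmoothingParams = SmoothingParams(),
) -> np.ndarray:
    """Separable 3D Gaussian blur of one channel (reflective boundaries)."""
    sigma = params.resolve(stack.voxel_size_um)
    vol = stack.channel(channel)
    return ndimage.gaussian_filter(
        vol.astype(np.float64, copy=False), sigma=sigma, mode="reflect"
    )


def threshold_mask(
    blurred: np.ndarray,
    threshold: float,
    source_channel: str = "",
) -> SegmentationMask:
    """Mask of voxels with blurred intensity >= threshold (inclusive bound)."""
    if threshold < 0:
        raise ParameterError("threshold must be nonnegative")
    return SegmentationMask(
        np.asarray(blurred) >= threshold,
        source_channel=source_channel,
        threshold_used=float(threshold),
        provenance=(f"threshold({source_channel}, {threshold!r})",),
    )


def remove_autofluorescence(
    expr: SegmentationMask, af: SegmentationMask
) -> SegmentationMask:
    """Exclude autofluorescent structures (e.g. blood cells) from a domain."""
    out = expr.minus(af)
    out.provenance = expr.provenance + ("remove_autofluorescence",) + af.provenance
    return out


def split_axin2_compartments(
    axin2: SegmentationMask, fgf8_lowthresh: SegmentationMask
) -> tuple[SegmentationMask, SegmentationMask]:
    """Split an Axin2 domain into epidermal and mesenchymal compartments.

    The low-threshold Fgf8 mask covers the whole mesenchyme, so subtracting
    it from the Axin2 mask leaves the epidermal Axin2 domain; subtracting
    the epidermal domain back from Axin2 leaves the mesenchymal one. The
    two results are disjoint and their union is the input Axin2 mask.
    """
    if axin2.shape != fgf8_lowthresh.shape:
        raise GeometryError(
            f"mask shapes differ: {axin2.shape} vs {fgf8_lowthresh.shape}"
        )
    epidermal = axin2.minus(fgf8_lowthresh)
    mesenchymal = axin2.minus(epidermal)
    epidermal.provenance = axin2.provenance + ("split:epidermal",)
    mesenchymal.provenance = axin2.provenance + ("split:mesenchymal",)
    return epidermal, mesenchymal
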