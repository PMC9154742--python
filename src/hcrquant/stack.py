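"""Core in-memory containers: multi-channel volumes and segmentation masks.

Axis convention throughout the package: voxel arrays are indexed
``(channel, z, y, x)`` and all physical triples (voxel size, sigmas, shapes)
are stated in ``(z, y, x)`` order. Coordinates are 0-based; boxes are
half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

#: channel roles understood by the pipeline
ROLES = ("nuclei", "autofluorescence", "hcr")


class GeometryError(ValueError):
    """Shape/extent mismatch between volumes, masks, boxes or ROIs."""


class FormatError(ValueError):
    """On-disk layout inconsistent with the declared channel structure."""


class MetadataError(ValueError):
    """Required physical metadata (voxel size) missing."""


class IntegrityError(ValueError):
    """Duplicate keys or other table-level consistency violations."""


class EmptyDomainError(ValueError):
    """A quantification mask contains no voxels; the sample's data point is invalid."""


@dataclass
class ImageStack:
    """A multi-channel 3D fluorescence volume with physical voxel size.

    Parameters
    ----------
    voxels : ndarray, shape (C, Z, Y, X)
        Nonnegative finite intensities.
    voxel_size_um : tuple of float
        Physical spacing ``(z, y, x)`` in micrometres.
    channel_roles : mapping int -> str
        Role per channel index, one of :data:`ROLES`.
    channel_names : mapping int -> str
        Free-form label per channel (e.g. ``"Axin2-647"``).
    """

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_roles: Mapping[int, str] = field(default_factory=dict)
    channel_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise FormatError(
                f"expected a (channel, z, y, x) array, got ndim={self.voxels.ndim}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("voxel values must be nonnegative")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise MetadataError(f"voxel_size_um must be 3 positive reals, got {vs!r}")
        self.voxel_size_um = vs
        for idx, role in dict(self.channel_roles).items():
            if role not in ROLES:
                raise ValueError(f"unknown channel role {role!r} for channel {idx}")
            if not 0 <= idx < self.n_channels:
                raise FormatError(f"channel index {idx} out of range")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, key: int | str) -> np.ndarray:
        """Return one channel's 3D volume by index or by name."""
        return self.voxels[self.channel_index(key)]

    def channel_index(self, key: int | str) -> int:
        if isinstance(key, (int, np.integer)):
            if not 0 <= key < self.n_channels:
                raise KeyError(f"channel index {key} out of range")
            return int(key)
        for idx, name in dict(self.channel_names).items():
            if name == key:
                return int(idx)
        raise KeyError(f"no channel named {key!r}")

    def hcr_channels(self) -> list[int]:
        return [i for i, r in dict(self.channel_roles).items() if r == "hcr"]

    def autofluorescence_channel(self) -> int:
        af = [i for i, r in dict(self.channel_roles).items() if r == "autofluorescence"]
        if len(af) != 1:
            raise ValueError(
                f"exactly one autofluorescence channel required, found {len(af)}"
            )
        return af[0]

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return replace(self, voxels=voxels)


@dataclass
class SegmentationMask:
    """Boolean 3D volume registered to an :class:`ImageStack`.

    Supports set algebra through ``&``, ``|`` and :meth:`minus`; every
    derived mask records the operation in ``provenance``.
    """

    voxels: np.ndarray
    source_channel: str = ""
    threshold_used: float = float("nan")
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise GeometryError(f"mask must be 3D, got ndim={self.voxels.ndim}")
        self.provenance = tuple(self.provenance)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def _check_shape(self, other: "SegmentationMask") -> None:
        if self.shape != other.shape:
            raise GeometryError(f"mask shapes differ: {self.shape} vs {other.shape}")

    def __and__(self, other: "SegmentationMask") -> "SegmentationMask":
        self._check_shape(other)
        return SegmentationMask(
            self.voxels & other.voxels,
            source_channel=self.source_channel,
            threshold_used=self.threshold_used,
            provenance=self.provenance
            + (f"and({other.source_channel or 'mask'})",)
            + other.provenance,
        )

    def __or__(self, other: "SegmentationMask") -> "SegmentationMask":
        self._check_shape(other)
        return SegmentationMask(
            self.voxels | other.voxels,
            source_channel=self.source_channel,
            threshold_used=self.threshold_used,
            provenance=self.provenance
            + (f"or({other.source_channel or 'mask'})",)
            + other.provenance,
        )

    def minus(self, other: "SegmentationMask") -> "SegmentationMask":
        """Set difference: voxels in this mask and not in ``other``."""
        self._check_shape(other)
        return SegmentationMask(
            self.voxels & ~other.voxels,
            source_channel=self.source_channel,
            threshold_used=self.threshold_used,
            provenance=self.provenance
            + (f"minus({other.source_channel or 'mask'})",)
            + other.provenance,
        )
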