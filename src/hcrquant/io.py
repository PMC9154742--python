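"""TIFF and CSV input/output.

Volumes travel as ImageJ-style multi-page TIFF hyperstacks with the channel
axis interleaved per z-plane; the z spacing is stored in the ImageJ
``spacing`` field and the in-plane spacing in the standard resolution tags.
Masks are 8-bit (0/255) TIFFs. Measurement tables are RFC-4180 CSV with a
"." decimal separator.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .stack import (
    FormatError,
    ImageStack,
    IntegrityError,
    MetadataError,
    SegmentationMask,
)

#: columns identifying one measurement row
TABLE_KEY = ["sample_id", "domain", "channel"]
TABLE_COLUMNS = TABLE_KEY[:1] + ["group", "staining_round"] + TABLE_KEY[1:] + [
    "mean_intensity",
    "voxel_count",
]


def write_stack(path: str | os.PathLike, stack: ImageStack) -> None:
    """Write a stack as an ImageJ hyperstack TIFF with voxel-size metadata."""
    vz, vy, vx = stack.voxel_size_um
    # ImageJ axis order is (Z, C, Y, X)
    data = np.ascontiguousarray(np.swapaxes(stack.voxels, 0, 1))
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZCYX"},
    )


def read_stack(
    path: str | os.PathLike,
    channel_roles: Mapping[int, str],
    channel_names: Mapping[int, str] | None = None,
    voxel_size_um: Sequence[float] | None = None,
) -> ImageStack:
    """Read a multi-channel volume, normalizing axes to (channel, z, y, x).

    ``channel_roles`` declares the role of every channel present in the
    file. The voxel size is read from the TIFF metadata (ImageJ ``spacing``
    + resolution tags) unless supplied explicitly.
    """
    n_channels = len(channel_roles)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta_voxel = _voxel_size_from_tiff(tif)

    data = _normalize_axes(data, axes, n_channels, path)
    if data.shape[0] != n_channels:
        raise FormatError(
            f"{path}: file has {data.shape[0]} channels but "
            f"{n_channels} channel roles were declared"
        )
    if voxel_size_um is None:
        voxel_size_um = meta_voxel
    if voxel_size_um is None:
        raise MetadataError(
            f"{path}: no voxel size in TIFF metadata and none supplied"
        )
    return ImageStack(
        voxels=data,
        voxel_size_um=tuple(voxel_size_um),
        channel_roles=dict(channel_roles),
        channel_names=dict(channel_names or {}),
    )


def _normalize_axes(data: np.ndarray, axes: str, n_channels: int, path) -> np.ndarray:
    """Bring an on-disk array with tifffile axis labels to (C, Z, Y, X)."""
    axes = axes.replace("S", "C").replace("Q", "Z").replace("I", "Z")
    if data.ndim == 3:
        # single plane-major stack: interpret pages as interleaved (Z*C, Y, X)
        if data.shape[0] % n_channels:
            raise FormatError(
                f"{path}: {data.shape[0]} pages not divisible into "
                f"{n_channels} channels"
            )
        data = data.reshape(-1, n_channels, *data.shape[1:])
        axes = "ZCYX"
    if data.ndim != 4 or sorted(axes) != sorted("CZYX"):
        raise FormatError(f"{path}: unsupported axis layout {axes!r}")
    order = [axes.index(a) for a in "CZYX"]
    return np.transpose(data, order)


def _voxel_size_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    meta = tif.imagej_metadata or {}
    spacing = meta.get("spacing")
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if spacing is None or xres is None or yres is None:
        return None
    def _as_um(tag):
        num, den = tag.value
        return den / num if num else None
    vx = _as_um(xres)
    vy = _as_um(yres)
    if vx is None or vy is None:
        return None
    return (float(spacing), float(vy), float(vx))


def write_mask(path: str | os.PathLike, mask: SegmentationMask,
               voxel_size_um: Sequence[float] | None = None) -> None:
    """Export a mask as an 8-bit (0/255) TIFF."""
    data = (mask.voxels.astype(np.uint8)) * np.uint8(255)
    kwargs = {}
    if voxel_size_um is not None:
        vz, vy, vx = voxel_size_um
        kwargs = dict(
            imagej=True,
            resolution=(1.0 / vx, 1.0 / vy),
            metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
        )
    tifffile.imwrite(path, data, **kwargs)


def read_mask(path: str | os.PathLike) -> SegmentationMask:
    data = tifffile.imread(path)
    return SegmentationMask(data > 0, provenance=(f"read({os.fspath(path)})",))


def _check_table(table: pd.DataFrame) -> None:
    if table.empty:
        raise IntegrityError("results table is empty")
    missing = [c for c in TABLE_KEY if c not in table.columns]
    if missing:
        raise IntegrityError(f"results table lacks key columns {missing}")
    dup = table.duplicated(subset=TABLE_KEY)
    if dup.any():
        keys = table.loc[dup, TABLE_KEY].to_records(index=False).tolist()
        raise IntegrityError(f"duplicate (sample_id, domain, channel) keys: {keys}")


def write_results(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a sample-measurement table as CSV; one row per (sample, domain, channel)."""
    _check_table(table)
    table.to_csv(path, index=False, lineterminator="\n")


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"sample_id": str, "group": str,
                                     "staining_round": str, "domain": str,
                                     "channel": str})
    _check_table(table)
    return table
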