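"""Per-sample 3D mean-intensity measurement inside final masks.

Measurements are always taken on the background-subtracted, *unblurred*
data; the Gaussian blur exists only to build segmentation masks. One
blastema contributes one data point per (domain, channel) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .stack import EmptyDomainError, GeometryError, ImageStack, SegmentationMask


@dataclass
class SampleMeasurement:
    """One blastema's mean HCR intensity in one expression domain."""

    sample_id: str
    group: str
    staining_round: str
    domain: str
    channel: str
    mean_intensity: float
    voxel_count: int

    def as_row(self) -> dict:
        return asdict(self)


def mean_intensity(
    stack: ImageStack, channel: int | str, mask: SegmentationMask
) -> tuple[float, int]:
    """Arithmetic mean of one channel's voxels where the mask is true."""
    vol = stack.channel(channel)
    if vol.shape != mask.shape:
        raise GeometryError(
            f"mask shape {mask.shape} does not match volume {vol.shape}"
        )
    n = mask.voxel_count
    if n == 0:
        raise EmptyDomainError("mask selects no voxels")
    total = float(vol[mask.voxels].sum(dtype=np.float64))
    return total / n, n


def quantify_sample(
    stack: ImageStack,
    masks: dict[str, SegmentationMask],
    domain_channels: dict[str, str],
    sample_id: str,
    group: str = "",
    staining_round: str = "",
    error_sink: list | None = None,
) -> list[SampleMeasurement]:
    """Measure every configured (domain, channel) pair for one sample.

    ``domain_channels`` maps domain name -> channel label to measure it on.
    A domain whose mask is empty invalidates that data point: by default an
    :class:`EmptyDomainError` naming the domain is raised; when
    ``error_sink`` is given, a flagged error record is appended there
    instead and the remaining domains are still measured. Never a silent
    zero.
    """
    out = []
    for domain, channel in domain_channels.items():
        if domain not in masks:
            raise KeyError(f"no mask produced for configured domain {domain!r}")
        try:
            mean, n = mean_intensity(stack, channel, masks[domain])
        except EmptyDomainError as e:
            if error_sink is not None:
                error_sink.append({
                    "sample_id": sample_id, "domain": domain,
                    "error": "empty domain mask",
                })
                continue
            raise EmptyDomainError(
                f"sample {sample_id!r}: domain {domain!r} mask is empty"
            ) from e
        out.append(SampleMeasurement(
            sample_id=sample_id, group=group, staining_round=staining_round,
            domain=domain, channel=channel, mean_intensity=mean, voxel_count=n,
        ))
    return out


def measurements_to_table(measurements: list[SampleMeasurement]) -> pd.DataFrame:
    """Stack measurements into the tabular (CSV-ready) form."""
    return pd.DataFrame([m.as_row() for m in measurements])
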