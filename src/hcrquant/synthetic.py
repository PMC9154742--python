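"""Synthetic blastema phantoms with known expression-domain ground truth.

The generator emulates what the quantification pipeline sees in a cleared,
light-sheet-imaged regenerating axolotl limb: a blastema-shaped tissue
volume (a half-ellipsoid dome capping an elliptic cylinder, the stump cut
face open at the proximal volume edge), split into an epidermal shell and a
mesenchymal core; an anterior-mesenchymal Fgf8 expression domain; Axin2
expression that is strong throughout the mesenchyme and weaker in the
distal epidermis; a weak diffuse Fgf8 component across the whole mesenchyme
(which is what lets a low Fgf8 threshold isolate the mesenchymal
compartment); bright autofluorescent blood-cell inclusions visible in every
channel including 488 nm; additive per-channel background; and additive
Gaussian sensor noise.

Channel layout is fixed: 0 nuclei (DAPI), 1 autofluorescence (488 nm),
2 HCR 546 nm (Fgf8 probe), 3 HCR 647 nm (Axin2 probe).

Treatment condition presets inject known fold changes into the mesenchymal
Axin2, epidermal Axin2 and Fgf8 domains, so the full pipeline can be
checked as a parameter-recovery experiment.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import write_stack, write_mask
from .stack import GeometryError, ImageStack, SegmentationMask

CHANNEL_NAMES = {0: "DAPI", 1: "AF488", 2: "Fgf8-546", 3: "Axin2-647"}
CHANNEL_ROLES = {0: "nuclei", 1: "autofluorescence", 2: "hcr", 3: "hcr"}

#: domain name -> the channel it is measured on
DOMAIN_CHANNELS = {
    "Fgf8": "Fgf8-546",
    "Axin2_total": "Axin2-647",
    "Axin2_epidermal": "Axin2-647",
    "Axin2_mesenchymal": "Axin2-647",
}


class ParameterError(ValueError):
    """Invalid phantom or preset parameters."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensity and noise parameters of one synthetic blastema.

    All physical quantities are micrometres; triples are (z, y, x). The
    proximal-distal axis runs along +y, the amputation (crop) plane being
    the y=0 face. ``base_intensity`` and ``background_level`` are per
    channel in the fixed order (nuclei, 488 autofluorescence, HCR-546,
    HCR-647).
    """

    shape_px: tuple[int, int, int] = (64, 128, 128)
    voxel_size_um: tuple[float, float, float] = (4.0, 1.6, 1.6)
    epidermis_thickness_um: float = 24.0
    outer_epidermis_um: float = 8.0
    fgf8_fraction: float = 0.15
    fgf8_band_depth_um: float = 40.0
    fgf8_mesenchyme_ratio: float = 0.25
    axin2_epidermal_ratio: float = 0.5
    base_intensity: tuple[float, float, float, float] = (80.0, 0.0, 100.0, 100.0)
    background_level: tuple[float, float, float, float] = (20.0, 20.0, 20.0, 20.0)
    n_blood_cells: int = 15
    blood_cell_radius_um: float = 8.0
    blood_cell_brightness: float = 300.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape_px) != 3 or any(int(s) < 4 for s in self.shape_px):
            raise ParameterError(f"shape_px must be 3 ints >= 4, got {self.shape_px}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ParameterError("voxel_size_um must be positive")
        if not 0 < self.fgf8_fraction < 0.5:
            raise ParameterError("fgf8_fraction must be in (0, 0.5)")
        if any(b < 0 for b in self.base_intensity) or any(
            b < 0 for b in self.background_level
        ):
            raise ParameterError("intensities and background must be nonnegative")
        if self.noise_sd < 0 or self.n_blood_cells < 0:
            raise ParameterError("noise_sd and n_blood_cells must be nonnegative")
        if self.blood_cell_radius_um <= 0 or self.blood_cell_brightness <= 0:
            raise ParameterError("blood cell radius and brightness must be positive")
        if self.epidermis_thickness_um <= 0:
            raise ParameterError("epidermis thickness must be positive")
        if not 0 < self.outer_epidermis_um < self.epidermis_thickness_um:
            raise ParameterError(
                "outer_epidermis_um must be positive and smaller than the "
                "epidermis thickness"
            )


@dataclass(frozen=True)
class ConditionPreset:
    """A drug-treatment arm with its injected ground-truth fold changes."""

    name: str
    fold_mesenchymal_axin2: float = 1.0
    fold_epidermal_axin2: float = 1.0
    fold_fgf8: float = 1.0
    n_per_arm: int = 4
    n_rounds: int = 1

    def __post_init__(self) -> None:
        for f in (self.fold_mesenchymal_axin2, self.fold_epidermal_axin2,
                  self.fold_fgf8):
            if f <= 0:
                raise ParameterError("fold factors must be positive")
        if self.n_per_arm < 3:
            raise ParameterError("n_per_arm must be >= 3 for a usable rank-sum test")

    @property
    def injected_folds(self) -> dict[str, float]:
        return {
            "Axin2_mesenchymal": self.fold_mesenchymal_axin2,
            "Axin2_epidermal": self.fold_epidermal_axin2,
            "Fgf8": self.fold_fgf8,
        }


#: study-condition presets. Mesenchymal/epidermal Axin2 folds for CHIR 3 h
#: and 6 h are the published estimates being used as recovery ground truth;
#: the remaining folds encode published directions (CHIR 3 h Fgf8 up,
#: 6 h unchanged, 12 h Fgf8 down with Axin2 up; IWR all down).
PRESETS: dict[str, ConditionPreset] = {
    "DMSO": ConditionPreset("DMSO"),
    "CHIR_3h": ConditionPreset("CHIR_3h", 2.6, 1.8, 1.5, n_per_arm=4, n_rounds=2),
    "CHIR_6h": ConditionPreset("CHIR_6h", 4.4, 1.7, 1.0, n_per_arm=4, n_rounds=2),
    "CHIR_12h": ConditionPreset("CHIR_12h", 2.0, 1.5, 0.6, n_per_arm=4),
    "IWR_12h": ConditionPreset("IWR_12h", 0.5, 0.5, 0.5, n_per_arm=4),
}

#: staining-efficiency multipliers per imaging/staining round
DEFAULT_ROUND_FACTORS = (1.0, 1.2)
#: per-sample variability defaults (multiplicative, lognormal sigma)
INTENSITY_JITTER_SD = 0.10
SIZE_JITTER_SD = 0.05


@dataclass
class GroundTruth:
    """What the generator actually put into a phantom."""

    true_masks: dict[str, SegmentationMask]
    true_mean_intensity: dict[tuple[str, str], float]
    injected_folds: dict[str, float]
    seed: int
    intensity_factor: float = 1.0
    size_factor: float = 1.0
    blood_centers_um: list[tuple[float, float, float]] = field(default_factory=list)

    def scalar_record(self) -> dict:
        """JSON-serializable record (masks omitted)."""
        return {
            "seed": self.seed,
            "intensity_factor": self.intensity_factor,
            "size_factor": self.size_factor,
            "injected_folds": self.injected_folds,
            "true_mean_intensity": {
                f"{d}|{c}": v for (d, c), v in self.true_mean_intensity.items()
            },
            "blood_centers_um": [list(c) for c in self.blood_centers_um],
            "mask_voxels": {k: m.voxel_count for k, m in self.true_masks.items()},
        }


def _physical_grids(params: PhantomParams):
    nz, ny, nx = params.shape_px
    vz, vy, vx = params.voxel_size_um
    z = (np.arange(nz) + 0.5)[:, None, None] * vz
    y = (np.arange(ny) + 0.5)[None, :, None] * vy
    x = (np.arange(nx) + 0.5)[None, None, :] * vx
    return z, y, x


def _shape_indicator(z, y, x, cz, cx, rz, rx, ry, y_join) -> np.ndarray:
    """Capped-cylinder-plus-dome indicator: inside where f <= 1."""
    dy = np.maximum(y - y_join, 0.0) / ry
    f = ((x - cx) / rx) ** 2 + ((z - cz) / rz) ** 2 + dy**2
    return f <= 1.0


def build_geometry(params: PhantomParams, size_factor: float = 1.0
                   ) -> dict[str, np.ndarray]:
    """Analytic tissue, compartment and expression-domain masks.

    The epidermal shell splits into an HCR-free outer layer (where
    background ROIs can live) and a basal layer carrying the weak epidermal
    Axin2 expression, matching the basal-epidermal localization of Wnt
    activity in the regenerating limb.
    """
    nz, ny, nx = params.shape_px
    vz, vy, vx = params.voxel_size_um
    Lz, Ly, Lx = nz * vz, ny * vy, nx * vx
    s = float(size_factor)
    cz, cx = Lz / 2.0, Lx / 2.0
    rx, rz = 0.40 * Lx * s, 0.40 * Lz * s
    y_join, ry = 0.45 * Ly * s, 0.50 * Ly * s
    t = params.epidermis_thickness_um
    o = params.outer_epidermis_um
    if t >= min(rx, rz, ry):
        raise GeometryError(
            f"epidermis thickness {t} um >= smallest tissue radius "
            f"{min(rx, rz, ry):.1f} um"
        )

    z, y, x = _physical_grids(params)
    tissue = _shape_indicator(z, y, x, cz, cx, rz, rx, ry, y_join)
    mesenchyme = _shape_indicator(z, y, x, cz, cx, rz - t, rx - t, ry - t, y_join)
    mesenchyme &= tissue
    epidermis = tissue & ~mesenchyme

    # epidermal Axin2: the basal (inner) part of the shell
    basal_outer = _shape_indicator(z, y, x, cz, cx, rz - o, rx - o, ry - o, y_join)
    axin2_epi = (basal_outer & tissue) & ~mesenchyme
    yb = np.broadcast_to(y, tissue.shape)

    # Fgf8: anterior mesenchyme, within a subepidermal band, distal cut
    # chosen so the domain occupies ~fgf8_fraction of the mesenchyme
    band_r = t + params.fgf8_band_depth_um
    if band_r < min(rx, rz, ry):
        core = _shape_indicator(z, y, x, cz, cx, rz - band_r, rx - band_r,
                                ry - band_r, y_join)
    else:
        core = np.zeros_like(tissue)
    xb = np.broadcast_to(x, tissue.shape)
    candidates = mesenchyme & ~core & (xb < cx)
    n_target = params.fgf8_fraction * mesenchyme.sum()
    cand_y = yb[candidates]
    if cand_y.size == 0:
        raise GeometryError("no candidate voxels for the Fgf8 domain")
    if cand_y.size <= n_target:
        fgf8 = candidates
    else:
        q = 1.0 - n_target / cand_y.size
        y_cut = np.quantile(cand_y, q)
        fgf8 = candidates & (yb >= y_cut)

    return {
        "tissue": tissue,
        "epidermis": epidermis,
        "mesenchyme": mesenchyme,
        "Fgf8": fgf8,
        "Axin2_epidermal": axin2_epi,
        "Axin2_mesenchymal": mesenchyme,
    }


def _add_blood_cells(voxels: np.ndarray, params: PhantomParams,
                     tissue: np.ndarray, rng: np.random.Generator):
    """Add bright spheres to every channel; returns (mask, centers_um)."""
    mask = np.zeros(tissue.shape, dtype=bool)
    centers: list[tuple[float, float, float]] = []
    if params.n_blood_cells == 0:
        return mask, centers
    idx = np.flatnonzero(tissue)
    picks = rng.choice(idx, size=params.n_blood_cells, replace=False)
    vz, vy, vx = params.voxel_size_um
    r = params.blood_cell_radius_um
    rpx = (int(np.ceil(r / vz)), int(np.ceil(r / vy)), int(np.ceil(r / vx)))
    nz, ny, nx = tissue.shape
    for flat in picks:
        pz, py, px = np.unravel_index(flat, tissue.shape)
        centers.append(((pz + 0.5) * vz, (py + 0.5) * vy, (px + 0.5) * vx))
        z0, z1 = max(pz - rpx[0], 0), min(pz + rpx[0] + 1, nz)
        y0, y1 = max(py - rpx[1], 0), min(py + rpx[1] + 1, ny)
        x0, x1 = max(px - rpx[2], 0), min(px + rpx[2] + 1, nx)
        zz = ((np.arange(z0, z1) - pz)[:, None, None] * vz) ** 2
        yy = ((np.arange(y0, y1) - py)[None, :, None] * vy) ** 2
        xx = ((np.arange(x0, x1) - px)[None, None, :] * vx) ** 2
        sphere = zz + yy + xx <= r * r
        mask[z0:z1, y0:y1, x0:x1] |= sphere
    voxels[:, mask] += params.blood_cell_brightness
    return mask, centers


def generate_phantom(
    params: PhantomParams,
    preset: ConditionPreset,
    intensity_factor: float = 1.0,
    size_factor: float = 1.0,
) -> tuple[ImageStack, GroundTruth]:
    """Build one synthetic blastema stack plus its ground truth.

    ``intensity_factor`` (sample jitter x round staining efficiency) scales
    the HCR signal only — not the background and not the autofluorescent
    blood cells, which are staining-independent.
    """
    g = build_geometry(params, size_factor)
    rng = np.random.default_rng(params.seed % (2**31))
    nz, ny, nx = params.shape_px
    base = params.base_intensity
    bg = params.background_level
    f = preset.injected_folds
    k = float(intensity_factor)

    voxels = np.zeros((4, nz, ny, nx), dtype=np.float32)
    voxels[0][g["tissue"]] += base[0]
    # 488: background only (plus blood, below) — tissue itself is dark
    voxels[2][g["mesenchyme"]] += (
        base[2] * params.fgf8_mesenchyme_ratio * f["Fgf8"] * k
    )
    voxels[2][g["Fgf8"]] += (
        base[2] * (1.0 - params.fgf8_mesenchyme_ratio) * f["Fgf8"] * k
    )
    voxels[3][g["Axin2_mesenchymal"]] += base[3] * f["Axin2_mesenchymal"] * k
    voxels[3][g["Axin2_epidermal"]] += (
        base[3] * params.axin2_epidermal_ratio * f["Axin2_epidermal"] * k
    )

    true_mean = {
        ("Fgf8", CHANNEL_NAMES[2]): base[2] * f["Fgf8"] * k,
        ("Axin2_mesenchymal", CHANNEL_NAMES[3]):
            base[3] * f["Axin2_mesenchymal"] * k,
        ("Axin2_epidermal", CHANNEL_NAMES[3]):
            base[3] * params.axin2_epidermal_ratio * f["Axin2_epidermal"] * k,
    }
    n_mes = g["Axin2_mesenchymal"].sum()
    n_epi = g["Axin2_epidermal"].sum()
    true_mean[("Axin2_total", CHANNEL_NAMES[3])] = (
        n_mes * true_mean[("Axin2_mesenchymal", CHANNEL_NAMES[3])]
        + n_epi * true_mean[("Axin2_epidermal", CHANNEL_NAMES[3])]
    ) / (n_mes + n_epi)

    blood_mask, centers = _add_blood_cells(voxels, params, g["tissue"], rng)
    for c in range(4):
        voxels[c] += bg[c]
    if params.noise_sd > 0:
        noise = rng.standard_normal(size=voxels.shape, dtype=np.float32)
        noise *= params.noise_sd
        voxels += noise
        np.maximum(voxels, 0.0, out=voxels)

    stack = ImageStack(
        voxels=voxels,
        voxel_size_um=params.voxel_size_um,
        channel_roles=dict(CHANNEL_ROLES),
        channel_names=dict(CHANNEL_NAMES),
    )
    masks = {
        name: SegmentationMask(arr, source_channel=name, provenance=("ground_truth",))
        for name, arr in g.items()
    }
    masks["Axin2_total"] = SegmentationMask(
        g["Axin2_mesenchymal"] | g["Axin2_epidermal"],
        source_channel="Axin2_total", provenance=("ground_truth",),
    )
    masks["blood"] = SegmentationMask(
        blood_mask, source_channel="blood", provenance=("ground_truth",)
    )
    truth = GroundTruth(
        true_masks=masks,
        true_mean_intensity=true_mean,
        injected_folds=dict(f),
        seed=params.seed,
        intensity_factor=k,
        size_factor=float(size_factor),
        blood_centers_um=centers,
    )
    return stack, truth


def generate_arm(
    params: PhantomParams,
    preset: ConditionPreset,
    n: int,
    seed: int,
    intensity_jitter_sd: float = INTENSITY_JITTER_SD,
    size_jitter_sd: float = SIZE_JITTER_SD,
    round_factors: tuple[float, ...] = DEFAULT_ROUND_FACTORS,
    n_rounds: int | None = None,
) -> list[tuple[ImageStack, GroundTruth]]:
    """Generate one treatment arm of ``n`` phantoms with per-sample jitter.

    Jitter, noise and blood placement for sample ``i`` depend only on
    ``(seed, i)`` — never on the preset — so two arms generated with the
    same seed are sample-wise paired and the ratio of their arm-mean true
    intensities equals the injected fold exactly.

    ``n_rounds`` is the staining-round structure of the *experiment* (both
    arms of an experiment are stained in the same batches); it defaults to
    the preset's round count.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if n_rounds is None:
        n_rounds = preset.n_rounds
    out = []
    for i in range(n):
        jit_rng = np.random.default_rng(np.random.SeedSequence([seed % (2**31), i, 0]))
        g = float(np.exp(jit_rng.normal(0.0, intensity_jitter_sd)))
        s = float(np.exp(jit_rng.normal(0.0, size_jitter_sd)))
        round_idx = sample_round(i, n, n_rounds)
        k = g * round_factors[round_idx % len(round_factors)]
        child_seed = int(
            np.random.SeedSequence([seed % (2**31), i, 1]).generate_state(1)[0]
            % (2**31)
        )
        p_i = replace(params, seed=child_seed)
        out.append(generate_phantom(p_i, preset, intensity_factor=k, size_factor=s))
    return out


def sample_round(i: int, n: int, n_rounds: int) -> int:
    """Round index for sample i of n (contiguous blocks, like batched staining)."""
    if n_rounds <= 1:
        return 0
    block = int(np.ceil(n / n_rounds))
    return min(i // block, n_rounds - 1)


def auto_thresholds(params: PhantomParams, preset: ConditionPreset) -> dict[str, float]:
    """Per-experiment thresholds for a two-arm phantom experiment.

    Mimics an analyst picking, per channel, a single threshold that
    segments both the control and the treated arm, based on the half-height
    edge-recovery rule: a threshold at half the edge amplitude places the
    mask boundary on the true domain boundary. Where the two arms' edge
    heights differ (injected fold != 1) the geometric mean of the two
    half-heights is used for domains with uniform interiors (Axin2, low
    Fgf8); for the bright Fgf8 domain, which sits on the weak pan-
    mesenchymal floor, the midpoint between the highest floor and the
    lowest domain level across arms is used instead. Thresholds apply to
    blurred, background-subtracted data (the autofluorescence channel is
    not background-subtracted, so its threshold includes the background).
    """
    base = params.base_intensity
    epi = params.axin2_epidermal_ratio * base[3]
    weak = params.fgf8_mesenchyme_ratio * base[2]
    f_epi = preset.fold_epidermal_axin2
    f_fgf8 = preset.fold_fgf8
    floor_max = weak * max(1.0, f_fgf8)
    domain_min = base[2] * min(1.0, f_fgf8)
    return {
        "Axin2": 0.5 * epi * float(np.sqrt(f_epi)),
        "Fgf8": 0.5 * (floor_max + domain_min),
        "Fgf8_low": 0.5 * weak * float(np.sqrt(f_fgf8)),
        "autofluorescence": params.background_level[1]
        + 0.3 * params.blood_cell_brightness,
    }


def place_background_rois(
    params: PhantomParams,
    truth: GroundTruth,
    n_rois: int = 3,
    roi_size_um: float = 5.0,
    seed: int = 0,
    min_separation_um: float = 10.0,
) -> list[tuple[int, int, int]]:
    """Auto-place HCR-free epidermal background ROIs on a phantom.

    Candidate centers lie in the proximal epidermis (outside the epidermal
    Axin2 domain), clear of blood cells, with the whole in-plane ROI box
    inside the shell. Returns ``(z, y0, x0)`` corners of square in-plane
    boxes of ``roi_size_um`` per side (nearest voxel count, min 1).
    """
    vz, vy, vx = params.voxel_size_um
    ky = max(1, round(roi_size_um / vy))
    kx = max(1, round(roi_size_um / vx))
    epi = truth.true_masks["epidermis"].voxels
    allowed = epi & ~truth.true_masks["Axin2_epidermal"].voxels
    blood = truth.true_masks["blood"].voxels
    if blood.any():
        margin_px = (
            max(1, int(np.ceil(2.0 / vz))),
            max(1, int(np.ceil(2.0 / vy))),
            max(1, int(np.ceil(2.0 / vx))),
        )
        dil = ndimage.binary_dilation(
            blood, structure=np.ones((3, 3, 3), bool),
            iterations=max(margin_px),
        )
        allowed &= ~dil
    centers_ok = ndimage.minimum_filter(allowed, size=(1, ky, kx))
    # the filter reflects at edges; keep the whole box inside the volume
    centers_ok[:, : ky // 2, :] = False
    centers_ok[:, centers_ok.shape[1] - (ky - ky // 2 - 1):, :] = False
    centers_ok[:, :, : kx // 2] = False
    centers_ok[:, :, centers_ok.shape[2] - (kx - kx // 2 - 1):] = False
    coords = np.argwhere(centers_ok)
    if coords.shape[0] == 0:
        raise GeometryError("no valid background ROI placement found")
    rng = np.random.default_rng(seed % (2**31))
    order = rng.permutation(coords.shape[0])
    chosen: list[np.ndarray] = []
    scale = np.array([vz, vy, vx])
    for j in order:
        c = coords[j]
        if all(np.linalg.norm((c - p) * scale) >= min_separation_um for p in chosen):
            chosen.append(c)
        if len(chosen) == n_rois:
            break
    while len(chosen) < n_rois:  # relax separation if the shell is crowded
        chosen.append(coords[order[len(chosen) % len(order)]])
    return [(int(z), int(y - ky // 2), int(x - kx // 2)) for z, y, x in chosen]


def write_sample(
    out_dir: str | os.PathLike,
    sample_id: str,
    stack: ImageStack,
    truth: GroundTruth,
    write_masks: bool = False,
) -> dict[str, str]:
    """Write one phantom: TIFF stack + JSON ground-truth sidecar."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    tif_path = os.path.join(out_dir, f"{sample_id}.tif")
    json_path = os.path.join(out_dir, f"{sample_id}_truth.json")
    write_stack(tif_path, stack)
    with open(json_path, "w") as fh:
        json.dump(truth.scalar_record(), fh, indent=1)
    paths = {"stack": tif_path, "truth": json_path}
    if write_masks:
        for name, mask in truth.true_masks.items():
            mpath = os.path.join(out_dir, f"{sample_id}_mask_{name}.tif")
            write_mask(mpath, mask, voxel_size_um=stack.voxel_size_um)
            paths[f"mask_{name}"] = mpath
    return paths


def treated_group_label(preset: ConditionPreset,
                        control_preset: ConditionPreset) -> str:
    """Manifest group label of the treated arm.

    Disambiguated with a ``_b`` suffix when treated and control presets
    share a name, as in DMSO-vs-DMSO null-calibration experiments where the
    two arms are independent animals that must stay distinguishable.
    """
    if preset.name == control_preset.name:
        return f"{preset.name}_b"
    return preset.name


def write_experiment(
    out_dir: str | os.PathLike,
    params: PhantomParams,
    preset: ConditionPreset,
    n_per_arm: int,
    seed: int,
    control_preset: ConditionPreset | None = None,
    n_background_rois: int = 3,
    write_masks: bool = False,
) -> pd.DataFrame:
    """Generate and write a full two-arm experiment (treated vs DMSO).

    The two arms use distinct child seeds (independent animals). Returns
    the manifest table (sample_id, path, group, staining_round, rois, seed)
    and writes it as ``manifest.csv``.
    """
    control_preset = control_preset or PRESETS["DMSO"]
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    arm_seeds = [
        int(np.random.SeedSequence([seed % (2**31), tag]).generate_state(1)[0]
            % (2**31))
        for tag in (11, 22)
    ]
    labels = (control_preset.name, treated_group_label(preset, control_preset))
    for (arm_preset, label, arm_seed) in zip((control_preset, preset), labels,
                                             arm_seeds):
        samples = generate_arm(
            params, arm_preset, n_per_arm, arm_seed,
            round_factors=DEFAULT_ROUND_FACTORS,
            n_rounds=preset.n_rounds,
        )
        for i, (stack, truth) in enumerate(samples):
            sid = f"{label}_{i+1:02d}"
            paths = write_sample(out_dir, sid, stack, truth,
                                 write_masks=write_masks)
            rois = place_background_rois(
                params, truth, n_rois=n_background_rois,
                seed=truth.seed + 13,
            )
            rows.append({
                "sample_id": sid,
                "path": os.path.basename(paths["stack"]),
                "group": label,
                "staining_round":
                    f"r{sample_round(i, n_per_arm, preset.n_rounds) + 1}",
                "background_rois": json.dumps([list(r) for r in rois]),
                "seed": truth.seed,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
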