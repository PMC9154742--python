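"""Phantom generator: geometry, intensities, jitter pairing, experiment layout."""

import json

import numpy as np
import pytest

from hcrquant import PRESETS, ConditionPreset, PhantomParams, generate_arm, generate_phantom
from hcrquant.synthetic import (
    ParameterError,
    auto_thresholds,
    build_geometry,
    place_background_rois,
    sample_round,
    treated_group_label,
    write_experiment,
)

from conftest import small_phantom_params


class TestParams:
    def test_validation(self):
        with pytest.raises(ParameterError):
            PhantomParams(shape_px=(2, 8, 8))
        with pytest.raises(ParameterError):
            PhantomParams(fgf8_fraction=0.7)
        with pytest.raises(ParameterError):
            PhantomParams(noise_sd=-1.0)
        with pytest.raises(ParameterError):
            PhantomParams(outer_epidermis_um=30.0, epidermis_thickness_um=24.0)
        with pytest.raises(ParameterError):
            ConditionPreset("x", fold_fgf8=0.0)
        with pytest.raises(ParameterError):
            ConditionPreset("x", n_per_arm=2)

    def test_preset_injected_folds(self):
        f = PRESETS["CHIR_3h"].injected_folds
        assert set(f) == {"Axin2_mesenchymal", "Axin2_epidermal", "Fgf8"}


class TestGeometry:
    def test_compartments_partition_tissue(self, small_params):
        g = build_geometry(small_params)
        assert not (g["epidermis"] & g["mesenchyme"]).any()
        assert np.array_equal(g["epidermis"] | g["mesenchyme"], g["tissue"])

    def test_domains_live_in_their_compartments(self, small_params):
        g = build_geometry(small_params)
        assert (g["Fgf8"] & ~g["mesenchyme"]).sum() == 0
        assert (g["Axin2_epidermal"] & ~g["epidermis"]).sum() == 0
        assert g["Fgf8"].sum() > 0 and g["Axin2_epidermal"].sum() > 0

    def test_fgf8_fraction_roughly_honored(self, small_params):
        g = build_geometry(small_params)
        frac = g["Fgf8"].sum() / g["mesenchyme"].sum()
        assert frac == pytest.approx(small_params.fgf8_fraction, rel=0.2)

    def test_fgf8_is_anterior_only(self, small_params):
        g = build_geometry(small_params)
        nx = small_params.shape_px[2]
        assert not g["Fgf8"][:, :, nx // 2:].any()

    def test_tissue_open_at_proximal_face(self, small_params):
        g = build_geometry(small_params)
        assert g["tissue"][:, 0, :].any()
        assert not g["tissue"][:, -1, :].any()

    def test_too_thick_epidermis_rejected(self):
        from hcrquant import GeometryError
        p = small_phantom_params(epidermis_thickness_um=20.0,
                                 outer_epidermis_um=5.0, shape_px=(8, 16, 16))
        with pytest.raises(GeometryError):
            build_geometry(p)


class TestPhantomIntensities:
    def test_channel_layout_and_roles(self, small_params, dmso):
        stack, _ = generate_phantom(small_params, dmso)
        assert stack.voxels.shape[0] == 4
        assert stack.channel_roles == {0: "nuclei", 1: "autofluorescence",
                                       2: "hcr", 3: "hcr"}

    def test_mean_intensities_in_clean_phantom(self, clean_params, dmso):
        stack, truth = generate_phantom(clean_params, dmso)
        b = clean_params.base_intensity
        expected = {
            ("Axin2_mesenchymal", "Axin2-647"): b[3],
            ("Axin2_epidermal", "Axin2-647"):
                b[3] * clean_params.axin2_epidermal_ratio,
            ("Fgf8", "Fgf8-546"): b[2],
        }
        for key, val in expected.items():
            assert truth.true_mean_intensity[key] == pytest.approx(val)

    def test_injected_folds_scale_hcr_only(self, clean_params):
        chir = PRESETS["CHIR_6h"]
        s0, _ = generate_phantom(clean_params, PRESETS["DMSO"])
        s1, _ = generate_phantom(clean_params, chir)
        # DAPI identical, Axin2 scaled where expressed
        assert np.array_equal(s0.channel(0), s1.channel(0))
        m = s0.channel(3) > 0
        ratio = np.unique(s1.channel(3)[m] / s0.channel(3)[m])
        folds = (chir.fold_mesenchymal_axin2, chir.fold_epidermal_axin2)
        for r in ratio:
            assert min(abs(r - f) for f in folds) < 1e-5

    def test_intensity_factor_spares_background_and_blood(self):
        p = small_phantom_params(noise_sd=0.0, n_blood_cells=3)
        s1, t1 = generate_phantom(p, PRESETS["DMSO"], intensity_factor=1.0)
        s2, t2 = generate_phantom(p, PRESETS["DMSO"], intensity_factor=2.0)
        blood = t1.true_masks["blood"].voxels
        assert np.array_equal(s1.channel(1), s2.channel(1))  # AF channel
        outside = ~t1.true_masks["tissue"].voxels & ~blood
        assert np.array_equal(s1.channel(3)[outside], s2.channel(3)[outside])
        mes = t1.true_masks["Axin2_mesenchymal"].voxels & ~blood
        bg = p.background_level[3]
        np.testing.assert_allclose(s2.channel(3)[mes] - bg,
                                   2.0 * (s1.channel(3)[mes] - bg), rtol=1e-5)

    def test_blood_cells_visible_in_all_channels(self):
        p = small_phantom_params(noise_sd=0.0, n_blood_cells=3)
        stack, truth = generate_phantom(p, PRESETS["DMSO"])
        blood = truth.true_masks["blood"].voxels
        assert blood.any()
        for c in range(4):
            assert (stack.channel(c)[blood]
                    >= p.blood_cell_brightness).all()

    def test_determinism(self, small_params, dmso):
        s1, _ = generate_phantom(small_params, dmso)
        s2, _ = generate_phantom(small_params, dmso)
        assert np.array_equal(s1.voxels, s2.voxels)


class TestArmsAndRounds:
    def test_same_seed_arms_pair_exactly(self, small_params):
        # jitter depends only on (seed, i): true arm-mean ratio == injected fold
        chir = PRESETS["CHIR_6h"]
        arm_c = generate_arm(small_params, PRESETS["DMSO"], 4, seed=9,
                             n_rounds=chir.n_rounds)
        arm_t = generate_arm(small_params, chir, 4, seed=9,
                             n_rounds=chir.n_rounds)
        key = ("Axin2_mesenchymal", "Axin2-647")
        mc = np.mean([t.true_mean_intensity[key] for _, t in arm_c])
        mt = np.mean([t.true_mean_intensity[key] for _, t in arm_t])
        assert mt / mc == pytest.approx(chir.fold_mesenchymal_axin2, rel=1e-6)

    def test_sample_round_blocks(self):
        assert [sample_round(i, 8, 2) for i in range(8)] == [0] * 4 + [1] * 4
        assert [sample_round(i, 4, 1) for i in range(4)] == [0] * 4
        assert [sample_round(i, 5, 2) for i in range(5)] == [0, 0, 0, 1, 1]

    def test_round_factor_applied(self, small_params):
        arm = generate_arm(small_params, PRESETS["DMSO"], 4, seed=3,
                           n_rounds=2, round_factors=(1.0, 1.2),
                           intensity_jitter_sd=0.0, size_jitter_sd=0.0)
        key = ("Axin2_mesenchymal", "Axin2-647")
        # contiguous blocks: samples 0-1 in round 1, samples 2-3 in round 2
        vals = [t.true_mean_intensity[key] for _, t in arm]
        assert vals[1] / vals[0] == pytest.approx(1.0)
        assert vals[3] / vals[2] == pytest.approx(1.0)
        assert vals[2] / vals[0] == pytest.approx(1.2)

    def test_treated_group_label_disambiguates_null(self):
        dmso = PRESETS["DMSO"]
        assert treated_group_label(PRESETS["CHIR_3h"], dmso) == "CHIR_3h"
        assert treated_group_label(dmso, dmso) == "DMSO_b"


class TestAutoThresholds:
    def test_required_keys_and_positive(self, small_params):
        for preset in PRESETS.values():
            thr = auto_thresholds(small_params, preset)
            assert set(thr) == {"Axin2", "Fgf8", "Fgf8_low", "autofluorescence"}
            assert all(v > 0 for v in thr.values())

    def test_half_height_rule_null_case(self, small_params):
        thr = auto_thresholds(small_params, PRESETS["DMSO"])
        b = small_params.base_intensity
        assert thr["Axin2"] == pytest.approx(
            0.5 * small_params.axin2_epidermal_ratio * b[3])
        assert thr["Fgf8_low"] == pytest.approx(
            0.5 * small_params.fgf8_mesenchyme_ratio * b[2])

    def test_orderings_that_make_the_split_work(self, small_params):
        # low Fgf8 threshold sits below the weak pan-mesenchymal level and
        # the Axin2 threshold below the epidermal Axin2 level, in every preset
        b = small_params.base_intensity
        for preset in PRESETS.values():
            thr = auto_thresholds(small_params, preset)
            weak = b[2] * small_params.fgf8_mesenchyme_ratio * preset.fold_fgf8
            assert thr["Fgf8_low"] < weak
            assert thr["Fgf8_low"] < thr["Fgf8"]
            epi = (b[3] * small_params.axin2_epidermal_ratio
                   * preset.fold_epidermal_axin2)
            assert thr["Axin2"] < epi


class TestBackgroundRoiPlacement:
    def test_rois_fall_in_signal_free_epidermis(self, small_params, dmso):
        _, truth = generate_phantom(small_params, dmso)
        rois = place_background_rois(small_params, truth, n_rois=3, seed=1)
        assert len(rois) == 3
        vy, vx = small_params.voxel_size_um[1:]
        ky, kx = max(1, round(5.0 / vy)), max(1, round(5.0 / vx))
        epi = truth.true_masks["epidermis"].voxels
        signal = (truth.true_masks["Axin2_epidermal"].voxels
                  | truth.true_masks["blood"].voxels)
        for z, y0, x0 in rois:
            box_epi = epi[z, y0:y0 + ky, x0:x0 + kx]
            box_sig = signal[z, y0:y0 + ky, x0:x0 + kx]
            assert box_epi.shape == (ky, kx)  # fully inside the volume
            assert box_epi.all()
            assert not box_sig.any()


class TestWriteExperiment:
    def test_manifest_layout_and_determinism(self, tmp_path, small_params):
        m1 = write_experiment(tmp_path / "a", small_params, PRESETS["CHIR_6h"],
                              n_per_arm=3, seed=5)
        m2 = write_experiment(tmp_path / "b", small_params, PRESETS["CHIR_6h"],
                              n_per_arm=3, seed=5)
        assert list(m1["group"]) == ["DMSO"] * 3 + ["CHIR_6h"] * 3
        assert m1["sample_id"].is_unique
        assert (tmp_path / "a" / "manifest.csv").exists()
        assert (tmp_path / "a" / "DMSO_01.tif").exists()
        assert (tmp_path / "a" / "DMSO_01_truth.json").exists()
        assert m1.drop(columns=["path"]).equals(m2.drop(columns=["path"]))
        # rounds follow the treated preset's structure in both arms
        assert list(m1["staining_round"]) == ["r1", "r1", "r2"] * 2

    def test_null_experiment_groups_distinct(self, tmp_path, small_params):
        m = write_experiment(tmp_path / "n", small_params, PRESETS["DMSO"],
                             n_per_arm=3, seed=5)
        assert set(m["group"]) == {"DMSO", "DMSO_b"}
        assert m["sample_id"].is_unique

    def test_rois_are_json_parseable(self, tmp_path, small_params):
        m = write_experiment(tmp_path / "r", small_params, PRESETS["DMSO"],
                             n_per_arm=3, seed=2)
        rois = json.loads(m.loc[0, "background_rois"])
        assert len(rois) == 3 and all(len(r) == 3 for r in rois)


class TestSeedDerivation:
    def test_child_seeds_below_2_31(self, small_params):
        arm = generate_arm(small_params, PRESETS["DMSO"], 3, seed=2**31 + 7)
        for _, truth in arm:
            assert 0 <= truth.seed < 2**31
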