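"""Feature-bank correctness: closed-form GLCM/Haralick cases, brute-force
oracle equivalence for every sliding-window family, and extraction
invariants (determinism, affine invariance, finiteness)."""

import itertools

import numpy as np
import pytest
from scipy import stats

from _oracles import (
    naive_glcm,
    naive_gray_maps,
    naive_haralick,
    naive_haralick_maps,
    naive_separable_correlate,
)
from ipmnrisk import (
    FeatureConfig,
    aggregate_map,
    compute_collage_maps,
    compute_gradient_maps,
    compute_gray_maps,
    compute_haralick_maps,
    compute_laws_maps,
    extract_features,
    glcm_window,
    haralick_stats,
    quantize_roi,
)
from ipmnrisk.radiomics import HARALICK_NAMES, LAWS_KERNELS, OFFSETS_2D, OFFSETS_3D


class TestQuantizeRoi:
    def test_uniform_span_four_levels(self):
        vals = np.linspace(0, 1, 64).reshape(4, 4, 4)
        q = quantize_roi(vals, None, 4)
        edges = [0.25, 0.5, 0.75]
        expected = 1 + np.searchsorted(edges, vals, side="right")
        expected[vals >= 1.0] = 4
        assert np.array_equal(q, expected)

    def test_constant_roi_all_level_one(self):
        q = quantize_roi(np.full((3, 3, 3), 5.0), None, 8)
        assert np.all(q == 1)

    def test_affine_rescale_invariance(self, rng):
        vals = rng.random((6, 6, 6))
        q1 = quantize_roi(vals, None, 16)
        q2 = quantize_roi(3.7 * vals + 11.0, None, 16)
        assert np.array_equal(q1, q2)

    def test_outside_mask_is_ignore_label(self, rng):
        vals = rng.random((5, 5, 5))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        q = quantize_roi(vals, mask, 4)
        assert np.all(q[~mask] == 0)
        assert np.all(q[mask] >= 1)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            quantize_roi(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool), 4)


class TestGlcmWindow:
    def test_constant_patch_single_entry(self):
        G = glcm_window(np.ones((3, 3, 3), dtype=int), 4)
        assert G.sum() == pytest.approx(1.0)
        assert G[0, 0] == pytest.approx(1.0)

    def test_alternating_strip_worked_example(self):
        strip = np.array([1, 2, 1, 2]).reshape(4, 1, 1)
        G = glcm_window(strip, 2, offsets=((1, 0, 0),))
        assert G[0, 1] == pytest.approx(0.5)
        assert G[1, 0] == pytest.approx(0.5)
        assert G[0, 0] == G[1, 1] == 0.0

    def test_nonnegative_and_normalized(self, rng):
        patch = rng.integers(1, 5, size=(4, 4, 4))
        G = glcm_window(patch, 4)
        assert np.all(G >= 0)
        assert G.sum() == pytest.approx(1.0)

    def test_matches_naive_enumeration(self, rng):
        patch = rng.integers(0, 4, size=(4, 4, 3))  # includes ignore voxels
        G = glcm_window(patch, 3)
        assert np.allclose(G, naive_glcm(patch, 3, OFFSETS_3D), atol=1e-12)

    def test_no_valid_pairs_raises(self):
        with pytest.raises(ValueError, match="no valid"):
            glcm_window(np.zeros((3, 3, 3), dtype=int), 4)


class TestHaralickStats:
    def test_single_entry_matrix(self):
        G = np.zeros((4, 4))
        G[0, 0] = 1.0
        s = dict(zip(HARALICK_NAMES, haralick_stats(G)))
        assert s["energy"] == pytest.approx(1.0)
        assert s["contrast"] == pytest.approx(0.0)
        assert s["entropy"] == pytest.approx(0.0)

    def test_two_entry_worked_example(self):
        G = np.zeros((2, 2))
        G[0, 1] = G[1, 0] = 0.5
        s = dict(zip(HARALICK_NAMES, haralick_stats(G)))
        assert s["contrast"] == pytest.approx(1.0)
        assert s["energy"] == pytest.approx(0.5)

    @pytest.mark.parametrize("L", [2, 4, 8])
    def test_uniform_matrix_entropy(self, L):
        G = np.full((L, L), 1.0 / L**2)
        s = dict(zip(HARALICK_NAMES, haralick_stats(G)))
        assert s["entropy"] == pytest.approx(2.0 * np.log2(L))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        G = rng.random((6, 6))
        G = (G + G.T) / 2
        G /= G.sum()
        assert np.allclose(haralick_stats(G), naive_haralick(G), atol=1e-9)


class TestHaralickMaps:
    def test_constant_volume_maps(self):
        maps = compute_haralick_maps(np.full((8, 8, 8), 2.0), None,
                                     windows=(3,), levels_list=(4,))
        assert np.allclose(maps["contrast_w3_g4"], 0.0)
        assert np.allclose(maps["energy_w3_g4"], 1.0)

    def test_default_grid_yields_195_maps(self):
        cfg = FeatureConfig()
        n = len(cfg.haralick_windows) * len(cfg.gray_levels) * len(HARALICK_NAMES)
        assert n == 195
        specs = [s for s in cfg.expand_specs("3D") if s.family == "Haralick"]
        assert len(specs) == n * len(cfg.statistics)

    @pytest.mark.parametrize("mode,offsets", [("3D", OFFSETS_3D), ("2D", OFFSETS_2D)])
    def test_matches_bruteforce_oracle(self, mode, offsets, rng):
        data = rng.random((8, 8, 4))
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[2:6, 2:6, 1:3] = True
        q = quantize_roi(data, mask, 4)
        maps = compute_haralick_maps(data, mask, windows=(3,), levels_list=(4,),
                                     mode=mode)
        oracle = naive_haralick_maps(q, mask, 4, 3, offsets, mode=mode)
        for i, name in enumerate(HARALICK_NAMES):
            assert np.allclose(maps[f"{name}_w3_g4"], oracle[i], atol=1e-9), name

    def test_window_larger_than_volume_raises(self):
        with pytest.raises(ValueError, match="window"):
            compute_haralick_maps(np.zeros((4, 4, 4)), None, windows=(7,),
                                  levels_list=(4,))


class TestCollage:
    def test_ramp_has_near_zero_orientation_entropy(self):
        x = np.arange(16, dtype=float)
        ramp = np.broadcast_to(x[:, None, None], (16, 16, 4)).copy()
        mask = np.zeros((16, 16, 4), dtype=bool)
        mask[4:12, 4:12, 1:3] = True
        maps = compute_collage_maps(ramp, mask, window=5, bins=16, mode="2D")
        assert np.abs(maps["theta_entropy"][mask]).max() < 1e-9

    def test_noise_more_disordered_than_ramp(self, rng):
        shape = (16, 16, 4)
        mask = np.zeros(shape, dtype=bool)
        mask[4:12, 4:12, 1:3] = True
        x = np.arange(16, dtype=float)
        ramp = np.broadcast_to(x[:, None, None], shape).copy()
        noise = rng.random(shape)
        e_ramp = compute_collage_maps(ramp, mask, 5, 16, "2D")["theta_entropy"]
        e_noise = compute_collage_maps(noise, mask, 5, 16, "2D")["theta_entropy"]
        assert e_noise[mask].mean() > e_ramp[mask].mean()

    def test_inplane_rotation_leaves_entropy_unchanged(self, rng):
        shape = (12, 12, 4)
        data = rng.random(shape)
        mask = np.zeros(shape, dtype=bool)
        mask[3:9, 3:9, 1:3] = True
        e = compute_collage_maps(data, mask, 5, 16, "2D")["theta_entropy"]
        data_r = np.rot90(data, k=1, axes=(0, 1)).copy()
        mask_r = np.rot90(mask, k=1, axes=(0, 1)).copy()
        e_r = compute_collage_maps(data_r, mask_r, 5, 16, "2D")["theta_entropy"]
        assert np.median(e[mask]) == pytest.approx(
            np.median(e_r[mask_r]), abs=1e-6
        )

    def test_3d_mode_emits_theta_and_phi(self, rng):
        data = rng.random((10, 10, 10))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[3:7, 3:7, 3:7] = True
        maps = compute_collage_maps(data, mask, 3, 8, "3D")
        assert set(maps) == {"theta_entropy", "phi_entropy"}
        assert np.all(np.isfinite(maps["theta_entropy"][mask]))


class TestLaws:
    def test_derivative_kernels_kill_constants(self):
        const = np.full((8, 8, 8), 3.0)
        maps = compute_laws_maps(const, mode="3D")
        for name, m in maps.items():
            if name == "L5L5L5":
                continue
            assert np.allclose(m, 0.0, atol=1e-9), name

    def test_map_counts(self):
        vol = np.zeros((6, 6, 6))
        assert len(compute_laws_maps(vol, "2D")) == 25
        assert len(compute_laws_maps(vol, "3D")) == 125

    def test_separable_equals_direct_convolution(self, rng):
        data = rng.random((8, 8, 8))
        maps = compute_laws_maps(data, mode="3D")
        for combo in [("L5", "E5", "S5"), ("R5", "R5", "W5"), ("E5", "L5", "L5")]:
            direct = np.abs(
                naive_separable_correlate(data, [LAWS_KERNELS[c] for c in combo])
            )
            assert np.allclose(maps["".join(combo)], direct, atol=1e-9)

    def test_2d_mode_acts_per_slice(self, rng):
        data = rng.random((16, 16, 3))
        maps = compute_laws_maps(data, mode="2D")
        one_slice = compute_laws_maps(data[:, :, 1:2], mode="2D")
        assert np.allclose(maps["E5S5"][:, :, 1], one_slice["E5S5"][:, :, 0])


class TestGradient:
    def test_constant_image_all_zero(self):
        maps = compute_gradient_maps(np.full((6, 6, 6), 2.0), "3D")
        for m in maps.values():
            assert np.allclose(m, 0.0)

    def test_ramp_interior_gradient_equals_slope(self):
        s = 0.75
        x = np.arange(10, dtype=float) * s
        ramp = np.broadcast_to(x[:, None, None], (10, 10, 10)).copy()
        maps = compute_gradient_maps(ramp, "3D")
        interior = maps["fd_magnitude"][1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, s)

    def test_magnitudes_nonnegative(self, rng):
        maps = compute_gradient_maps(rng.standard_normal((6, 6, 6)), "3D")
        assert np.all(maps["sobel_magnitude"] >= 0)
        assert np.all(maps["fd_magnitude"] >= 0)


class TestGray:
    def test_constant_image(self):
        maps = compute_gray_maps(np.full((5, 5, 5), 4.0), window=3)
        assert np.allclose(maps["mean"], 4.0)
        assert np.allclose(maps["median"], 4.0)
        assert np.allclose(maps["std"], 0.0)
        assert np.allclose(maps["range"], 0.0)

    def test_single_bright_voxel_range(self):
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 1.0
        rng_map = compute_gray_maps(data, window=3)["range"]
        expected = np.zeros((7, 7, 7))
        expected[2:5, 2:5, 2:5] = 1.0
        assert np.array_equal(rng_map, expected)

    def test_matches_naive_loops(self, rng):
        data = rng.random((6, 6, 6))
        maps = compute_gray_maps(data, window=3)
        oracle = naive_gray_maps(data, 3)
        for k in ("median", "mean", "std", "range"):
            assert np.allclose(maps[k], oracle[k], atol=1e-9), k


class TestAggregateMap:
    def test_constant_map_degenerate_rule(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        assert aggregate_map(np.full((3, 3, 3), 2.5), mask) == (2.5, 0.0, 0.0, 0.0)

    def test_symmetric_values(self):
        vals = np.array([1.0, 2, 3, 4, 5]).reshape(5, 1, 1)
        med, _, skew, _ = aggregate_map(vals, np.ones((5, 1, 1), bool))
        assert med == 3.0
        assert skew == pytest.approx(0.0)

    def test_matches_scipy_moments(self, rng):
        vals = rng.standard_normal((6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.3
        med, std, sk, ku = aggregate_map(vals, mask)
        v = vals[mask]
        assert med == pytest.approx(np.median(v))
        assert std == pytest.approx(v.std())
        assert sk == pytest.approx(stats.skew(v), abs=1e-12)
        assert ku == pytest.approx(stats.kurtosis(v), abs=1e-12)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            aggregate_map(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), bool))


@pytest.fixture(scope="module")
def volume_and_mask():
    rng = np.random.default_rng(42)
    data = rng.random((12, 12, 8))
    mask = np.zeros((12, 12, 8), dtype=bool)
    mask[3:9, 3:9, 2:6] = True
    return data, mask


class TestExtractFeatures:
    CFG = FeatureConfig(haralick_windows=(3,), gray_levels=(4,), collage_bins=8)

    @pytest.mark.parametrize("mode", ["3D", "2D"])
    def test_deterministic_and_self_consistent(self, volume_and_mask, mode):
        data, mask = volume_and_mask
        v1, specs = extract_features(data, mask, mode, self.CFG)
        v2, _ = extract_features(data, mask, mode, self.CFG)
        assert np.array_equal(v1, v2)
        assert len(v1) == len(specs) == self.CFG.n_features(mode)
        assert np.all(np.isfinite(v1))

    def test_affine_rescaling_preserves_quantized_families(self, volume_and_mask):
        data, mask = volume_and_mask
        v1, specs = extract_features(data, mask, "3D", self.CFG)
        v2, _ = extract_features(5.0 * data + 2.0, mask, "3D", self.CFG)
        idx = [i for i, s in enumerate(specs) if s.family in ("Haralick", "CoLlAGe")]
        assert np.allclose(v1[idx], v2[idx], atol=1e-9)
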