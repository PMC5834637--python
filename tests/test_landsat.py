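"""Cross-sensor offsets, guano classification, gridding, epoch comparison."""

import numpy as np
import pytest
from shapely.geometry import box

import pengcensus as pc
from pengcensus.landsat import GuanoMask

SPECTRA = {"guano": {"green": 0.18, "red": 0.22, "nir": 0.30},
           "non_guano": {"green": 0.08, "red": 0.09, "nir": 0.12}}
OFFSETS = {"green": 0.02, "red": -0.015, "nir": 0.03}


def scene_pair(noise_sd, seed=0, size=32):
    truth = np.zeros((size, size), bool)
    truth[size // 4: size // 2, size // 4: 3 * size // 4] = True
    ref, off = pc.generate_scene_pair(truth, SPECTRA, OFFSETS,
                                      noise_sd=noise_sd, seed=seed)
    return truth, ref, off


class TestOffsets:
    def test_identical_scenes_zero_offsets(self):
        _, ref, _ = scene_pair(0.0)
        est = pc.estimate_offsets(ref, ref)
        assert all(v == 0.0 for v in est.offsets.values())

    def test_noiseless_offsets_recovered_exactly(self):
        _, ref, off = scene_pair(0.0)
        est = pc.estimate_offsets(off, ref)
        for b, v in OFFSETS.items():
            assert est.offsets[b] == pytest.approx(v, abs=1e-12)

    def test_noisy_offsets_within_two_standard_errors(self):
        _, ref, off = scene_pair(0.01, seed=3, size=64)
        est = pc.estimate_offsets(off, ref)
        se = 0.01 * np.sqrt(2) / 64
        for b, v in OFFSETS.items():
            assert abs(est.offsets[b] - v) <= 2 * se

    def test_apply_then_estimate_is_zero_noiseless(self):
        _, ref, off = scene_pair(0.0)
        adj = pc.apply_offsets(off, pc.estimate_offsets(off, ref))
        residual = pc.estimate_offsets(adj, ref)
        assert all(abs(v) < 1e-12 for v in residual.offsets.values())

    def test_adjustment_shrinks_mean_differences_under_noise(self):
        _, ref, off = scene_pair(0.02, seed=9)
        est = pc.estimate_offsets(off, ref)
        adj = pc.apply_offsets(off, est)
        for b in ref.band_names:
            before = abs((off.bands[b] - ref.bands[b]).mean())
            after = abs((adj.bands[b] - ref.bands[b]).mean())
            assert after < before

    def test_empty_mask_rejected(self):
        _, ref, off = scene_pair(0.0)
        with pytest.raises(ValueError, match="mask"):
            pc.estimate_offsets(off, ref, mask=np.zeros(ref.shape, bool))


class TestClassification:
    def test_separable_classes_recovered_exactly(self):
        truth, ref, _ = scene_pair(0.0)
        mask = pc.classify_guano(ref, spectra=SPECTRA)
        np.testing.assert_array_equal(mask.mask, truth)

    def test_high_accuracy_under_small_noise(self):
        truth, ref, _ = scene_pair(0.02, seed=4, size=64)
        mask = pc.classify_guano(ref, spectra=SPECTRA)
        assert (mask.mask == truth).mean() >= 0.99

    def test_all_background_scene_empty_mask(self):
        ref, _ = pc.generate_scene_pair(np.zeros((16, 16), bool), SPECTRA,
                                        {b: 0.0 for b in OFFSETS},
                                        noise_sd=0.0, seed=0)
        assert pc.classify_guano(ref, spectra=SPECTRA).mask.sum() == 0

    def test_untrained_classifier_rejected(self):
        _, ref, _ = scene_pair(0.0)
        with pytest.raises(ValueError, match="classifier"):
            pc.classify_guano(ref)

    def test_accuracy_non_increasing_in_noise(self):
        accs = []
        for noise in (0.01, 0.05, 0.1, 0.2):
            truth, ref, _ = scene_pair(noise, seed=11, size=64)
            mask = pc.classify_guano(ref, spectra=SPECTRA)
            accs.append((mask.mask == truth).mean())
        assert all(a >= b - 0.005 for a, b in zip(accs, accs[1:]))


class TestGridding:
    def test_polygon_covering_one_cell(self):
        mask = pc.reduce_to_grid(box(0, 0, 30, 30), cell_size=30)
        assert mask.mask.shape == (1, 1) and mask.mask.all()

    def test_partial_coverage_below_threshold_unset(self):
        mask = pc.reduce_to_grid(box(0, 0, 12, 30), cell_size=30,
                                 threshold=0.5)
        assert not mask.mask.any()   # 40% covered

    def test_area_preserved_within_perimeter_ring(self):
        rect = box(3, 7, 154, 96)
        mask = pc.reduce_to_grid(rect, cell_size=30)
        assert abs(mask.area_m2 - rect.area) <= rect.length * 30

    def test_mask_reduction_is_idempotent_on_target_grid(self, rng):
        fine = rng.random((8, 8)) > 0.5
        m30 = GuanoMask(fine, cell_size=30.0, epoch="a")
        again = pc.reduce_to_grid(m30, cell_size=30.0)
        np.testing.assert_array_equal(again.mask, m30.mask)

    def test_fine_mask_majority_reduction(self):
        fine = np.zeros((6, 6), bool)
        fine[:3, :3] = True          # upper-left 10 m sub-block fully guano
        fine[0, 3:] = True           # 1/3 coverage on the right block
        out = pc.reduce_to_grid(fine, cell_size=30, fine_cell_size=10)
        np.testing.assert_array_equal(out.mask, [[True, False],
                                                 [False, False]])

    def test_incompatible_cell_sizes_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            pc.reduce_to_grid(np.zeros((4, 4), bool), cell_size=30,
                              fine_cell_size=7)


class TestEpochComparison:
    def masks(self, *grids):
        return [GuanoMask(np.array(g, bool), 30, f"e{i}")
                for i, g in enumerate(grids)]

    def test_identical_masks_no_change(self):
        a = [[1, 0], [1, 1]]
        out = pc.compare_epochs(self.masks(a, a))
        row = out["changes"].iloc[0]
        assert row.gained == 0 and row.lost == 0 and row.area_ratio == 1.0

    def test_pure_gain(self):
        a = np.zeros((5, 5), bool)
        b = a.copy()
        b.ravel()[:10] = True
        out = pc.compare_epochs([GuanoMask(a, 30, "a"), GuanoMask(b, 30, "b")])
        row = out["changes"].iloc[0]
        assert row.gained == 10 and row.lost == 0

    def test_gain_minus_loss_equals_area_difference(self, rng):
        for _ in range(10):
            a = rng.random((12, 12)) > 0.5
            b = rng.random((12, 12)) > 0.5
            out = pc.compare_epochs([GuanoMask(a, 30, "a"),
                                     GuanoMask(b, 30, "b")])
            row = out["changes"].iloc[0]
            assert row.gained - row.lost == int(b.sum()) - int(a.sum())

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            pc.compare_epochs([GuanoMask(np.zeros((2, 2), bool), 30),
                               GuanoMask(np.zeros((3, 3), bool), 30)])
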