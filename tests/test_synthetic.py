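"""Generator behaviour: hard-core spacing, rendering, observer error, scenes."""

import numpy as np
import pytest
from scipy.stats import ranksums

import pengcensus as pc
from pengcensus.synthetic import BlobParams, InfeasibleLayoutError


class TestColonyLayout:
    def test_zero_subcolonies_gives_empty_layout(self):
        layout = pc.generate_colony_layout((0, 0, 10, 10), 0, seed=0)
        assert layout.n_nests == 0

    def test_hardcore_spacing_holds_all_pairs(self):
        layout = pc.generate_colony_layout(
            (0, 0, 30, 30), 1, 60, cluster_radius=3.0, hardcore=0.7, seed=3
        )
        # brute-force all-pairs scan
        assert layout.min_pairwise_distance() >= 0.7

    def test_all_nests_inside_extent_with_labels(self):
        layout = pc.generate_colony_layout(
            (0, 0, 40, 30), 3, 50, seed=5
        )
        assert len(layout.subcolony_id) == layout.n_nests
        x, y = layout.nests[:, 0], layout.nests[:, 1]
        assert (x >= 0).all() and (x <= 40).all()
        assert (y >= 0).all() and (y <= 30).all()

    def test_seed_determinism(self):
        a = pc.generate_colony_layout((0, 0, 30, 30), 2, 40, seed=11)
        b = pc.generate_colony_layout((0, 0, 30, 30), 2, 40, seed=11)
        c = pc.generate_colony_layout((0, 0, 30, 30), 2, 40, seed=12)
        np.testing.assert_array_equal(a.nests, b.nests)
        assert not np.array_equal(a.nests, c.nests)

    def test_infeasible_packing_raises(self):
        with pytest.raises(InfeasibleLayoutError):
            pc.generate_colony_layout(
                (0, 0, 3, 3), 1, 400, cluster_radius=1.0, hardcore=0.7,
                seed=0, attempts_per_nest=50,
            )

    def test_hardcore_must_be_below_cluster_radius(self):
        with pytest.raises(ValueError):
            pc.generate_colony_layout((0, 0, 10, 10), 1, 10,
                                      cluster_radius=1.0, hardcore=2.0)

    def test_nest_nn_shorter_than_csr_at_matched_intensity(self, rng):
        # the premise the spatial filter exploits
        layout = pc.generate_colony_layout((0, 0, 60, 60), 3, 100, seed=21)
        csr = rng.uniform(0, 60, size=(layout.n_nests, 2))
        stat = ranksums(pc.nn_distances(layout.nests),
                        pc.nn_distances(csr), alternative="less")
        assert stat.pvalue < 1e-6


class TestRendering:
    def test_single_nest_brightest_pixel_at_nest(self):
        layout = pc.ColonyLayout(
            "one", np.array([[5.0, 5.0]]), np.array([0]),
            pc.synthetic._as_polygon((0, 0, 10, 10)), 0.0,
        )
        ortho, arts = pc.render_orthomosaic(
            layout, gsd=0.05, artifact_intensity=0.0, noise_sd=0.0, seed=0
        )
        assert len(arts) == 0
        r, c = np.unravel_index(np.argmax(ortho.pixels), ortho.pixels.shape)
        x, y = ortho.pixel_to_world(r, c)
        assert np.hypot(x - 5.0, y - 5.0) <= 0.15  # half a blob width

    def test_artifact_count_scales_with_area(self):
        # doubling area at fixed intensity doubles the expected count
        empty = lambda ext, s: pc.render_orthomosaic(
            pc.generate_colony_layout(ext, 0, seed=0),
            gsd=0.25, artifact_intensity=0.1, noise_sd=0.0, seed=s,
        )[1]
        n1 = np.array([len(empty((0, 0, 20, 10), s)) for s in range(200)])
        n2 = np.array([len(empty((0, 0, 20, 20), s + 500))
                       for s in range(200)])
        se = np.sqrt(n1.var() / len(n1) * 4 + n2.var() / len(n2))
        assert abs(n2.mean() - 2 * n1.mean()) <= 3 * se

    def test_blob_below_one_pixel_rejected(self):
        layout = pc.generate_colony_layout((0, 0, 10, 10), 1, 5, seed=0)
        with pytest.raises(ValueError, match="gsd"):
            pc.render_orthomosaic(layout, gsd=0.5,
                                  blob_params=BlobParams(sigma=0.15))

    def test_world_pixel_roundtrip(self, study_island):
        _, ortho, _ = study_island
        x, y = 12.3, 45.6
        r, c = ortho.world_to_pixel(x, y)
        x2, y2 = ortho.pixel_to_world(r, c)
        assert x2 == pytest.approx(x) and y2 == pytest.approx(y)


class TestObserver:
    @pytest.mark.parametrize("cv,bias,true,expected", [
        (0.0, 1.0, 100, 100),
        (0.0, 1.1, 100, 110),
        (0.0, 1.0, 0, 0),
    ])
    def test_noiseless_counts(self, cv, bias, true, expected):
        obs = pc.ObserverModel(cv=cv, bias=bias)
        assert pc.simulate_observer_count(true, obs, seed=0) == expected

    def test_monte_carlo_relative_sd(self):
        obs = pc.ObserverModel(cv=0.05)
        draws = np.array([
            pc.simulate_observer_count(1000, obs, seed=s) for s in range(1000)
        ])
        assert 0.04 <= draws.std() / draws.mean() <= 0.06

    def test_invalid_observer_params(self):
        with pytest.raises(ValueError):
            pc.ObserverModel(cv=-0.1)
        with pytest.raises(ValueError):
            pc.ObserverModel(bias=0.0)


class TestScenePair:
    SPECTRA = {"guano": {"red": 0.22, "nir": 0.30},
               "non_guano": {"red": 0.09, "nir": 0.12}}

    def test_zero_noise_zero_offset_identical(self):
        truth = np.zeros((8, 8), bool)
        truth[2:5, 2:5] = True
        ref, off = pc.generate_scene_pair(
            truth, self.SPECTRA, {"red": 0.0, "nir": 0.0}, noise_sd=0.0, seed=0
        )
        for b in ref.band_names:
            np.testing.assert_array_equal(ref.bands[b], off.bands[b])

    def test_constant_shift_is_exact_without_noise(self):
        truth = np.zeros((8, 8), bool)
        ref, off = pc.generate_scene_pair(
            truth, self.SPECTRA, {"red": 0.05, "nir": 0.0}, noise_sd=0.0,
            seed=0,
        )
        np.testing.assert_allclose(off.bands["red"] - ref.bands["red"], 0.05)

    def test_mean_difference_tracks_offset_under_noise(self):
        truth = np.zeros((64, 64), bool)
        truth[:20] = True
        offsets = {"red": 0.02, "nir": -0.03}
        ref, off = pc.generate_scene_pair(truth, self.SPECTRA, offsets,
                                          noise_sd=0.01, seed=5)
        for b, true_off in offsets.items():
            got = (off.bands[b] - ref.bands[b]).mean()
            assert abs(got - true_off) < 0.002

    def test_band_name_mismatch_rejected(self):
        with pytest.raises(ValueError, match="band"):
            pc.generate_scene_pair(np.zeros((4, 4), bool), self.SPECTRA,
                                   {"red": 0.0}, seed=0)
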