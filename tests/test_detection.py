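"""Focus detection: pre-blur, prominence maxima, size filter, expression gating."""

import numpy as np
import pytest
from scipy import ndimage

import focikit as fk
from focikit.detection import choose_prominence, robust_noise_sd
from oracles import maxima_bruteforce


class TestPreblur:
    def test_sigma_zero_is_identity(self, rng):
        img = rng.normal(size=(20, 20))
        assert np.array_equal(fk.preblur(img, 0.0), img)

    def test_delta_response_is_sampled_gaussian_kernel(self):
        # independent oracle: separable sampled-and-normalized Gaussian kernel
        sigma, truncate = 0.8, 6.0
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = fk.preblur(img, sigma)
        radius = int(truncate * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        expected = np.zeros_like(img)
        expected[20 - radius : 20 + radius + 1, 20 - radius : 20 + radius + 1] = kernel
        assert np.allclose(out, expected, atol=1e-6 * kernel.max())

    def test_constant_image_is_preserved(self):
        img = np.full((15, 15), 3.7)
        assert np.allclose(fk.preblur(img, 0.8), img)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            fk.preblur(np.zeros((4, 4)), -1.0)


class TestFindMaxima:
    def test_uniform_image_has_no_maxima(self):
        img = np.full((16, 16), 5.0)
        assert fk.find_maxima(img, np.ones((16, 16), bool), 1.0) == []

    def test_single_rendered_spot_found_within_half_pixel(self, small_scene):
        _, _, truth = small_scene
        nuc = truth.nuclei[1]
        pos = (nuc.center[0] + 2.3, nuc.center[1] - 1.6)
        truth.foci.append(
            fk.FocusSpec(nucleus_id=nuc.nucleus_id, channel_name="53bp1", position=pos)
        )
        image = fk.render_channels(truth, fk.NoiseSpec())
        mask = truth.nucleus_masks == nuc.nucleus_id
        found = fk.find_maxima(image["53bp1"], mask, prominence=10.0)
        assert len(found) == 1
        assert abs(found[0].centroid[0] - pos[0]) <= 0.5
        assert abs(found[0].centroid[1] - pos[1]) <= 0.5

    def test_matches_bruteforce_oracle_on_random_images(self, rng):
        for i in range(60):
            img = rng.integers(0, rng.integers(3, 12), size=(16, 16)).astype(float)
            mask = np.ones((16, 16), bool) if i % 3 else rng.random((16, 16)) > 0.2
            for prom in (1.0, 2.5):
                mine = sorted(
                    (round(f.centroid[0], 9), round(f.centroid[1], 9))
                    for f in fk.find_maxima(img, mask, prom)
                )
                assert mine == maxima_bruteforce(img, mask, prom)

    def test_invariant_under_constant_offset(self, rng):
        img = rng.integers(0, 9, size=(16, 16)).astype(float)
        mask = np.ones((16, 16), bool)
        base = [(f.centroid, f.prominence) for f in fk.find_maxima(img, mask, 2.0)]
        shifted = [
            (f.centroid, f.prominence) for f in fk.find_maxima(img + 137.0, mask, 2.0)
        ]
        assert base == shifted

    def test_plateau_reported_once_at_centroid(self):
        img = np.zeros((11, 11))
        img[4:6, 4:7] = 8.0  # 2x3 plateau
        found = fk.find_maxima(img, np.ones((11, 11), bool), 3.0)
        assert len(found) == 1
        assert found[0].centroid == (4.5, 5.0)

    def test_prominence_must_be_positive(self):
        with pytest.raises(ValueError):
            fk.find_maxima(np.zeros((4, 4)), np.ones((4, 4), bool), 0.0)


class TestFilterAndCount:
    def _focus(self, area, nid=1):
        return fk.FocusRecord(nid, "egfp", (0.0, 0.0), 5.0, area, 10.0)

    def test_within_bounds_unchanged(self):
        foci = [self._focus(a) for a in (2, 10, 50)]
        params = fk.DetectionParams(size_min=2, size_max=50)
        assert fk.filter_foci(foci, params) == foci

    def test_undersized_focus_removed(self):
        foci = [self._focus(1), self._focus(3)]
        params = fk.DetectionParams(size_min=2, size_max=50)
        assert fk.filter_foci(foci, params) == [foci[1]]

    def test_bounds_applied_exactly(self):
        areas = [1, 2, 5, 50, 51, 200]
        foci = [self._focus(a) for a in areas]
        params = fk.DetectionParams(size_min=2, size_max=50)
        kept = fk.filter_foci(foci, params)
        assert [f.area for f in kept] == [a for a in areas if 2 <= a <= 50]

    def test_count_foci_no_gated_cells(self):
        table, mean = fk.count_foci([self._focus(5)], set())
        assert table.empty and mean is None

    def test_count_foci_k_per_cell(self):
        foci = [self._focus(5, nid) for nid in (1, 1, 1, 2, 2, 2)]
        table, mean = fk.count_foci(foci, {1, 2})
        assert mean == 3.0
        assert list(table["n_foci"]) == [3, 3]

    def test_counts_ignore_non_gated_cells(self):
        foci = [self._focus(5, 1), self._focus(5, 2)]
        table, mean = fk.count_foci(foci, {1})
        assert list(table["nucleus_id"]) == [1] and mean == 1.0


class TestExpressionGating:
    def _half_expressing_scene(self):
        spec = fk.SceneSpec(
            image_shape=(220, 220),
            n_nuclei=6,
            nucleus_radius_range=(14, 18),
            egfp_fraction=0.5,
            seed=33,
        )
        image, truth = fk.generate_nuclei_scene(spec)
        # a seeded draw may express any subset; regenerate until both kinds exist
        attempt = 33
        while not (0 < len(truth.expressing_ids()) < truth.n_nuclei):
            attempt += 1
            spec = fk.SceneSpec(
                image_shape=(220, 220),
                n_nuclei=6,
                nucleus_radius_range=(14, 18),
                egfp_fraction=0.5,
                seed=attempt,
            )
            image, truth = fk.generate_nuclei_scene(spec)
        return image, truth

    def test_exactly_the_expressing_half_passes(self):
        image, truth = self._half_expressing_scene()
        lm = fk.LabelMap(truth.nucleus_masks, truth.pixel_scale)
        gated = fk.gate_expressing_cells(image["egfp"], lm)
        assert gated == truth.expressing_ids()

    def test_gate_invariant_under_global_scaling(self):
        image, truth = self._half_expressing_scene()
        lm = fk.LabelMap(truth.nucleus_masks, truth.pixel_scale)
        gated = fk.gate_expressing_cells(image["egfp"], lm)
        assert fk.gate_expressing_cells(image["egfp"] * 4.0, lm) == gated

    def test_zero_contrast_channel_raises_no_expressing_cells(self, small_scene):
        _, _, truth = small_scene
        lm = fk.LabelMap(truth.nucleus_masks, truth.pixel_scale)
        with pytest.raises(fk.NoExpressingCellsError):
            fk.gate_expressing_cells(np.zeros(truth.nucleus_masks.shape), lm)

    def test_empty_label_map_gives_empty_set(self):
        lm = fk.LabelMap(np.zeros((32, 32), dtype=np.int32), 1.0)
        assert fk.gate_expressing_cells(np.random.default_rng(0).random((32, 32)), lm) == set()


class TestDetectFoci:
    def test_counts_equal_generator_truth_noiseless(self, small_scene):
        _, _, truth = small_scene
        truth = fk.place_random_foci(truth, "53bp1", 3, seed=5)
        image = fk.render_channels(truth, fk.NoiseSpec())
        lm = fk.LabelMap(truth.nucleus_masks, truth.pixel_scale)
        foci = fk.detect_foci(image["53bp1"], lm, channel_name="53bp1")
        per_cell = {nid: 0 for nid in lm.label_ids}
        for f in foci:
            per_cell[f.nucleus_id] += 1
        assert all(v == 3 for v in per_cell.values())

    @pytest.mark.parametrize("seed", [8, 9, 10])
    def test_recall_and_precision_at_high_snr(self, seed):
        """>= 0.95 recall/precision for amplitude >= 10x noise SD on resolvable
        foci (8 px spacing, above the Rayleigh limit of 6 px FWHM spots)."""
        spec = fk.SceneSpec(
            image_shape=(256, 256),
            n_nuclei=5,
            nucleus_radius_range=(16, 22),
            noise=fk.NoiseSpec(read_noise_sd=10.0),
            seed=seed,
        )
        _, truth = fk.generate_nuclei_scene(spec)
        truth = fk.place_random_foci(truth, "53bp1", 4, amplitude=100.0, seed=seed)
        image = fk.render_channels(truth, spec.noise, seed=seed)
        lm = fk.LabelMap(truth.nucleus_masks, truth.pixel_scale)
        found = fk.detect_foci(image["53bp1"], lm, channel_name="53bp1")
        true_pos = [f.position for f in truth.foci]
        matched_truth = set()
        matched_det = 0
        for f in found:
            dists = [
                np.hypot(f.centroid[0] - p[0], f.centroid[1] - p[1]) for p in true_pos
            ]
            j = int(np.argmin(dists))
            if dists[j] <= 3.0:
                matched_det += 1
                matched_truth.add(j)
        recall = len(matched_truth) / len(true_pos)
        precision = matched_det / len(found) if found else 0.0
        assert recall >= 0.95 and precision >= 0.95

    def test_detection_invariant_to_label_permutation(self, small_scene):
        _, _, truth = small_scene
        truth = fk.place_random_foci(truth, "53bp1", 2, seed=6)
        image = fk.render_channels(truth, fk.NoiseSpec())
        lm = fk.LabelMap(truth.nucleus_masks, truth.pixel_scale)
        foci = fk.detect_foci(image["53bp1"], lm, channel_name="53bp1")
        # permute labels 1->2->3->1
        perm = {0: 0, 1: 2, 2: 3, 3: 1}
        permuted = np.vectorize(perm.get)(truth.nucleus_masks).astype(np.int32)
        lm2 = fk.LabelMap(permuted, truth.pixel_scale)
        foci2 = fk.detect_foci(image["53bp1"], lm2, channel_name="53bp1")
        c1 = sorted(f.centroid for f in foci)
        c2 = sorted(f.centroid for f in foci2)
        assert c1 == c2


def test_robust_noise_sd_matches_gaussian_sd(rng):
    x = rng.normal(0.0, 7.0, size=40000)
    assert robust_noise_sd(x) == pytest.approx(7.0, rel=0.05)


def test_choose_prominence_scales_with_background_noise(rng):
    img = rng.normal(50.0, 4.0, size=(128, 128))
    lm = fk.LabelMap(np.zeros((128, 128), dtype=np.int32), 1.0)
    prom = choose_prominence(img, lm, fk.DetectionParams(prominence_k=5.0))
    assert prom == pytest.approx(20.0, rel=0.1)
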