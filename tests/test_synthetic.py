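"""Generator contracts: determinism, truth consistency, noise and kinetics."""

import numpy as np
import pytest

import focikit as fk
from focikit.synthetic import _gaussian_spot


class TestNucleiScene:
    def test_empty_scene_is_blank(self):
        spec = fk.SceneSpec(image_shape=(64, 64), n_nuclei=0, seed=1)
        image, truth = fk.generate_nuclei_scene(spec)
        assert np.allclose(image["hoechst"], spec.background_level)
        assert truth.nucleus_masks.max() == 0

    def test_touching_allowed_yields_requested_count(self):
        spec = fk.SceneSpec(
            image_shape=(96, 96),
            n_nuclei=2,
            nucleus_radius_range=(14, 18),
            allow_touching=True,
            seed=4,
        )
        _, truth = fk.generate_nuclei_scene(spec)
        labels = set(np.unique(truth.nucleus_masks)) - {0}
        assert labels == {1, 2}

    def test_fixed_seed_is_bit_identical(self):
        spec = fk.SceneSpec(image_shape=(96, 96), n_nuclei=3, seed=9,
                            nucleus_radius_range=(10, 14),
                            noise=fk.NoiseSpec(poisson_scale=1.0, read_noise_sd=2.0))
        img1, _ = fk.generate_nuclei_scene(spec)
        img2, _ = fk.generate_nuclei_scene(spec)
        for ch in img1.channel_names:
            assert np.array_equal(img1[ch], img2[ch])

    def test_nuclei_rendered_above_background(self, small_scene):
        _, image, truth = small_scene
        hoechst = image["hoechst"]
        for nuc in truth.nuclei:
            r, c = int(round(nuc.center[0])), int(round(nuc.center[1]))
            assert hoechst[r, c] > truth.background_level

    def test_overcrowded_placement_raises(self):
        spec = fk.SceneSpec(
            image_shape=(64, 64),
            n_nuclei=12,
            nucleus_radius_range=(14, 16),
            allow_touching=False,
            seed=2,
        )
        with pytest.raises(fk.PlacementError):
            fk.generate_nuclei_scene(spec)


class TestFocusPairs:
    def test_requested_distances_recover_exactly(self, small_scene):
        _, _, truth = small_scene
        distances = [3.0, 10.0, 20.0]
        truth = fk.place_focus_pairs(truth, "egfp", "53bp1", distances)
        assert [d for _, _, d in truth.pair_distances] == pytest.approx(
            distances, abs=1e-9
        )
        truth.verify_pair_distances(atol=1e-9)
        # the three requested separations span the three proximity classes
        classes = [fk.classify_proximity(d) for d in distances]
        assert classes == ["overlapping", "proximal", "distant"]

    def test_zero_distance_gives_coincident_centroids(self, small_scene):
        _, _, truth = small_scene
        truth = fk.place_focus_pairs(truth, "egfp", "53bp1", [0.0])
        fa, fb = truth.foci[-2:]
        assert fa.position == pytest.approx(fb.position, abs=1e-12)

    def test_random_distances_fixed_seed(self, small_scene, rng):
        _, _, truth = small_scene
        distances = list(rng.uniform(0, 18, size=6))
        truth = fk.place_focus_pairs(truth, "egfp", "53bp1", distances)
        for (ia, ib, d), want in zip(truth.pair_distances, distances):
            pa = np.array(truth.foci[ia].position)
            pb = np.array(truth.foci[ib].position)
            assert np.hypot(*(pa - pb)) == pytest.approx(want, abs=1e-9)
        # both members inside the same nucleus
        for ia, ib, _ in truth.pair_distances:
            assert truth.foci[ia].nucleus_id == truth.foci[ib].nucleus_id
            nuc = truth.nucleus(truth.foci[ia].nucleus_id)
            assert nuc.contains(*truth.foci[ia].position)
            assert nuc.contains(*truth.foci[ib].position)

    def test_oversized_distance_raises(self, small_scene):
        _, _, truth = small_scene
        with pytest.raises(fk.PlacementError):
            fk.place_focus_pairs(truth, "egfp", "53bp1", [200.0])


class TestRenderChannels:
    def test_zero_noise_single_focus_peaks_at_position(self, small_scene):
        _, _, truth = small_scene
        nuc = truth.nuclei[0]
        pos = (round(nuc.center[0]) + 0.0, round(nuc.center[1]) + 0.0)
        truth.foci.append(
            fk.FocusSpec(nucleus_id=nuc.nucleus_id, channel_name="53bp1", position=pos)
        )
        image = fk.render_channels(truth, fk.NoiseSpec())
        peak = np.unravel_index(np.argmax(image["53bp1"]), image.shape)
        assert peak == (int(pos[0]), int(pos[1]))

    def test_zero_amplitude_focus_leaves_background(self, small_scene):
        _, _, truth = small_scene
        nuc = truth.nuclei[0]
        truth.foci.append(
            fk.FocusSpec(
                nucleus_id=nuc.nucleus_id,
                channel_name="53bp1",
                position=nuc.center,
                amplitude=0.0,
            )
        )
        image = fk.render_channels(truth, fk.NoiseSpec())
        assert np.allclose(image["53bp1"], truth.background_level)

    def test_all_pixels_non_negative_under_noise(self, small_scene):
        _, _, truth = small_scene
        noise = fk.NoiseSpec(poisson_scale=0.5, read_noise_sd=20.0, offset=1.0)
        image = fk.render_channels(truth, noise, seed=3)
        for ch in image.channel_names:
            assert (image[ch] >= 0).all()

    def test_poisson_mean_matches_noiseless_render(self, small_scene):
        """Monte-Carlo: Poisson-only sampling is unbiased at the focus peak."""
        _, _, truth = small_scene
        nuc = truth.nuclei[0]
        pos = (float(round(nuc.center[0])), float(round(nuc.center[1])))
        truth.foci.append(
            fk.FocusSpec(
                nucleus_id=nuc.nucleus_id, channel_name="53bp1",
                position=pos, amplitude=500.0,
            )
        )
        clean = fk.render_channels(truth, fk.NoiseSpec())
        r, c = int(pos[0]), int(pos[1])
        expected = clean["53bp1"][r, c]
        noise = fk.NoiseSpec(poisson_scale=1.0)
        samples = [
            fk.render_channels(truth, noise, seed=s)["53bp1"][r, c] for s in range(100)
        ]
        se = np.std(samples, ddof=1) / 10.0
        assert abs(np.mean(samples) - expected) < 3 * se


class TestStripeMovie:
    def test_null_amplitude_damage_equals_control(self):
        kin = fk.KineticsSpec(amplitude=0.0, tau=120.0, n_frames=20)
        movie, truth = fk.generate_stripe_movie(kin, fk.default_stripe_scene(1))
        nid = int(truth.nucleus_masks[truth.damage_roi.slices].max())
        pair = fk.auto_place_control(truth.nucleus_masks == nid, truth.damage_roi)
        trace = fk.normalize_trace(fk.extract_traces(movie, pair))
        assert np.allclose(trace.ratio, 1.0, atol=1e-9)

    def test_plateau_of_unit_amplitude_is_two(self):
        # noiseless, no bleaching: R -> 1 + A = 2 as t >> tau
        kin = fk.KineticsSpec(amplitude=1.0, tau=60.0, bleach_rate=0.0)
        movie, truth = fk.generate_stripe_movie(kin, fk.default_stripe_scene(2))
        nid = int(truth.nucleus_masks[truth.damage_roi.slices].max())
        pair = fk.auto_place_control(truth.nucleus_masks == nid, truth.damage_roi)
        trace = fk.normalize_trace(fk.extract_traces(movie, pair))
        assert trace.ratio[-1] == pytest.approx(2.0, abs=1e-6)

    def test_ratio_matches_closed_form_despite_bleaching(self):
        kin = fk.KineticsSpec(amplitude=0.8, tau=120.0, bleach_rate=0.001)
        movie, truth = fk.generate_stripe_movie(kin, fk.default_stripe_scene(3))
        nid = int(truth.nucleus_masks[truth.damage_roi.slices].max())
        pair = fk.auto_place_control(truth.nucleus_masks == nid, truth.damage_roi)
        trace = fk.normalize_trace(fk.extract_traces(movie, pair))
        expected = kin.ratio(movie.times)
        assert np.abs(trace.ratio - expected).max() < 1e-6

    @pytest.mark.parametrize("bleach_rate", [0.0, 1e-4, 1e-3, 5e-3, 2e-2])
    def test_bleach_cancellation_invariant(self, bleach_rate):
        """The noiseless double-normalized ratio is independent of bleach rate."""
        kin = fk.KineticsSpec(amplitude=0.5, tau=90.0, bleach_rate=bleach_rate, n_frames=40)
        movie, truth = fk.generate_stripe_movie(kin, fk.default_stripe_scene(4))
        nid = int(truth.nucleus_masks[truth.damage_roi.slices].max())
        pair = fk.auto_place_control(truth.nucleus_masks == nid, truth.damage_roi)
        trace = fk.normalize_trace(fk.extract_traces(movie, pair))
        reference = fk.KineticsSpec(
            amplitude=0.5, tau=90.0, bleach_rate=0.0, n_frames=40
        ).ratio(movie.times)
        assert np.abs(trace.ratio - reference).max() < 1e-9

    def test_no_recruitment_before_damage_frame(self):
        kin = fk.KineticsSpec(amplitude=1.0, tau=30.0, n_frames=30)
        movie, truth = fk.generate_stripe_movie(kin, fk.default_stripe_scene(5))
        rs, cs = truth.damage_roi.slices
        pre = movie.frames[: kin.damage_frame + 1, rs, cs].mean(axis=(1, 2))
        assert np.allclose(pre, pre[0], atol=1e-9)
        post = movie.frames[kin.damage_frame + 1 :, rs, cs].mean(axis=(1, 2))
        assert (post > pre[0]).all()

    def test_stripe_too_large_raises(self):
        kin = fk.KineticsSpec(stripe_length=30.0)  # 300 px stripe, 128 px image
        with pytest.raises(fk.GeometryError):
            fk.generate_stripe_movie(kin, fk.default_stripe_scene(6))

    def test_movie_deterministic_for_fixed_seed(self):
        kin = fk.KineticsSpec(n_frames=12)
        scene = fk.default_stripe_scene(7, snr=10.0)
        m1, _ = fk.generate_stripe_movie(kin, scene)
        m2, _ = fk.generate_stripe_movie(kin, scene)
        assert np.array_equal(m1.frames, m2.frames)


def test_gaussian_spot_is_sampled_gaussian():
    spot = _gaussian_spot((21, 21), (10.0, 10.0), sigma=2.0, amplitude=5.0)
    rows, cols = np.mgrid[0:21, 0:21]
    expected = 5.0 * np.exp(-((rows - 10.0) ** 2 + (cols - 10.0) ** 2) / 8.0)
    assert np.allclose(spot, expected, atol=1e-12)


def test_spec_validation_rejects_bad_parameters():
    with pytest.raises(ValueError):
        fk.SceneSpec(pixel_scale=0.0)
    with pytest.raises(ValueError):
        fk.SceneSpec(nucleus_radius_range=(5.0, 2.0))
    with pytest.raises(ValueError):
        fk.KineticsSpec(tau=-1.0)
    with pytest.raises(ValueError):
        fk.KineticsSpec(damage_frame=100, n_frames=80)
    with pytest.raises(ValueError):
        fk.NoiseSpec(read_noise_sd=-1.0)
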