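"""Generator correctness: determinism, geometry, intensity models, masks."""

import dataclasses

import numpy as np
import pytest

from guvquant import (
    SimImageConfig,
    simulate_field,
    simulate_patterned_field,
    stripe_mask,
)
from guvquant.synthetic_microscopy import (
    GFP,
    TXR,
    LogNormalModel,
    TruncatedLogNormalModel,
    disk_mean,
    truth_to_dataframe,
)


class TestDiameterModel:
    def test_truncated_moments_match_population_statistics(self, rng):
        """10^4 draws: mean 6.5 +- 0.2 um, sd 2.3 +- 0.2 um, all in [3, 20]."""
        model = TruncatedLogNormalModel()
        draws = model.sample(rng, 10_000)
        assert abs(draws.mean() - 6.5) < 0.2
        assert abs(draws.std(ddof=1) - 2.3) < 0.2
        assert draws.min() >= 3.0 and draws.max() <= 20.0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            TruncatedLogNormalModel(lower=20.0, upper=3.0)
        with pytest.raises(ValueError):
            TruncatedLogNormalModel(mean=25.0)  # outside [3, 20]

    def test_gfp_on_model_spans_an_order_of_magnitude(self):
        """Default reporter 'on' intensities span >= 10x between 5th/95th pct."""
        model = SimImageConfig().gfp_on_model
        assert model.quantile(0.95) / model.quantile(0.05) >= 10.0


class TestSimulateField:
    def test_empty_field_is_background_only(self):
        cfg = SimImageConfig(field_size_px=(64, 64), n_vesicles=0, noise_sd=0.0,
                             rng_seed=0)
        images, truths = simulate_field(cfg)
        assert truths == []
        assert np.allclose(images[TXR].pixels, cfg.background_level[TXR])
        assert np.allclose(images[GFP].pixels, cfg.background_level[GFP])

    def test_fixed_seed_is_bit_reproducible(self):
        cfg = SimImageConfig(field_size_px=(128, 128), n_vesicles=5, rng_seed=7)
        a_images, a_truths = simulate_field(cfg)
        b_images, b_truths = simulate_field(cfg)
        for ch in (TXR, GFP):
            np.testing.assert_array_equal(a_images[ch].pixels, b_images[ch].pixels)
        assert truth_to_dataframe(a_truths).equals(truth_to_dataframe(b_truths))

    def test_rendered_intensity_matches_truth(self):
        """Interior mean of a noise-free rendered disk equals truth within 2%."""
        cfg = SimImageConfig(field_size_px=(256, 256), n_vesicles=6, noise_sd=0.0,
                             pixel_size_um=0.13, rng_seed=3)
        images, truths = simulate_field(cfg)
        for t in truths:
            r_px = t.diameter_um / (2 * cfg.pixel_size_um)
            measured = disk_mean(images[TXR], t.center, r_px, interior_margin=0.5)
            expected = t.txr_intensity + cfg.background_level[TXR]
            assert measured == pytest.approx(expected, rel=0.02)

    def test_nonexpressing_vesicles_render_at_off_level(self):
        cfg = SimImageConfig(field_size_px=(256, 256), n_vesicles=6, noise_sd=0.0,
                             pixel_size_um=0.13, expressing_fraction=0.0, rng_seed=3)
        images, truths = simulate_field(cfg)
        for t in truths:
            assert not t.expressing
            assert t.gfp_intensity == cfg.gfp_off_level
            r_px = t.diameter_um / (2 * cfg.pixel_size_um)
            measured = disk_mean(images[GFP], t.center, r_px, interior_margin=0.5)
            expected = cfg.gfp_off_level + cfg.background_level[GFP]
            assert measured == pytest.approx(expected, rel=0.02)

    def test_vesicles_respect_overlap_rule(self):
        cfg = SimImageConfig(field_size_px=(512, 512), n_vesicles=40, rng_seed=5)
        _, truths = simulate_field(cfg)
        centers = np.array([t.center for t in truths])
        radii = np.array([t.diameter_um for t in truths]) / (2 * cfg.pixel_size_um)
        for i in range(len(truths)):
            for j in range(i + 1, len(truths)):
                dist = np.hypot(*(centers[i] - centers[j]))
                assert dist > 0.9 * (radii[i] + radii[j])

    def test_impossible_density_raises_naming_achievable_density(self):
        cfg = SimImageConfig(field_size_px=(80, 80), n_vesicles=200,
                             pixel_size_um=0.65, rng_seed=0)
        from guvquant.synthetic_microscopy import PlacementError

        with pytest.raises(PlacementError, match="density"):
            simulate_field(cfg)

    def test_expressing_fraction_validation(self):
        with pytest.raises(ValueError):
            SimImageConfig(expressing_fraction=1.5)


class TestPatternedField:
    def test_all_ones_mask_matches_unmasked_simulation(self):
        cfg = SimImageConfig(field_size_px=(128, 128), n_vesicles=6, rng_seed=11)
        plain_images, plain_truths = simulate_field(cfg)
        mask = np.ones((128, 128), dtype=np.uint8)
        masked_images, masked_truths = simulate_patterned_field(cfg, mask)
        for ch in (TXR, GFP):
            np.testing.assert_array_equal(
                plain_images[ch].pixels, masked_images[ch].pixels
            )
        assert [t.expressing for t in plain_truths] == [
            t.expressing for t in masked_truths
        ]

    def test_all_zeros_mask_silences_every_vesicle(self):
        cfg = SimImageConfig(field_size_px=(128, 128), n_vesicles=6, rng_seed=11)
        _, truths = simulate_patterned_field(cfg, np.zeros((128, 128), dtype=np.uint8))
        assert all(not t.expressing for t in truths)
        assert all(not t.inside_mask for t in truths)

    def test_expressing_centers_lie_inside_stripes(self):
        shape = (256, 256)
        mask = stripe_mask(shape, stripe_width_px=40)
        cfg = SimImageConfig(field_size_px=shape, n_vesicles=20,
                             expressing_fraction=1.0, rng_seed=2)
        _, truths = simulate_patterned_field(cfg, mask)
        assert any(t.expressing for t in truths)
        for t in truths:
            r, c = int(round(t.center[0])), int(round(t.center[1]))
            if t.expressing:
                assert mask[r, c] == 1
            assert t.inside_mask == bool(mask[r, c])

    def test_non_binary_mask_rejected(self):
        cfg = SimImageConfig(field_size_px=(64, 64), n_vesicles=2, rng_seed=0)
        with pytest.raises(ValueError, match="binary"):
            simulate_patterned_field(cfg, np.full((64, 64), 2, dtype=np.uint8))

    def test_mask_shape_mismatch_rejected(self):
        cfg = SimImageConfig(field_size_px=(64, 64), n_vesicles=2, rng_seed=0)
        with pytest.raises(ValueError, match="shape"):
            simulate_patterned_field(cfg, np.ones((32, 32), dtype=np.uint8))


class TestStripeMask:
    def test_stripe_geometry(self):
        mask = stripe_mask((8, 10), stripe_width_px=2, pitch_px=5)
        assert mask.shape == (8, 10)
        np.testing.assert_array_equal(mask[0], [1, 1, 0, 0, 0, 1, 1, 0, 0, 0])

    def test_roundtrip_field_io(self, tmp_path, small_field):
        from guvquant.synthetic_microscopy import read_channel_image, write_field

        cfg, images, truths = small_field
        paths = write_field(tmp_path, images, truths)
        back = read_channel_image(paths[TXR], TXR, cfg.pixel_size_um)
        # 16-bit quantization only
        assert np.abs(back.pixels - images[TXR].pixels).max() <= 0.5 + 1e-9
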