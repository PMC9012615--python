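"""Scalogram encoding: transform correctness against a brute-force oracle,
normalisation and rendering contracts."""

import numpy as np
import pytest

from raecg.encoding import (
    CWTConfig,
    CWTScalogram,
    ScalogramImage,
    cwt_scalogram,
    default_scales,
    mexican_hat,
    morlet,
    render_image,
)


def brute_force_scalogram(x, scales, psi):
    """Direct O(n_scales * n^2) evaluation of the discretised transform."""
    n = len(x)
    out = np.empty((len(scales), n))
    t = np.arange(n)
    for i, a in enumerate(scales):
        for b in range(n):
            out[i, b] = np.sum(x * psi((t - b) / a)) / np.sqrt(a)
    return np.abs(out)


class TestCWT:
    def test_zero_input_gives_zero_matrix(self):
        cfg = CWTConfig(scales=np.array([2.0, 4.0, 8.0]))
        assert np.all(cwt_scalogram(np.zeros(256), cfg) == 0)

    def test_magnitude_is_homogeneous_in_input_scale(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(128)
        cfg = CWTConfig(scales=np.array([3.0, 9.0]))
        base = cwt_scalogram(x, cfg)
        assert np.allclose(cwt_scalogram(-2.5 * x, cfg), 2.5 * base, rtol=1e-10)

    @pytest.mark.parametrize("wavelet,psi", [("morlet", morlet),
                                             ("mexican_hat", mexican_hat)])
    def test_impulse_response_is_scaled_wavelet(self, wavelet, psi):
        n, loc, a = 256, 128, 12.0
        x = np.zeros(n)
        x[loc] = 1.0
        cfg = CWTConfig(wavelet=wavelet, scales=np.array([a, 2 * a]))
        got = cwt_scalogram(x, cfg)
        b = np.arange(n)
        expected = np.abs(psi((loc - b) / a) / np.sqrt(a))
        assert np.allclose(got[0], expected, atol=1e-10)

    @pytest.mark.parametrize("n", [64, 200, 512])
    def test_matches_brute_force_summation_oracle(self, n):
        rng = np.random.default_rng(n)
        x = rng.standard_normal(n)
        scales = np.array([2.0, 5.0, 17.0, 60.0])
        cfg = CWTConfig(wavelet="morlet", scales=scales)
        got = cwt_scalogram(x, cfg)
        want = brute_force_scalogram(x, scales, morlet)
        assert np.allclose(got, want, rtol=1e-6, atol=1e-6 * want.max())

    def test_non_finite_samples_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            cwt_scalogram(np.array([0.0, np.nan, 1.0]))

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            cwt_scalogram(np.array([1.0]))

    def test_default_scales_cover_requested_band_in_order(self):
        scales = default_scales(n_scales=32, fmin=0.5, fmax=45.0,
                                sampling_rate=360.0)
        assert len(scales) == 32
        assert np.all(np.diff(scales) > 0)  # increasing scale = decreasing freq
        fc = 5.0 / (2 * np.pi)
        freqs = fc * 360.0 / scales
        assert np.isclose(freqs[0], 45.0) and np.isclose(freqs[-1], 0.5)


class TestRenderImage:
    def test_output_is_3x224x224_in_unit_range(self):
        rng = np.random.default_rng(1)
        img = render_image(rng.random((64, 300)))
        assert img.pixels.shape == (3, 224, 224)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_output_shape_independent_of_beat_length(self):
        rng = np.random.default_rng(2)
        shapes = {render_image(rng.random((32, n))).pixels.shape
                  for n in (40, 173, 801)}
        assert shapes == {(3, 224, 224)}

    def test_constant_matrix_renders_all_zero(self):
        img = render_image(np.full((16, 100), 3.7))
        assert np.all(img.pixels == 0)

    def test_replicate_mode_gives_identical_channels(self):
        rng = np.random.default_rng(3)
        mat = rng.random((224, 224))
        img = render_image(mat, channel_mode="replicate")
        assert np.array_equal(img.pixels[0], img.pixels[1])
        assert np.array_equal(img.pixels[0], img.pixels[2])
        # already at target size: normalisation only
        span = mat.max() - mat.min()
        assert np.allclose(img.pixels[0], (mat - mat.min()) / span, atol=1e-6)

    def test_colormap_mode_gives_rgb(self):
        img = render_image(np.random.default_rng(4).random((16, 50)),
                           channel_mode="colormap")
        assert img.pixels.shape == (3, 224, 224)
        assert not np.array_equal(img.pixels[0], img.pixels[1])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            render_image(np.empty((0, 0)))

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ScalogramImage(pixels=np.full((3, 8, 8), np.inf), label="N")
        with pytest.raises(ValueError, match="3, H, W"):
            ScalogramImage(pixels=np.zeros((1, 8, 8)), label="N")


class TestTransformer:
    def test_transforms_beats_with_labels_and_provenance(self, mixed_record):
        from raecg.segmentation import segment_beats
        beats = segment_beats(mixed_record)[:5]
        enc = CWTScalogram(image_size=32, n_scales=12)
        images = enc.fit_transform(beats)
        assert len(images) == 5
        for beat, img in zip(beats, images):
            assert img.pixels.shape == (3, 32, 32)
            assert img.label == beat.label
            assert img.record_id == beat.record_id

    def test_sklearn_param_round_trip(self):
        enc = CWTScalogram(n_scales=20)
        assert CWTScalogram(**enc.get_params()).n_scales == 20
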