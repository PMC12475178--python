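"""Stimulus-engineering invariants: whitening, 1/f, band filters, gratings."""

import numpy as np
import pytest
import scipy.fft  # independent transform for phase checks

from tiltfilm.frames import (FilterSpec, FrameImage, GratingSpec,
                             apply_one_over_f, circular_crop, filter_frame,
                             frequency_grid, make_test_grating,
                             orientation_filter_profile, sf_filter_profile,
                             whiten_amplitude, wrap_orientation)


def nondc_amplitudes(pixels):
    amp = np.abs(np.fft.fft2(pixels))
    mask = np.ones(amp.shape, dtype=bool)
    mask[0, 0] = False
    return amp[mask]


class TestWhitening:
    def test_flat_amplitude_spectrum(self, texture_frame):
        out = whiten_amplitude(texture_frame)
        amps = nondc_amplitudes(out.pixels)
        assert np.ptp(amps) / amps.mean() < 1e-10

    def test_equalises_unequal_sinusoids(self):
        x = np.arange(64)
        img = (0.5 + 0.3 * np.cos(2 * np.pi * 4 * x[None, :] / 64)
               + 0.05 * np.cos(2 * np.pi * 4 * x[:, None] / 64))
        out = whiten_amplitude(FrameImage(img, ppd=16.0))
        amp = np.abs(np.fft.fft2(out.pixels))
        assert amp[0, 4] == pytest.approx(amp[4, 0], rel=1e-10)

    def test_phase_preserved_against_independent_transform(self, texture_frame):
        out = whiten_amplitude(texture_frame)
        # oracle: scipy.fft, separate implementation from np.fft used inside
        ph_in = np.angle(scipy.fft.fft2(texture_frame.pixels))
        ph_out = np.angle(scipy.fft.fft2(out.pixels))
        mask = np.ones(ph_in.shape, dtype=bool)
        mask[0, 0] = False
        diff = np.angle(np.exp(1j * (ph_out - ph_in)))[mask]
        assert np.abs(diff).max() < 1e-10

    def test_dc_is_mean_luminance(self, texture_frame):
        out = whiten_amplitude(texture_frame)
        assert out.mean_lum == pytest.approx(texture_frame.mean_lum, abs=1e-12)

    def test_constant_frame_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            whiten_amplitude(FrameImage(np.full((16, 16), 0.5), ppd=10.0))


class TestOneOverF:
    def test_log_log_slope_is_minus_one(self, texture_frame):
        out = apply_one_over_f(whiten_amplitude(texture_frame))
        amp = np.abs(np.fft.fft2(out.pixels))
        f, _ = frequency_grid(out.pixels.shape, out.ppd)
        sel = (f > 0.5) & (f < 6.0)  # resolvable band away from DC/Nyquist
        slope = np.polyfit(np.log(f[sel]), np.log(amp[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_two_to_one_amplitude_ratio(self):
        # 64 px at 16 ppd -> 4 deg field; 2 cpd and 4 cpd fall on exact bins
        x = np.arange(64)
        img = (0.5 + 0.1 * np.cos(2 * np.pi * 8 * x[None, :] / 64)
               + 0.1 * np.cos(2 * np.pi * 16 * x[None, :] / 64))
        out = apply_one_over_f(FrameImage(img, ppd=16.0))
        amp = np.abs(np.fft.fft2(out.pixels))
        assert amp[0, 8] / amp[0, 16] == pytest.approx(2.0, rel=1e-6)

    def test_dc_untouched(self, texture_frame):
        out = apply_one_over_f(texture_frame)
        assert out.mean_lum == pytest.approx(texture_frame.mean_lum, abs=1e-12)


class TestFilterProfiles:
    @pytest.mark.parametrize("f,expected", [
        (2.0, 1.0),                      # inside the flat 1-4 cpd top
        (1.0, 1.0), (4.0, 1.0),          # passband edges
        (4.0 * np.sqrt(2.0), 0.0),       # half an octave above 4 -> zero
        (1.0 / np.sqrt(2.0), 0.0),       # half an octave below 1 -> zero
        (2.0 ** (-0.25), 0.5),           # lower ramp midpoint (log2 units)
        (4.0 * 2.0 ** 0.25, 0.5),        # upper ramp midpoint
        (0.0, 0.0),
    ])
    def test_sf_profile(self, f, expected):
        spec = FilterSpec(adaptor_theta=0.0)
        assert sf_filter_profile(f, spec) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("delta,expected", [
        (0.0, 1.0), (22.5, 0.5), (-22.5, 0.5), (45.0, 0.0), (90.0, 0.0),
        (67.5, pytest.approx(0.0, abs=1e-12)),
    ])
    def test_orientation_profile(self, delta, expected):
        spec = FilterSpec(adaptor_theta=0.0)
        assert orientation_filter_profile(delta, spec) == pytest.approx(
            expected, abs=1e-12)

    def test_orientation_profile_symmetric_and_bounded(self):
        spec = FilterSpec(adaptor_theta=30.0)
        th = np.linspace(-180, 180, 721)
        w = orientation_filter_profile(th, spec)
        w_neg = orientation_filter_profile(2 * 30.0 - th, spec)  # mirror
        np.testing.assert_allclose(w, w_neg, atol=1e-12)
        assert np.all((w >= 0) & (w <= 1))
        f = np.linspace(0, 20, 500)
        ws = sf_filter_profile(f, spec)
        assert np.all((ws >= 0) & (ws <= 1))

    def test_fwhh_equals_45_degrees(self):
        spec = FilterSpec(adaptor_theta=0.0, ori_halfwidth=45.0)
        lo = orientation_filter_profile(-22.5, spec)
        hi = orientation_filter_profile(22.5, spec)
        assert lo == pytest.approx(0.5, abs=1e-12)
        assert hi == pytest.approx(0.5, abs=1e-12)


class TestFilterFrame:
    @pytest.mark.parametrize("theta", [0.0, 45.0, 90.0, 135.0])
    def test_energy_matched_to_original(self, texture_frame, theta):
        out = filter_frame(texture_frame, FilterSpec(adaptor_theta=theta))
        assert out.contrast_energy == pytest.approx(
            texture_frame.contrast_energy, rel=1e-6)
        assert out.mean_lum == pytest.approx(texture_frame.mean_lum, abs=1e-9)

    def test_orthogonal_leakage_below_one_percent(self, texture_frame):
        out = filter_frame(texture_frame, FilterSpec(adaptor_theta=0.0))
        amp2 = np.abs(np.fft.fft2(out.pixels - out.mean_lum)) ** 2
        f, th = frequency_grid(out.pixels.shape, out.ppd)
        d = np.abs(th)
        d = np.minimum(d, 180.0 - d)
        band = (f >= 1.0) & (f <= 4.0)
        e_adaptor = amp2[band & (d <= 10.0)].sum()
        e_orth = amp2[band & (d >= 80.0)].sum()
        assert e_orth < 0.01 * e_adaptor

    def test_result_is_real_valued(self, texture_frame):
        # hermitian integrity: the pipeline keeps the spectrum conjugate
        # symmetric, so the reconstruction has no imaginary part to discard
        spec = FilterSpec(adaptor_theta=45.0)
        stage = apply_one_over_f(whiten_amplitude(texture_frame))
        from tiltfilm.frames import _fft_split
        amp, phase = _fft_split(stage)
        f, th = frequency_grid(stage.pixels.shape, stage.ppd)
        w = sf_filter_profile(f, spec) * orientation_filter_profile(th, spec)
        img = np.fft.ifft2(amp * w * phase)
        assert np.abs(img.imag).max() < 1e-9 * np.ptp(img.real)

    def test_allpass_round_trip(self, texture_frame):
        # a fully open filter reduces the pipeline to whiten + 1/f
        # (up to the final energy-matching rescale)
        spec = FilterSpec(adaptor_theta=0.0, sf_lo=1e-3, sf_hi=1e3,
                          allpass_orientation=True)
        out = filter_frame(texture_frame, spec)
        ref = apply_one_over_f(whiten_amplitude(texture_frame))
        a = out.pixels - out.mean_lum
        b = ref.pixels - ref.mean_lum
        b *= np.sqrt(np.sum(a * a) / np.sum(b * b))
        np.testing.assert_allclose(a, b, atol=1e-9 * np.ptp(a))

    def test_stopband_matches_reference_spectrum(self, texture_frame):
        # outside the SF band at adaptor-far orientations there is no energy
        out = filter_frame(texture_frame, FilterSpec(adaptor_theta=0.0))
        amp = np.abs(np.fft.fft2(out.pixels - out.mean_lum))
        f, th = frequency_grid(out.pixels.shape, out.ppd)
        spec = FilterSpec(adaptor_theta=0.0)
        w = sf_filter_profile(f, spec) * orientation_filter_profile(th, spec)
        stop = (w == 0)
        stop[0, 0] = False
        assert np.abs(amp[stop]).max() < 1e-9 * amp.max()

    def test_zero_energy_frame_rejected(self):
        with pytest.raises(ValueError, match="zero contrast"):
            filter_frame(FrameImage(np.full((16, 16), 0.3), ppd=10.0),
                         FilterSpec(adaptor_theta=0.0))


class TestOrientationConvention:
    def test_vertical_grating_maps_to_zero_degrees(self):
        x = np.arange(64)
        vert = FrameImage(0.5 + 0.2 * np.cos(2 * np.pi * 8 * x[None, :] / 64),
                          ppd=16.0)
        amp = np.abs(np.fft.fft2(vert.pixels - 0.5))
        _, th = frequency_grid((64, 64), 16.0)
        peak_theta = th[np.unravel_index(np.argmax(amp), amp.shape)]
        assert peak_theta == pytest.approx(0.0, abs=1e-9)

    def test_vertical_filter_passes_vertical_blocks_horizontal(self):
        x = np.arange(64)
        vert = 0.2 * np.cos(2 * np.pi * 8 * x[None, :] / 64)
        horiz = 0.2 * np.cos(2 * np.pi * 8 * x[:, None] / 64)
        frame = FrameImage(0.5 + vert + horiz, ppd=16.0)  # 2 cpd components
        out = filter_frame(frame, FilterSpec(adaptor_theta=0.0))
        amp = np.abs(np.fft.fft2(out.pixels - out.mean_lum))
        assert amp[0, 8] > 1e6 * max(amp[8, 0], 1e-300)

    def test_clockwise_tilt_is_positive(self):
        g = make_test_grating(GratingSpec(orientation=20.0), 128, 32.0)
        amp = np.abs(np.fft.fft2(g.pixels - g.pixels.mean()))
        _, th = frequency_grid((128, 128), 32.0)
        peak_theta = th[np.unravel_index(np.argmax(amp), amp.shape)]
        assert 10.0 < peak_theta < 30.0


class TestCircularCrop:
    def test_uniform_frame_unchanged(self):
        frame = FrameImage(np.full((32, 32), 0.4), ppd=10.0)
        out = circular_crop(frame, 3.0)
        np.testing.assert_allclose(out.pixels, frame.pixels, atol=1e-15)

    def test_corners_set_to_mean(self, texture_frame):
        out = circular_crop(texture_frame, 64 / texture_frame.ppd)
        for corner in [(0, 0), (0, -1), (-1, 0), (-1, -1)]:
            assert out.pixels[corner] == pytest.approx(texture_frame.mean_lum)

    def test_retained_fraction_is_pi_over_four(self):
        n = 200
        rng = np.random.default_rng(3)
        frame = FrameImage(rng.random((n, n)), ppd=10.0)
        out = circular_crop(frame, n / frame.ppd)  # inscribed circle
        changed = np.sum(out.pixels != frame.pixels)
        frac_inside = 1 - changed / n ** 2
        assert frac_inside == pytest.approx(np.pi / 4, abs=2 / n)

    def test_oversized_circle_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            circular_crop(FrameImage(np.ones((32, 32)), ppd=10.0), 4.0)


class TestTestGrating:
    def test_rms_contrast_is_one(self):
        g = make_test_grating(GratingSpec(), 256, 75.5)
        assert g.pixels.std() / g.pixels.mean() == pytest.approx(1.0, abs=1e-6)

    def test_peak_at_two_cpd(self):
        g = make_test_grating(GratingSpec(orientation=22.5), 256, 75.5)
        amp = np.abs(np.fft.fft2(g.pixels - g.pixels.mean()))
        f, _ = frequency_grid((256, 256), 75.5)
        peak_f = f[np.unravel_index(np.argmax(amp), amp.shape)]
        bin_width = 75.5 / 256
        assert abs(peak_f - 2.0) <= bin_width

    def test_half_amplitude_at_half_fwhh(self):
        # radial slice at 2 cpd: amplitude at 22.5 deg off-orientation is
        # half the peak (orientation FWHH = 45 deg)
        ppd, n = 64.0, 512
        g = make_test_grating(GratingSpec(orientation=0.0), n, ppd)
        amp = np.abs(np.fft.fft2(g.pixels - g.pixels.mean()))
        f, th = frequency_grid((n, n), ppd)
        ring = np.abs(f - 2.0) < (ppd / n) / 2
        d = np.abs(th)
        d = np.minimum(d, 180 - d)
        peak = amp[ring & (d < 2.0)].max()
        off = amp[ring & (np.abs(d - 22.5) < 2.0)].max()
        assert off / peak == pytest.approx(0.5, rel=0.05)

    def test_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            make_test_grating(GratingSpec(center_sf=2.0), 64, 3.0)


def test_wrap_orientation_canonical_range():
    th = np.linspace(-400, 400, 1601)
    w = wrap_orientation(th)
    assert np.all((w > -90) & (w <= 90))
    np.testing.assert_allclose(np.cos(np.radians(2 * w)),
                               np.cos(np.radians(2 * th)), atol=1e-9)
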