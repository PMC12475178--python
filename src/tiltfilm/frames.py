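"""Fourier-domain stimulus engineering for orientation-adaptation experiments.

Turns any grayscale frame into an adaptor frame whose contrast energy at low
spatial frequencies (1-4 cpd by default) is confined to a single orientation,
and synthesises the frequency-domain-defined test grating used in the
clockwise/counterclockwise judgement task.

The processing chain for an adaptor frame is

    whiten -> 1/f -> (spatial-frequency filter x orientation filter)
           -> inverse transform -> match total contrast energy to the
              original frame -> circular aperture crop

All operations act on the amplitude spectrum only; the phase spectrum, and
hence the spatial structure of the scene, is preserved throughout.

Conventions
-----------
Orientation is measured in degrees from vertical, positive clockwise, with
180-degree periodicity (a vertical grating is 0, horizontal is 90).  The DC
coefficient carries mean luminance and is excluded from whitening, 1/f
scaling, band filtering, and the energy match; "total energy" always means
contrast energy, the sum of squared deviations from the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameImage",
    "FilterSpec",
    "GratingSpec",
    "whiten_amplitude",
    "apply_one_over_f",
    "sf_filter_profile",
    "orientation_filter_profile",
    "filter_frame",
    "circular_crop",
    "make_test_grating",
    "frequency_grid",
]


@dataclass
class FrameImage:
    """A luminance image with display-geometry metadata.

    Parameters
    ----------
    pixels : ndarray
        2D array of luminance values (any linear luminance unit; [0, 1] for
        frames loaded from 8/16-bit files).
    ppd : float
        Pixels per degree of visual angle; must be positive.
    """

    pixels: np.ndarray
    ppd: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if not (self.ppd > 0):
            raise ValueError(f"ppd must be > 0, got {self.ppd}")

    @property
    def mean_lum(self) -> float:
        """Mean luminance (the DC level)."""
        return float(self.pixels.mean())

    @property
    def contrast_energy(self) -> float:
        """Sum of squared deviations from mean luminance."""
        d = self.pixels - self.pixels.mean()
        return float(np.sum(d * d))


@dataclass
class FilterSpec:
    """Adaptor filter: orientation band x spatial-frequency passband.

    ``ori_halfwidth`` is the angular distance (deg) from the adaptor
    orientation at which the raised-cosine orientation filter reaches zero;
    its full width at half height equals ``ori_halfwidth``.
    ``allpass_orientation=True`` disables orientation filtering entirely
    (weight identically 1), used for round-trip checks.
    """

    adaptor_theta: float
    sf_lo: float = 1.0
    sf_hi: float = 4.0
    sf_edge_octaves: float = 0.5
    ori_halfwidth: float = 45.0
    allpass_orientation: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.sf_lo < self.sf_hi):
            raise ValueError("need 0 < sf_lo < sf_hi")
        if not (0 < self.ori_halfwidth <= 90):
            raise ValueError("need 0 < ori_halfwidth <= 90")
        if self.sf_edge_octaves <= 0:
            raise ValueError("sf_edge_octaves must be positive")
        self.adaptor_theta = wrap_orientation(self.adaptor_theta)


@dataclass
class GratingSpec:
    """Test grating defined by a raised-cosine bump in the frequency plane.

    FWHH values are full widths at half height: the raised cosine falls to
    zero at +-``sf_fwhh`` cpd (resp. +-``ori_fwhh`` deg) from the centre and
    to one half at +-half that distance.
    """

    orientation: float = 0.0
    center_sf: float = 2.0
    sf_fwhh: float = 1.148
    ori_fwhh: float = 45.0
    phase: float = 0.0
    rms_contrast: float = 1.0
    mean_lum: float = 0.5

    def __post_init__(self) -> None:
        if self.center_sf <= 0:
            raise ValueError("center_sf must be positive")
        if not (0 < self.ori_fwhh <= 90):
            raise ValueError("need 0 < ori_fwhh <= 90")
        if not (0 <= self.rms_contrast <= 1):
            raise ValueError("rms_contrast must be in [0, 1]")


def wrap_orientation(theta: float | np.ndarray) -> float | np.ndarray:
    """Fold an orientation (deg) to the canonical range (-90, 90]."""
    wrapped = -np.mod(-np.asarray(theta, dtype=float) + 90.0, 180.0) + 90.0
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return float(wrapped)
    return wrapped


def frequency_grid(shape: tuple[int, int], ppd: float):
    """Radial frequency (cpd) and image orientation (deg) of each FFT bin.

    The orientation of a frequency bin is the orientation of the sinusoidal
    grating it represents: 0 deg for a vertical grating (energy on the
    horizontal frequency axis), 90 deg for horizontal, positive clockwise.
    This is the single place where the Fourier-plane angle convention is
    fixed; every filter and grating goes through it.
    """
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=1.0 / ppd)[:, None]
    fx = np.fft.fftfreq(nx, d=1.0 / ppd)[None, :]
    f_rad = np.hypot(fx, fy)
    # wave vector (fx, fy) with y down; stripes are perpendicular to it, so
    # the stripe orientation from vertical (clockwise +) is atan2(fy, fx).
    theta = wrap_orientation(np.degrees(np.arctan2(fy, fx)))
    return f_rad, theta


def _fft_split(frame: FrameImage):
    spec = np.fft.fft2(frame.pixels)
    amp = np.abs(spec)
    phase = np.where(amp > 0, spec / np.maximum(amp, 1e-300), 1.0 + 0j)
    return amp, phase


def whiten_amplitude(frame: FrameImage) -> FrameImage:
    """Flatten the amplitude spectrum while preserving phase.

    Every non-DC coefficient is set to the same constant amplitude, chosen so
    the total contrast energy of the frame is unchanged; the DC coefficient
    (mean luminance) is untouched.  Raises on constant input, whose phase
    spectrum is undefined.
    """
    px = frame.pixels
    if np.ptp(px) == 0:
        raise ValueError("cannot whiten a constant frame: phase undefined")
    amp, phase = _fft_split(frame)
    n = px.size
    # Parseval: contrast energy = sum(|A|^2)/n over non-DC bins.
    energy = frame.contrast_energy
    const = np.sqrt(energy * n / (n - 1))
    amp_flat = np.full_like(amp, const)
    amp_flat[0, 0] = amp[0, 0]
    out = np.fft.ifft2(amp_flat * phase).real
    return FrameImage(out, frame.ppd)


def apply_one_over_f(frame: FrameImage) -> FrameImage:
    """Impose a 1/f amplitude spectrum (f = radial frequency in cpd).

    Each non-DC amplitude is scaled by 1/f, giving the falloff
    characteristic of natural images; DC is untouched.
    """
    amp, phase = _fft_split(frame)
    f_rad, _ = frequency_grid(frame.pixels.shape, frame.ppd)
    scale = np.zeros_like(f_rad)
    nz = f_rad > 0
    scale[nz] = 1.0 / f_rad[nz]
    new_amp = amp * scale
    new_amp[0, 0] = amp[0, 0]
    out = np.fft.ifft2(new_amp * phase).real
    return FrameImage(out, frame.ppd)


def sf_filter_profile(f, spec: FilterSpec):
    """Flat-topped spatial-frequency passband with raised-cosine edges.

    Weight is 1 on [sf_lo, sf_hi] cpd and falls to zero over
    ``sf_edge_octaves`` octaves on each side; the ramp is a raised cosine in
    log2-frequency (octaves are log units, so the stated edge width is only
    meaningful on a log axis).  Returns values in [0, 1]; f = 0 maps to 0.
    """
    f = np.asarray(f, dtype=float)
    w = np.zeros_like(f)
    e = spec.sf_edge_octaves
    pos = f > 0
    lf = np.full_like(f, -np.inf)
    lf[pos] = np.log2(f[pos])
    lo, hi = np.log2(spec.sf_lo), np.log2(spec.sf_hi)
    w[(lf >= lo) & (lf <= hi)] = 1.0
    lower = (lf >= lo - e) & (lf < lo)
    w[lower] = 0.5 * (1 + np.cos(np.pi * (lo - lf[lower]) / e))
    upper = (lf > hi) & (lf <= hi + e)
    w[upper] = 0.5 * (1 + np.cos(np.pi * (lf[upper] - hi) / e))
    return w if w.ndim else float(w)


def orientation_filter_profile(theta, spec: FilterSpec):
    """Raised-cosine orientation band centred on the adaptor orientation.

    weight = 0.5 * (1 + cos(pi * d / ori_halfwidth)) for |d| <= ori_halfwidth
    and 0 beyond, where d is theta - adaptor_theta folded to (-90, 90] under
    180-degree orientation periodicity.  Full width at half height equals
    ``ori_halfwidth`` (half-height points at +-ori_halfwidth / 2).
    """
    theta = np.asarray(theta, dtype=float)
    if spec.allpass_orientation:
        w = np.ones_like(theta)
        return w if w.ndim else float(w)
    d = wrap_orientation(theta - spec.adaptor_theta)
    d = np.abs(np.asarray(d, dtype=float))
    # +-90 is the same fold point; use the smaller distance
    d = np.minimum(d, 180.0 - d)
    w = np.where(d <= spec.ori_halfwidth,
                 0.5 * (1 + np.cos(np.pi * d / spec.ori_halfwidth)), 0.0)
    return w if w.ndim else float(w)


def filter_frame(frame: FrameImage, spec: FilterSpec) -> FrameImage:
    """Full adaptor-frame pipeline with energy matching.

    whiten -> 1/f -> multiply the amplitude spectrum by
    sf_filter_profile x orientation_filter_profile -> inverse transform ->
    rescale so the output's contrast energy equals that of the ORIGINAL
    unfiltered frame -> restore mean luminance.
    """
    original_energy = frame.contrast_energy
    if original_energy == 0 or np.ptp(frame.pixels) == 0:
        raise ValueError("frame has zero contrast energy; nothing to match")
    stage = apply_one_over_f(whiten_amplitude(frame))

    amp, phase = _fft_split(stage)
    f_rad, theta = frequency_grid(frame.pixels.shape, frame.ppd)
    w = sf_filter_profile(f_rad, spec) * orientation_filter_profile(theta, spec)
    w[0, 0] = 0.0  # DC handled separately
    dc = amp[0, 0]
    new_amp = amp * w
    new_amp[0, 0] = 0.0
    out = np.fft.ifft2(new_amp * phase).real  # zero-mean contrast image

    e = float(np.sum(out * out))
    if e == 0:
        raise ValueError("filter removed all contrast energy from the frame")
    out *= np.sqrt(original_energy / e)
    out += dc / frame.pixels.size  # mean luminance back
    return FrameImage(out, frame.ppd)


def circular_crop(frame: FrameImage, diameter_deg: float) -> FrameImage:
    """Set pixels outside a centred circular aperture to mean luminance.

    Removes the cardinal orientation cues a rectangular frame edge would
    introduce.  The aperture diameter is given in degrees of visual angle.
    """
    ny, nx = frame.pixels.shape
    radius_px = diameter_deg * frame.ppd / 2.0
    if 2 * radius_px > min(ny, nx):
        raise ValueError(
            f"aperture diameter {diameter_deg} deg = {2 * radius_px:.1f} px "
            f"exceeds frame size {min(ny, nx)} px")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    y = np.arange(ny)[:, None] - cy
    x = np.arange(nx)[None, :] - cx
    inside = np.hypot(x, y) <= radius_px
    out = np.where(inside, frame.pixels, frame.mean_lum)
    return FrameImage(out, frame.ppd)


def make_test_grating(spec: GratingSpec, size_px: int, ppd: float) -> FrameImage:
    """Synthesise the test grating from its frequency-domain definition.

    The amplitude spectrum is a 2D raised-cosine bump centred at
    (center_sf, orientation): separable raised cosines in radial frequency
    (FWHH ``sf_fwhh`` cpd) and orientation (FWHH ``ori_fwhh`` deg).  The
    spatial phase at the image centre is ``spec.phase`` degrees and the
    output RMS contrast (std / mean luminance) equals ``spec.rms_contrast``.
    """
    if size_px <= 0:
        raise ValueError("size_px must be positive")
    nyquist = ppd / 2.0
    if spec.center_sf >= nyquist:
        raise ValueError(
            f"center_sf {spec.center_sf} cpd is at or beyond Nyquist "
            f"({nyquist} cpd) for ppd={ppd}")
    f_rad, theta = frequency_grid((size_px, size_px), ppd)

    df = np.abs(f_rad - spec.center_sf)
    w_sf = np.where(df <= spec.sf_fwhh,
                    0.5 * (1 + np.cos(np.pi * df / spec.sf_fwhh)), 0.0)
    dth = np.abs(np.asarray(wrap_orientation(theta - spec.orientation)))
    dth = np.minimum(dth, 180.0 - dth)
    w_ori = np.where(dth <= spec.ori_fwhh,
                     0.5 * (1 + np.cos(np.pi * dth / spec.ori_fwhh)), 0.0)
    amp = w_sf * w_ori
    amp[0, 0] = 0.0
    if amp.max() == 0:
        raise ValueError("grating spectrum is empty at this size/ppd")

    # phase: rotate each half-plane of wave vectors by +-phase so the
    # centre-pixel phase of every component is spec.phase (cosine phase 0
    # gives an even, real spectrum).
    ny = nx = size_px
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    halfplane = np.where((fx > 0) | ((fx == 0) & (fy > 0)), 1.0, -1.0)
    phase = np.exp(1j * np.radians(spec.phase) * halfplane)
    # shift origin to the image centre so "phase" refers to the centre pixel
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    shift = np.exp(-2j * np.pi * (fy * cy + fx * cx))

    img = np.fft.ifft2(amp * phase * shift).real
    sd = img.std()
    if sd == 0:
        raise ValueError("degenerate grating (zero contrast)")
    img = spec.mean_lum * (1.0 + spec.rms_contrast * img / sd)
    return FrameImage(img, ppd)
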