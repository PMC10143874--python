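"""Point-spread-function analysis of k-space weight maps.

The PSF of an acquisition is the inverse DFT of its k-space signal
weighting.  A flat weighting (single-shot EPI) gives the periodic-sinc
(Dirichlet) kernel of the matrix size; signal decay across CSI phase
encodes apodizes k-space and reshapes the kernel.  Zero-filling before
the inverse transform interpolates the image-domain grid so the width
metrics can be read off with sub-voxel precision.

Resolution metrics on the central (y = 0) profile:

* ``fwhm_mm`` — distance between the half-maximum crossings of the main
  lobe (linear interpolation between grid samples).
* ``width10_mm`` — distance between the *outermost* crossings of 10% of
  the maximum, which captures sidelobe extent and hence signal bleed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import (
    AcquisitionProtocol, KSpaceWeights, simulate_csi_frame_weights,
)
from .kinetics import GammaInput, PKParams, evolve_with_input, pyruvate_peak_time

__all__ = [
    "PSF2D", "PSFProfile", "PSFMetrics",
    "weights_to_psf", "central_profile", "profile_metrics",
    "csi_psf_report", "DEFAULT_CSI_FRAME_START_FACTOR",
]

#: Default start time of the simulated CSI frame on the bolus clock, as a
#: multiple of the RF-free pyruvate-peak time.  The frame opens shortly
#: after the pyruvate peak, while lactate is still building; see
#: docs/methods.md for how this default was fixed.
DEFAULT_CSI_FRAME_START_FACTOR = 1.43


@dataclass
class PSF2D:
    """Magnitude point spread function on a zero-filled image grid."""

    image: np.ndarray          # 2-D, peak-normalized magnitude
    pitch_mm: float            # grid spacing = voxel_mm / zero_fill_factor
    zero_fill_factor: int


@dataclass
class PSFProfile:
    """Central 1-D slice through a PSF peak."""

    positions_mm: np.ndarray   # zero-centered at the peak
    magnitudes: np.ndarray     # normalized so max = 1
    zero_fill_factor: int


@dataclass
class PSFMetrics:
    fwhm_mm: float
    width10_mm: float

    def __post_init__(self) -> None:
        if not (self.width10_mm >= self.fwhm_mm > 0):
            raise ValueError(
                f"inconsistent metrics: fwhm={self.fwhm_mm}, width10={self.width10_mm}")


def weights_to_psf(weights: KSpaceWeights | np.ndarray, zero_fill_factor: int = 16,
                   voxel_mm: float | None = None) -> PSF2D:
    """Zero-fill a k-space weight map and inverse-transform to the PSF.

    The weight map (DC at index n//2) is embedded centrally in a grid
    ``zero_fill_factor`` times larger, inverse DFT'd, and the magnitude is
    peak-normalized.  Physical grid pitch is ``voxel_mm / zero_fill_factor``.
    """
    if isinstance(weights, KSpaceWeights):
        w = weights.weights
        vox = weights.voxel_mm if voxel_mm is None else voxel_mm
    else:
        w = np.asarray(weights, dtype=float)
        if voxel_mm is None:
            raise ValueError("voxel_mm is required for bare weight arrays")
        vox = voxel_mm
    if zero_fill_factor < 1:
        raise ValueError("zero_fill_factor must be >= 1")
    if w.ndim != 2:
        raise ValueError("weights must be 2-D")
    if not np.any(w):
        raise ValueError("all-zero weights: PSF undefined")

    ny, nx = w.shape
    NY, NX = ny * zero_fill_factor, nx * zero_fill_factor
    pad = np.zeros((NY, NX))
    y0 = NY // 2 - ny // 2
    x0 = NX // 2 - nx // 2
    pad[y0:y0 + ny, x0:x0 + nx] = w
    img = np.abs(np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(pad))))
    img /= img.max()
    return PSF2D(image=img, pitch_mm=vox / zero_fill_factor,
                 zero_fill_factor=zero_fill_factor)


def central_profile(psf: PSF2D) -> PSFProfile:
    """Row through the PSF peak (the y = 0 slice)."""
    iy, ix = np.unravel_index(int(np.argmax(psf.image)), psf.image.shape)
    row = psf.image[iy, :].copy()
    pos = (np.arange(row.size) - ix) * psf.pitch_mm
    return PSFProfile(positions_mm=pos, magnitudes=row,
                      zero_fill_factor=psf.zero_fill_factor)


def _interp_crossing(x_in, y_in, x_out, y_out, level):
    """Position where the line between (x_in, y_in) and (x_out, y_out) hits level."""
    if y_in == y_out:
        return x_in
    f = (y_in - level) / (y_in - y_out)
    return x_in + f * (x_out - x_in)


def profile_metrics(profile: PSFProfile) -> PSFMetrics:
    """FWHM (main lobe) and width at 10% of max (outermost crossings)."""
    y = np.asarray(profile.magnitudes, dtype=float)
    x = np.asarray(profile.positions_mm, dtype=float)
    peak = int(np.argmax(y))
    if not np.isclose(y[peak], 1.0, rtol=1e-6):
        raise ValueError("profile must be normalized to max = 1")

    # main-lobe half-maximum crossings, walking outward from the peak
    def _main_lobe(level):
        i = peak
        while i + 1 < y.size and y[i + 1] >= level:
            i += 1
        if i + 1 >= y.size:
            raise ValueError(f"profile never drops below {level} to the right")
        right = _interp_crossing(x[i], y[i], x[i + 1], y[i + 1], level)
        i = peak
        while i - 1 >= 0 and y[i - 1] >= level:
            i -= 1
        if i - 1 < 0:
            raise ValueError(f"profile never drops below {level} to the left")
        left = _interp_crossing(x[i], y[i], x[i - 1], y[i - 1], level)
        return left, right

    lo, hi = _main_lobe(0.5)
    fwhm = hi - lo

    # outermost 10% crossings, walking inward from the profile edges
    level = 0.1
    if y[0] >= level or y[-1] >= level:
        raise ValueError("profile never drops below the 10% threshold; "
                         "width unresolvable on this grid")
    j = y.size - 1
    while y[j] < level:
        j -= 1
    right10 = _interp_crossing(x[j], y[j], x[j + 1], y[j + 1], level)
    j = 0
    while y[j] < level:
        j += 1
    left10 = _interp_crossing(x[j], y[j], x[j - 1], y[j - 1], level)
    width10 = right10 - left10

    return PSFMetrics(fwhm_mm=float(fwhm), width10_mm=float(width10))


def csi_psf_report(protocol: AcquisitionProtocol, params: PKParams,
                   input_fn: GammaInput,
                   frame_start: float | str = "default",
                   zero_fill_factor: int = 16) -> dict:
    """Bolus-driven CSI PSF metrics for pyruvate and lactate.

    The two-pool model is run RF-free under the bolus up to the frame
    start, then the single CSI frame is simulated across the ordered phase
    encodes and each pool's weight map is transformed to its PSF.

    ``frame_start`` may be a time in seconds, ``"peak"`` (the RF-free
    pyruvate-peak time), or ``"default"``
    (``DEFAULT_CSI_FRAME_START_FACTOR`` times the peak time — the
    documented default, shortly after the pyruvate peak).

    Returns a dict with per-metabolite ``PSFMetrics`` and ``PSFProfile``
    plus the frame start time used.
    """
    if frame_start == "peak":
        t0 = pyruvate_peak_time(params, input_fn)
    elif frame_start == "default":
        t0 = DEFAULT_CSI_FRAME_START_FACTOR * pyruvate_peak_time(params, input_fn)
    else:
        t0 = float(frame_start)
    start_state = evolve_with_input(params, input_fn, t0)
    wp, wl = simulate_csi_frame_weights(protocol, params, start_state,
                                        input_fn=input_fn, frame_start_time=t0)
    out = {"frame_start_s": t0, "metrics": {}, "profiles": {}}
    for w in (wp, wl):
        prof = central_profile(weights_to_psf(w, zero_fill_factor))
        out["profiles"][w.metabolite] = prof
        out["metrics"][w.metabolite] = profile_metrics(prof)
    return out
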