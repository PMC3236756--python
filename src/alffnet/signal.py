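"""Temporal band-pass filtering and spatial Gaussian smoothing.

The band-pass filter is an ideal frequency-domain mask: the series is
linearly detrended (optional), transformed with a real FFT, DFT bins whose
frequency lies outside [low, high] are zeroed (the DC bin always is), and
the series is transformed back.  An ideal mask is exactly invertible on the
retained bins, which makes it straightforward to test against a brute-force
DFT and makes ALFF of band-limited synthetic signals analytic.

Smoothing is a mask-aware (renormalized) Gaussian convolution: the field is
convolved inside the brain mask and divided by the convolved mask, so voxels
at the brain edge are not diluted by out-of-mask zeros.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.signal import detrend as _linear_detrend

from .errors import ParameterError
from .grid import VolumeGrid
from .images import Bold4D, ScalarMap

__all__ = ["bandpass_filter", "spatial_smooth", "band_bins", "FWHM_TO_SIGMA"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
_FREQ_TOL = 1e-9  # relative tolerance for band-edge bin inclusion


def band_bins(n: int, tr_seconds: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Indices of rfft bins with low <= f_k <= high, excluding DC and Nyquist.

    f_k = k / (n * TR); band edges are inclusive (with a tiny floating-point
    tolerance so analytically exact edges are kept).
    """
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    tol = _FREQ_TOL * max(high_hz, freqs[-1])
    keep = (freqs >= low_hz - tol) & (freqs <= high_hz + tol)
    keep[0] = False  # DC
    if n % 2 == 0:
        keep[-1] = False  # unpaired Nyquist bin
    return np.flatnonzero(keep)


def bandpass_filter(
    bold: Bold4D,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    detrend: bool = True,
) -> Bold4D:
    """Ideal band-pass: keep spectral content with low <= f <= high.

    The mean (0 Hz) is always removed.  Input is not modified.

    Raises
    ------
    ParameterError
        If the band is empty/negative or ``high_hz`` exceeds the Nyquist
        frequency 1/(2 TR).
    """
    nyq = bold.nyquist_hz
    if not (0 <= low_hz < high_hz):
        raise ParameterError(f"invalid band [{low_hz}, {high_hz}] Hz")
    if high_hz > nyq + _FREQ_TOL:
        raise ParameterError(
            f"high_hz={high_hz} Hz exceeds Nyquist {nyq:.6g} Hz for TR={bold.tr_seconds} s"
        )
    n = bold.n_timepoints
    x = bold.data
    if detrend:
        x = _linear_detrend(x, axis=0, type="linear")
    spec = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(n, d=bold.tr_seconds)
    tol = _FREQ_TOL * max(high_hz, freqs[-1])
    keep = (freqs >= low_hz - tol) & (freqs <= high_hz + tol)
    keep[0] = False
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=0)
    return bold.with_data(out)


def _smooth_frame(
    frame: np.ndarray, sigma_vox: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    num = ndimage.gaussian_filter(
        np.where(mask, frame, 0.0), sigma=sigma_vox, mode="constant", cval=0.0
    )
    den = ndimage.gaussian_filter(
        mask.astype(float), sigma=sigma_vox, mode="constant", cval=0.0
    )
    out = np.zeros_like(frame, dtype=float)
    inside = mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out


def spatial_smooth(volume, fwhm_mm: float, mask: np.ndarray | None = None):
    """Gaussian smoothing with an isotropic-in-mm FWHM kernel.

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis in mm, converted to voxel units
    using the grid's (possibly anisotropic) voxel sizes.  Smoothing is
    renormalized inside ``mask`` (default: the grid's brain mask), and
    ``fwhm_mm = 0`` returns the input unchanged (as a copy).

    Accepts a :class:`ScalarMap` or a :class:`Bold4D` (each frame smoothed
    independently); returns the same type.
    """
    if fwhm_mm < 0:
        raise ParameterError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    grid: VolumeGrid = volume.grid
    if mask is None:
        mask = grid.brain_mask
    mask = np.asarray(mask, dtype=bool)
    if isinstance(volume, ScalarMap):
        if fwhm_mm == 0:
            return volume.with_values(volume.values.copy())
        sigma_vox = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_sizes_mm
        return volume.with_values(_smooth_frame(volume.values, sigma_vox, mask))
    if isinstance(volume, Bold4D):
        if fwhm_mm == 0:
            return volume.with_data(volume.data.copy())
        sigma_vox = fwhm_mm * FWHM_TO_SIGMA / grid.voxel_sizes_mm
        out = np.empty_like(volume.data, dtype=float)
        for t in range(volume.n_timepoints):
            out[t] = _smooth_frame(volume.data[t], sigma_vox, mask)
        return volume.with_data(out)
    raise ParameterError(f"unsupported volume type {type(volume).__name__}")
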