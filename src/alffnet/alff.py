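"""Amplitude of low-frequency fluctuations (ALFF).

ALFF indexes local resting activity as the mean square-root spectral power
of a voxel's BOLD series over a low-frequency band (default 0.01-0.08 Hz).
Per voxel the series is Fourier transformed, the one-sided power at each
retained bin is folded across conjugate pairs and normalized so that a pure
sinusoid of amplitude A on a single bin yields sqrt(power) = A, i.e. the
per-bin amplitude is 2|X_k|/N, and ALFF is the arithmetic mean of those
amplitudes over the in-band bins (DC excluded, Nyquist excluded as
unpaired).  The standardized map divides every voxel by the full-brain mean
ALFF, making the in-mask mean exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, GridMismatchError
from .grid import VolumeGrid
from .images import Bold4D
from .signal import band_bins

__all__ = ["AlffMap", "compute_alff_map", "standardize_alff"]

DEFAULT_BAND_HZ = (0.01, 0.08)


@dataclass(frozen=True)
class AlffMap:
    """Per-voxel ALFF values with the band/TR provenance that produced them."""

    grid: VolumeGrid
    values: np.ndarray
    band_hz: tuple[float, float]
    tr_seconds: float
    standardized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise GridMismatchError(
                f"ALFF shape {values.shape} != grid {self.grid.shape}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "band_hz", tuple(float(b) for b in self.band_hz))


def compute_alff_map(bold: Bold4D, band_hz: tuple[float, float] = DEFAULT_BAND_HZ) -> AlffMap:
    """Unstandardized ALFF: mean in-band sqrt power per voxel.

    Bins are included when low <= k/(N*TR) <= high with k >= 1; at least one
    DFT bin must fall in the band.
    """
    low, high = band_hz
    n = bold.n_timepoints
    bins = band_bins(n, bold.tr_seconds, low, high)
    if bins.size == 0:
        spacing = 1.0 / (n * bold.tr_seconds)
        raise ConfigurationError(
            f"no DFT bin falls in [{low}, {high}] Hz: bin spacing is "
            f"{spacing:.6g} Hz for N={n}, TR={bold.tr_seconds} s"
        )
    spec = np.fft.rfft(bold.data, axis=0)
    amplitudes = 2.0 * np.abs(spec[bins]) / n  # sqrt of folded one-sided power
    values = amplitudes.mean(axis=0)
    return AlffMap(
        grid=bold.grid,
        values=values,
        band_hz=(low, high),
        tr_seconds=bold.tr_seconds,
        standardized=False,
    )


def standardize_alff(alff: AlffMap, brain_mask: np.ndarray | None = None) -> AlffMap:
    """Divide every voxel by the in-mask mean ALFF (full-brain standardization)."""
    mask = alff.grid.brain_mask if brain_mask is None else np.asarray(brain_mask, bool)
    if mask.shape != alff.grid.shape:
        raise GridMismatchError("brain mask shape does not match grid")
    if not mask.any():
        raise DegenerateInputError("standardize_alff: empty brain mask")
    mean = float(alff.values[mask].mean())
    if mean <= 0:
        raise DegenerateInputError(
            f"standardize_alff: non-positive in-mask mean ALFF ({mean:.6g})"
        )
    return replace(alff, values=alff.values / mean, standardized=True)
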