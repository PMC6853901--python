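"""Conditioning of raw fluorescence movies before phase computation.

Optical-mapping voltage movies are noisy and carry slow photobleaching
drift, so a standard sequence of filters is applied per pixel before the
Hilbert phase transform: spatial uniform binning, a zero-phase temporal
low-pass, baseline (drift) removal, and per-pixel amplitude
normalisation.  All filters respect an optional binary tissue mask:
non-tissue pixels never leak signal into tissue pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage, signal

logger = logging.getLogger("rotortrack")

__all__ = [
    "VoltageMovie",
    "PreprocessConfig",
    "spatial_bin",
    "temporal_filter",
    "remove_baseline",
    "normalize",
    "preprocess",
]


@dataclass
class VoltageMovie:
    """A fluorescence (or simulated transmembrane voltage) movie.

    Parameters
    ----------
    frames
        Array of shape ``(time, height, width)``, arbitrary fluorescence
        units.  Each time frame is a 2-D image on a regular pixel grid.
    sampling_rate
        Acquisition rate in Hz.
    pixel_pitch
        Distance between neighbouring pixels in mm.
    mask
        Optional boolean ``(height, width)`` tissue mask; ``True`` marks
        tissue pixels.  ``None`` means the whole frame is tissue.
    """

    frames: np.ndarray
    sampling_rate: float
    pixel_pitch: float = 0.13
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, height, width) array")
        if self.frames.shape[0] < 2:
            raise ValueError("movie must have at least 2 frames")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.mask is None:
            self.mask = np.ones(self.frames.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[1:]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match frame "
                    f"shape {self.frames.shape[1:]}"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def duration_ms(self) -> float:
        return self.n_frames / self.sampling_rate * 1000.0


@dataclass
class PreprocessConfig:
    """Filter settings for the pre-processing pipeline.

    ``bin_size`` is the side of the uniform spatial binning kernel in
    pixels (odd).  ``lowpass_cutoff`` (Hz) must stay below Nyquist.
    Baseline removal is either a per-pixel polynomial fit
    (``baseline_method="polynomial"`` of order ``baseline_order``) or a
    zero-phase high-pass (``baseline_method="highpass"`` with cutoff
    ``baseline_cutoff`` Hz).
    """

    bin_size: int = 3
    lowpass_cutoff: float = 100.0
    baseline_method: str = "polynomial"
    baseline_order: int = 4
    baseline_cutoff: float = 1.0
    normalize: bool = True
    invert: bool = False

    def __post_init__(self) -> None:
        if self.bin_size < 1 or self.bin_size % 2 == 0:
            raise ValueError("bin_size must be odd and >= 1")
        if self.baseline_method not in ("polynomial", "highpass"):
            raise ValueError("baseline_method must be 'polynomial' or 'highpass'")


def _masked_uniform(frame: np.ndarray, mask: np.ndarray, size: int) -> np.ndarray:
    """Uniform mean over size x size neighbourhoods restricted to mask.

    The kernel is renormalised by the local mask coverage so bins
    truncated by the grid or tissue boundary stay unbiased.
    """
    num = ndimage.uniform_filter(np.where(mask, frame, 0.0), size=size, mode="constant")
    den = ndimage.uniform_filter(mask.astype(float), size=size, mode="constant")
    out = frame.copy()
    valid = mask & (den > 0)
    out[valid] = num[valid] / den[valid]
    return out


def spatial_bin(movie: VoltageMovie, bin_size: int) -> VoltageMovie:
    """Replace each pixel by the uniform mean of its bin_size x bin_size
    neighbourhood, restricted to tissue pixels."""
    if bin_size % 2 == 0:
        raise ValueError("bin_size must be odd")
    if bin_size == 1:
        return replace(movie, frames=movie.frames.copy())
    out = np.empty_like(movie.frames)
    for t in range(movie.n_frames):
        out[t] = _masked_uniform(movie.frames[t], movie.mask, bin_size)
    return replace(movie, frames=out)


def temporal_filter(movie: VoltageMovie, lowpass_cutoff: float, order: int = 4) -> VoltageMovie:
    """Zero-phase Butterworth low-pass per pixel (unit DC gain)."""
    nyq = movie.sampling_rate / 2.0
    if not 0 < lowpass_cutoff < nyq:
        raise ValueError(
            f"lowpass_cutoff must lie in (0, Nyquist={nyq:g} Hz), got {lowpass_cutoff}"
        )
    sos = signal.butter(order, lowpass_cutoff, btype="low", fs=movie.sampling_rate, output="sos")
    out = signal.sosfiltfilt(sos, movie.frames, axis=0)
    return replace(movie, frames=np.ascontiguousarray(out))


def remove_baseline(movie: VoltageMovie, config: Optional[PreprocessConfig] = None) -> VoltageMovie:
    """Remove slow per-pixel drift (photobleaching trend)."""
    config = config or PreprocessConfig()
    T = movie.n_frames
    flat = movie.frames.reshape(T, -1)
    if config.baseline_method == "polynomial":
        if T <= config.baseline_order + 1:
            raise ValueError("trace too short for polynomial baseline fit")
        t = np.linspace(-1.0, 1.0, T)
        coeffs = np.polynomial.polynomial.polyfit(t, flat, config.baseline_order)
        trend = np.polynomial.polynomial.polyval(t, coeffs).T
        out = flat - trend
    else:
        sos = signal.butter(
            2, config.baseline_cutoff, btype="high", fs=movie.sampling_rate, output="sos"
        )
        out = signal.sosfiltfilt(sos, flat, axis=0)
    return replace(movie, frames=out.reshape(movie.frames.shape))


def normalize(movie: VoltageMovie) -> VoltageMovie:
    """Rescale each tissue pixel's trace to [0, 1] by its own min/max.

    Pixels with zero range carry no signal and are dropped from the mask.
    """
    lo = movie.frames.min(axis=0)
    hi = movie.frames.max(axis=0)
    rng = hi - lo
    flat_ok = rng > 0
    dead = movie.mask & ~flat_ok
    if dead.any():
        logger.warning("normalize: dropping %d zero-range pixel(s) from mask", int(dead.sum()))
    mask = movie.mask & flat_ok
    safe = np.where(rng > 0, rng, 1.0)
    frames = (movie.frames - lo) / safe
    return replace(movie, frames=frames, mask=mask)


def preprocess(movie: VoltageMovie, config: Optional[PreprocessConfig] = None) -> VoltageMovie:
    """Full conditioning pipeline: invert -> bin -> low-pass -> baseline -> normalise."""
    config = config or PreprocessConfig()
    out = movie
    if config.invert:
        out = replace(out, frames=-out.frames)
    out = spatial_bin(out, config.bin_size)
    out = temporal_filter(out, config.lowpass_cutoff)
    out = remove_baseline(out, config)
    if config.normalize:
        out = normalize(out)
    return out
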