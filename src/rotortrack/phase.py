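"""Phase mapping and per-frame phase-singularity (PS) detection.

Each pixel's conditioned voltage trace is transformed to instantaneous
phase via the analytic signal (Hilbert transform), mapping every action
potential onto a single [-pi, pi) cycle regardless of amplitude or
period.  A phase singularity -- the tip of a spiral wave -- is a point
with no definite phase around which neighbouring phases complete a full
cycle; it is located by summing wrapped phase differences around every
2x2 pixel loop and keeping loops whose winding is +/-2pi.

Sign convention: chirality +1 means the phase increases counter-clockwise
when traversing a loop in image coordinates (x right, y down).  The
tracker and the wavefront-edge module inherit this convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import hilbert

from .preprocess import VoltageMovie

logger = logging.getLogger("rotortrack")

__all__ = [
    "PhaseMovie",
    "PSDetection",
    "wrap_phase",
    "compute_phase",
    "detect_ps",
    "detect_ps_movie",
    "smooth_phase",
    "smooth_phase_movie",
]

TWO_PI = 2.0 * np.pi


def wrap_phase(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into [-pi, pi)."""
    return (np.asarray(a) + np.pi) % TWO_PI - np.pi


@dataclass
class PhaseMovie:
    """Per-pixel instantaneous phase in [-pi, pi).

    Non-tissue pixels are NaN.  ``low_confidence_frames`` marks the
    leading/trailing stretch (about one dominant period) where the
    analytic signal suffers end effects; detections there are kept but
    flagged.
    """

    phase: np.ndarray  # (time, height, width), radians
    sampling_rate: float
    mask: np.ndarray  # (height, width) bool
    low_confidence_frames: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.phase.ndim != 3:
            raise ValueError("phase must be 3-D (time, height, width)")
        if self.mask.shape != self.phase.shape[1:]:
            raise ValueError("mask shape does not match phase frames")

    @property
    def n_frames(self) -> int:
        return self.phase.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.phase.shape[1:]  # type: ignore[return-value]


@dataclass(frozen=True)
class PSDetection:
    """One candidate phase singularity in one frame."""

    frame: int
    x: int  # pixel column
    y: int  # pixel row
    chirality: int  # +1 counter-clockwise winding, -1 clockwise
    low_confidence: bool = False

    @property
    def position(self) -> tuple[int, int]:
        return (self.x, self.y)


def _dominant_period_frames(traces: np.ndarray, sampling_rate: float) -> int:
    """Median dominant period (in frames) across pixel traces."""
    T = traces.shape[0]
    spec = np.abs(np.fft.rfft(traces - traces.mean(axis=0), axis=0))
    spec[0] = 0.0
    k = np.argmax(spec, axis=0)
    k_med = max(int(np.median(k[k > 0])) if (k > 0).any() else 1, 1)
    return min(int(round(T / k_med)), T // 2)


def compute_phase(movie: VoltageMovie, detrend: str = "mean") -> PhaseMovie:
    """Analytic-signal phase of every tissue pixel trace.

    The trace is mean-subtracted (``detrend="mean"``, the default
    contract; ``"none"`` skips it), its quadrature is formed by the
    Hilbert transform, and phase = atan2(quadrature, in-phase), wrapped
    to [-pi, pi).  Zero-variance pixels are dropped from the mask.
    """
    frames = movie.frames
    mask = movie.mask.copy()
    var = frames.var(axis=0)
    dead = mask & (var <= 0)
    if dead.any():
        logger.warning("compute_phase: dropping %d zero-variance pixel(s)", int(dead.sum()))
        mask &= var > 0
    flat = frames.reshape(movie.n_frames, -1)[:, mask.ravel()]
    if detrend == "mean":
        flat = flat - flat.mean(axis=0)
    elif detrend != "none":
        raise ValueError("detrend must be 'mean' or 'none'")
    analytic = hilbert(flat, axis=0)
    ph = wrap_phase(np.angle(analytic))
    phase = np.full(frames.shape, np.nan)
    phase.reshape(movie.n_frames, -1)[:, mask.ravel()] = ph
    n_edge = _dominant_period_frames(flat, movie.sampling_rate) if flat.size else 0
    return PhaseMovie(
        phase=phase,
        sampling_rate=movie.sampling_rate,
        mask=mask,
        low_confidence_frames=(n_edge, n_edge),
    )


def _plaquette_winding(phase: np.ndarray) -> np.ndarray:
    """Loop sum of wrapped phase differences around every 2x2 plaquette.

    Corners are visited (y,x) -> (y,x+1) -> (y+1,x+1) -> (y+1,x); the
    sum is a multiple of 2pi (up to float error), nonzero only at a
    singularity.  Works on a single frame or a whole (time, h, w) movie.
    """
    a = phase[..., :-1, :-1]
    b = phase[..., :-1, 1:]
    c = phase[..., 1:, 1:]
    d = phase[..., 1:, :-1]
    return wrap_phase(b - a) + wrap_phase(c - b) + wrap_phase(d - c) + wrap_phase(a - d)


_EIGHT = np.ones((3, 3), dtype=int)


def detect_ps(
    phase_frame: np.ndarray,
    mask: Optional[np.ndarray] = None,
    frame: int = 0,
    tol: float = np.pi,
    low_confidence: bool = False,
) -> List[PSDetection]:
    """Detect candidate phase singularities in one phase frame.

    Plaquettes whose winding exceeds ``tol`` (default pi, the natural
    midpoint between 0 and 2pi in floating point) yield detections;
    8-connected same-chirality plaquettes are merged into a single
    detection at their centroid so a thick singularity is not counted
    twice.  Returned positions are plaquette centres rounded to the
    nearest pixel.
    """
    phase_frame = np.asarray(phase_frame, dtype=float)
    if phase_frame.shape[0] < 2 or phase_frame.shape[1] < 2:
        raise ValueError("phase frame must be at least 2x2")
    if mask is None:
        mask = ~np.isnan(phase_frame)
    valid = mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, 1:] & mask[1:, :-1]
    winding = _plaquette_winding(np.nan_to_num(phase_frame))
    return _detections_from_winding(
        winding, valid, phase_frame.shape, frame, tol, low_confidence
    )


def _detections_from_winding(
    winding: np.ndarray,
    valid: np.ndarray,
    frame_shape: tuple[int, int],
    frame: int,
    tol: float,
    low_confidence: bool,
) -> List[PSDetection]:
    detections: List[PSDetection] = []
    for sign in (1, -1):
        hits = valid & (sign * winding > tol)
        if not hits.any():
            continue
        labels, n = ndimage.label(hits, structure=_EIGHT)
        iy, ix = np.nonzero(hits)
        lab = labels[iy, ix]
        counts = np.bincount(lab, minlength=n + 1)[1:]
        cy = np.bincount(lab, weights=iy, minlength=n + 1)[1:] / counts
        cx = np.bincount(lab, weights=ix, minlength=n + 1)[1:] / counts
        for yy, xx in zip(cy, cx):
            # plaquette (iy, ix) is centred at (ix + 0.5, iy + 0.5); the
            # centre rounds to the nearest pixel, ties to the plaquette's
            # own top-left corner
            x = min(max(int(np.floor(xx + 0.5)), 0), frame_shape[1] - 1)
            y = min(max(int(np.floor(yy + 0.5)), 0), frame_shape[0] - 1)
            detections.append(
                PSDetection(frame=frame, x=x, y=y, chirality=sign, low_confidence=low_confidence)
            )
    detections.sort(key=lambda d: (d.y, d.x, d.chirality))
    return detections


def detect_ps_movie(phase_movie: PhaseMovie, tol: float = np.pi) -> List[List[PSDetection]]:
    """Run ``detect_ps`` on every frame; returns one list per frame."""
    lo, hi = phase_movie.low_confidence_frames
    n = phase_movie.n_frames
    mask = phase_movie.mask
    valid = mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, 1:] & mask[1:, :-1]
    winding = _plaquette_winding(np.nan_to_num(phase_movie.phase))
    out = []
    for t in range(n):
        lc = t < lo or t >= n - hi
        out.append(
            _detections_from_winding(
                winding[t], valid, phase_movie.frame_shape, t, tol, lc
            )
        )
    return out


def smooth_phase(
    phase_frame: np.ndarray, bin_size: int = 3, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Circular (vector) uniform smoothing of a phase frame.

    Unit vectors (cos, sin) are averaged over the neighbourhood and the
    smoothed phase is the angle of the mean vector, so values straddling
    the +/-pi wrap average correctly.
    """
    if bin_size % 2 == 0:
        raise ValueError("bin_size must be odd")
    phase_frame = np.asarray(phase_frame, dtype=float)
    if mask is None:
        mask = ~np.isnan(phase_frame)
    if bin_size == 1:
        return phase_frame.copy()
    m = mask.astype(float)
    cos = ndimage.uniform_filter(np.where(mask, np.cos(phase_frame), 0.0), bin_size, mode="constant")
    sin = ndimage.uniform_filter(np.where(mask, np.sin(phase_frame), 0.0), bin_size, mode="constant")
    cover = ndimage.uniform_filter(m, bin_size, mode="constant")
    out = np.full_like(phase_frame, np.nan)
    ok = mask & (cover > 0)
    out[ok] = np.arctan2(sin[ok], cos[ok])
    return wrap_phase(out)


def smooth_phase_movie(phase_movie: PhaseMovie, bin_size: int = 3) -> PhaseMovie:
    """Circular smoothing of every frame (vectorised over time)."""
    if bin_size == 1:
        return phase_movie
    if bin_size % 2 == 0:
        raise ValueError("bin_size must be odd")
    mask = phase_movie.mask
    ph = phase_movie.phase
    size = (1, bin_size, bin_size)
    cos = ndimage.uniform_filter(np.where(mask, np.cos(ph), 0.0), size, mode="constant")
    sin = ndimage.uniform_filter(np.where(mask, np.sin(ph), 0.0), size, mode="constant")
    cover = ndimage.uniform_filter(mask.astype(float), bin_size, mode="constant")
    out = np.full_like(ph, np.nan)
    ok = mask & (cover > 0)
    out[:, ok] = np.arctan2(sin[:, ok], cos[:, ok])
    return PhaseMovie(
        phase=wrap_phase(out),
        sampling_rate=phase_movie.sampling_rate,
        mask=mask,
        low_confidence_frames=phase_movie.low_confidence_frames,
    )
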