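"""Counting full rotations of a tracked PS via wavefront-edge distances.

The leading edge of a spiral wave is the locus where phase jumps from
pi to -pi (a new action potential's wavefront), as opposed to the
smooth wavefront-to-wavetail progression elsewhere.  Within an L x L
box centred on the PS, the jump is located by thresholding the Sobel
gradient magnitude of the wrapped phase: a smooth phase field never
exceeds about 1 rad/pixel while crossing the wrap line costs about
2*pi, so only the wrap discontinuity passes an absolute floor of pi/2
rad/pixel.  The suprathreshold component attached to the PS is kept and
its pixels are indexed by distance to the PS.

Each frame's edge is compared with the trajectory's reference edge
(frame 1): both are truncated to the shorter length n_d, the n_d x 2
matrix of element-wise coordinate differences is formed, and its
largest singular value is the edge distance.  As the rotor turns, this
distance rises and falls once per revolution; the number of full
rotations N_r is the number of sufficiently prominent local minima of
the edge-distance series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.spatial.distance import directed_hausdorff
from skimage.morphology import skeletonize

from .phase import PhaseMovie, PSDetection
from .tracking import PSTrajectory

logger = logging.getLogger("rotortrack")

__all__ = [
    "RotationConfig",
    "EdgeTrace",
    "EdgeDistanceSeries",
    "detect_edge",
    "edge_distance",
    "build_distance_series",
    "count_rotations",
    "quantify_trajectory",
    "TrajectoryQuantification",
]

# A smooth phase field's per-pixel gradient stays well below this; the
# pi -> -pi wrap costs ~2*pi across one pixel (~pi after the central
# difference), so pi/2 separates the two regimes.
EDGE_GRADIENT_FLOOR = np.pi / 2.0


@dataclass
class RotationConfig:
    """Edge detection and cycle counting settings.

    ``L`` is the side of the square edge-detection box centred on the PS
    (odd pixels; recommended default 11, or 15 for ~0.26 mm pitch data).
    ``sobel_threshold`` is the within-box relative gradient threshold (a
    fraction of the box's maximum gradient magnitude), applied on top of
    the absolute wrap-jump floor.  ``min_prominence`` is the minimum
    prominence of an accepted edge-distance minimum, as a fraction of
    the series range.  Gap runs longer than ``max_gap_span`` frames
    split the series: minima may not bridge them (incomplete cycles).
    """

    L: int = 11
    min_prominence: float = 0.2
    sobel_threshold: float = 0.5
    metric: str = "svd"  # "svd" | "mean" | "hausdorff"
    length_normalise: bool = True
    max_gap_span: int = 5
    attach_radius: int = 2
    smooth_window: int = 5  # centred moving average before minima detection

    def __post_init__(self) -> None:
        if self.L < 3 or self.L % 2 == 0:
            raise ValueError("L must be odd and >= 3")
        if not 0 < self.min_prominence < 1 or not 0 < self.sobel_threshold < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        if self.metric not in ("svd", "mean", "hausdorff"):
            raise ValueError("metric must be 'svd', 'mean' or 'hausdorff'")


@dataclass
class EdgeTrace:
    """Leading-edge pixels for one frame, ordered by distance to the PS."""

    frame: int
    pixels: np.ndarray  # (n, 2) global (x, y) coordinates
    clipped: bool = False  # box truncated at the grid boundary

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float).reshape(-1, 2)

    @property
    def is_empty(self) -> bool:
        return self.pixels.shape[0] == 0

    def __len__(self) -> int:
        return self.pixels.shape[0]


@dataclass
class EdgeDistanceSeries:
    """Edge distance to the reference edge, per tracked frame."""

    frames: np.ndarray  # global frame indices
    values: np.ndarray  # distances; NaN where no edge was detected
    reference_index: int  # index into frames of the reference edge
    minima_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_rotations: int = 0
    reliable: bool = True

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


_EIGHT = np.ones((3, 3), dtype=int)


def detect_edge(
    phase_frame: np.ndarray,
    ps: PSDetection,
    config: Optional[RotationConfig] = None,
    mask: Optional[np.ndarray] = None,
) -> EdgeTrace:
    """Detect the leading-edge pixels around one PS in one phase frame.

    Returns an empty trace when no suprathreshold pixel is attached to
    the PS (a missing-edge frame).
    """
    config = config or RotationConfig()
    phase_frame = np.asarray(phase_frame, dtype=float)
    H, W = phase_frame.shape
    half = config.L // 2
    y0, y1 = max(ps.y - half, 0), min(ps.y + half + 1, H)
    x0, x1 = max(ps.x - half, 0), min(ps.x + half + 1, W)
    clipped = (y1 - y0) != config.L or (x1 - x0) != config.L
    sub = phase_frame[y0:y1, x0:x1]
    if mask is not None:
        sub = np.where(mask[y0:y1, x0:x1], sub, np.nan)
    sub = np.nan_to_num(sub)
    gy = ndimage.sobel(sub, axis=0, mode="nearest") / 8.0
    gx = ndimage.sobel(sub, axis=1, mode="nearest") / 8.0
    grad = np.hypot(gx, gy)
    thr = max(config.sobel_threshold * float(grad.max(initial=0.0)), EDGE_GRADIENT_FLOOR)
    hits = grad >= thr
    if mask is not None:
        hits &= mask[y0:y1, x0:x1]
    if not hits.any():
        return EdgeTrace(frame=ps.frame, pixels=np.empty((0, 2)), clipped=clipped)
    # The Sobel response straddles the wrap line, giving a 2-3 pixel
    # thick band whose pixel count swings with orientation; thin it to a
    # one-pixel curve so edge length (and hence the truncated distance)
    # is stable over a rotation.
    thinned = skeletonize(hits)
    if thinned.any():
        hits = thinned
    labels, n = ndimage.label(hits, structure=_EIGHT)
    py, px = ps.y - y0, ps.x - x0
    ly, lx = np.nonzero(hits)
    cheb = np.maximum(np.abs(ly - py), np.abs(lx - px))
    attached = np.unique(labels[ly[cheb <= config.attach_radius], lx[cheb <= config.attach_radius]])
    attached = attached[attached > 0]
    if attached.size == 0:
        return EdgeTrace(frame=ps.frame, pixels=np.empty((0, 2)), clipped=clipped)
    keep = np.isin(labels[ly, lx], attached)
    ey, ex = ly[keep], lx[keep]
    gx_glob, gy_glob = ex + x0, ey + y0
    dist = np.hypot(gx_glob - ps.x, gy_glob - ps.y)
    order = np.lexsort((gx_glob, gy_glob, dist))  # distance, then (y, x) for ties
    pixels = np.column_stack([gx_glob[order], gy_glob[order]]).astype(float)
    return EdgeTrace(
        frame=ps.frame,
        pixels=_index_by_radius(pixels, dist[order], r_cap=config.L // 2),
        clipped=clipped,
    )


def _index_by_radius(pixels: np.ndarray, radii: np.ndarray, r_cap: int) -> np.ndarray:
    """Index edge pixels by their distance to the PS: entry k-1 is the
    edge pixel nearest radius k (k = 1 .. min(floor(max radius), r_cap)).

    Raw rasterised edges have orientation-dependent pixel counts (a
    diagonal ray's radii step by sqrt(2), an axial ray's by 1, and a
    diagonal ray reaches sqrt(2) times further inside a square box), so
    the truncated index-matched distance would swing over a rotation for
    purely geometric reasons.  Snapping the index to integer radii and
    capping at the box's inscribed radius makes position-i radii
    comparable between any two edges regardless of orientation.
    """
    if len(pixels) == 0:
        return pixels
    r_max = min(int(np.floor(radii.max())), r_cap)
    if r_max < 1:
        return pixels[:1]
    idx = [int(np.argmin(np.abs(radii - k))) for k in range(1, r_max + 1)]
    idx = [i for n, i in enumerate(idx) if n == 0 or i != idx[n - 1]]  # no repeats
    return pixels[idx]


def edge_distance(edge_a: EdgeTrace, edge_b: EdgeTrace, metric: str = "svd") -> float:
    """Scalar dissimilarity between two edges.

    Both edges are truncated to the shorter length n_d, keeping the
    pixels nearest the PS.  The default metric forms the n_d x 2 matrix
    of element-wise differences of index-matched (x, y) coordinates and
    returns its largest singular value; alternates are the mean
    Euclidean distance of matched pixels and the symmetric Hausdorff
    distance of the full pixel sets.
    """
    if edge_a.is_empty or edge_b.is_empty:
        return float("nan")
    if metric == "hausdorff":
        a, b = edge_a.pixels, edge_b.pixels
        return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])
    n_d = min(len(edge_a), len(edge_b))
    diff = edge_a.pixels[:n_d] - edge_b.pixels[:n_d]
    if metric == "svd":
        return float(np.linalg.svd(diff, compute_uv=False)[0])
    if metric == "mean":
        return float(np.mean(np.hypot(diff[:, 0], diff[:, 1])))
    raise ValueError("metric must be 'svd', 'mean' or 'hausdorff'")


def _length_factor(n_d: int, metric: str) -> float:
    """Growth of the matched-edge distance with truncation length n_d.

    For an ideal radius-indexed ray rotated by a fixed angle, rows of
    the difference matrix are r_k * chord with r_k = 1..n_d, so the
    largest singular value grows as sqrt(sum k^2) and the mean matched
    distance as mean(k).  Dividing by this factor removes the spurious
    modulation caused by frame-to-frame fluctuation of the detected edge
    length, which otherwise mimics partial rotations.
    """
    k = np.arange(1, n_d + 1, dtype=float)
    if metric == "svd":
        return float(np.sqrt(np.sum(k**2)))
    if metric == "mean":
        return float(np.mean(k))
    return 1.0  # hausdorff: max-based, already length-robust


def build_distance_series(
    edges: Sequence[EdgeTrace],
    frames: Optional[Sequence[int]] = None,
    metric: str = "svd",
    length_normalise: bool = True,
) -> EdgeDistanceSeries:
    """Distance of every edge to the reference (first non-empty) edge.

    With ``length_normalise`` (default) each value is divided by the
    ideal-ray length factor of its truncation length n_d, putting frames
    with shorter detected edges on the same scale as full-length ones.
    """
    if frames is None:
        frames = [e.frame for e in edges]
    ref_idx = next((i for i, e in enumerate(edges) if not e.is_empty), None)
    values = np.full(len(edges), np.nan)
    if ref_idx is not None:
        ref = edges[ref_idx]
        for i, e in enumerate(edges):
            v = edge_distance(ref, e, metric=metric)
            if length_normalise and np.isfinite(v):
                v /= _length_factor(min(len(ref), len(e)), metric)
            values[i] = v
        values[ref_idx] = 0.0
    return EdgeDistanceSeries(
        frames=np.asarray(frames, dtype=int),
        values=values,
        reference_index=ref_idx if ref_idx is not None else 0,
    )


def _segments(finite: np.ndarray, max_gap_span: int) -> List[np.ndarray]:
    """Index runs separated by missing-value gaps longer than max_gap_span."""
    idx = np.nonzero(finite)[0]
    if idx.size == 0:
        return []
    splits = np.nonzero(np.diff(idx) > max_gap_span + 1)[0] + 1
    return np.split(idx, splits)


def count_rotations(
    series: EdgeDistanceSeries | np.ndarray, config: Optional[RotationConfig] = None
) -> int:
    """Count full rotations as prominent local minima of the series.

    Short missing runs (<= ``max_gap_span`` frames) are bridged by
    linear interpolation; longer runs split the series and minima may
    not bridge them, reflecting incomplete cycles.  A terminal value
    lower than its predecessor counts as a final (completed) return, but
    the reference frame itself (distance 0 at the start) does not.
    """
    config = config or RotationConfig()
    values = series.values if isinstance(series, EdgeDistanceSeries) else np.asarray(series, float)
    finite = np.isfinite(values)
    if finite.sum() < 3:
        if isinstance(series, EdgeDistanceSeries):
            series.n_rotations = 0
        if not finite.any():
            logger.warning("count_rotations: all edge distances missing")
        return 0
    rng = float(np.nanmax(values) - np.nanmin(values))
    if rng <= 0:
        return 0
    prominence = config.min_prominence * rng
    total = 0
    minima: List[int] = []
    segs = _segments(finite, config.max_gap_span)
    for si, seg in enumerate(segs):
        lo, hi = seg[0], seg[-1]
        s = values[lo : hi + 1].copy()
        bad = ~np.isfinite(s)
        if bad.any():  # interpolate short gaps inside the segment
            xi = np.arange(s.size)
            s[bad] = np.interp(xi[bad], xi[~bad], s[~bad])
        # a centred moving average suppresses the pixel-discretisation
        # ripple of the edge distance without displacing cycle minima;
        # short segments (where every sample matters) are left untouched
        w = min(config.smooth_window, max(1, s.size // 10))
        if w > 1:
            s = np.convolve(np.pad(s, w // 2, mode="edge"), np.ones(w) / w, mode="valid")[: s.size]
        if si == len(segs) - 1:
            # sentinel so a final completed return counts as a minimum
            s = np.append(s, np.nanmax(values) + rng)
        peaks, _ = find_peaks(-s, prominence=prominence)
        total += len(peaks)
        minima.extend(int(lo + p) for p in peaks)
    if isinstance(series, EdgeDistanceSeries):
        series.minima_frames = series.frames[np.asarray(minima, dtype=int)] if minima else np.array([], dtype=int)
        series.n_rotations = total
    return total


@dataclass
class TrajectoryQuantification:
    """Rotation count, displacement and path of one tracked PS."""

    trajectory: PSTrajectory
    n_rotations: int
    p_d: Tuple[int, int]  # (|dx|, |dy|) start-to-end displacement
    path: List[Tuple[int, int, int]]  # (frame, x, y)
    series: EdgeDistanceSeries
    n_missing_edges: int
    reliable: bool

    @property
    def id(self) -> int:
        return self.trajectory.id

    @property
    def duration_ms(self) -> float:
        return self.trajectory.duration_ms


def quantify_trajectory(
    traj: PSTrajectory,
    phase: PhaseMovie,
    config: Optional[RotationConfig] = None,
) -> TrajectoryQuantification:
    """Quantify one trajectory: N_r, p_D and the tracked path.

    Runs edge detection at every tracked PS position, builds the
    edge-distance series against the trajectory's reference edge, and
    counts rotations.  With more than half the edges missing, N_r is
    flagged unreliable.
    """
    config = config or RotationConfig()
    if len(traj) < 3:
        raise ValueError("trajectory must span at least 3 tracked frames")
    edges = [
        detect_edge(phase.phase[d.frame], d, config, mask=phase.mask) for d in traj.detections
    ]
    series = build_distance_series(
        edges,
        frames=[d.frame for d in traj.detections],
        metric=config.metric,
        length_normalise=config.length_normalise,
    )
    n_missing = series.n_missing
    reliable = n_missing <= 0.5 * len(edges)
    if not reliable:
        logger.warning(
            "trajectory %d: %d/%d missing edges; rotation count unreliable",
            traj.id, n_missing, len(edges),
        )
    n_r = count_rotations(series, config)
    series.reliable = reliable
    first, last = traj.detections[0], traj.detections[-1]
    p_d = (abs(last.x - first.x), abs(last.y - first.y))
    path = [(d.frame, d.x, d.y) for d in traj.detections]
    return TrajectoryQuantification(
        trajectory=traj,
        n_rotations=n_r,
        p_d=p_d,
        path=path,
        series=series,
        n_missing_edges=n_missing,
        reliable=reliable,
    )
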