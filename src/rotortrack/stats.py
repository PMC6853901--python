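"""Group statistics of rotational activity.

Pooled over all tracked PS trajectories: duration and rotation-count
histograms split into short-lived PS vs rotational drivers (RDs, at
least 2 full rotations by default), sliding-window incidence/location
counts, per-recording summary statistics, and rotation-thresholded
incidence heat-maps that grade how organised the fibrillation is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .rotation import TrajectoryQuantification

__all__ = [
    "SummaryStats",
    "IncidenceMap",
    "summarize",
    "incidence_heatmap",
    "windowed_counts",
    "histograms",
]


@dataclass
class SummaryStats:
    """Recording-level statistics of PS/RD activity."""

    n_ps: int
    n_rd: int
    n_locations_ps: int
    n_locations_rd: int
    max_duration_ms: float
    max_rotations: int
    rd_threshold: float = 2.0

    def as_dict(self) -> Dict[str, float]:
        return {
            "n_ps": self.n_ps,
            "n_rd": self.n_rd,
            "n_locations_ps": self.n_locations_ps,
            "n_locations_rd": self.n_locations_rd,
            "max_duration_ms": self.max_duration_ms,
            "max_rotations": self.max_rotations,
            "rd_threshold": self.rd_threshold,
        }


@dataclass
class IncidenceMap:
    """Per-pixel fraction of the recording occupied by qualifying PSs.

    ``grid[y, x] * recording_duration_ms`` is the total time (ms) pixel
    (x, y) hosted a PS with at least ``rotation_threshold`` rotations.
    """

    grid: np.ndarray
    rotation_threshold: float
    recording_duration_ms: float


def _qualifying(
    quants: Sequence[TrajectoryQuantification], threshold: float
) -> List[TrajectoryQuantification]:
    return [q for q in quants if q.n_rotations >= threshold]


def _visited_pixels(quants: Sequence[TrajectoryQuantification]) -> Set[Tuple[int, int]]:
    return {(x, y) for q in quants for (_, x, y) in q.path}


def summarize(
    quants: Sequence[TrajectoryQuantification], threshold: float = 2.0
) -> SummaryStats:
    """Counts, distinct locations and maxima over all trajectories."""
    rds = _qualifying(quants, threshold)
    return SummaryStats(
        n_ps=len(quants),
        n_rd=len(rds),
        n_locations_ps=len(_visited_pixels(quants)),
        n_locations_rd=len(_visited_pixels(rds)),
        max_duration_ms=max((q.duration_ms for q in quants), default=0.0),
        max_rotations=max((q.n_rotations for q in quants), default=0),
        rd_threshold=threshold,
    )


def incidence_heatmap(
    quants: Sequence[TrajectoryQuantification],
    movie_shape: Tuple[int, int],
    n_frames: int,
    sampling_rate: float,
    threshold: float = 2.0,
) -> IncidenceMap:
    """Heat-map of per-pixel PS occupancy fraction.

    Each pixel's value is the fraction of recording frames during which
    some trajectory with N_r >= threshold occupied it; simultaneous
    occupancy by several PSs counts once (distinct frames).
    """
    grid = np.zeros(movie_shape, dtype=float)
    occupied: Set[Tuple[int, int, int]] = {
        (f, x, y) for q in _qualifying(quants, threshold) for (f, x, y) in q.path
    }
    for _, x, y in occupied:
        grid[y, x] += 1.0
    grid /= n_frames
    return IncidenceMap(
        grid=grid,
        rotation_threshold=threshold,
        recording_duration_ms=n_frames / sampling_rate * 1000.0,
    )


def windowed_counts(
    quants: Sequence[TrajectoryQuantification],
    n_frames: int,
    sampling_rate: float,
    window_ms: float = 20.0,
    step: int = 1,
    rd_threshold: float = 2.0,
) -> pd.DataFrame:
    """Sliding-window incidence and location counts (default 20 ms).

    For each window start t, the number of trajectories with a tracked
    detection inside [t, t + window) and the number of distinct pixels
    they occupy, split into all PS vs RDs.
    """
    window = max(int(round(window_ms * sampling_rate / 1000.0)), 1)
    if window > n_frames:
        import warnings

        warnings.warn("window longer than the recording; using a single window")
        window = n_frames
    rd_ids = {q.id for q in _qualifying(quants, rd_threshold)}
    starts = np.arange(0, max(n_frames - window, 0) + 1, step)
    rows = []
    paths = [(q.id, np.asarray(q.path, dtype=int)) for q in quants]
    for t0 in starts:
        t1 = t0 + window
        n_ps = n_rd = 0
        loc_ps: Set[Tuple[int, int]] = set()
        loc_rd: Set[Tuple[int, int]] = set()
        for qid, path in paths:
            inside = path[(path[:, 0] >= t0) & (path[:, 0] < t1)]
            if inside.size == 0:
                continue
            n_ps += 1
            pix = {(int(x), int(y)) for _, x, y in inside}
            loc_ps |= pix
            if qid in rd_ids:
                n_rd += 1
                loc_rd |= pix
        rows.append(
            {
                "t_ms": t0 / sampling_rate * 1000.0,
                "n_ps": n_ps,
                "n_rd": n_rd,
                "n_locations_ps": len(loc_ps),
                "n_locations_rd": len(loc_rd),
            }
        )
    return pd.DataFrame(rows)


def histograms(
    quants: Sequence[TrajectoryQuantification],
    duration_bin_ms: float = 100.0,
    rotation_bin: float = 1.0,
    rd_threshold: float = 2.0,
) -> Dict[str, pd.DataFrame]:
    """Duration and rotation-count histograms, split by PS class.

    Returns ``{"duration": df, "rotations": df}`` where each frame has
    the bin left edge and per-class counts (short-lived vs RD).
    """
    rds = _qualifying(quants, rd_threshold)
    shorts = [q for q in quants if q.n_rotations < rd_threshold]

    def _hist(values_short, values_rd, bin_width, name):
        allv = list(values_short) + list(values_rd)
        top = max(allv, default=0.0)
        edges = np.arange(0.0, top + 2 * bin_width, bin_width)
        cs, _ = np.histogram(values_short, bins=edges)
        cr, _ = np.histogram(values_rd, bins=edges)
        return pd.DataFrame(
            {name: edges[:-1], "short_lived": cs, "rd": cr, "total": cs + cr}
        )

    return {
        "duration": _hist(
            [q.duration_ms for q in shorts],
            [q.duration_ms for q in rds],
            duration_bin_ms,
            "duration_ms",
        ),
        "rotations": _hist(
            [q.n_rotations for q in shorts],
            [q.n_rotations for q in rds],
            rotation_bin,
            "n_rotations",
        ),
    }
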