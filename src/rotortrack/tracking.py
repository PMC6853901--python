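"""Linking per-frame PS detections into trajectories.

Even a stable rotor drifts across pixels and its detection is
occasionally missed, so a detection at frame t is attributed to an
existing trajectory if the trajectory's last position falls inside a
spatial allowance box of half-width ``d_gap`` pixels (per axis) within
the last ``t_gap`` frames.  Candidates are considered most-recent frame
first; among candidates in the same frame the spatially closest
(Euclidean) wins.  A detection with no admissible candidate starts a new
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from .phase import PSDetection

__all__ = [
    "TrackingConfig",
    "PSTrajectory",
    "t_gap_frames",
    "link_ps",
    "classify_trajectories",
]


def t_gap_frames(t_gap_ms: float, sampling_rate: float) -> int:
    """Convert a temporal allowance in ms to frames (at least 1)."""
    return max(int(round(t_gap_ms * sampling_rate / 1000.0)), 1)


@dataclass
class TrackingConfig:
    """Spatial/temporal gap allowances for PS linking.

    ``d_gap`` is the per-axis (Chebyshev) half-width of the allowance
    box in pixels; ``t_gap`` the look-back in frames.  Defaults follow
    the recommended settings for a 0.13 mm inter-pixel camera: d_gap 5
    pixels, t_gap 5 ms (= 5 frames at 1 kHz).
    """

    d_gap: float = 5.0
    t_gap: int = 5
    match_chirality: bool = True

    def __post_init__(self) -> None:
        if self.d_gap < 0:
            raise ValueError("d_gap must be >= 0")
        if self.t_gap < 1:
            raise ValueError("t_gap must be >= 1")

    @classmethod
    def from_ms(
        cls, d_gap: float = 5.0, t_gap_ms: float = 5.0, sampling_rate: float = 1000.0, **kw
    ) -> "TrackingConfig":
        return cls(d_gap=d_gap, t_gap=t_gap_frames(t_gap_ms, sampling_rate), **kw)


@dataclass
class PSTrajectory:
    """A linked PS over time.

    Stored detections are time-ordered; consecutive ones differ by at
    most ``t_gap`` frames and by at most ``d_gap`` pixels per axis.
    """

    id: int
    detections: List[PSDetection]
    sampling_rate: Optional[float] = None

    @property
    def chirality(self) -> int:
        return self.detections[0].chirality

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame

    @property
    def n_frames_spanned(self) -> int:
        return self.end_frame - self.start_frame + 1

    @property
    def duration_ms(self) -> float:
        """Duration = (end - start + 1) frames converted to ms."""
        if self.sampling_rate is None:
            raise ValueError("sampling_rate unknown; set it to compute duration")
        return self.n_frames_spanned / self.sampling_rate * 1000.0

    @property
    def last(self) -> PSDetection:
        return self.detections[-1]

    def positions(self) -> np.ndarray:
        return np.array([[d.x, d.y] for d in self.detections], dtype=float)

    def __len__(self) -> int:
        return len(self.detections)


def _group_by_frame(detections: Iterable[PSDetection]) -> Dict[int, List[PSDetection]]:
    by_frame: Dict[int, List[PSDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    for lst in by_frame.values():
        # canonical in-frame order makes linking independent of input order
        lst.sort(key=lambda d: (d.y, d.x, d.chirality))
    return by_frame


def link_ps(
    detections: Iterable[PSDetection],
    config: Optional[TrackingConfig] = None,
    sampling_rate: Optional[float] = None,
) -> List[PSTrajectory]:
    """Link detections into trajectories with gap allowances.

    For each detection at frame t the look-back frames t-1 ... t-t_gap
    are searched in order of recency for trajectory ends inside the
    d_gap box (same chirality unless ``match_chirality`` is off).  When
    several detections compete for the same trajectory end, assignment
    is greedy by increasing Euclidean distance (ties: lower trajectory
    id, then detection order); each trajectory gains at most one
    detection per frame.  Losers fall through to older look-back frames
    and finally start new trajectories.
    """
    config = config or TrackingConfig()
    by_frame = _group_by_frame(detections)
    trajectories: List[PSTrajectory] = []
    active: List[PSTrajectory] = []
    for t in sorted(by_frame):
        active = [tr for tr in active if t - tr.end_frame <= config.t_gap]
        dets = by_frame[t]
        unmatched = list(range(len(dets)))
        extended: set[int] = set()
        for delta in range(1, config.t_gap + 1):
            if not unmatched:
                break
            frame_prev = t - delta
            cands = [tr for tr in active if tr.end_frame == frame_prev and tr.id not in extended]
            if not cands:
                continue
            pairs = []
            for i in unmatched:
                d = dets[i]
                for tr in cands:
                    last = tr.last
                    if config.match_chirality and d.chirality != tr.chirality:
                        continue
                    if abs(d.x - last.x) <= config.d_gap and abs(d.y - last.y) <= config.d_gap:
                        dist = float(np.hypot(d.x - last.x, d.y - last.y))
                        pairs.append((dist, tr.id, i, tr))
            pairs.sort(key=lambda p: (p[0], p[1], p[2]))
            used_traj: set[int] = set()
            used_det: set[int] = set()
            for dist, tid, i, tr in pairs:
                if tid in used_traj or i in used_det:
                    continue
                tr.detections.append(dets[i])
                used_traj.add(tid)
                used_det.add(i)
                extended.add(tid)
            unmatched = [i for i in unmatched if i not in used_det]
        for i in unmatched:
            tr = PSTrajectory(id=len(trajectories), detections=[dets[i]], sampling_rate=sampling_rate)
            trajectories.append(tr)
            active.append(tr)
    if sampling_rate is not None:
        for tr in trajectories:
            tr.sampling_rate = sampling_rate
    return trajectories


def classify_trajectories(
    trajectories: Sequence[PSTrajectory],
    rotation_counts: Mapping[int, float],
    threshold: float = 2.0,
) -> Dict[str, List[PSTrajectory]]:
    """Partition trajectories into rotational drivers vs short-lived PS.

    A trajectory with at least ``threshold`` full rotations (default 2,
    the threshold commonly used to call a PS a rotational driver) is
    classed ``"rd"``; the rest are ``"short_lived"``.
    """
    out: Dict[str, List[PSTrajectory]] = {"short_lived": [], "rd": []}
    for tr in trajectories:
        n_r = rotation_counts.get(tr.id, 0.0)
        out["rd" if n_r >= threshold else "short_lived"].append(tr)
    return out
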