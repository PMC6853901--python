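"""Readers and writers for movies, detections, trajectories and maps.

Movies travel as multi-page TIFF stacks (or raw ``.npy`` arrays) with a
small JSON sidecar (``<stem>.json``) holding acquisition metadata:
sampling rate (Hz), pixel pitch (mm) and, for synthetic movies, the
generator seed.  Tabular outputs are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .phase import PhaseMovie, PSDetection
from .preprocess import VoltageMovie
from .rotation import TrajectoryQuantification
from .stats import IncidenceMap
from .tracking import PSTrajectory

__all__ = [
    "read_movie",
    "write_movie",
    "write_phase_movie",
    "detections_to_frame",
    "write_detections",
    "read_detections",
    "write_trajectories",
    "write_quantification",
    "write_heatmap",
    "write_summary_json",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_movie(
    path: str | Path,
    sampling_rate: Optional[float] = None,
    pixel_pitch: Optional[float] = None,
) -> VoltageMovie:
    """Load a voltage movie from a TIFF stack or ``.npy`` array.

    Metadata comes from the JSON sidecar next to the file unless given
    explicitly; a missing sampling rate is an error naming the field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: Dict = {}
    sc = _sidecar_path(path)
    if sc.exists() and sc != path:
        meta = json.loads(sc.read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    elif path.suffix.lower() == ".npy":
        frames = np.load(path)
    else:
        raise ValueError(f"unsupported movie format: {path.suffix}")
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"expected (time, height, width) data, got shape {frames.shape}")
    rate = sampling_rate if sampling_rate is not None else meta.get("sampling_rate_hz")
    if rate is None:
        raise ValueError("sampling_rate missing: pass it or provide 'sampling_rate_hz' in the sidecar")
    pitch = pixel_pitch if pixel_pitch is not None else meta.get("pixel_pitch_mm", 0.13)
    return VoltageMovie(frames=np.asarray(frames, dtype=float), sampling_rate=float(rate), pixel_pitch=float(pitch))


def write_movie(movie: VoltageMovie, path: str | Path, seed: Optional[int] = None) -> Path:
    """Write a movie as float32 TIFF (or ``.npy``) plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, movie.frames.astype(np.float32))
    elif path.suffix.lower() == ".npy":
        np.save(path, movie.frames)
    else:
        raise ValueError(f"unsupported movie format: {path.suffix}")
    meta = {
        "sampling_rate_hz": movie.sampling_rate,
        "pixel_pitch_mm": movie.pixel_pitch,
        "shape": list(movie.frames.shape),
    }
    if seed is not None:
        meta["seed"] = seed
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def write_phase_movie(phase: PhaseMovie, path: str | Path) -> Path:
    """Export a phase movie as a float32 TIFF stack for inspection."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, phase.phase.astype(np.float32))
    return path


def detections_to_frame(detections: Sequence[PSDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"frame": d.frame, "x": d.x, "y": d.y, "chirality": d.chirality,
             "low_confidence": int(d.low_confidence)}
            for d in detections
        ],
        columns=["frame", "x", "y", "chirality", "low_confidence"],
    )


def write_detections(detections: Sequence[PSDetection], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    detections_to_frame(detections).to_csv(path, index=False)
    return path


def read_detections(path: str | Path) -> List[PSDetection]:
    df = pd.read_csv(path)
    return [
        PSDetection(
            frame=int(r.frame), x=int(r.x), y=int(r.y), chirality=int(r.chirality),
            low_confidence=bool(getattr(r, "low_confidence", 0)),
        )
        for r in df.itertuples()
    ]


def write_trajectories(trajectories: Sequence[PSTrajectory], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"trajectory_id": tr.id, "frame": d.frame, "x": d.x, "y": d.y, "chirality": d.chirality}
        for tr in trajectories
        for d in tr.detections
    ]
    pd.DataFrame(rows, columns=["trajectory_id", "frame", "x", "y", "chirality"]).to_csv(
        path, index=False
    )
    return path


def write_quantification(quants: Sequence[TrajectoryQuantification], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "trajectory_id": q.id,
            "n_rotations": q.n_rotations,
            "duration_ms": q.duration_ms,
            "p_d_x": q.p_d[0],
            "p_d_y": q.p_d[1],
            "n_missing_edges": q.n_missing_edges,
            "reliable": int(q.reliable),
        }
        for q in quants
    ]
    pd.DataFrame(
        rows,
        columns=["trajectory_id", "n_rotations", "duration_ms", "p_d_x", "p_d_y",
                 "n_missing_edges", "reliable"],
    ).to_csv(path, index=False)
    return path


def write_heatmap(hmap: IncidenceMap, path: str | Path) -> Path:
    """Write an incidence map as float TIFF, or PNG with a colour bar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, hmap.grid.astype(np.float32))
    elif path.suffix.lower() == ".png":
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(hmap.grid, cmap="hot", origin="upper")
        ax.set_title(f"PS incidence (N_r >= {hmap.rotation_threshold:g})")
        fig.colorbar(im, ax=ax, label="occupancy fraction")
        fig.savefig(path, dpi=120)
        plt.close(fig)
    else:
        raise ValueError(f"unsupported heat-map format: {path.suffix}")
    return path


def write_summary_json(summary: Dict, path: str | Path) -> Path:
    """Deterministic (sorted, fixed-format) JSON dump of a summary."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(summary, indent=2, sort_keys=True, allow_nan=False) + "\n")
    return path
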