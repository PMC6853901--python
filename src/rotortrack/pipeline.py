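"""End-to-end pipeline: preprocess -> phase -> detect -> track -> quantify -> statistics.

``RunConfig`` bundles every stage's settings; the shipped defaults are
the recommended profile for a ~0.13 mm inter-pixel optical-mapping
camera ("rat-vf-0.13mm"): 3x3 phase binning, d_gap 5 pixels, t_gap
5 ms, edge box L = 11 pixels, RD threshold 2 rotations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import pandas as pd
import yaml

from . import io as rio
from .phase import PhaseMovie, PSDetection, compute_phase, detect_ps_movie, smooth_phase_movie
from .preprocess import PreprocessConfig, VoltageMovie, preprocess
from .rotation import RotationConfig, TrajectoryQuantification, quantify_trajectory
from .stats import (
    IncidenceMap,
    SummaryStats,
    histograms,
    incidence_heatmap,
    summarize,
    windowed_counts,
)
from .tracking import PSTrajectory, TrackingConfig, link_ps, t_gap_frames

logger = logging.getLogger("rotortrack")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "parameter_sweep", "scale_for_pitch"]

DEFAULT_PROFILE = "rat-vf-0.13mm"
CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All pipeline parameters.

    ``t_gap_ms`` is converted to frames via the movie's sampling rate at
    run time.  ``heatmap_thresholds`` selects the rotation thresholds of
    the exported incidence maps.
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    rotation: RotationConfig = field(default_factory=RotationConfig)
    t_gap_ms: Optional[float] = 5.0  # overrides tracking.t_gap when set
    phase_smooth_bin: int = 3
    rd_threshold: float = 2.0
    window_ms: float = 20.0
    heatmap_thresholds: tuple = (1, 2, 10, 20)
    min_quantify_frames: int = 3
    seed: int = 0
    profile: str = DEFAULT_PROFILE

    def resolved_tracking(self, sampling_rate: float) -> TrackingConfig:
        if self.t_gap_ms is None:
            return self.tracking
        return dataclasses.replace(
            self.tracking, t_gap=t_gap_frames(self.t_gap_ms, sampling_rate)
        )

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["heatmap_thresholds"] = list(self.heatmap_thresholds)
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        d = dict(d)
        d.pop("schema_version", None)
        for key, sub in (
            ("preprocess", PreprocessConfig),
            ("tracking", TrackingConfig),
            ("rotation", RotationConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "heatmap_thresholds" in d:
            d["heatmap_thresholds"] = tuple(d["heatmap_thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def scale_for_pitch(
    config: RunConfig, pixel_pitch_mm: float, reference_pitch_mm: float = 0.26
) -> RunConfig:
    """Rescale the pixel-denominated parameters d_gap and L to a new
    inter-pixel distance (same physical allowance at finer/coarser
    resolution); L is kept odd."""
    ratio = reference_pitch_mm / pixel_pitch_mm
    L = max(int(round(config.rotation.L * ratio)) | 1, 3)
    return dataclasses.replace(
        config,
        tracking=dataclasses.replace(config.tracking, d_gap=config.tracking.d_gap * ratio),
        rotation=dataclasses.replace(config.rotation, L=L),
    )


@dataclass
class PipelineResult:
    """Everything the pipeline computes for one movie."""

    config: RunConfig
    phase: PhaseMovie
    detections: List[PSDetection]
    trajectories: List[PSTrajectory]
    quantifications: List[TrajectoryQuantification]
    summary_stats: SummaryStats
    heatmaps: Dict[float, IncidenceMap]
    windowed: pd.DataFrame
    histograms: Dict[str, pd.DataFrame]

    def summary_dict(self) -> Dict:
        """Deterministic JSON-ready summary of the run."""
        return {
            "config_hash": self.config.config_hash(),
            "profile": self.config.profile,
            "seed": self.config.seed,
            "n_frames": int(self.phase.n_frames),
            "n_detections": len(self.detections),
            "stats": self.summary_stats.as_dict(),
            "trajectories": [
                {
                    "id": q.id,
                    "n_rotations": q.n_rotations,
                    "duration_ms": round(q.duration_ms, 6),
                    "p_d": list(q.p_d),
                    "n_missing_edges": q.n_missing_edges,
                    "reliable": q.reliable,
                }
                for q in self.quantifications
            ],
        }


def _quantify_all(
    trajectories: Sequence[PSTrajectory],
    phase: PhaseMovie,
    rotation: RotationConfig,
    min_frames: int,
) -> List[TrajectoryQuantification]:
    from .rotation import EdgeDistanceSeries
    import numpy as np

    quants: List[TrajectoryQuantification] = []
    for tr in trajectories:
        if len(tr) >= min_frames:
            quants.append(quantify_trajectory(tr, phase, rotation))
        else:
            # too short to host a full rotation; quantified trivially
            first, last = tr.detections[0], tr.detections[-1]
            quants.append(
                TrajectoryQuantification(
                    trajectory=tr,
                    n_rotations=0,
                    p_d=(abs(last.x - first.x), abs(last.y - first.y)),
                    path=[(d.frame, d.x, d.y) for d in tr.detections],
                    series=EdgeDistanceSeries(
                        frames=np.array([d.frame for d in tr.detections]),
                        values=np.full(len(tr), np.nan),
                        reference_index=0,
                    ),
                    n_missing_edges=len(tr),
                    reliable=False,
                )
            )
    return quants


def run_pipeline(
    movie: VoltageMovie,
    config: Optional[RunConfig] = None,
    output_dir: Optional[str | Path] = None,
    skip_preprocess: bool = False,
) -> PipelineResult:
    """Run the full analysis on one movie.

    With ``output_dir`` set, writes detections/trajectories/
    quantification CSVs, per-threshold heat-map TIFFs, a summary JSON
    and a config echo (with its hash) for provenance.
    ``skip_preprocess`` accepts movies that are already conditioned
    (e.g. noiseless synthetic input).
    """
    config = config or RunConfig()
    logger.info("pipeline start: config %s", config.config_hash())
    conditioned = movie if skip_preprocess else preprocess(movie, config.preprocess)
    phase = compute_phase(conditioned)
    phase = smooth_phase_movie(phase, config.phase_smooth_bin)
    per_frame = detect_ps_movie(phase)
    detections = [d for frame in per_frame for d in frame]
    tracking = config.resolved_tracking(movie.sampling_rate)
    trajectories = link_ps(detections, tracking, sampling_rate=movie.sampling_rate)
    quants = _quantify_all(trajectories, phase, config.rotation, config.min_quantify_frames)
    stats = summarize(quants, config.rd_threshold)
    n_frames = movie.n_frames
    heatmaps = {
        thr: incidence_heatmap(quants, movie.frame_shape, n_frames, movie.sampling_rate, thr)
        for thr in config.heatmap_thresholds
    }
    windows = windowed_counts(
        quants, n_frames, movie.sampling_rate, config.window_ms, rd_threshold=config.rd_threshold
    )
    hists = histograms(quants, rd_threshold=config.rd_threshold)
    result = PipelineResult(
        config=config,
        phase=phase,
        detections=detections,
        trajectories=trajectories,
        quantifications=quants,
        summary_stats=stats,
        heatmaps=heatmaps,
        windowed=windows,
        histograms=hists,
    )
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        rio.write_detections(detections, out / "detections.csv")
        rio.write_trajectories(trajectories, out / "trajectories.csv")
        rio.write_quantification(quants, out / "quantification.csv")
        for thr, hm in heatmaps.items():
            rio.write_heatmap(hm, out / f"heatmap_thr{thr:g}.tif")
        windows.to_csv(out / "windowed_counts.csv", index=False)
        rio.write_summary_json(result.summary_dict(), out / "summary.json")
        config.to_yaml(out / "config_echo.yaml")
        logger.info("pipeline outputs written to %s", out)
    return result


def parameter_sweep(
    movie: VoltageMovie,
    config: Optional[RunConfig] = None,
    d_gap: Optional[Iterable[float]] = None,
    t_gap: Optional[Iterable[int]] = None,
    L: Optional[Iterable[int]] = None,
    skip_preprocess: bool = False,
) -> pd.DataFrame:
    """Re-run tracking/quantification over a parameter grid.

    Phase mapping and PS detection do not depend on the swept
    parameters, so detections are computed once and reused.  Returns a
    long-format table of summary statistics per grid point.
    """
    config = config or RunConfig()
    conditioned = movie if skip_preprocess else preprocess(movie, config.preprocess)
    phase = compute_phase(conditioned)
    phase = smooth_phase_movie(phase, config.phase_smooth_bin)
    detections = [d for frame in detect_ps_movie(phase) for d in frame]
    base_tracking = config.resolved_tracking(movie.sampling_rate)
    d_gaps = list(d_gap) if d_gap is not None else [base_tracking.d_gap]
    t_gaps = list(t_gap) if t_gap is not None else [base_tracking.t_gap]
    Ls = list(L) if L is not None else [config.rotation.L]
    rows = []
    for dg, tg, box in itertools.product(d_gaps, t_gaps, Ls):
        tracking = dataclasses.replace(base_tracking, d_gap=dg, t_gap=int(tg))
        rotation = dataclasses.replace(config.rotation, L=int(box))
        trajectories = link_ps(detections, tracking, sampling_rate=movie.sampling_rate)
        quants = _quantify_all(trajectories, phase, rotation, config.min_quantify_frames)
        stats = summarize(quants, config.rd_threshold)
        missing = sum(q.n_missing_edges for q in quants)
        rows.append(
            {
                "d_gap": dg,
                "t_gap": int(tg),
                "L": int(box),
                "n_trajectories": len(trajectories),
                "n_missing_edges": missing,
                **stats.as_dict(),
            }
        )
    return pd.DataFrame(rows)
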