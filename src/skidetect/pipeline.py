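"""End-to-end pipeline and the model-selection grid.

The pipeline runs: resample to the operating rate -> complementary-filter
orientation tracking -> body-to-world rotation -> two-stage smoothing ->
windowing and feature extraction -> min-max normalization (NFS) and optional
PCA -> two-cluster detection -> segment construction -> 30 s minimum-duration
rule.

The model-selection grid enumerates window sizes 3..10 s crossed with
sliding rates {1.0, 0.8, 0.5, 0.2} (overlaps 0/20/50/80%, 32 combinations)
and the six models (3 clustering algorithms x 2 feature sets), scoring each
setting on every session and aggregating mean and standard deviation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import detection, evaluation, features, io, orientation, preprocessing
from .detection import ClusterConfig, WindowLabeling
from .features import (
    GRID_SLIDING_RATES,
    GRID_WINDOW_SIZES,
    FeatureMatrix,
    WindowConfig,
)
from .io import ActivitySegment, IMURecording
from .orientation import WorldFrameRecording
from .preprocessing import FilterConfig

log = logging.getLogger(__name__)

FEATURE_SETS = ("NFS", "PCA")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs, fanned out from one top-level seed.

    Defaults are the shipped setting: KMeans on PCA features, 8 s windows at
    sliding rate 0.5, operating at 50 Hz.
    """

    operating_rate: float = 50.0
    orientation_gain: float = orientation.DEFAULT_GAIN
    filter: FilterConfig = field(default_factory=FilterConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    feature_set: str = "PCA"
    variance_kept: float = 0.95
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    min_duration: float = detection.MIN_ACTIVITY_DURATION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"feature_set must be one of {FEATURE_SETS}, got {self.feature_set!r}")
        if self.operating_rate <= 0:
            raise ValueError("operating_rate must be positive")
        # the single top-level seed drives the (only) stochastic stage
        object.__setattr__(self, "cluster", replace(self.cluster, seed=self.seed))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "filter" in d:
            d["filter"] = FilterConfig(**d["filter"])
        if "window" in d:
            d["window"] = WindowConfig(**d["window"])
        if "cluster" in d:
            d["cluster"] = ClusterConfig(**d["cluster"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    segments: list[ActivitySegment]
    feature_matrix: FeatureMatrix
    labeling: WindowLabeling
    world: WorldFrameRecording
    operating_recording: IMURecording


def run_pipeline(recording: IMURecording, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Segment one recording into Skiing / Not_Skiing activities."""
    cfg = cfg or PipelineConfig()
    t0 = time.perf_counter()
    if cfg.operating_rate < recording.sample_rate * (1 - 1e-9):
        recording = io.resample(recording, cfg.operating_rate)
    track = orientation.track_orientation(recording, gain=cfg.orientation_gain)
    world = orientation.to_world(recording, track)
    filtered = preprocessing.two_stage_filter(world, cfg.filter)
    windows = features.segment_windows(filtered, cfg.window)
    if not windows:
        raise ValueError(
            f"recording ({recording.duration:.3g} s) shorter than one window "
            f"({cfg.window.window_size} s)"
        )
    raw = features.extract_features(windows)
    nfs = features.normalize_minmax(raw)
    feats = features.pca_reduce(nfs, cfg.variance_kept) if cfg.feature_set == "PCA" else nfs
    labeling = detection.cluster_windows(feats, cfg.cluster)
    if labeling.degenerate:
        log.warning("degenerate clustering: all windows identical, everything Not_Skiing")
    labeling = detection.map_clusters_to_classes(labeling, raw)
    segments = detection.windows_to_segments(labeling)
    segments = detection.drop_short(segments, cfg.min_duration)
    log.info(
        "pipeline: %d samples -> %d windows -> %d segments (%d skiing) in %.2f s",
        len(recording), len(windows), len(segments),
        detection.count_activities(segments), time.perf_counter() - t0,
    )
    return PipelineResult(segments, feats, labeling, filtered, recording)


def grid_settings(
    algorithms=detection.ALGORITHMS,
    feature_sets=FEATURE_SETS,
    window_sizes=GRID_WINDOW_SIZES,
    sliding_rates=GRID_SLIDING_RATES,
) -> list[dict]:
    """Enumerate the model-selection grid (full grid: 6 models x 32 windowings)."""
    return [
        {
            "algorithm": alg,
            "feature_set": fs,
            "window_size": float(ws),
            "sliding_rate": float(sr),
        }
        for alg in algorithms
        for fs in feature_sets
        for ws in window_sizes
        for sr in sliding_rates
    ]


@dataclass
class GridResult:
    """Per-session rows plus per-setting aggregates of the grid search."""

    rows: pd.DataFrame
    summary: pd.DataFrame


def run_grid(
    sessions: list[tuple[IMURecording, list[ActivitySegment]]],
    base_cfg: PipelineConfig | None = None,
    algorithms=detection.ALGORITHMS,
    feature_sets=FEATURE_SETS,
    window_sizes=GRID_WINDOW_SIZES,
    sliding_rates=GRID_SLIDING_RATES,
) -> GridResult:
    """Score every grid setting on every session.

    The summary aggregates mean and SD of accuracy/NMI/ARI per setting and is
    ranked by mean accuracy, ties broken by ARI then NMI.
    """
    base_cfg = base_cfg or PipelineConfig()
    settings = grid_settings(algorithms, feature_sets, window_sizes, sliding_rates)
    if not settings or not sessions:
        raise ValueError("grid search needs at least one setting and one session")
    rows = []
    for setting in settings:
        cfg = replace(
            base_cfg,
            window=WindowConfig(setting["window_size"], setting["sliding_rate"]),
            feature_set=setting["feature_set"],
            cluster=replace(base_cfg.cluster, algorithm=setting["algorithm"]),
        )
        for sess_id, (recording, truth) in enumerate(sessions):
            t0 = time.perf_counter()
            result = run_pipeline(recording, cfg)
            report = evaluation.evaluate(
                result.segments, truth, result.operating_recording, setting=setting
            )
            row = report.to_row()
            row["session"] = sess_id
            row["runtime_s"] = time.perf_counter() - t0
            rows.append(row)
    df = pd.DataFrame(rows)
    keys = ["algorithm", "feature_set", "window_size", "sliding_rate"]
    summary = (
        df.groupby(keys)
        .agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_sd=("accuracy", "std"),
            nmi_mean=("nmi", "mean"),
            nmi_sd=("nmi", "std"),
            ari_mean=("ari", "mean"),
            ari_sd=("ari", "std"),
            detected_activities_mean=("detected_activities", "mean"),
        )
        .reset_index()
        .sort_values(
            ["accuracy_mean", "ari_mean", "nmi_mean"], ascending=False, kind="mergesort"
        )
        .reset_index(drop=True)
    )
    return GridResult(rows=df, summary=summary)
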