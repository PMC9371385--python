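"""Two-cluster window labeling and conversion to activity segments.

Windows are clustered into exactly two groups (KMeans, Gaussian mixture, or
Ward agglomerative).  The cluster whose windows carry the larger mean raw
accelerometer energy is identified as Skiing — turn oscillations add proper
acceleration on top of gravity, so skiing windows are the energetic ones.
Window labels are then voted down to a per-interval timeline and maximal
constant-class runs become segments.  Finally, any Skiing segment shorter
than a minimum duration (default 30 s — a real alpine-skiing run lasts at
least that long) is relabeled Not_Skiing and merged into its neighbours, so
the timeline stays fully covered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.mixture import GaussianMixture

from .features import FeatureMatrix
from .io import NOT_SKIING, SKIING, ActivitySegment

ALGORITHMS = ("kmeans", "gmm", "ward")

#: minimum duration of a real alpine-skiing activity, seconds
MIN_ACTIVITY_DURATION = 30.0


@dataclass(frozen=True)
class ClusterConfig:
    algorithm: str = "kmeans"
    seed: int = 0
    restarts: int = 10
    n_clusters: int = 2  # fixed: Skiing vs Not_Skiing

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.n_clusters != 2:
            raise ValueError("the task is binary: n_clusters must be 2")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class WindowLabeling:
    """Per-window cluster ids, spans, and (once mapped) activity classes."""

    cluster_ids: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    classes: np.ndarray | None = None
    degenerate: bool = False  # data collapsed to a single cluster

    def __len__(self) -> int:
        return len(self.cluster_ids)


def cluster_windows(features: FeatureMatrix, cfg: ClusterConfig | None = None) -> WindowLabeling:
    """Assign each window to one of two clusters.

    Deterministic for a fixed seed (Ward is deterministic by construction).
    Literally identical rows cannot be split; they come back as a single
    cluster with the ``degenerate`` flag set.
    """
    cfg = cfg or ClusterConfig()
    X = features.values.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError(f"need at least 2 windows to cluster, got {X.shape[0]}")
    if np.allclose(X, X[0], atol=0.0):
        return WindowLabeling(
            cluster_ids=np.zeros(X.shape[0], dtype=int),
            starts=features.starts.copy(),
            ends=features.ends.copy(),
            degenerate=True,
        )
    if cfg.algorithm == "kmeans":
        model = KMeans(n_clusters=2, init="k-means++", n_init=cfg.restarts, random_state=cfg.seed)
        ids = model.fit_predict(X)
    elif cfg.algorithm == "gmm":
        model = GaussianMixture(
            n_components=2,
            covariance_type="full",
            init_params="kmeans",
            n_init=cfg.restarts,
            random_state=cfg.seed,
            reg_covar=1e-5,
        )
        ids = model.fit_predict(X)
    else:  # ward
        model = AgglomerativeClustering(n_clusters=2, linkage="ward")
        ids = model.fit_predict(X)
    degenerate = len(np.unique(ids)) < 2
    return WindowLabeling(
        cluster_ids=np.asarray(ids, dtype=int),
        starts=features.starts.copy(),
        ends=features.ends.copy(),
        degenerate=degenerate,
    )


def map_clusters_to_classes(labeling: WindowLabeling, raw_features: FeatureMatrix) -> WindowLabeling:
    """Identify the Skiing cluster by accelerometer energy.

    Skiing = the cluster with the larger mean raw-window energy summed over
    the three accelerometer channels.  On an exact tie the smaller cluster is
    Skiing (skiing is the minority class over a full day).  A degenerate
    single cluster maps to all Not_Skiing.
    """
    if labeling.degenerate:
        classes = np.full(len(labeling), NOT_SKIING, dtype=object)
        return WindowLabeling(
            labeling.cluster_ids.copy(), labeling.starts.copy(), labeling.ends.copy(),
            classes=classes, degenerate=True,
        )
    energy_cols = [f"acc_{ax}__raw__energy" for ax in "xyz"]
    energy = raw_features.values[energy_cols].to_numpy(float).sum(axis=1)
    ids = labeling.cluster_ids
    means = {c: float(energy[ids == c].mean()) for c in (0, 1)}
    sizes = {c: int(np.sum(ids == c)) for c in (0, 1)}
    if means[0] != means[1]:
        skiing_cluster = max(means, key=means.get)
    elif sizes[0] != sizes[1]:
        skiing_cluster = min(sizes, key=sizes.get)
    else:
        skiing_cluster = 1
    classes = np.where(ids == skiing_cluster, SKIING, NOT_SKIING).astype(object)
    return WindowLabeling(
        ids.copy(), labeling.starts.copy(), labeling.ends.copy(),
        classes=classes, degenerate=False,
    )


def windows_to_segments(labeling: WindowLabeling) -> list[ActivitySegment]:
    """Majority-vote overlapping windows into a partition of the covered span.

    Every instant is assigned the class voted by the windows covering it
    (ties go to Not_Skiing); maximal constant-class intervals become
    segments.  The result partitions [first window start, last window end).
    """
    if labeling.classes is None:
        raise ValueError("labeling has no classes; run map_clusters_to_classes first")
    if len(labeling) == 0:
        return []
    edges = np.unique(np.concatenate([labeling.starts, labeling.ends]))
    ski_votes = np.zeros(len(edges) - 1)
    tot_votes = np.zeros(len(edges) - 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    for start, end, cls in zip(labeling.starts, labeling.ends, labeling.classes):
        covered = (mids > start) & (mids < end)
        tot_votes[covered] += 1
        if cls == SKIING:
            ski_votes[covered] += 1
    piece_class = np.where(
        (tot_votes > 0) & (ski_votes * 2 > tot_votes), SKIING, NOT_SKIING
    )
    segments: list[ActivitySegment] = []
    run_start = edges[0]
    for i in range(1, len(piece_class) + 1):
        if i == len(piece_class) or piece_class[i] != piece_class[i - 1]:
            segments.append(ActivitySegment(float(run_start), float(edges[i]), str(piece_class[i - 1])))
            if i < len(piece_class):
                run_start = edges[i]
    return segments


def drop_short(segments: list[ActivitySegment], min_duration: float = MIN_ACTIVITY_DURATION) -> list[ActivitySegment]:
    """Relabel Skiing segments shorter than ``min_duration`` as Not_Skiing.

    Relabeling (rather than deleting) keeps the timeline fully covered;
    adjacent Not_Skiing segments are merged afterwards.  A segment of
    exactly ``min_duration`` is kept (closed lower bound).
    """
    relabeled = [
        ActivitySegment(s.start, s.end, NOT_SKIING)
        if s.label == SKIING and s.duration < min_duration
        else s
        for s in segments
    ]
    merged: list[ActivitySegment] = []
    for seg in relabeled:
        if merged and merged[-1].label == seg.label and abs(merged[-1].end - seg.start) < 1e-9:
            merged[-1] = ActivitySegment(merged[-1].start, seg.end, seg.label)
        else:
            merged.append(seg)
    return merged


def count_activities(segments: list[ActivitySegment]) -> int:
    """Number of detected Skiing segments."""
    return sum(1 for s in segments if s.label == SKIING)
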