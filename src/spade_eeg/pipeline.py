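"""End-to-end orchestration: record → windows → SCMs → distances → features →
deep embedded clustering → microstate sequence.

``run_spade`` executes the five-step pipeline on one channels × samples
record and returns the fitted cluster model together with the per-sample
microstate sequence and every intermediate (segments, covariances, both
distance matrices, fused features), so downstream evaluation and
validation reuse them instead of recomputing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .dec import ClusterModel, EncoderSpec, dec_fit
from .features import FeatureMatrix, build_features
from .geometry import DistanceMatrix, pairwise_both, pairwise_matrix
from .segment import CovarianceSet, EEGRecord, SegmentSet, covariance_set, segment

__all__ = [
    "RunConfig",
    "MicrostateSequence",
    "SpadeResult",
    "run_spade",
    "labels_to_sequence",
    "representative_segment",
    "segment_truth",
]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters: window geometry, cluster count, encoder, seeds.

    ``window_ms`` is converted with the record's sampling rate unless
    ``window_samples`` is given explicitly. ``shrinkage=None`` picks the
    rank-aware default. ``analysis_interval_ms`` restricts the record to
    [start, end) before windowing; the default uses the whole record.
    """

    window_ms: float = 200.0
    window_samples: int | None = None
    step_samples: int = 1
    n_clusters: int = 5
    shrinkage: float | None = None
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    seed: int = 0
    analysis_interval_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.step_samples < 1:
            raise ValueError("step must be >= 1")

    def resolve_window(self, record: EEGRecord) -> int:
        if self.window_samples is not None:
            return self.window_samples
        return record.ms_to_samples(self.window_ms)


@dataclass
class MicrostateSequence:
    """Per-sample state labels with their run-length representation."""

    labels: np.ndarray                       # (T,) 1-based state per sample
    runs: list[tuple[int, float, float]]     # (state, start_ms, end_ms), half-open
    srate_hz: float
    representative_index: dict[int, int] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.labels)


@dataclass
class SpadeResult:
    """Everything produced by one pipeline run."""

    model: ClusterModel
    sequence: MicrostateSequence
    segments: SegmentSet
    covariances: CovarianceSet
    D_sensor: DistanceMatrix
    D_source: DistanceMatrix
    features: FeatureMatrix
    config: RunConfig

    @property
    def segment_labels(self) -> np.ndarray:
        return self.model.labels


def labels_to_sequence(segment_labels, starts, t: int, T: int,
                       srate_hz: float = 1000.0) -> MicrostateSequence:
    """Expand per-window labels to a per-sample microstate sequence.

    Each sample takes the label of the window whose center (start + t//2)
    is nearest in time, ties resolved toward the earlier window; samples
    before the first / after the last center inherit the flanking window's
    label. Runs are the maximal constant stretches of the result.
    """
    segment_labels = np.asarray(segment_labels)
    starts = np.asarray(starts)
    if len(segment_labels) != len(starts):
        raise ValueError("labels must align with window starts")
    centers = starts + t // 2
    mids = (centers[:-1] + centers[1:]) / 2.0
    idx = np.searchsorted(mids, np.arange(T), side="left")
    labels = segment_labels[idx]
    change = np.flatnonzero(np.diff(labels)) + 1
    edges = np.concatenate([[0], change, [T]])
    ms = 1000.0 / srate_hz
    runs = [(int(labels[lo]), lo * ms, hi * ms)
            for lo, hi in zip(edges[:-1], edges[1:])]
    return MicrostateSequence(labels=labels, runs=runs, srate_hz=srate_hz)


def representative_segment(covset: CovarianceSet, labels, cluster_id: int,
                           D: DistanceMatrix | np.ndarray | None = None) -> int:
    """Index of the cluster member closest to the cluster's Fréchet mean.

    Minimizes Σ_members δ_R²(C_index, C_member); ties break toward the
    smallest index. A precomputed distance matrix avoids requadrature.
    """
    labels = np.asarray(labels)
    members = np.where(labels == cluster_id)[0]
    if len(members) == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    if D is None:
        D = pairwise_matrix(covset.matrices[members], "source").values
        sub = D
    else:
        Dv = getattr(D, "values", D)
        sub = Dv[np.ix_(members, members)]
    cost = np.sum(sub ** 2, axis=1)
    return int(members[np.argmin(cost)])


def segment_truth(truth: np.ndarray, segs: SegmentSet) -> np.ndarray:
    """Ground-truth state of each window: the label at its center sample."""
    return np.asarray(truth)[segs.centers]


def run_spade(record: EEGRecord, config: RunConfig) -> SpadeResult:
    """Execute the full pipeline on one record.

    Steps: slide a window over the (optionally cropped) record, estimate
    SCMs, compute sensor- and source-space pairwise distances, fuse the
    three standardized feature blocks, run deep embedded clustering, and
    expand the window labels to a per-sample microstate sequence with a
    representative window per cluster.
    """
    if config.analysis_interval_ms is not None:
        lo, hi = config.analysis_interval_ms
        a, b = record.ms_to_samples(lo), record.ms_to_samples(hi)
        record = EEGRecord(record.data[:, a:b], record.srate_hz,
                           list(record.channel_names))
    t = config.resolve_window(record)
    segs = segment(record, t, config.step_samples)
    covs = covariance_set(segs, config.shrinkage)
    D_sen, D_src = pairwise_both(covs)
    feats = build_features(covs, D_sen, D_src)
    spec = config.encoder if config.encoder.seed == config.seed else \
        dataclasses.replace(config.encoder, seed=config.seed)
    model = dec_fit(feats, spec, config.n_clusters)
    seq = labels_to_sequence(model.labels, segs.starts, t,
                             record.n_samples, record.srate_hz)
    for cid in np.unique(model.labels):
        seq.representative_index[int(cid)] = representative_segment(
            covs, model.labels, int(cid), D=D_src)
    return SpadeResult(model=model, sequence=seq, segments=segs, covariances=covs,
                       D_sensor=D_sen, D_source=D_src, features=feats, config=config)
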