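"""Sliding-window segmentation and spatial covariance estimation.

An EEG record (channels × samples) is cut into overlapping windows; each
window is zero-meaned per channel and summarized by its spatial covariance
matrix (SCM), optionally shrunk toward a scaled identity so that short
windows on many channels still yield symmetric positive definite matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EEGRecord",
    "SegmentSet",
    "CovarianceSet",
    "segment",
    "compute_scm",
    "covariance_set",
    "default_shrinkage",
]


@dataclass
class EEGRecord:
    """A multichannel recording: ``data`` is channels × samples."""

    data: np.ndarray
    srate_hz: float
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels × samples matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.srate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_names is None:
            self.channel_names = [f"ch{i + 1}" for i in range(self.data.shape[0])]
        elif len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def ms_to_samples(self, ms: float) -> int:
        return int(round(ms * self.srate_hz / 1000.0))


@dataclass
class SegmentSet:
    """Zero-meaned sliding windows of a record."""

    window_len: int                      # t, samples
    step: int                            # s, samples
    starts: np.ndarray                   # (m,) 0-based start indices
    segments: np.ndarray                 # (m, n, t) zero-meaned windows
    srate_hz: float
    n_samples_total: int                 # T of the source record

    @property
    def m(self) -> int:
        return len(self.starts)

    @property
    def n_channels(self) -> int:
        return self.segments.shape[1]

    @property
    def centers(self) -> np.ndarray:
        """Window-center sample indices (start + t//2)."""
        return self.starts + self.window_len // 2


def segment(record: EEGRecord, t: int, s: int = 1) -> SegmentSet:
    """Cut ``record`` into m = floor((T − t)/s) + 1 zero-meaned windows.

    Windows are half-open ``[start, start + t)`` with 0-based starts
    ``0, s, 2s, …``; a final partial window is discarded.
    """
    T = record.n_samples
    if not 1 <= t <= T:
        raise ValueError(f"window length t={t} must be in [1, T={T}]")
    if s < 1:
        raise ValueError("step must be >= 1")
    m = (T - t) // s + 1
    starts = np.arange(m) * s
    idx = starts[:, None] + np.arange(t)[None, :]
    segs = record.data[:, idx].transpose(1, 0, 2).copy()  # (m, n, t)
    segs -= segs.mean(axis=2, keepdims=True)
    return SegmentSet(window_len=t, step=s, starts=starts, segments=segs,
                      srate_hz=record.srate_hz, n_samples_total=T)


def default_shrinkage(t: int, n: int) -> float:
    """γ = 0.05 when the raw SCM is rank deficient (t − 1 < n), else 0."""
    return 0.05 if t - 1 < n else 0.0


def compute_scm(seg: np.ndarray, gamma: float = 0.0) -> np.ndarray:
    """SCM of a zero-meaned window: C = X Xᵀ/(t−1), shrunk toward scaled identity.

    Shrinkage replaces C with (1−γ)C + γ(trace(C)/n)I, which preserves the
    trace and guarantees positive definiteness for γ > 0 on any non-zero
    window.
    """
    X = np.asarray(seg, dtype=float)
    n, t = X.shape
    if t < 2:
        raise ValueError("need at least 2 samples per window")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    C = X @ X.T / (t - 1)
    if gamma > 0.0:
        C = (1.0 - gamma) * C + gamma * (np.trace(C) / n) * np.eye(n)
    if gamma == 0.0 and np.trace(C) == 0.0:
        raise np.linalg.LinAlgError("all-zero window yields a singular SCM with gamma=0")
    return C


@dataclass
class CovarianceSet:
    """Per-window SPD spatial covariance matrices."""

    matrices: np.ndarray                  # (m, n, n)
    shrinkage_gamma: float
    segment_set: SegmentSet | None = field(default=None, repr=False)

    @property
    def m(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]


MAX_RAW_CONDITION = 1e8


def covariance_set(segs: SegmentSet, gamma: float | None = None) -> CovarianceSet:
    """SCMs of every window in one batched pass.

    ``gamma=None`` picks an automatic shrinkage: 0.05 when the windows are
    too short for full rank (t − 1 < n) **or** when any raw SCM's condition
    number exceeds ``MAX_RAW_CONDITION`` — near-singular SCMs make the
    affine-invariant geometry floor-dominated float noise — and 0 otherwise.
    """
    X = segs.segments
    m, n, t = X.shape
    C = np.einsum("mnt,mkt->mnk", X, X) / (t - 1)
    if gamma is None:
        gamma = default_shrinkage(t, n)
        if gamma == 0.0:
            w = np.linalg.eigvalsh(0.5 * (C + C.transpose(0, 2, 1)))
            if w[:, 0].min() <= 0.0 or \
                    (w[:, -1] / w[:, 0]).max() > MAX_RAW_CONDITION:
                gamma = 0.05
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must be in [0, 1)")
    if gamma > 0.0:
        traces = np.trace(C, axis1=1, axis2=2)
        C = (1.0 - gamma) * C
        C[:, np.arange(n), np.arange(n)] += gamma * traces[:, None] / n
    C = 0.5 * (C + C.transpose(0, 2, 1))
    return CovarianceSet(matrices=C, shrinkage_gamma=gamma, segment_set=segs)
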