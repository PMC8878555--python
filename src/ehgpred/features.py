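"""Per-window features on IMFs and their aggregation to per-record vectors.

Three features are computed on each of the first two IMFs of every 1-minute
window — RMS, sample entropy (m=3, r=0.15·SD by default), and the mean
Teager–Kaiser energy — then averaged over a record's windows, giving six
numbers per record per channel. Feature columns are z-scored before
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import emd
from .data_io import ChannelMap, DEFAULT_CHANNEL_MAP, preprocess_channel
from .records import EHGRecord

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "FeatureVector",
    "FeatureMatrix",
    "UndefinedEntropyError",
    "DegenerateFeatureError",
    "rms",
    "sample_entropy",
    "sample_entropy_counts",
    "mtke",
    "extract_record_features",
    "build_feature_matrix",
    "normalize_features",
]

logger = logging.getLogger(__name__)

#: Frozen column order of every feature vector / matrix.
FEATURE_NAMES = (
    "RMS_IMF1", "RMS_IMF2",
    "SampEn_IMF1", "SampEn_IMF2",
    "MTKE_IMF1", "MTKE_IMF2",
)


class UndefinedEntropyError(ValueError):
    """No template matches at length m or m+1; SampEn is undefined."""

    def __init__(self, a: int, b: int):
        super().__init__(f"sample entropy undefined: A={a}, B={b}")
        self.a = a
        self.b = b


class DegenerateFeatureError(ValueError):
    """A feature column has zero variance and cannot be z-scored."""


def rms(x: np.ndarray) -> float:
    """Root mean square: sqrt of the arithmetic mean of squared samples."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(x * x)))


def sample_entropy_counts(x: np.ndarray, m: int = 3, r: float | None = None) -> tuple[int, int]:
    """Template-match counts (A, B) for sample entropy.

    B counts unordered pairs of distinct length-``m`` templates within
    Chebyshev distance ``r``; A does the same for length ``m+1``. Both use
    the n−m template start positions for which the longer template exists,
    so self-matches are excluded and A ≤ B by construction.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {n}")
    if r is None or r < 0:
        raise ValueError(f"tolerance must be non-negative, got {r}")
    n_templates = n - m
    a = 0
    b = 0
    # One pass per template-pair lag; inner comparisons are vectorized.
    for lag in range(1, n_templates):
        n_pairs = n_templates - lag
        diff = np.abs(x[: n - lag] - x[lag:])
        cheb = diff[:n_pairs]
        for k in range(1, m):
            cheb = np.maximum(cheb, diff[k:k + n_pairs])
        b += int(np.count_nonzero(cheb <= r))
        cheb_ext = np.maximum(cheb, diff[m:m + n_pairs])
        a += int(np.count_nonzero(cheb_ext <= r))
    return a, b


def sample_entropy(
    x: np.ndarray,
    m: int = 3,
    r: float = 0.15,
    r_mode: str = "sd",
) -> float:
    """Sample entropy: −ln(A/B) with Chebyshev distance, self-matches excluded.

    ``r_mode="sd"`` scales the tolerance by the window's standard deviation
    (so the measure is amplitude-invariant); ``r_mode="absolute"`` uses ``r``
    in signal units directly.
    """
    x = np.asarray(x, dtype=float)
    if r_mode == "sd":
        tol = r * float(np.std(x))
    elif r_mode == "absolute":
        tol = r
    else:
        raise ValueError(f"unknown r_mode {r_mode!r}")
    a, b = sample_entropy_counts(x, m=m, r=tol)
    if a == 0 or b == 0:
        raise UndefinedEntropyError(a, b)
    return float(-np.log(a / b))


def mtke(x: np.ndarray) -> float:
    """Mean Teager–Kaiser energy: mean over interior samples of
    x(n)² − x(n−1)·x(n+1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 samples, got {x.size}")
    return float(np.mean(x[1:-1] ** 2 - x[:-2] * x[2:]))


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the window → feature-vector stage."""

    n_imfs: int = 2
    sd_threshold: float = emd.DEFAULT_SD_THRESHOLD
    max_iterations: int = emd.DEFAULT_MAX_ITERATIONS
    sift_criterion: str = "sd"
    sampen_m: int = 3
    sampen_r: float = 0.15
    sampen_r_mode: str = "sd"
    window_seconds: float = 60.0
    bandpass_low: float = 0.08
    bandpass_high: float = 4.0
    bandpass_order: int = 4
    trim_seconds: float = 180.0
    zero_phase: bool = False


DEFAULT_FEATURE_CONFIG = FeatureConfig()


@dataclass(frozen=True)
class FeatureVector:
    record_id: str
    channel: str
    values: np.ndarray  # length 6, FEATURE_NAMES order
    n_windows_averaged: int
    n_windows_skipped: int = 0


def _window_features(samples: np.ndarray, config: FeatureConfig) -> np.ndarray | None:
    """Six features of one window, or None when the window is unusable
    (fewer than two IMFs, or undefined entropy on either IMF)."""
    dec = emd.decompose(
        samples,
        n_imfs=config.n_imfs,
        sd_threshold=config.sd_threshold,
        max_iterations=config.max_iterations,
        criterion=config.sift_criterion,
    )
    if dec.n_imfs < 2:
        return None
    imf1, imf2 = dec.imfs[0], dec.imfs[1]
    try:
        se1 = sample_entropy(imf1, m=config.sampen_m, r=config.sampen_r,
                             r_mode=config.sampen_r_mode)
        se2 = sample_entropy(imf2, m=config.sampen_m, r=config.sampen_r,
                             r_mode=config.sampen_r_mode)
    except UndefinedEntropyError:
        return None
    return np.array([rms(imf1), rms(imf2), se1, se2, mtke(imf1), mtke(imf2)])


def extract_record_features(
    record: EHGRecord,
    channel: str,
    config: FeatureConfig = DEFAULT_FEATURE_CONFIG,
    channel_map: ChannelMap = DEFAULT_CHANNEL_MAP,
) -> FeatureVector:
    """Preprocess one channel, decompose each window, average the per-window
    features into a single 6-vector.

    Windows with fewer than two IMFs or undefined entropy are skipped and
    counted; a record with no usable window raises."""
    windows = preprocess_channel(
        record, channel, channel_map=channel_map,
        low=config.bandpass_low, high=config.bandpass_high,
        order=config.bandpass_order, trim_seconds=config.trim_seconds,
        window_seconds=config.window_seconds, zero_phase=config.zero_phase,
    )
    used, skipped = [], 0
    for window in windows:
        values = _window_features(window.samples, config)
        if values is None:
            skipped += 1
        else:
            used.append(values)
    if not used:
        raise ValueError(
            f"record {record.record_id} channel {channel}: all {len(windows)} "
            f"windows unusable (too few IMFs or undefined entropy)"
        )
    if skipped:
        logger.info("record %s channel %s: skipped %d/%d windows",
                    record.record_id, channel, skipped, len(windows))
    return FeatureVector(
        record_id=record.record_id,
        channel=channel,
        values=np.mean(used, axis=0),
        n_windows_averaged=len(used),
        n_windows_skipped=skipped,
    )


@dataclass
class FeatureMatrix:
    """Records × features table for one channel, with labels."""

    channel: str
    record_ids: list[str]
    X: np.ndarray  # shape (n_records, 6)
    labels: np.ndarray  # array of "term"/"preterm" strings
    n_windows: np.ndarray = field(default=None)
    normalized: bool = False
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.shape[0] != len(self.labels):
            raise ValueError("row/label count mismatch")
        if self.n_windows is None:
            self.n_windows = np.zeros(len(self.labels), dtype=int)

    @property
    def n_records(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        frame.insert(0, "record_id", self.record_ids)
        frame.insert(1, "channel", self.channel)
        frame.insert(2, "label", self.labels)
        frame["n_windows_averaged"] = self.n_windows
        return frame

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, channel: str | None = None) -> "FeatureMatrix":
        if channel is not None:
            frame = frame[frame["channel"] == channel]
        if frame.empty:
            raise ValueError(f"no rows for channel {channel!r}")
        channels = frame["channel"].unique()
        if len(channels) != 1:
            raise ValueError(f"matrix mixes channels {list(channels)}; pass channel=")
        return cls(
            channel=str(channels[0]),
            record_ids=[str(r) for r in frame["record_id"]],
            X=frame[list(FEATURE_NAMES)].to_numpy(dtype=float),
            labels=frame["label"].to_numpy(),
            n_windows=frame["n_windows_averaged"].to_numpy(dtype=int)
            if "n_windows_averaged" in frame else None,
        )

    @classmethod
    def read_csv(cls, path: str | Path, channel: str | None = None) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path, dtype={"record_id": str}), channel=channel)


def build_feature_matrix(
    records: list[EHGRecord],
    channel: str,
    config: FeatureConfig = DEFAULT_FEATURE_CONFIG,
    channel_map: ChannelMap = DEFAULT_CHANNEL_MAP,
) -> FeatureMatrix:
    vectors = [extract_record_features(r, channel, config=config, channel_map=channel_map)
               for r in records]
    return FeatureMatrix(
        channel=channel,
        record_ids=[v.record_id for v in vectors],
        X=np.vstack([v.values for v in vectors]),
        labels=np.array([r.label for r in records]),
        n_windows=np.array([v.n_windows_averaged for v in vectors]),
    )


def normalize_features(
    matrix: FeatureMatrix,
    mode: str = "global",
    train_indices: np.ndarray | None = None,
) -> FeatureMatrix:
    """Z-score feature columns.

    ``global`` computes column statistics from every row (matching the
    published protocol but leaking test statistics); ``train_only`` computes
    them from ``train_indices`` rows and applies them to all rows. Sample
    standard deviation (ddof=1) is used.
    """
    if matrix.n_records < 2:
        raise ValueError("need at least 2 rows to normalize")
    if mode == "global":
        ref = matrix.X
    elif mode == "train_only":
        if train_indices is None:
            raise ValueError("train_only mode requires train_indices")
        ref = matrix.X[np.asarray(train_indices)]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    means = ref.mean(axis=0)
    sds = ref.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sds == 0)
    if degenerate.size:
        names = [FEATURE_NAMES[i] for i in degenerate]
        raise DegenerateFeatureError(f"zero-variance feature column(s): {names}")
    return FeatureMatrix(
        channel=matrix.channel,
        record_ids=list(matrix.record_ids),
        X=(matrix.X - means) / sds,
        labels=matrix.labels.copy(),
        n_windows=matrix.n_windows.copy(),
        normalized=True,
        column_means=means,
        column_sds=sds,
    )
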