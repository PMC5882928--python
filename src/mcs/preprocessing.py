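"""Convert multichannel recordings into labeled state vectors.

Each condition block of a recording (channels x time) is turned into a
sequence of n-dimensional state vectors: a window of fixed width slides
through the block in fixed steps, the root-mean-square amplitude of every
channel within the window gives one coordinate per channel, and each vector
is z-scored across channels to remove activity common to all channels.
Transient onset responses in the first fraction of a second after stimulus
onset are excluded before windowing.  Concatenating the per-block series in
time order yields a labeled point set for the cluster statistics.

Defaults follow sustained-activity electrophysiology practice: 20 s
windows shifted in 5 s steps, 200 ms onset exclusion.  A 180 s block then
yields floor((180 - 20)/5) + 1 = 33 windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .core import LabeledPointSet
from .errors import (
    DegenerateWindowError,
    EmptySegmentError,
    InvalidInputError,
)

__all__ = [
    "RecordingSegment",
    "StateVectorSeries",
    "exclude_onset",
    "sliding_rms",
    "zscore_states",
    "build_pointset",
    "preprocess_segments",
]


@dataclass(frozen=True)
class RecordingSegment:
    """One condition block of a multichannel recording.

    samples : (C, T) array, channels x time, recording units.
    sampling_rate : Hz.
    condition : the block's condition label.
    onset_time : seconds of this block's start relative to the recording.
    """

    samples: np.ndarray
    sampling_rate: float
    condition: str
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise InvalidInputError("sampling_rate must be positive")
        if not np.isfinite(s).all():
            raise InvalidInputError(
                f"non-finite sample(s) in segment {self.condition!r}")
        object.__setattr__(self, "samples", s)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class StateVectorSeries:
    """Time-ordered state vectors of one condition block.

    vectors : (W, C) array, one row per window.
    window_centers : window-center times in seconds (recording clock).
    """

    vectors: np.ndarray
    window_centers: np.ndarray
    condition: str
    window_length: float
    step: float

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2:
            raise InvalidInputError("vectors must be a (W, C) matrix")
        c = np.asarray(self.window_centers, dtype=float)
        if v.shape[0] != c.shape[0]:
            raise InvalidInputError("vectors and window_centers length mismatch")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "window_centers", c)

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_channels(self) -> int:
        return self.vectors.shape[1]


def exclude_onset(segment: RecordingSegment, exclusion: float = 0.2
                  ) -> RecordingSegment:
    """Drop the first ``exclusion`` seconds (onset response) of a block."""
    if exclusion < 0:
        raise InvalidInputError("exclusion must be >= 0")
    if exclusion == 0:
        return segment
    n_drop = int(round(exclusion * segment.sampling_rate))
    if n_drop >= segment.n_samples:
        raise EmptySegmentError(
            f"excluding {exclusion} s removes the whole "
            f"{segment.duration:.3f} s segment {segment.condition!r}")
    return replace(segment, samples=segment.samples[:, n_drop:],
                   onset_time=segment.onset_time + n_drop / segment.sampling_rate)


def sliding_rms(segment: RecordingSegment, window_length: float = 20.0,
                step: float = 5.0) -> StateVectorSeries:
    """Per-channel RMS amplitude in sliding windows.

    Windows are closed-open sample intervals [t, t + window); only windows
    lying entirely inside the segment are emitted, so windows never span
    condition boundaries.  A segment shorter than one window yields an
    empty series with a warning.
    """
    if step <= 0:
        raise InvalidInputError("step must be positive")
    rate = segment.sampling_rate
    win = int(round(window_length * rate))
    hop = int(round(step * rate))
    if win < 1 or hop < 1:
        raise InvalidInputError("window_length and step must span >= 1 sample")
    T = segment.n_samples
    if win > T:
        warnings.warn(
            f"segment {segment.condition!r} ({segment.duration:.1f} s) is "
            f"shorter than one {window_length} s window; empty series",
            stacklevel=2)
        return StateVectorSeries(
            np.empty((0, segment.n_channels)), np.empty(0),
            segment.condition, window_length, step)
    starts = np.arange(0, T - win + 1, hop)
    # cumulative sum of squares -> O(T) window power regardless of overlap
    csum = np.concatenate(
        [np.zeros((segment.n_channels, 1)),
         np.cumsum(segment.samples ** 2, axis=1)], axis=1)
    power = (csum[:, starts + win] - csum[:, starts]) / win
    vectors = np.sqrt(power).T
    centers = segment.onset_time + (starts + win / 2.0) / rate
    return StateVectorSeries(vectors, centers, segment.condition,
                             window_length, step)


def zscore_states(series: StateVectorSeries, mode: str = "window"
                  ) -> StateVectorSeries:
    """Standardize state vectors.

    mode='window' (default): each vector is standardized across its
    channels (subtract the vector's mean, divide by its standard
    deviation), which removes activity common to the channels.
    mode='channel': each channel is standardized over time within the
    series (the alternative reading; kept behind this flag).
    """
    v = series.vectors
    if v.shape[1] < 2:
        raise InvalidInputError("z-scoring needs at least 2 channels")
    if mode == "window":
        mean = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, keepdims=True)
        dead = np.flatnonzero(sd[:, 0] == 0)
        if dead.size:
            raise DegenerateWindowError(
                f"zero across-channel variance in window(s) {dead.tolist()}")
    elif mode == "channel":
        mean = v.mean(axis=0, keepdims=True)
        sd = v.std(axis=0, keepdims=True)
        dead = np.flatnonzero(sd[0] == 0)
        if dead.size:
            raise DegenerateWindowError(
                f"zero temporal variance in channel(s) {dead.tolist()}")
    else:
        raise InvalidInputError("mode must be 'window' or 'channel'")
    return replace(series, vectors=(v - mean) / sd)


def build_pointset(series_list) -> LabeledPointSet:
    """Concatenate state-vector series into a labeled point set.

    Vectors keep time order; each point carries its block's condition label
    and the index of the series it came from.
    """
    series_list = list(series_list)
    if not series_list:
        raise InvalidInputError("no series given")
    n_ch = {s.n_channels for s in series_list}
    if len(n_ch) != 1:
        raise InvalidInputError(f"channel-count mismatch across series: {sorted(n_ch)}")
    counts: dict[str, int] = {}
    for s in series_list:
        counts[s.condition] = counts.get(s.condition, 0) + s.n_windows
    thin = [lab for lab, c in counts.items() if c < 2]
    if thin:
        raise InvalidInputError(
            f"condition(s) {thin} contribute fewer than 2 windows")
    coords = np.concatenate([s.vectors for s in series_list], axis=0)
    labels = np.concatenate(
        [np.full(s.n_windows, s.condition, dtype=object) for s in series_list])
    time = np.concatenate([s.window_centers for s in series_list])
    segment = np.concatenate(
        [np.full(s.n_windows, i, dtype=int) for i, s in enumerate(series_list)])
    order = tuple(dict.fromkeys(s.condition for s in series_list))
    return LabeledPointSet(coords, labels, order, time=time, segment=segment)


def preprocess_segments(segments, window_length: float = 20.0,
                        step: float = 5.0, onset_exclusion: float = 0.2,
                        zscore: bool = True, zscore_mode: str = "window"
                        ) -> LabeledPointSet:
    """Full preprocessing pipeline: onset exclusion -> sliding RMS ->
    (optional) z-score -> labeled point set."""
    series = []
    for seg in segments:
        s = sliding_rms(exclude_onset(seg, onset_exclusion),
                        window_length, step)
        if zscore and s.n_windows:
            s = zscore_states(s, mode=zscore_mode)
        series.append(s)
    return build_pointset([s for s in series if s.n_windows])
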