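"""Synthetic data with the statistical structure the method assumes.

Three generators cover the package's input kinds:

* ``make_gaussian_clusters`` — labeled Gaussian point clouds with centroids
  on a regular simplex, so a single ``separation`` knob (in units of the
  within-cluster standard deviation) controls every pairwise centroid
  distance.  ``separation = 0`` gives exchangeable null data.
* ``make_attractor_trajectory`` — a mean-reverting (discrete
  Ornstein-Uhlenbeck-type) walk pulled toward the active condition's
  centroid, emulating state-space trajectories that converge to and persist
  within attractor basins and return to them when a condition repeats.
* ``make_recording`` — multichannel surrogate recordings in which each
  condition contributes a *spatial pattern* (a unit vector over channels)
  riding on a band-limited noise carrier, plus a common-mode signal shared
  by all channels and white channel noise.  With ``power_matched`` on
  (default), per-condition noise power is adjusted so the expected total
  power is identical across conditions: overall amplitude then carries no
  condition information while the spatial pattern does — the regime the
  cluster statistics are designed for.  The carrier is band-limited noise
  rather than a pure tone so windowed RMS estimates a stationary amplitude
  instead of locking to carrier phase.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .core import LabeledPointSet
from .errors import InvalidConfigError
from .preprocessing import RecordingSegment

__all__ = [
    "ClusterSpec",
    "ConditionSpec",
    "RecordingSpec",
    "make_gaussian_clusters",
    "make_attractor_trajectory",
    "make_recording",
    "simplex_centroids",
]


def _default_labels(k: int) -> tuple[str, ...]:
    letters = string.ascii_uppercase
    return tuple(letters[i] if i < 26 else f"C{i}" for i in range(k))


@dataclass(frozen=True)
class ClusterSpec:
    """Gaussian cluster layout: k centroids on a regular simplex.

    ``separation`` is the mutual centroid distance in units of the
    within-cluster standard deviation ``sigma``; ``covariance`` (full
    matrix) overrides the spherical ``sigma`` if given.
    """

    n_clusters: int = 2
    points_per_cluster: int = 100
    dimension: int = 16
    separation: float = 5.0
    sigma: float = 1.0
    covariance: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise InvalidConfigError("n_clusters must be >= 1")
        if self.points_per_cluster < 2:
            raise InvalidConfigError("points_per_cluster must be >= 2")
        if self.separation < 0:
            raise InvalidConfigError("separation must be >= 0")
        if self.sigma <= 0:
            raise InvalidConfigError("sigma must be positive")
        if self.dimension < self.n_clusters - 1:
            raise InvalidConfigError(
                f"simplex layout of {self.n_clusters} centroids needs "
                f"dimension >= {self.n_clusters - 1}")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            if cov.shape != (self.dimension, self.dimension):
                raise InvalidConfigError("covariance shape must match dimension")
            object.__setattr__(self, "covariance", cov)

    @property
    def labels(self) -> tuple[str, ...]:
        return _default_labels(self.n_clusters)


def simplex_centroids(k: int, dimension: int, distance: float) -> np.ndarray:
    """k centroids in ``dimension`` dims, all pairwise ``distance`` apart."""
    if k == 1:
        return np.zeros((1, dimension))
    verts = np.eye(k) - 1.0 / k  # centered identity spans a (k-1)-subspace
    # orthonormal basis of that subspace
    u, s, _ = np.linalg.svd(verts, full_matrices=False)
    coords = (u * s)[:, : k - 1]  # pairwise distance sqrt(2)
    coords = coords * (distance / np.sqrt(2.0))
    out = np.zeros((k, dimension))
    out[:, : k - 1] = coords
    return out


def make_gaussian_clusters(spec: ClusterSpec) -> LabeledPointSet:
    """Labeled Gaussian clusters; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    centroids = simplex_centroids(spec.n_clusters, spec.dimension,
                                  spec.separation * spec.sigma)
    n, d = spec.points_per_cluster, spec.dimension
    noise = rng.standard_normal((spec.n_clusters * n, d))
    if spec.covariance is not None:
        noise = noise @ np.linalg.cholesky(spec.covariance).T
    else:
        noise = noise * spec.sigma
    coords = np.repeat(centroids, n, axis=0) + noise
    labels = np.repeat(np.array(spec.labels, dtype=object), n)
    return LabeledPointSet(coords, labels, spec.labels)


def make_attractor_trajectory(spec: ClusterSpec, dwell_steps: int = 50,
                              relaxation_rate: float = 0.2,
                              noise_sd: float = 0.1,
                              schedule=None) -> LabeledPointSet:
    """Mean-reverting trajectory through the cluster centroids.

    ``schedule`` lists the visited cluster indices (default: every cluster
    twice, so repeated visits demonstrate the return to a prior basin).
    Each visit lasts ``dwell_steps`` steps of
    x <- x + rate * (centroid - x) + noise.  The step index is stored as
    the point's timestamp.
    """
    if not 0 < relaxation_rate <= 1:
        raise InvalidConfigError("relaxation_rate must be in (0, 1]")
    if dwell_steps < 1:
        raise InvalidConfigError("dwell_steps must be >= 1")
    rng = np.random.default_rng(spec.seed)
    centroids = simplex_centroids(spec.n_clusters, spec.dimension,
                                  spec.separation * spec.sigma)
    if schedule is None:
        schedule = list(range(spec.n_clusters)) * 2
    schedule = list(schedule)
    T = dwell_steps * len(schedule)
    positions = np.empty((T, spec.dimension))
    labels = np.empty(T, dtype=object)
    x = np.zeros(spec.dimension)
    t = 0
    names = spec.labels
    for ci in schedule:
        mu = centroids[ci]
        for _ in range(dwell_steps):
            x = x + relaxation_rate * (mu - x)
            if noise_sd > 0:
                x = x + noise_sd * rng.standard_normal(spec.dimension)
            positions[t] = x
            labels[t] = names[ci]
            t += 1
    return LabeledPointSet(positions, labels, names, time=np.arange(T))


@dataclass(frozen=True)
class ConditionSpec:
    """One stimulation condition of a surrogate recording.

    ``spatial_pattern`` is a unit vector over channels (generated
    orthonormally per condition when None); ``modulation_depth`` scales the
    patterned signal (0 = no pattern, e.g. silence / spontaneous activity).
    """

    label: str
    modulation_depth: float = 3.0
    spatial_pattern: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.modulation_depth < 0:
            raise InvalidConfigError("modulation_depth must be >= 0")
        if self.spatial_pattern is not None:
            p = np.asarray(self.spatial_pattern, dtype=float)
            norm = np.linalg.norm(p)
            if norm == 0:
                raise InvalidConfigError("spatial_pattern must be nonzero")
            object.__setattr__(self, "spatial_pattern", p / norm)


def _default_conditions() -> tuple[ConditionSpec, ...]:
    return (
        ConditionSpec("silence", 0.0),
        ConditionSpec("1kHz", 3.0),
        ConditionSpec("2kHz", 3.0),
        ConditionSpec("4kHz", 3.0),
    )


@dataclass(frozen=True)
class RecordingSpec:
    """Surrogate multichannel recording protocol.

    Defaults emulate a sustained-stimulation session: 16 channels at
    1 kHz, 3-minute blocks, four conditions (silence + three stimuli)
    presented twice each, power matching on.
    """

    channels: int = 16
    sampling_rate: float = 1000.0
    block_duration_s: float = 180.0
    conditions: tuple[ConditionSpec, ...] = field(
        default_factory=_default_conditions)
    common_mode_amplitude: float = 1.0
    noise_sd: float = 1.0
    schedule: tuple[str, ...] | None = None
    power_matched: bool = True
    carrier_band: tuple[float, float] = (5.0, 45.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_duration_s <= 0:
            raise InvalidConfigError("block_duration_s must be positive")
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling_rate must be positive")
        if self.channels < 2:
            raise InvalidConfigError("need at least 2 channels")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be positive")
        conds = tuple(self.conditions)
        if len({c.label for c in conds}) != len(conds):
            raise InvalidConfigError("condition labels must be unique")
        object.__setattr__(self, "conditions", conds)
        sched = (tuple(self.schedule) if self.schedule is not None
                 else tuple(c.label for c in conds) * 2)
        known = {c.label for c in conds}
        unknown = [lab for lab in sched if lab not in known]
        if unknown:
            raise InvalidConfigError(f"schedule labels {unknown} not defined")
        object.__setattr__(self, "schedule", sched)

    def condition(self, label: str) -> ConditionSpec:
        return next(c for c in self.conditions if c.label == label)


def _band_limited_noise(n: int, rate: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise restricted to ``band`` (Hz) via FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    sig = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(sig ** 2))
    if rms == 0:
        raise InvalidConfigError("carrier band contains no FFT bins")
    return sig / rms


def make_recording(spec: RecordingSpec):
    """Generate surrogate recording blocks plus their condition schedule.

    Returns ``(segments, schedule_rows)`` where ``schedule_rows`` is a list
    of ``(label, start_s, end_s)`` with half-open intervals in seconds.
    Per block, each channel carries common_mode(t) + depth * pattern_c *
    carrier(t) + white noise; carriers and common mode are drawn fresh per
    block, so condition identity lives only in the spatial pattern.
    """
    rng = np.random.default_rng(spec.seed)
    C = spec.channels
    # orthonormal default patterns, fixed across blocks of one condition
    need = [c for c in spec.conditions if c.spatial_pattern is None]
    q, _ = np.linalg.qr(rng.standard_normal((C, max(len(need), 1))))
    patterns = {}
    for i, cond in enumerate(need):
        patterns[cond.label] = q[:, i]
    for cond in spec.conditions:
        if cond.spatial_pattern is not None:
            if cond.spatial_pattern.shape[0] != C:
                raise InvalidConfigError(
                    f"pattern of {cond.label!r} has wrong channel count")
            patterns[cond.label] = cond.spatial_pattern

    depths = {c.label: c.modulation_depth for c in spec.conditions}
    max_d2 = max(d ** 2 for d in depths.values())
    T = int(round(spec.block_duration_s * spec.sampling_rate))

    segments: list[RecordingSegment] = []
    schedule_rows: list[tuple[str, float, float]] = []
    t0 = 0.0
    for label in spec.schedule:
        depth = depths[label]
        if spec.power_matched:
            # equal expected total power: surplus pattern power is traded
            # against unpatterned channel-noise power
            var = spec.noise_sd ** 2 + (max_d2 - depth ** 2) / C
        else:
            var = spec.noise_sd ** 2
        common = spec.common_mode_amplitude * _band_limited_noise(
            T, spec.sampling_rate, spec.carrier_band, rng)
        carrier = _band_limited_noise(T, spec.sampling_rate,
                                      spec.carrier_band, rng)
        noise = np.sqrt(var) * rng.standard_normal((C, T))
        samples = common[None, :] + depth * np.outer(patterns[label], carrier) + noise
        segments.append(RecordingSegment(samples, spec.sampling_rate, label,
                                         onset_time=t0))
        schedule_rows.append((label, t0, t0 + spec.block_duration_s))
        t0 += spec.block_duration_s
    return segments, schedule_rows
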