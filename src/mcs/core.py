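"""Distance, proximity and discrimination-value computations on labeled point sets.

A labeled point set holds M observations in n-dimensional space, each
carrying one of L condition labels.  All statistics downstream derive from
the M x M matrix of pairwise Euclidean distances: block means of that matrix
(the *proximity matrix*) hold the mean intra-cluster distances on the
diagonal and the mean inter-cluster distances off it, and the discrimination
value of two clusters A and B is

    delta(A, B) = d(A, A) + d(B, B) - 2 * d(A, B)

where d are the proximities.  The inter-cluster term carries the factor 2 so
that the intra- and inter-cluster contributions balance.  Geometrically,
delta < 0 means the two clusters are disjoint (dense and far apart) and
delta > 0 means they overlap; delta = 0 is the boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateClusterError, InvalidInputError, InvalidPairError

__all__ = [
    "LabeledPointSet",
    "DistanceMatrix",
    "ProximityMatrix",
    "pairwise_distances",
    "proximity_matrix",
    "proximity_of",
    "discrimination_value",
    "global_discrimination",
]


def _check_finite(coordinates: np.ndarray) -> None:
    finite = np.isfinite(coordinates)
    if not finite.all():
        bad_rows = np.flatnonzero(~finite.all(axis=1))
        raise InvalidInputError(
            f"non-finite coordinate(s) in row(s) {bad_rows.tolist()}"
        )


@dataclass(frozen=True)
class LabeledPointSet:
    """M points in n-dimensional space with one condition label per point.

    Parameters
    ----------
    coordinates
        (M, n) array of real coordinates, arbitrary units.
    labels
        Length-M sequence of condition labels.
    label_order
        Canonical ordering of the distinct labels.  Defaults to order of
        first appearance in ``labels``.
    time, segment
        Optional per-point timestamps (seconds) and segment-of-origin ids,
        carried through from preprocessing for trajectory plots.

    Finiteness and label membership are enforced here; the statistical
    operations additionally require L >= 2 and every cluster to have at
    least two members (a single-label set remains valid for visualization).
    """

    coordinates: np.ndarray
    labels: np.ndarray
    label_order: tuple[str, ...] = ()
    time: np.ndarray | None = None
    segment: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        labels = np.asarray(self.labels, dtype=object)
        if coords.shape[0] != labels.shape[0]:
            raise InvalidInputError(
                f"{coords.shape[0]} coordinate rows but {labels.shape[0]} labels"
            )
        _check_finite(coords)
        order = tuple(self.label_order) or tuple(dict.fromkeys(labels.tolist()))
        extra = set(labels.tolist()) - set(order)
        if extra:
            raise InvalidInputError(f"labels {sorted(map(str, extra))} not in label_order")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "label_order", order)
        for name in ("time", "segment"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val)
                if val.shape[0] != coords.shape[0]:
                    raise InvalidInputError(f"{name} length does not match M")
                object.__setattr__(self, name, val)

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coordinates.shape[1]

    @property
    def n_labels(self) -> int:
        return len(self.label_order)

    def label_counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in self.label_order}

    def label_codes(self) -> np.ndarray:
        """Integer code per point, following label_order."""
        lut = {lab: i for i, lab in enumerate(self.label_order)}
        return np.fromiter((lut[lab] for lab in self.labels), dtype=np.intp,
                           count=self.n_points)

    def subset(self, keep_labels) -> "LabeledPointSet":
        """Restrict to the points carrying one of ``keep_labels``;
        label_order keeps its relative order."""
        keep = tuple(keep_labels)
        missing = [lab for lab in keep if lab not in self.label_order]
        if missing:
            raise InvalidPairError(f"labels {missing} not in label_order")
        mask = np.isin(self.labels, keep)
        return LabeledPointSet(
            self.coordinates[mask],
            self.labels[mask],
            tuple(lab for lab in self.label_order if lab in keep),
            None if self.time is None else self.time[mask],
            None if self.segment is None else self.segment[mask],
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """M x M matrix of pairwise Euclidean distances."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidInputError("distance matrix must be square")
        object.__setattr__(self, "values", v)

    @property
    def n_points(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ProximityMatrix:
    """L x L matrix of mean intra- (diagonal) and inter-cluster distances."""

    values: np.ndarray
    label_order: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        L = len(self.label_order)
        if v.shape != (L, L):
            raise InvalidInputError("proximity matrix shape does not match label_order")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "label_order", tuple(self.label_order))

    def _index(self, label) -> int:
        try:
            return self.label_order.index(label)
        except ValueError:
            raise InvalidPairError(f"label {label!r} not in label_order") from None

    def proximity(self, a, b) -> float:
        return float(self.values[self._index(a), self._index(b)])


def pairwise_distances(points) -> DistanceMatrix:
    """All pairwise Euclidean distances between points.

    Accepts a :class:`LabeledPointSet` or a plain (M, n) array.
    """
    coords = points.coordinates if isinstance(points, LabeledPointSet) else (
        np.atleast_2d(np.asarray(points, dtype=float)))
    _check_finite(coords)
    if coords.shape[0] < 2:
        raise InvalidInputError("need at least 2 points for pairwise distances")
    return DistanceMatrix(squareform(pdist(coords, metric="euclidean")))


def _block_sums(dist: np.ndarray, codes: np.ndarray, n_labels: int) -> np.ndarray:
    """Full-matrix block sums S[a, b] = sum_{i in a, j in b} D[i, j].

    The diagonal block sum counts every within-cluster pair twice and the
    zero self-distances not at all.
    """
    onehot = np.zeros((codes.shape[0], n_labels))
    onehot[np.arange(codes.shape[0]), codes] = 1.0
    return onehot.T @ dist @ onehot


def proximity_from_block_sums(sums: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Turn block sums into block means (works on stacked (..., L, L) sums)."""
    n = counts.astype(float)
    denom = np.outer(n, n)
    np.fill_diagonal(denom, n * (n - 1))
    return sums / denom


def proximity_matrix(dist, labels, label_order=None) -> ProximityMatrix:
    """Average the pairwise distances according to the points' cluster labels.

    Diagonal entries are mean within-cluster distances over the unordered
    within-cluster pairs (self-distances excluded); off-diagonal entries are
    mean cross-cluster distances over all |A|*|B| pairs.
    """
    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != d.shape[0]:
        raise InvalidInputError("labels length does not match distance matrix")
    order = tuple(label_order) if label_order is not None else tuple(
        dict.fromkeys(labels.tolist()))
    if len(order) < 2:
        raise DegenerateClusterError("need at least 2 distinct labels")
    lut = {lab: i for i, lab in enumerate(order)}
    try:
        codes = np.fromiter((lut[lab] for lab in labels), dtype=np.intp,
                            count=labels.shape[0])
    except KeyError as exc:
        raise InvalidInputError(f"label {exc.args[0]!r} not in label_order") from None
    counts = np.bincount(codes, minlength=len(order))
    small = [order[i] for i in np.flatnonzero(counts < 2)]
    if small:
        raise DegenerateClusterError(
            f"cluster(s) {small} have fewer than 2 members"
        )
    values = proximity_from_block_sums(_block_sums(d, codes, len(order)), counts)
    return ProximityMatrix(values, order)


def proximity_of(points: LabeledPointSet) -> ProximityMatrix:
    """Convenience: proximity matrix straight from a labeled point set."""
    return proximity_matrix(pairwise_distances(points), points.labels,
                            points.label_order)


def discrimination_value(prox: ProximityMatrix, a, b) -> float:
    """delta(a, b) = d(a,a) + d(b,b) - 2 d(a,b); negative means disjoint."""
    if a == b:
        raise InvalidPairError("discrimination value needs two distinct clusters")
    i, j = prox._index(a), prox._index(b)
    v = prox.values
    return float(v[i, i] + v[j, j] - 2.0 * v[i, j])


def global_discrimination(prox: ProximityMatrix) -> float:
    """Sum of pairwise discrimination values over all unordered label pairs.

    Quantifies how well all L clusters separate jointly; for L = 2 it
    reduces exactly to the two-cluster discrimination value.
    """
    return float(deltas_from_proximity(prox.values[None, ...])[0])


def deltas_from_proximity(prox_stack: np.ndarray) -> np.ndarray:
    """Global discrimination for a (..., L, L) stack of proximity matrices.

    Sum over unordered pairs of d(a,a) + d(b,b) - 2 d(a,b) equals
    (L - 1) * trace - 2 * (off-diagonal upper-triangle sum).
    """
    L = prox_stack.shape[-1]
    diag = np.einsum("...ii->...i", prox_stack)
    total = prox_stack.sum(axis=(-2, -1))
    off_sum_half = 0.5 * (total - diag.sum(axis=-1))
    return np.asarray((L - 1) * diag.sum(axis=-1) - 2.0 * off_sum_half, dtype=float)


def pair_iter(label_order):
    """Unordered label pairs in canonical order."""
    return itertools.combinations(label_order, 2)
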