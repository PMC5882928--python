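"""Assign new points to clusters via the global discrimination value.

A new point x is tentatively appended to each cluster i in turn and the
global discrimination value of the resulting configuration is recomputed;
the most probable cluster is the one whose assignment minimizes that value
(adding a point where it belongs keeps clusters dense and separated, i.e.
keeps the value small).  Block sums of the reference distance matrix are
precomputed once, so each candidate assignment is an O(M) incremental
update rather than a full O(M^2) recomputation; the two agree to
floating-point round-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    LabeledPointSet,
    deltas_from_proximity,
    pairwise_distances,
    proximity_from_block_sums,
)
from .errors import DegenerateClusterError, InvalidInputError

__all__ = ["AssignmentResult", "ClusterAssigner", "assign_point", "assign_points"]

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of assigning one point.

    ``delta_per_assignment[i]`` is the global discrimination value with the
    point placed in cluster ``label_order[i]``; the predicted label attains
    the minimum and ``margin`` is the gap to the second-best assignment.
    """

    predicted_label: str
    delta_per_assignment: np.ndarray
    margin: float
    label_order: tuple[str, ...]


class ClusterAssigner:
    """Precomputed reference structures for repeated assignments."""

    def __init__(self, reference: LabeledPointSet):
        if reference.n_labels < 2:
            raise DegenerateClusterError("assignment needs at least 2 clusters")
        counts = np.bincount(reference.label_codes(),
                             minlength=reference.n_labels)
        if np.any(counts < 2):
            raise DegenerateClusterError(
                "every reference cluster needs at least 2 members")
        self.reference = reference
        self.codes = reference.label_codes()
        self.counts = counts
        dist = pairwise_distances(reference).values
        onehot = np.zeros((reference.n_points, reference.n_labels))
        onehot[np.arange(reference.n_points), self.codes] = 1.0
        self.block_sums = onehot.T @ dist @ onehot

    def assign(self, x) -> AssignmentResult:
        x = np.asarray(x, dtype=float).ravel()
        ref = self.reference
        if x.shape[0] != ref.n_dims:
            raise InvalidInputError(
                f"query has {x.shape[0]} dimensions, reference has {ref.n_dims}")
        if not np.isfinite(x).all():
            raise InvalidInputError("non-finite coordinate in query point")
        d_x = np.linalg.norm(ref.coordinates - x, axis=1)
        # distance mass from x into each existing cluster
        t = np.bincount(self.codes, weights=d_x, minlength=ref.n_labels)
        L = ref.n_labels
        deltas = np.empty(L)
        for i in range(L):
            sums = self.block_sums.copy()
            sums[i, :] += t
            sums[:, i] += t
            counts = self.counts.copy()
            counts[i] += 1
            prox = proximity_from_block_sums(sums, counts)
            deltas[i] = deltas_from_proximity(prox[None])[0]
        best = int(np.argmin(deltas))
        rest = np.delete(deltas, best)
        margin = float(rest.min() - deltas[best])
        scale = max(1.0, float(np.abs(deltas).max()))
        if margin <= _TIE_RTOL * scale:
            warnings.warn(
                "tied assignment; resolved by canonical label order",
                stacklevel=2)
            tied = np.flatnonzero(deltas - deltas[best] <= _TIE_RTOL * scale)
            best = int(tied.min())
            margin = 0.0
        return AssignmentResult(ref.label_order[best], deltas, margin,
                                ref.label_order)


def assign_point(x, reference: LabeledPointSet) -> AssignmentResult:
    """Assign one n-dimensional point to its most probable cluster."""
    return ClusterAssigner(reference).assign(x)


def assign_points(queries, reference: LabeledPointSet) -> list[AssignmentResult]:
    """Assign each row of ``queries``; the reference is prepared once."""
    assigner = ClusterAssigner(reference)
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    return [assigner.assign(q) for q in queries]
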