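"""Label-permutation null distribution and p-value for cluster disjointness.

The test asks whether the observed labeling of points into clusters is
significantly better — in terms of a smaller (more negative) discrimination
value — than random re-labelings that preserve the cluster sizes.  The
pairwise point distances are computed once; each permutation only reassigns
labels, so the null distribution is obtained from block means of a fixed
distance matrix.

With M points and L labels there are M!/(n_1!...n_L!) distinct
count-preserving labelings.  When that number does not exceed the requested
number of permutations the null is enumerated exhaustively; otherwise
labelings are sampled uniformly with replacement.

Two p-value estimators are provided.  ``paper_literal_strict`` is the plain
empirical Pr(X < delta_0) over the sampled null.  The default
``add_one_leq`` is the standard permutation estimator
(1 + #{delta_i <= delta_0}) / (N + 1), which cannot return 0; in the
exhaustive branch it becomes the exact #{delta <= delta_0} / total.

Overlapping sliding windows make successive state vectors autocorrelated,
which violates the exchangeability the full shuffle assumes; the
``block_shuffle`` scheme permutes contiguous label blocks as units and is
the conservative option for such data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sympy.utilities.iterables import multiset_permutations

from .core import (
    LabeledPointSet,
    deltas_from_proximity,
    pairwise_distances,
    proximity_from_block_sums,
)
from .errors import DegenerateClusterError, InvalidConfigError, InvalidPairError

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "permute_labels",
    "permutation_test_pair",
    "permutation_test_global",
    "pairwise_pvalue_matrix",
    "n_distinct_labelings",
]

_MODES = ("add_one_leq", "paper_literal_strict")
_SCHEMES = ("full_shuffle", "block_shuffle")
_CHUNK = 2048  # permutations evaluated per batched matrix product


@dataclass(frozen=True)
class PermutationConfig:
    """Configuration of the permutation test.

    n_permutations : number of sampled re-labelings N (default 10^4).
    seed : RNG seed; fixed seed gives bit-identical results.
    comparison_mode : ``add_one_leq`` (default) or ``paper_literal_strict``.
    scheme : ``full_shuffle`` or ``block_shuffle`` (needs ``block_length``).
    exhaustive : ``auto`` enumerates all labelings when there are at most
        N of them, ``always`` forces enumeration, ``never`` forces sampling.
    """

    n_permutations: int = 10_000
    seed: int = 0
    comparison_mode: str = "add_one_leq"
    scheme: str = "full_shuffle"
    block_length: int | None = None
    exhaustive: str = "auto"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise InvalidConfigError("n_permutations must be >= 1")
        if self.comparison_mode not in _MODES:
            raise InvalidConfigError(f"comparison_mode must be one of {_MODES}")
        if self.scheme not in _SCHEMES:
            raise InvalidConfigError(f"scheme must be one of {_SCHEMES}")
        if self.scheme == "block_shuffle":
            if self.block_length is None or self.block_length < 1:
                raise InvalidConfigError("block_shuffle needs block_length >= 1")
        if self.exhaustive not in ("auto", "always", "never"):
            raise InvalidConfigError("exhaustive must be auto, always or never")


@dataclass(frozen=True)
class PermutationResult:
    """Observed delta_0, the permuted null deltas, and the p-value."""

    delta_observed: float
    delta_null: np.ndarray
    p_value: float
    config: PermutationConfig
    labels_compared: tuple | str
    exhaustive: bool = False

    @property
    def n_permutations(self) -> int:
        return int(self.delta_null.shape[0])

    def to_report(self) -> dict:
        labels = (self.labels_compared if isinstance(self.labels_compared, str)
                  else list(self.labels_compared))
        return {
            "labels": labels,
            "delta0": float(self.delta_observed),
            "p": float(self.p_value),
            "n_perm": self.n_permutations,
            "mode": self.config.comparison_mode,
            "scheme": self.config.scheme,
            "seed": self.config.seed,
            "exhaustive": bool(self.exhaustive),
        }


def n_distinct_labelings(counts) -> int:
    """Number of distinct count-preserving labelings M!/(n_1!...n_L!)."""
    counts = np.asarray(counts, dtype=int)
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _batch_permutation_indices(M: int, size: int, rng: np.random.Generator,
                               scheme: str, block_length: int | None) -> np.ndarray:
    """(size, M) row-wise uniformly random permutation index arrays."""
    if scheme == "full_shuffle":
        return np.argsort(rng.random((size, M)), axis=1)
    bl = int(block_length)
    if bl > M:
        raise InvalidConfigError(f"block_length {bl} exceeds M = {M}")
    starts = np.arange(0, M, bl)
    n_blocks = starts.shape[0]
    order = np.argsort(rng.random((size, n_blocks)), axis=1)
    if M % bl == 0:
        return (order[:, :, None] * bl + np.arange(bl)).reshape(size, M)
    blocks = [np.arange(s, min(s + bl, M)) for s in starts]
    return np.stack([np.concatenate([blocks[j] for j in row]) for row in order])


def permute_labels(labels, scheme: str = "full_shuffle", rng=None,
                   block_length: int | None = None) -> np.ndarray:
    """One uniformly random count-preserving rearrangement of ``labels``.

    ``block_shuffle`` permutes contiguous blocks of ``block_length`` labels
    as units (the final, possibly shorter, block moves as a unit too).
    """
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    idx = _batch_permutation_indices(labels.shape[0], 1, rng, scheme, block_length)
    return labels[idx[0]]


def _deltas_for_codes(dist: np.ndarray, codes_stack: np.ndarray, L: int,
                      counts: np.ndarray) -> np.ndarray:
    """Global discrimination value for a (B, M) stack of label-code rows."""
    B, M = codes_stack.shape
    eye = np.eye(L)
    out = np.empty(B)
    for start in range(0, B, _CHUNK):
        chunk = codes_stack[start:start + _CHUNK]
        b = chunk.shape[0]
        onehot = eye[chunk]                                   # (b, M, L)
        flat = np.moveaxis(onehot, 0, 1).reshape(M, b * L)
        prod = np.moveaxis((dist @ flat).reshape(M, b, L), 1, 0)
        sums = np.einsum("bml,bmk->blk", onehot, prod)        # (b, L, L)
        out[start:start + b] = deltas_from_proximity(
            proximity_from_block_sums(sums, counts))
    return out


def _run_test(dist: np.ndarray, codes: np.ndarray, n_labels: int,
              config: PermutationConfig, labels_compared,
              rng: np.random.Generator | None = None) -> PermutationResult:
    counts = np.bincount(codes, minlength=n_labels)
    if np.any(counts < 2):
        raise DegenerateClusterError(
            "every cluster in the test needs at least 2 members")
    M = codes.shape[0]
    delta0 = float(_deltas_for_codes(dist, codes[None, :], n_labels, counts)[0])

    total = n_distinct_labelings(counts)
    use_exhaustive = config.exhaustive == "always" or (
        config.exhaustive == "auto" and total <= config.n_permutations)

    if use_exhaustive:
        all_codes = np.array(list(multiset_permutations(sorted(codes.tolist()))),
                             dtype=np.intp)
        null = _deltas_for_codes(dist, all_codes, n_labels, counts)
        if config.comparison_mode == "paper_literal_strict":
            p = float(np.count_nonzero(null < delta0)) / total
        else:
            p = float(np.count_nonzero(null <= delta0)) / total
        return PermutationResult(delta0, null, p, config, labels_compared,
                                 exhaustive=True)

    rng = np.random.default_rng(config.seed) if rng is None else rng
    N = config.n_permutations
    null = np.empty(N)
    for start in range(0, N, _CHUNK):
        b = min(_CHUNK, N - start)
        idx = _batch_permutation_indices(M, b, rng, config.scheme,
                                         config.block_length)
        null[start:start + b] = _deltas_for_codes(dist, codes[idx], n_labels,
                                                  counts)
    if config.comparison_mode == "paper_literal_strict":
        p = float(np.count_nonzero(null < delta0)) / N
    else:
        p = (1.0 + np.count_nonzero(null <= delta0)) / (N + 1.0)
    return PermutationResult(delta0, null, float(p), config, labels_compared)


def permutation_test_pair(points: LabeledPointSet, a, b,
                          config: PermutationConfig | None = None,
                          rng: np.random.Generator | None = None
                          ) -> PermutationResult:
    """Permutation test of disjointness for clusters ``a`` vs ``b``.

    Only the points labeled ``a`` or ``b`` participate; labels are permuted
    within that subset.
    """
    if a == b:
        raise InvalidPairError("a and b must differ")
    config = config or PermutationConfig()
    sub = points.subset([a, b])
    dist = pairwise_distances(sub).values
    return _run_test(dist, sub.label_codes(), 2, config, (a, b), rng=rng)


def permutation_test_global(points: LabeledPointSet,
                            config: PermutationConfig | None = None
                            ) -> PermutationResult:
    """Permutation test on the global discrimination value over all L clusters."""
    config = config or PermutationConfig()
    if points.n_labels < 2:
        raise DegenerateClusterError("global test needs at least 2 labels")
    dist = pairwise_distances(points).values
    return _run_test(dist, points.label_codes(), points.n_labels, config,
                     "global")


def pairwise_pvalue_matrix(points: LabeledPointSet,
                           config: PermutationConfig | None = None,
                           correction: str | None = None) -> pd.DataFrame:
    """Symmetric L x L matrix of pairwise permutation p-values.

    The diagonal is NaN.  No multiplicity correction is applied by default
    (mutual raw p-values); ``correction='holm'`` adjusts the L(L-1)/2
    off-diagonal values with Holm-Bonferroni.
    """
    config = config or PermutationConfig()
    order = points.label_order
    L = len(order)
    if L < 2:
        raise DegenerateClusterError("need at least 2 labels")
    pairs = [(a, b) for i, a in enumerate(order) for b in order[i + 1:]]
    children = np.random.SeedSequence(config.seed).spawn(len(pairs))
    pvals = []
    for (a, b), child in zip(pairs, children):
        res = permutation_test_pair(points, a, b, config,
                                    rng=np.random.default_rng(child))
        pvals.append(res.p_value)
    if correction is not None:
        if correction != "holm":
            raise InvalidConfigError("only 'holm' correction is supported")
        from statsmodels.stats.multitest import multipletests
        pvals = list(multipletests(pvals, method="holm")[1])
    mat = np.full((L, L), np.nan)
    for (a, b), p in zip(pairs, pvals):
        i, j = order.index(a), order.index(b)
        mat[i, j] = mat[j, i] = p
    return pd.DataFrame(mat, index=list(order), columns=list(order))
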