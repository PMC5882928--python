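"""Classical (Torgerson) metric MDS for visualization.

The statistics operate on the full n-dimensional distances; MDS is used
only to draw point clouds, temporal trajectories and cluster-centroid
("attractor basin") summaries in the plane.  Classical scaling is chosen
over stress majorization because it is deterministic (no random
initialization) and exact for configurations whose distances have rank at
most the target dimension.  Residual distortion is reported as a stress
value so the projection's faithfulness is visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np

matplotlib.use("Agg")  # headless backend; figures only ever go to files
import matplotlib.pyplot as plt
from scipy.spatial.distance import pdist, squareform

from .core import DistanceMatrix, ProximityMatrix
from .errors import InvalidInputError

__all__ = [
    "Embedding2D",
    "AttractorSummary",
    "classical_mds",
    "embed_centroids",
    "plot_state_trajectory",
    "plot_attractor_basins",
]

_ALIGNMENT = ("axes ordered by descending eigenvalue; each axis sign fixed "
              "so its largest-magnitude coordinate is positive")


@dataclass(frozen=True)
class Embedding2D:
    """Low-dimensional embedding of a distance matrix.

    coordinates are centered (column means zero) and in arbitrary units;
    ``stress`` is the relative residual distance distortion
    sqrt(sum (d_emb - d_in)^2 / sum d_in^2); ``eigenvalues`` are the
    retained Gram eigenvalues (negative ones truncated to zero).
    """

    coordinates: np.ndarray
    stress: float
    eigenvalues: np.ndarray
    alignment_convention: str = _ALIGNMENT


@dataclass(frozen=True)
class AttractorSummary:
    """Cluster centroids in the plane plus basin diameters.

    ``diameters`` equal the mean intra-cluster distances (the proximity
    diagonal) exactly; centroids come from MDS of the off-diagonal
    inter-cluster distances.
    """

    centroid_xy: np.ndarray
    diameters: np.ndarray
    label_order: tuple[str, ...]


def _fix_orientation(coords: np.ndarray) -> np.ndarray:
    # removes the reflection indeterminacy axis by axis
    for j in range(coords.shape[1]):
        col = coords[:, j]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            coords[:, j] = -col
    return coords


def classical_mds(dist, target_dim: int = 2) -> Embedding2D:
    """Torgerson double-centering + eigendecomposition.

    Keeps the ``target_dim`` largest nonnegative eigenvalues of the
    double-centered Gram matrix; negative eigenvalues (non-Euclidean
    residue) are truncated to zero.
    """
    d = dist.values if isinstance(dist, DistanceMatrix) else np.asarray(dist, float)
    m = d.shape[0]
    if target_dim < 1:
        raise InvalidInputError("target_dim must be >= 1")
    if m < target_dim + 1:
        raise InvalidInputError(
            f"need at least {target_dim + 1} points for a {target_dim}-D embedding")
    sq = d ** 2
    j = np.eye(m) - np.ones((m, m)) / m
    gram = -0.5 * j @ sq @ j
    gram = 0.5 * (gram + gram.T)  # symmetrize against round-off
    evals, evecs = np.linalg.eigh(gram)
    idx = np.argsort(evals)[::-1][:target_dim]
    lam = np.clip(evals[idx], 0.0, None)
    coords = evecs[:, idx] * np.sqrt(lam)
    coords = _fix_orientation(coords - coords.mean(axis=0, keepdims=True))
    emb = squareform(pdist(coords))
    denom = float(np.sum(d ** 2))
    stress = float(np.sqrt(np.sum((emb - d) ** 2) / denom)) if denom > 0 else 0.0
    return Embedding2D(coords, stress, lam)


def embed_centroids(prox: ProximityMatrix) -> AttractorSummary:
    """Project cluster centroids from the inter-cluster distances.

    The off-diagonal proximity entries are treated as exact distances
    between cluster centers (the diagonal is replaced by zero for the
    embedding); basin diameters are copied from the proximity diagonal.
    Two clusters yield a 1-D layout padded with a zero second coordinate.
    """
    v = prox.values.copy()
    diameters = np.diag(prox.values).copy()
    np.fill_diagonal(v, 0.0)
    L = v.shape[0]
    dim = 1 if L == 2 else 2
    emb = classical_mds(v, target_dim=dim)
    xy = emb.coordinates
    if xy.shape[1] < 2:
        xy = np.column_stack([xy, np.zeros(L)])
    return AttractorSummary(xy, diameters, prox.label_order)


_COLORS = plt.rcParams["axes.prop_cycle"].by_key()["color"]


def _savefig_deterministic(fig, path) -> None:
    # fixed hashsalt + no Date metadata -> identical bytes for identical input
    path = str(path)
    with plt.rc_context({"svg.hashsalt": "mcs"}):
        if path.endswith(".svg"):
            fig.savefig(path, metadata={"Date": None})
        else:
            fig.savefig(path)
    plt.close(fig)


def plot_state_trajectory(embedding: Embedding2D, labels, path,
                          time_order=None,
                          summary: AttractorSummary | None = None):
    """Plot the embedded state vectors as a condition-colored trajectory.

    Points are connected in time order; contiguous runs of one condition
    are drawn as one polyline.  If ``summary`` is given, attractor basins
    are overlaid as disks whose diameters equal the mean intra-cluster
    distances.  Axes are in arbitrary units.
    """
    labels = np.asarray(labels, dtype=object)
    xy = embedding.coordinates
    if xy.shape[0] != labels.shape[0]:
        raise InvalidInputError("embedding rows and labels length differ")
    order = np.arange(len(labels)) if time_order is None else np.asarray(time_order)
    xy, labels = xy[order], labels[order]

    fig, ax = plt.subplots(figsize=(6, 6))
    present = list(dict.fromkeys(labels.tolist()))
    color_of = {lab: _COLORS[i % len(_COLORS)] for i, lab in enumerate(present)}
    # split the trajectory into contiguous same-condition runs
    breaks = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    seen = set()
    for run in np.split(np.arange(len(labels)), breaks):
        lab = labels[run[0]]
        ax.plot(xy[run, 0], xy[run, 1], "-o", ms=3, lw=0.8,
                color=color_of[lab], label=None if lab in seen else str(lab))
        seen.add(lab)
    if summary is not None:
        for lab, (cx, cy), dia in zip(summary.label_order, summary.centroid_xy,
                                      summary.diameters):
            ax.add_patch(plt.Circle((cx, cy), dia / 2.0, alpha=0.25,
                                    color=color_of.get(lab, "grey")))
    ax.set_xlabel("MDS axis 1 (a.u.)")
    ax.set_ylabel("MDS axis 2 (a.u.)")
    ax.set_aspect("equal", adjustable="datalim")
    ax.legend(loc="best", fontsize=8)
    _savefig_deterministic(fig, path)
    return path


def plot_attractor_basins(summary: AttractorSummary, path):
    """Abstracted configuration plot: centroid disks with intra-cluster
    diameters, from the proximity matrix alone."""
    fig, ax = plt.subplots(figsize=(6, 6))
    for i, (lab, (cx, cy), dia) in enumerate(zip(
            summary.label_order, summary.centroid_xy, summary.diameters)):
        color = _COLORS[i % len(_COLORS)]
        ax.add_patch(plt.Circle((cx, cy), dia / 2.0, alpha=0.4, color=color))
        ax.plot([cx], [cy], "o", color=color)
        ax.annotate(str(lab), (cx, cy), textcoords="offset points",
                    xytext=(4, 4), fontsize=9)
    span = np.abs(summary.centroid_xy).max() + summary.diameters.max()
    ax.set_xlim(-1.1 * span, 1.1 * span)
    ax.set_ylim(-1.1 * span, 1.1 * span)
    ax.set_aspect("equal")
    ax.set_xlabel("MDS axis 1 (a.u.)")
    ax.set_ylabel("MDS axis 2 (a.u.)")
    _savefig_deterministic(fig, path)
    return path
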