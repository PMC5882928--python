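import numpy as np
import pytest

from mcs import LabeledPointSet


@pytest.fixture
def line_points():
    """Four points on a line at 0, 1, 10, 11 labeled A, A, B, B."""
    return LabeledPointSet(np.array([[0.0], [1.0], [10.0], [11.0]]),
                           ["A", "A", "B", "B"])


@pytest.fixture
def rectangle_points():
    """Two tight clusters 10 apart: A = {(0,0),(0,2)}, B = {(10,0),(10,2)}."""
    return LabeledPointSet(
        np.array([[0.0, 0.0], [0.0, 2.0], [10.0, 0.0], [10.0, 2.0]]),
        ["A", "A", "B", "B"])


def brute_force_proximity(coords, labels, label_order):
    """Independent double-loop oracle for block mean distances."""
    coords = np.asarray(coords, float)
    labels = list(labels)
    L = len(label_order)
    out = np.zeros((L, L))
    for i, a in enumerate(label_order):
        for j, b in enumerate(label_order):
            acc, cnt = 0.0, 0
            for p in range(len(labels)):
                for q in range(len(labels)):
                    if p == q or labels[p] != a or labels[q] != b:
                        continue
                    acc += float(np.linalg.norm(coords[p] - coords[q]))
                    cnt += 1
            out[i, j] = acc / cnt
    return out


def brute_force_global_delta(coords, labels, label_order):
    """Oracle: sum over unordered pairs of d(aa) + d(bb) - 2 d(ab)."""
    prox = brute_force_proximity(coords, labels, label_order)
    total = 0.0
    for i in range(len(label_order)):
        for j in range(i + 1, len(label_order)):
            total += prox[i, i] + prox[j, j] - 2.0 * prox[i, j]
    return total
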