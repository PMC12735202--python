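"""Train/test partitioning: stratified random split and deterministic SPXY.

SPXY is the Kennard-Stone max-min accretion generalized to a joint
predictor-response distance: d(i,j) = dx(i,j)/max(dx) + dy(i,j)/max(dy) with
Euclidean dx over spectra and absolute difference over an ordinal-coded
response.  Ties are broken by lowest index so the selection is reproducible
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist


class PartitionError(ValueError):
    """Invalid partitioning request."""


@dataclass
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)

    def to_dict(self) -> dict:
        return {"train": self.train_idx.tolist(), "test": self.test_idx.tolist()}


def _train_size(n: int, train_fraction: float) -> int:
    # round half up, fixed so 0.75 * 200 -> 150 and 0.5 * 5 -> 3
    return int(np.floor(train_fraction * n + 0.5))


def stratified_split(labels: np.ndarray, train_fraction: float, seed: int) -> SplitResult:
    """Per-class random split at a fixed fraction (round half up)."""
    labels = np.asarray(labels)
    if not (0.0 < train_fraction < 1.0):
        raise PartitionError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise PartitionError(f"class {cls!r} has fewer than 2 samples")
        n_train = _train_size(idx.size, train_fraction)
        n_train = min(max(n_train, 1), idx.size - 1)  # keep both sides non-empty
        perm = rng.permutation(idx)
        train.extend(perm[:n_train].tolist())
        test.extend(perm[n_train:].tolist())
    return SplitResult(np.sort(train), np.sort(test))


def joint_distance_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Normalized joint distance dx/max(dx) + dy/max(dy)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.asarray(y).size:
        X = X.T  # allow 1-D predictor passed as a row
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise PartitionError("SPXY needs at least 3 samples")
    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    mx, my = dx.max(), dy.max()
    if mx == 0 and my == 0:
        raise PartitionError("all pairwise x- and y-distances are zero")
    d = np.zeros((n, n))
    if mx > 0:
        d += dx / mx
    if my > 0:
        d += dy / my
    return d


def spxy_split(X: np.ndarray, y: np.ndarray, train_fraction: float) -> SplitResult:
    """Deterministic SPXY selection of a calibration (train) set.

    The first two picks are the pair at maximum joint distance; subsequent
    picks maximize the minimum joint distance to the already-selected set.
    """
    if not (0.0 < train_fraction < 1.0):
        raise PartitionError("train_fraction must lie in (0, 1)")
    d = joint_distance_matrix(X, y)
    n = d.shape[0]
    n_train = _train_size(n, train_fraction)
    n_train = min(max(n_train, 2), n - 1)

    # seed pair: argmax over upper triangle, row-major -> lowest-index tie-break
    iu = np.triu_indices(n, k=1)
    best = int(np.argmax(d[iu]))
    selected = [int(iu[0][best]), int(iu[1][best])]

    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    min_dist = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_train:
        cand = np.flatnonzero(remaining)
        pick = int(cand[np.argmax(min_dist[cand])])  # argmax -> lowest index on ties
        selected.append(pick)
        remaining[pick] = False
        min_dist = np.minimum(min_dist, d[pick])

    test = np.flatnonzero(remaining)
    return SplitResult(np.sort(selected), np.sort(test))
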