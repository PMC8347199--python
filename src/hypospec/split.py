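"""Deterministic duplex training/test splitting.

The duplex algorithm builds two equally representative subsets: the two
mutually farthest samples seed the training set, the two farthest remaining
seed the test set, and the remaining samples are assigned alternately to
each set, each time picking the sample farthest (largest minimum distance)
from the set being grown.  Once the test set reaches its quota the rest go
to training (and vice versa).  There is no randomness anywhere; ties are
broken toward the lowest row index.

Distances are Euclidean on whatever representation the caller provides —
here, the preprocessed (baseline-corrected, cropped, normalized) spectra.
``stratified_duplex`` runs duplex independently inside each class, as the
splitting of the spectral dataset into 5600 training and 1809 test spectra
was done per class.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np

from .datatypes import SpectralDataset

__all__ = ["SplitAssignment", "duplex", "stratified_duplex"]


@dataclass
class SplitAssignment:
    train_rows: np.ndarray
    test_rows: np.ndarray
    per_class_counts: dict

    def __post_init__(self) -> None:
        self.train_rows = np.asarray(self.train_rows, dtype=int)
        self.test_rows = np.asarray(self.test_rows, dtype=int)
        if np.intersect1d(self.train_rows, self.test_rows).size:
            raise ValueError("train and test rows overlap")

    @property
    def n_train(self) -> int:
        return int(self.train_rows.size)

    @property
    def n_test(self) -> int:
        return int(self.test_rows.size)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "train_rows": self.train_rows.tolist(),
                    "test_rows": self.test_rows.tolist(),
                    "per_class_counts": {
                        k: list(v) for k, v in self.per_class_counts.items()
                    },
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "SplitAssignment":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            train_rows=np.array(d["train_rows"], dtype=int),
            test_rows=np.array(d["test_rows"], dtype=int),
            per_class_counts={k: tuple(v) for k, v in d["per_class_counts"].items()},
        )


def _farthest_pair(X: np.ndarray, sq_norms: np.ndarray, pool: np.ndarray):
    """Mutually farthest pair within ``pool``; first (lexicographic) pair on ties."""
    best = (-np.inf, -1, -1)
    Xp = X[pool]
    np_sq = sq_norms[pool]
    chunk = max(1, int(2**22 // max(1, Xp.shape[0])))
    for s in range(0, Xp.shape[0], chunk):
        e = min(s + chunk, Xp.shape[0])
        d2 = np_sq[s:e, None] + np_sq[None, :] - 2.0 * (Xp[s:e] @ Xp.T)
        # mask the lower triangle incl. diagonal so ties resolve to the
        # lexicographically first (i, j) with i < j
        cols = np.arange(Xp.shape[0])
        mask = cols[None, :] <= np.arange(s, e)[:, None]
        d2[mask] = -np.inf
        flat = int(np.argmax(d2))
        i_loc, j_loc = divmod(flat, Xp.shape[0])
        val = float(d2[i_loc, j_loc])
        if val > best[0]:
            best = (val, s + i_loc, j_loc)
    _, i, j = best
    return int(pool[i]), int(pool[j])


def duplex(X: np.ndarray, n_train: int, metric: str = "euclidean") -> SplitAssignment:
    """Classic duplex partition of the rows of X into train and test sets."""
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 4:
        raise ValueError("duplex requires at least 4 rows")
    if not (2 <= n_train <= n - 2):
        raise ValueError(f"n_train must lie in [2, {n - 2}], got {n_train}")
    n_test = n - n_train

    sq = np.einsum("ij,ij->i", X, X)

    remaining = np.ones(n, dtype=bool)
    train: list[int] = []
    test: list[int] = []
    # min squared distance from each remaining point to each set
    dmin = {"train": np.full(n, np.inf), "test": np.full(n, np.inf)}

    def add(which: list[int], key: str, idx: int) -> None:
        which.append(idx)
        remaining[idx] = False
        d2 = sq + sq[idx] - 2.0 * (X @ X[idx])
        np.minimum(dmin[key], d2, out=dmin[key])

    i0, j0 = _farthest_pair(X, sq, np.flatnonzero(remaining))
    add(train, "train", i0)
    add(train, "train", j0)
    i1, j1 = _farthest_pair(X, sq, np.flatnonzero(remaining))
    add(test, "test", i1)
    add(test, "test", j1)

    turn = "train"
    while remaining.any():
        if len(train) >= n_train:
            for idx in np.flatnonzero(remaining):
                add(test, "test", int(idx))
            break
        if len(test) >= n_test:
            for idx in np.flatnonzero(remaining):
                add(train, "train", int(idx))
            break
        key = turn
        cand = np.where(remaining, dmin[key], -np.inf)
        idx = int(np.argmax(cand))  # ties -> lowest index
        add(train if key == "train" else test, key, idx)
        turn = "test" if turn == "train" else "train"

    return SplitAssignment(
        train_rows=np.sort(np.array(train, dtype=int)),
        test_rows=np.sort(np.array(test, dtype=int)),
        per_class_counts={"all": (len(train), len(test))},
    )


def stratified_duplex(
    dataset: SpectralDataset, train_fraction: float = 5600 / 7409
) -> SplitAssignment:
    """Duplex applied independently to each class, merged on original rows.

    The default training fraction is 5600/7409 ~ 0.756, the realized split
    of the emulated study.  Per-class training counts are
    round(fraction x class size).
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    train_all: list[np.ndarray] = []
    test_all: list[np.ndarray] = []
    counts: dict = {}
    for cls in dataset.classes:
        rows = dataset.rows_for_class(cls)
        if rows.size < 4:
            raise ValueError(
                f"class {cls!r} has only {rows.size} rows; duplex needs >= 4"
            )
        n_train = int(round(train_fraction * rows.size))
        n_train = min(max(n_train, 2), rows.size - 2)
        sub = duplex(dataset.matrix[rows], n_train)
        train_all.append(rows[sub.train_rows])
        test_all.append(rows[sub.test_rows])
        counts[cls] = (sub.n_train, sub.n_test)
    return SplitAssignment(
        train_rows=np.sort(np.concatenate(train_all)),
        test_rows=np.sort(np.concatenate(test_all)),
        per_class_counts=counts,
    )
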