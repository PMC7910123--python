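"""First-principles SMOTEENN for the training split.

SMOTE oversamples each minority class by convex interpolation between a
class member and one of its k nearest same-class neighbours; ENN then
removes every sample (any class) whose k-NN majority label disagrees with
its own.  Resampling operates on whole per-patient flattened trajectories
so each synthetic sample is a coherent patient, and is only ever applied to
the training split (the pipeline enforces this).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureTable", "smote", "enn", "smoteenn"]


@dataclass
class FeatureTable:
    """Flat per-patient feature matrix with labels and provenance flags."""

    X: np.ndarray                 # (n, d), no missing entries
    y: np.ndarray                 # (n,) integer class codes
    synthetic: np.ndarray = field(default=None)  # (n,) bool, True = SMOTE sample

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be (n, d) with matching labels")
        if np.isnan(self.X).any():
            raise ValueError("feature table must be fully observed (impute first)")
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.y), dtype=bool)

    def __len__(self) -> int:
        return len(self.y)


def _target_counts(y: np.ndarray,
                   sampling_strategy: dict[int, int] | str) -> dict[int, int]:
    classes, counts = np.unique(y, return_counts=True)
    have = dict(zip(classes.tolist(), counts.tolist()))
    if sampling_strategy == "equalize":
        majority = max(have.values())
        return {c: majority for c in have}
    return {c: max(n, have.get(c, 0)) for c, n in sampling_strategy.items()}


def smote(table: FeatureTable, k_neighbors: int = 5,
          sampling_strategy: dict[int, int] | str = "equalize",
          seed: int = 0) -> FeatureTable:
    """Synthetic minority oversampling.

    Each synthetic sample is ``x_i + u * (x_nn - x_i)`` with ``u`` uniform
    on (0, 1) and ``x_nn`` one of the ``k_neighbors`` nearest same-class
    neighbours of ``x_i`` (Euclidean).  Original rows are preserved
    verbatim and synthetic rows carry a provenance flag.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    rng = np.random.default_rng(seed)
    targets = _target_counts(table.y, sampling_strategy)
    new_X, new_y = [table.X], [table.y]
    new_flag = [table.synthetic]
    for cls in sorted(targets):
        members = np.flatnonzero(table.y == cls)
        n_extra = targets[cls] - len(members)
        if n_extra <= 0:
            continue
        if len(members) < 2:
            raise ValueError(
                f"class {cls} has {len(members)} member(s); SMOTE needs >= 2")
        k = k_neighbors
        if k > len(members) - 1:
            k = len(members) - 1
            warnings.warn(f"class {cls}: k_neighbors reduced to {k} "
                          "(not enough same-class neighbours)", stacklevel=2)
        Xc = table.X[members]
        # pairwise distances within the class; self excluded via argsort[1:]
        d2 = _sq_dists(Xc, Xc)
        order = np.argsort(d2, axis=1, kind="stable")
        nn = order[:, 1:k + 1]
        base = rng.integers(0, len(members), n_extra)
        pick = nn[base, rng.integers(0, k, n_extra)]
        u = rng.random((n_extra, 1))
        synth = Xc[base] + u * (Xc[pick] - Xc[base])
        new_X.append(synth)
        new_y.append(np.full(n_extra, cls))
        new_flag.append(np.ones(n_extra, dtype=bool))
    return FeatureTable(np.vstack(new_X), np.concatenate(new_y),
                        np.concatenate(new_flag))


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances without the (n, m, d) broadcast."""
    d2 = (A * A).sum(1)[:, None] + (B * B).sum(1)[None, :] - 2.0 * (A @ B.T)
    return np.maximum(d2, 0.0)


def enn(table: FeatureTable, k: int = 3) -> FeatureTable:
    """Edited nearest neighbours cleaning (single pass, all classes).

    A sample is removed when the majority label among its k nearest
    neighbours (self excluded) disagrees with its own label; vote ties are
    treated as disagreement and removed.
    """
    n = len(table)
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    keep = np.ones(n, dtype=bool)
    classes = np.unique(table.y)
    chunk = max(1, int(2e8) // (8 * n))  # bound the distance-block memory
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = _sq_dists(table.X[start:stop], table.X)
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf
        part = np.argpartition(d2, k - 1, axis=1)[:, :k]
        votes = table.y[part]  # (chunk, k); order within k irrelevant to the vote
        counts = np.stack([(votes == c).sum(axis=1) for c in classes], axis=1)
        top = counts.max(axis=1)
        unique_winner = (counts == top[:, None]).sum(axis=1) == 1
        own = np.searchsorted(classes, table.y[start:stop])
        agrees = counts[np.arange(stop - start), own] == top
        keep[start:stop] = unique_winner & agrees
    return FeatureTable(table.X[keep], table.y[keep], table.synthetic[keep])


def smoteenn(table: FeatureTable, k_smote: int = 5, k_enn: int = 3,
             sampling_strategy: dict[int, int] | str = "equalize",
             seed: int = 0) -> FeatureTable:
    """SMOTE oversampling followed by ENN cleaning; deterministic per seed."""
    return enn(smote(table, k_smote, sampling_strategy, seed), k_enn)
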