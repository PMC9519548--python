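"""Kennard-Stone ordering and the stratified train/validation/test split.

Kennard-Stone picks, deterministically, the pair of samples at maximum
Euclidean distance, then repeatedly the sample whose minimum distance to the
already-selected set is largest.  Early picks therefore cover the extremes of
each class; consumed train -> validation -> test, the training set contains
the most mutually distant samples and the later, more central picks populate
the evaluation sets.

The split is stratified: the ordering runs within each class, and per-class
role quotas are the largest-remainder rounding of the requested fractions
(class sizes 83/147 with fractions 162/34/34 over 230 give exactly
(59, 12, 12) and (103, 22, 22)).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .core import EEMCube, SampleTable

ROLES = ("train", "validation", "test")


def kennard_stone_order(X: np.ndarray) -> np.ndarray:
    """Deterministic Kennard-Stone ordering of the rows of ``X``.

    The first two indices are a pair at maximum Euclidean distance (the
    lexicographically smallest such pair under ties); each subsequent index
    maximizes the minimum distance to all already-selected rows, ties broken
    by lowest index.  Returns a permutation of ``0..n-1``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries")
    n = X.shape[0]
    D = squareform(pdist(X))
    # lexicographically smallest maximizing pair (i < j)
    iu = np.triu_indices(n, k=1)
    flat = D[iu]
    best = int(np.argmax(flat))  # argmax returns the first maximizer: row-major = lexicographic
    first, second = int(iu[0][best]), int(iu[1][best])

    order = [first, second]
    selected = np.zeros(n, dtype=bool)
    selected[[first, second]] = True
    min_dist = np.minimum(D[first], D[second])
    for _ in range(n - 2):
        min_dist[selected] = -np.inf
        nxt = int(np.argmax(min_dist))  # first maximizer = lowest index
        order.append(nxt)
        selected[nxt] = True
        min_dist = np.minimum(min_dist, D[nxt])
    return np.array(order)


def largest_remainder_quotas(n: int, fractions: tuple[float, ...]) -> tuple[int, ...]:
    """Apportion ``n`` items to roles by the largest-remainder method.

    Ties in the fractional parts are resolved in role order
    (train before validation before test).
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    exact = fr * n
    base = np.floor(exact).astype(int)
    leftover = n - int(base.sum())
    # stable sort: equal remainders keep role order
    for idx in np.argsort(-(exact - base), kind="stable")[:leftover]:
        base[idx] += 1
    return tuple(int(q) for q in base)


@dataclass
class SplitAssignment:
    """Role and within-class Kennard-Stone selection rank per sample."""

    sample_id: list[str]
    label: list[str]
    role: list[str]
    selection_rank: list[int]  # 0-based rank at which the sample was picked within its class

    def indices(self, role: str) -> np.ndarray:
        """Positional indices (into the original cube) of samples with ``role``."""
        return np.array([i for i, r in enumerate(self.role) if r == role], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "label": self.label,
                "role": self.role,
                "selection_rank": self.selection_rank,
            }
        )

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load_tsv(cls, path: str | Path) -> "SplitAssignment":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        return cls(
            list(df["sample_id"]),
            list(df["label"]),
            list(df["role"]),
            [int(r) for r in df["selection_rank"]],
        )


def stratified_split(
    cube: EEMCube,
    table: SampleTable,
    fractions: tuple[float, float, float] = (162 / 230, 34 / 230, 34 / 230),
    counts: dict[str, tuple[int, int, int]] | None = None,
) -> SplitAssignment:
    """Per-class Kennard-Stone assignment to train/validation/test.

    Within each class the Kennard-Stone ordering is computed on the unfolded
    sample vectors; the first ``quota_train`` picks become training samples,
    the next ``quota_validation`` the validation set, and the remainder the
    test set.  Quotas default to largest-remainder rounding of ``fractions``
    times the class size; ``counts`` may instead fix explicit per-class
    ``(train, validation, test)`` quotas (keyed by label).

    The module is fully deterministic: no randomness anywhere.
    """
    if len(table) != cube.n_samples:
        raise ValueError("table length does not match cube")
    if not cube.is_complete:
        raise ValueError("split requires a complete (filled) cube")
    X = cube.unfold()
    labels = np.array(table.label)

    role = [""] * len(table)
    rank = [0] * len(table)
    for cls in sorted(set(table.label)):
        idx = np.nonzero(labels == cls)[0]
        if counts is not None:
            quotas = counts[cls]
            if sum(quotas) != idx.size:
                raise ValueError(f"counts for class {cls} sum to {sum(quotas)}, have {idx.size} samples")
        else:
            if idx.size < 3:
                raise ValueError(f"class {cls} has {idx.size} samples; need >= 3")
            quotas = largest_remainder_quotas(idx.size, fractions)
            if min(quotas) == 0:
                raise ValueError(f"class {cls}: zero quota for some role with fractions {fractions}")
        order = kennard_stone_order(X[idx])
        bounds = np.cumsum(quotas)
        for r, pos in enumerate(order):
            orig = int(idx[pos])
            rank[orig] = r
            role[orig] = ROLES[int(np.searchsorted(bounds, r, side="right"))]
    return SplitAssignment(list(table.sample_id), list(table.label), role, rank)
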