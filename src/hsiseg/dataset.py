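"""Pixel datasets, fruit-level splitting and class balancing.

Every labeled fruit pixel is one sample: its reflectance spectrum, its
class (healthy or defect) and the fruit it came from.  Train/test
splitting happens at the level of whole fruits so that no fruit
contributes pixels to both partitions, and the partition is chosen to
balance the defect-pixel proportion between the two sides.  The healthy
class is randomly under-sampled in the training set to match the defect
count, since defect pixels are typically outnumbered roughly five to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PixelDataset",
    "split_fruitwise",
    "undersample_healthy",
    "compute_reference_spectra",
    "ReferenceSpectra",
]

LABEL_HEALTHY = 0
LABEL_DEFECT = 1


@dataclass
class PixelDataset:
    """Spectra matrix with labels and fruit-of-origin indices."""

    X: np.ndarray          # (N, B) reflectance spectra
    y: np.ndarray          # (N,) {0 healthy, 1 defect}
    fruit: np.ndarray      # (N,) fruit index per pixel

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.fruit = np.asarray(self.fruit, dtype=np.int64)
        if self.X.ndim != 2 or self.X.shape[0] == 0:
            raise ValueError("spectra matrix must be (N, B) with N > 0")
        if self.y.shape != (self.X.shape[0],) or self.fruit.shape != self.y.shape:
            raise ValueError("labels and fruit indices must match N")
        if not np.isin(self.y, [LABEL_HEALTHY, LABEL_DEFECT]).all():
            raise ValueError("labels must be 0 (healthy) or 1 (defect)")

    @property
    def n_pixels(self) -> int:
        return self.X.shape[0]

    @property
    def class_counts(self) -> tuple[int, int]:
        return int((self.y == LABEL_HEALTHY).sum()), int((self.y == LABEL_DEFECT).sum())

    def subset(self, idx: np.ndarray) -> "PixelDataset":
        return PixelDataset(self.X[idx], self.y[idx], self.fruit[idx])

    def select_fruits(self, fruits) -> "PixelDataset":
        return self.subset(np.isin(self.fruit, np.asarray(list(fruits))))


def _label_array(obj) -> np.ndarray:
    """Accept a bare label map or a (cube, label map) pair."""
    if isinstance(obj, tuple):
        obj = obj[1]
    return np.asarray(obj)


def split_fruitwise(objects, train_fraction: float = 0.4, seed: int = 0,
                    n_candidates: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Whole-fruit train/test partition balancing defect proportions.

    ``objects`` is a sequence of per-fruit label maps (values {0, 1, 2})
    or (cube, label map) pairs.  Among ``n_candidates`` seeded random
    partitions with ``round(train_fraction * n)`` training fruits, the one
    minimizing the difference in defect-pixel proportion between the two
    partitions is returned as ``(train_indices, test_indices)``.
    """
    n = len(objects)
    if n < 2:
        raise ValueError("need at least two fruits to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError("split leaves an empty partition")

    defect = np.empty(n)
    total = np.empty(n)
    for k, obj in enumerate(objects):
        lab = _label_array(obj)
        defect[k] = np.count_nonzero(lab == 2)
        total[k] = np.count_nonzero(lab != 0)
    if total.sum() == 0:
        raise ValueError("objects contain no fruit pixels")

    rng = np.random.default_rng(seed)
    best_gap = np.inf
    best: np.ndarray | None = None
    for _ in range(max(n_candidates, 1)):
        perm = rng.permutation(n)
        tr = perm[:n_train]
        te = perm[n_train:]
        p_tr = defect[tr].sum() / max(total[tr].sum(), 1.0)
        p_te = defect[te].sum() / max(total[te].sum(), 1.0)
        gap = abs(p_tr - p_te)
        if gap < best_gap:
            best_gap = gap
            best = perm
    assert best is not None
    return np.sort(best[:n_train]), np.sort(best[n_train:])


def undersample_healthy(data: PixelDataset, seed: int = 0) -> PixelDataset:
    """Randomly drop healthy pixels until both classes are equal in size.

    Defect pixels are never removed; sampling is without replacement and
    fixed by ``seed``.  With healthy count already at or below the defect
    count the dataset is returned unchanged.
    """
    n_healthy, n_defect = data.class_counts
    if n_healthy == 0 or n_defect == 0:
        raise ValueError("both classes must be present for under-sampling")
    if n_healthy <= n_defect:
        return data
    rng = np.random.default_rng(seed)
    healthy_idx = np.flatnonzero(data.y == LABEL_HEALTHY)
    keep_healthy = rng.choice(healthy_idx, size=n_defect, replace=False)
    keep = np.sort(np.concatenate([keep_healthy,
                                   np.flatnonzero(data.y == LABEL_DEFECT)]))
    return data.subset(keep)


@dataclass
class ReferenceSpectra:
    """Class-mean training spectra with unit-norm copies."""

    healthy: np.ndarray
    defect: np.ndarray

    @property
    def healthy_unit(self) -> np.ndarray:
        return self.healthy / np.linalg.norm(self.healthy)

    @property
    def defect_unit(self) -> np.ndarray:
        return self.defect / np.linalg.norm(self.defect)


def compute_reference_spectra(train: PixelDataset) -> ReferenceSpectra:
    """Per-class mean spectrum over the training pixels."""
    n_healthy, n_defect = train.class_counts
    if n_healthy == 0 or n_defect == 0:
        raise ValueError("both classes must be present to form references")
    return ReferenceSpectra(
        healthy=train.X[train.y == LABEL_HEALTHY].mean(axis=0),
        defect=train.X[train.y == LABEL_DEFECT].mean(axis=0),
    )
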