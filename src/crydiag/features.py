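"""Feature tables: fusion, z-score normalisation and data splitting.

A :class:`FeatureTable` holds one row per cry segment with its class
label and subject id, and per-column feature names and modality tags
(``gfcc`` or ``hr``). Modalities are fused by plain concatenation of
columns; the fused vector is 13 GFCC + 4 HR = 17 elements. Standard
(z-score) normalisation is fitted on training rows only and applied
unchanged to validation/test rows, avoiding information leakage.

The 55/15/30 train/validation/test split is stratified by class by
default and reproducible from its seed. Because one newborn contributes
several segments, a subject-grouped split mode is provided as well;
the per-segment split mirrors the original random-per-sample protocol
and is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "Normalizer",
    "SplitSpec",
    "fuse",
    "fuse_tables",
    "fit_normalizer",
    "split_dataset",
]


@dataclass(frozen=True)
class FeatureTable:
    matrix: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    feature_names: tuple
    modality: tuple

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if not (m.shape[0] == len(self.labels) == len(self.subject_ids)):
            raise ValueError("row, label and subject counts differ")
        if m.shape[1] != len(self.feature_names) or m.shape[1] != len(self.modality):
            raise ValueError("column metadata length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", np.asarray(self.labels))
        object.__setattr__(self, "subject_ids", np.asarray(self.subject_ids))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "modality", tuple(self.modality))

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def rows(self, index) -> "FeatureTable":
        index = np.asarray(index)
        return FeatureTable(
            self.matrix[index], self.labels[index], self.subject_ids[index],
            self.feature_names, self.modality,
        )

    def select_modality(self, name: str) -> "FeatureTable":
        cols = [i for i, m in enumerate(self.modality) if m == name]
        if not cols:
            raise ValueError(f"no columns with modality {name!r}")
        return FeatureTable(
            self.matrix[:, cols], self.labels, self.subject_ids,
            tuple(self.feature_names[i] for i in cols),
            tuple(self.modality[i] for i in cols),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.feature_names))
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(0, "class_label", self.labels)
        return df


def fuse(gfcc_vec, hr_vec, strict: bool = True) -> np.ndarray:
    """Concatenate one 13-element GFCC vector with one 4-element HR vector."""
    gfcc_vec = np.asarray(gfcc_vec, dtype=np.float64).ravel()
    hr_vec = np.asarray(hr_vec, dtype=np.float64).ravel()
    if strict and (gfcc_vec.size != 13 or hr_vec.size != 4):
        raise ValueError(
            f"expected 13 GFCC + 4 HR elements, got {gfcc_vec.size} + {hr_vec.size}"
        )
    return np.concatenate([gfcc_vec, hr_vec])


def fuse_tables(gfcc_table: FeatureTable, hr_table: FeatureTable) -> FeatureTable:
    """Column-concatenate two per-modality tables over identical rows."""
    if not np.array_equal(gfcc_table.labels, hr_table.labels) or not np.array_equal(
        gfcc_table.subject_ids, hr_table.subject_ids
    ):
        raise ValueError("tables describe different rows")
    return FeatureTable(
        np.hstack([gfcc_table.matrix, hr_table.matrix]),
        gfcc_table.labels,
        gfcc_table.subject_ids,
        gfcc_table.feature_names + hr_table.feature_names,
        gfcc_table.modality + hr_table.modality,
    )


@dataclass(frozen=True)
class Normalizer:
    """Per-feature z-score model (std floored at 1e-12)."""

    mean: np.ndarray
    std: np.ndarray
    fitted_on: int

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=np.float64) - self.mean) / self.std

    def inverse_transform(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix, dtype=np.float64) * self.std + self.mean

    def transform_table(self, table: FeatureTable) -> FeatureTable:
        return FeatureTable(
            self.transform(table.matrix), table.labels, table.subject_ids,
            table.feature_names, table.modality,
        )


def fit_normalizer(train_matrix, std_floor: float = 1e-12) -> Normalizer:
    """Fit per-column mean/std on training rows only."""
    m = np.atleast_2d(np.asarray(train_matrix, dtype=np.float64))
    if m.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit a normalizer")
    std = np.maximum(m.std(axis=0, ddof=0), std_floor)
    return Normalizer(mean=m.mean(axis=0), std=std, fitted_on=m.shape[0])


@dataclass(frozen=True)
class SplitSpec:
    train_frac: float = 0.55
    val_frac: float = 0.15
    test_frac: float = 0.30
    seed: int = 0
    stratified: bool = True
    by_subject: bool = False

    def __post_init__(self):
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train_frac, self.val_frac, self.test_frac) <= 0:
            raise ValueError("split fractions must be positive")


def _partition_sizes(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    n_train = int(round(n * spec.train_frac))
    n_val = int(round(n * spec.val_frac))
    n_test = n - n_train - n_val
    if n_test < 0:  # rounding overshoot; shave the largest part
        n_train += n_test
        n_test = 0
    return n_train, n_val, n_test


def _split_indices(indices: np.ndarray, spec: SplitSpec, rng) -> tuple:
    perm = rng.permutation(indices)
    n_train, n_val, _ = _partition_sizes(perm.size, spec)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def split_dataset(table: FeatureTable, spec: SplitSpec = SplitSpec()):
    """Disjoint train/val/test row-index arrays covering the table.

    Stratified mode splits each class independently so per-class counts
    stay within one row of exact proportionality. Subject-grouped mode
    partitions subjects instead of rows, keeping all of a newborn's
    segments in one partition.
    """
    n = table.n_rows
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(spec.seed)

    if spec.by_subject:
        subjects = pd.unique(table.subject_ids)
        tr_s, va_s, te_s = _split_indices(np.asarray(subjects), spec, rng)
        row_of = lambda chosen: np.flatnonzero(np.isin(table.subject_ids, chosen))
        return row_of(tr_s), row_of(va_s), row_of(te_s)

    if not spec.stratified:
        return _split_indices(np.arange(n), spec, rng)

    classes = list(pd.unique(table.labels))
    class_idx = {c: np.flatnonzero(table.labels == c) for c in classes}
    targets = _partition_sizes(n, spec)
    # per-class allocation: floors of the proportional ideals, then the
    # remaining rows assigned by largest fractional remainder subject to
    # per-class and per-partition budgets (keeps both exact)
    ideal = {c: [t * class_idx[c].size / n for t in targets] for c in classes}
    counts = {c: [int(np.floor(v)) for v in ideal[c]] for c in classes}
    col_left = [t - sum(counts[c][p] for c in classes) for p, t in enumerate(targets)]
    row_left = {c: class_idx[c].size - sum(counts[c]) for c in classes}
    cells = sorted(
        ((c, p) for c in classes for p in range(3)),
        key=lambda cp: ideal[cp[0]][cp[1]] - np.floor(ideal[cp[0]][cp[1]]),
        reverse=True,
    )
    for c, p in cells:
        if row_left[c] > 0 and col_left[p] > 0:
            counts[c][p] += 1
            row_left[c] -= 1
            col_left[p] -= 1

    parts = [[], [], []]
    for c in classes:
        perm = rng.permutation(class_idx[c])
        n_tr, n_va, _ = counts[c]
        parts[0].append(perm[:n_tr])
        parts[1].append(perm[n_tr : n_tr + n_va])
        parts[2].append(perm[n_tr + n_va :])
    return tuple(np.sort(np.concatenate(p)) for p in parts)
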