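"""Deterministic per-class Kennard-Stone train/test partitioning.

The Kennard-Stone (KS) algorithm picks a representative, space-filling
training subset: it starts from the two most distant samples and greedily
adds the sample whose minimum Euclidean distance to the already-selected
set is largest (maximin).  Here KS runs independently within each class on
that class's SUM-PCA super scores, selecting ceil(fraction * n_class)
training samples; the remainder form the test set.  The assignment is
seedless and shared by every block and by the AFP benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import FeatureTable
from .preprocess import autoscale_fit
from .multiblock import sum_pca


@dataclass
class SplitAssignment:
    """Per-sample train/test membership with the KS selection order."""

    assignment: pd.DataFrame   # index sample_id; columns class, split, ks_rank
    fused_components: int
    fraction: float

    @property
    def train_ids(self) -> pd.Index:
        return self.assignment.index[self.assignment["split"] == "train"]

    @property
    def test_ids(self) -> pd.Index:
        return self.assignment.index[self.assignment["split"] == "test"]

    def class_counts(self) -> pd.DataFrame:
        return (self.assignment.groupby(["class", "split"], observed=True)
                .size().unstack(fill_value=0))


def kennard_stone(points: np.ndarray, k: int) -> list[int]:
    """Ordered KS selection of ``k`` row indices from ``points``.

    Classic maximin: the first two picks are the farthest pair; each
    subsequent pick maximises the minimum distance to the selected set.
    All ties break toward the lowest sample index, so the output is
    deterministic even with duplicate points.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    # pairwise distances; n is small (per-class), O(n^2) memory is fine
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(n, 1)
    flat = D[iu]
    best = np.argmax(flat)  # argmax returns first max -> lowest (i, j) pair
    i, j = iu[0][best], iu[1][best]
    selected = [int(i), int(j)]
    min_dist = np.minimum(D[i], D[j])
    remaining = np.ones(n, dtype=bool)
    remaining[[i, j]] = False
    while len(selected) < k:
        cand = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(cand))  # first max -> lowest index on ties
        selected.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, D[nxt])
    return selected


def split_per_class(tables: Mapping[str, FeatureTable] | Sequence[FeatureTable],
                    fused_components: int = 3, fraction: float = 0.7
                    ) -> SplitAssignment:
    """KS split on per-class SUM-PCA super scores, one shared assignment.

    For each class independently: the class's rows are taken from every
    preprocessed block, each block is autoscaled within the class, SUM-PCA
    is fit, and KS selects ceil(fraction * n_class) training samples on the
    first ``fused_components`` super-score columns.  QC pools are excluded.
    """
    if isinstance(tables, Mapping):
        blocks = list(tables.values())
    else:
        blocks = list(tables)
    if not blocks:
        raise ValueError("no blocks given")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    meta = blocks[0].sample_meta
    study_ids = meta.index[blocks[0].study_mask]
    for b in blocks[1:]:
        other = b.sample_meta.index[b.study_mask]
        if not study_ids.equals(other):
            diff = set(study_ids).symmetric_difference(other)
            raise ValueError(f"blocks disagree on study samples: {sorted(diff)[:6]}")
    groups = meta.loc[study_ids, "group"]

    rows = []
    for cls in pd.unique(groups):
        ids = study_ids[groups == cls]
        n_cls = len(ids)
        if n_cls < 3:
            raise ValueError(f"class {cls!r} has only {n_cls} samples (< 3)")
        mats = []
        for b in blocks:
            Xc = b.abundances.loc[ids]
            scaler = autoscale_fit(Xc)
            mats.append(scaler.transform(Xc).to_numpy())
        model = sum_pca(mats)
        d = min(fused_components, model.super_scores.shape[1])
        T = model.super_scores[:, :d]
        n_train = math.ceil(fraction * n_cls)
        if n_train >= n_cls:
            order = list(range(n_cls))  # fraction 1.0: everything is train
        elif n_train < 2:
            order = [0]
        else:
            order = kennard_stone(T, n_train)
        split = np.full(n_cls, "test", dtype=object)
        rank = np.full(n_cls, -1)
        for r, idx in enumerate(order[:n_train]):
            split[idx] = "train"
            rank[idx] = r
        rows.append(pd.DataFrame({"class": cls, "split": split,
                                  "ks_rank": rank}, index=ids))
    assignment = pd.concat(rows).loc[study_ids]
    return SplitAssignment(assignment=assignment,
                           fused_components=fused_components,
                           fraction=fraction)
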