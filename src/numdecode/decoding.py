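"""Chunked leave-k-out cross-validated decoding and permutation nulls.

Trials are grouped into "chunks" -- balanced sets holding exactly one trial
per numerosity -- and cross-validation leaves ``k_out`` chunks out per fold
(3 by default), training on the rest.  All C(m, k_out) chunk combinations
are used when feasible; above ``max_folds`` a seeded uniform subsample of
fold combinations keeps runs tractable.  Confusion counts are pooled over
folds; "decoding accuracy" is the mean of the confusion-matrix diagonal,
with chance at 1/4 for the four numerosities.  The label-permutation null
scrambles training labels (within the training partition) each iteration
and should center on chance for an unbiased decoder.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import NUMEROSITIES, PatternDataset
from .lda import ShrinkageLDA


@dataclass(frozen=True)
class ChunkAssignment:
    """Chunk id per trial of a (filtered) dataset; each chunk holds exactly
    one trial per class."""

    chunk_ids: np.ndarray
    classes: np.ndarray
    n_chunks: int


@dataclass
class ConfusionMatrix:
    """Target-by-prediction rate matrix pooled over folds."""

    labels: np.ndarray
    counts: np.ndarray  # raw prediction counts, targets x predictions
    fold_accuracies: list[float] = field(default_factory=list)

    @property
    def n_test(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def rates(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        return self.counts / totals

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(np.diag(self.rates)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rates, index=self.labels, columns=self.labels)
        df.index.name = "target"
        df.columns.name = "predicted"
        return df


@dataclass(frozen=True)
class PermutationNull:
    """Null distribution of mean accuracy under scrambled training labels."""

    accuracies: np.ndarray
    seed: int | None
    chance: float = 0.25

    @property
    def n_perm(self) -> int:
        return self.accuracies.size

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def mean_deviation_from_chance(self) -> float:
        return self.mean - self.chance

    def p_value(self, observed: float) -> float:
        """Empirical one-sided p with the +1 correction."""
        return float(
            (1 + np.sum(self.accuracies >= observed)) / (1 + self.n_perm)
        )


def make_chunks(ds: PatternDataset, **condition) -> ChunkAssignment:
    """Group trials of a condition into complete one-per-class chunks.

    Chunks follow within-class presentation order: the i-th occurrence of
    each numerosity joins chunk i.  Requires equal trial counts per class.
    """
    sub = ds.select_trials(**condition) if condition else ds
    y = sub.labels["numerosity"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() != counts.max():
        raise ValueError(
            "unequal trial counts per numerosity: "
            f"{dict(zip(classes.tolist(), counts.tolist()))}"
        )
    chunk_ids = np.empty(len(y), dtype=int)
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        chunk_ids[idx] = np.arange(idx.size)
    return ChunkAssignment(chunk_ids=chunk_ids, classes=classes,
                           n_chunks=int(counts[0]))


def enumerate_folds(
    n_chunks: int,
    k_out: int = 3,
    max_folds: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """List (train_chunks, test_chunks) index pairs.

    Returns all C(n_chunks, k_out) combinations when that is at most
    ``max_folds``; otherwise a seeded uniform subsample of distinct
    combinations of size ``max_folds`` (without replacement).
    """
    if n_chunks <= k_out:
        raise ValueError(
            f"need more chunks ({n_chunks}) than left-out sets ({k_out})"
        )
    total = math.comb(n_chunks, k_out)
    all_chunks = np.arange(n_chunks)
    if max_folds is None or total <= max_folds:
        combos = [np.array(c) for c in
                  itertools.combinations(range(n_chunks), k_out)]
    else:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        if total <= 200_000:
            pool = list(itertools.combinations(range(n_chunks), k_out))
            pick = rng.choice(total, size=max_folds, replace=False)
            combos = [np.array(pool[i]) for i in sorted(pick)]
        else:  # draw distinct combinations directly
            seen: set[tuple[int, ...]] = set()
            while len(seen) < max_folds:
                c = tuple(sorted(rng.choice(n_chunks, size=k_out,
                                            replace=False).tolist()))
                seen.add(c)
            combos = [np.array(c) for c in sorted(seen)]
    folds = []
    for test in combos:
        train = np.setdiff1d(all_chunks, test)
        folds.append((train, test))
    return folds


def _run_cv(
    X: np.ndarray,
    y: np.ndarray,
    chunk_ids: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    classes: np.ndarray,
    shrinkage: float,
    permute_rng: np.random.Generator | None = None,
) -> ConfusionMatrix:
    class_pos = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((classes.size, classes.size), dtype=float)
    fold_acc = []
    for train_chunks, test_chunks in folds:
        tr = np.isin(chunk_ids, train_chunks)
        te = np.isin(chunk_ids, test_chunks)
        if np.any(tr & te):
            raise AssertionError("train/test chunk overlap")
        y_tr = y[tr]
        if permute_rng is not None:
            y_tr = permute_rng.permutation(y_tr)
        model = ShrinkageLDA(shrinkage=shrinkage).fit(X[tr], y_tr)
        pred = model.predict(X[te])
        truth = y[te]
        for t, p in zip(truth, pred):
            counts[class_pos[t], class_pos[p]] += 1
        fold_acc.append(float(np.mean(pred == truth)))
    return ConfusionMatrix(labels=classes, counts=counts,
                           fold_accuracies=fold_acc)


def decode(
    ds: PatternDataset,
    condition: dict | None = None,
    shrinkage: float = 0.01,
    k_out: int = 3,
    max_folds: int = 2000,
    seed: int | None = None,
) -> ConfusionMatrix:
    """Cross-validated numerosity decoding within a condition.

    ``condition`` filters trials (e.g. ``{"format": "symbolic"}``); ``seed``
    only matters when the fold list is subsampled.
    """
    if not ds.normalized:
        raise ValueError("dataset must be z-normalized before decoding")
    sub = ds.select_trials(**(condition or {}))
    chunks = make_chunks(sub)
    folds = enumerate_folds(chunks.n_chunks, k_out=k_out,
                            max_folds=max_folds, seed=seed)
    y = sub.labels["numerosity"].to_numpy()
    return _run_cv(sub.betas, y, chunks.chunk_ids, folds, chunks.classes,
                   shrinkage)


def permutation_null(
    ds: PatternDataset,
    condition: dict | None = None,
    n_perm: int = 1000,
    seed: int | None = 0,
    shrinkage: float = 0.01,
    k_out: int = 3,
    max_folds: int = 2000,
) -> PermutationNull:
    """Label-permutation null of the cross-validated decoding accuracy.

    Each iteration scrambles the labels of the training partition in every
    fold (test labels stay intact for scoring) and records the pooled mean
    accuracy.  For an unbiased decoder the null centers on chance (25%).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not ds.normalized:
        raise ValueError("dataset must be z-normalized before decoding")
    sub = ds.select_trials(**(condition or {}))
    chunks = make_chunks(sub)
    rng = np.random.default_rng(seed)
    folds = enumerate_folds(chunks.n_chunks, k_out=k_out,
                            max_folds=max_folds, seed=rng)
    y = sub.labels["numerosity"].to_numpy()
    accs = np.empty(n_perm)
    for i in range(n_perm):
        cm = _run_cv(sub.betas, y, chunks.chunk_ids, folds, chunks.classes,
                     shrinkage, permute_rng=rng)
        accs[i] = cm.mean_accuracy
    return PermutationNull(accuracies=accs, seed=seed,
                           chance=1.0 / chunks.classes.size)
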