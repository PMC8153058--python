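"""Trial-pattern container and the two preprocessing steps of the pipeline.

A :class:`PatternDataset` holds a trials x voxels beta matrix plus per-trial
labels (numerosity, format, task, chunk).  Preprocessing consists of
trial-level spatial z-normalization (each trial pattern standardized across
voxels) and selection of the most active voxels by t-statistic, including
the combined-region variant that takes the top voxels from each parent
region to keep the combined region the same size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NUMEROSITIES = (2, 4, 6, 8)
FORMATS = ("nonsymbolic", "symbolic")
TASKS = ("identify", "compare")

LABEL_COLUMNS = ("numerosity", "format", "task", "chunk")


class DegenerateTrialError(ValueError):
    """A trial pattern is constant across voxels and cannot be z-scored."""


@dataclass
class PatternDataset:
    """Trials x voxels beta patterns with aligned per-trial labels.

    Parameters
    ----------
    betas
        2-D float array, one row per trial.
    labels
        DataFrame with one row per trial; must contain ``numerosity``,
        ``format`` and ``task`` columns (``chunk`` is added by the decoder
        when absent).
    participant_id, roi_name
        Provenance of the patterns.
    normalized
        Whether rows have been spatially z-scored.
    voxel_tstats
        Optional per-voxel activation t-statistics (all-trials-vs-baseline
        contrast, or the generator's signal-energy surrogate) used for
        feature selection.
    voxel_provenance
        One ``(roi_name, original_index)`` tuple per column, tracking where
        each voxel came from after selection / region combination.
    """

    betas: np.ndarray
    labels: pd.DataFrame
    participant_id: str = "sub-00"
    roi_name: str = "roi"
    normalized: bool = False
    voxel_tstats: np.ndarray | None = None
    voxel_provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 2:
            raise ValueError("betas must be a 2-D trials x voxels array")
        if len(self.labels) != self.betas.shape[0]:
            raise ValueError(
                f"label count ({len(self.labels)}) does not match trial "
                f"count ({self.betas.shape[0]})"
            )
        if not np.isfinite(self.betas).all():
            raise ValueError("betas contain non-finite values")
        self.labels = self.labels.reset_index(drop=True)
        if not self.voxel_provenance:
            self.voxel_provenance = [
                (self.roi_name, j) for j in range(self.betas.shape[1])
            ]

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def select_trials(self, **conditions) -> "PatternDataset":
        """Subset trials by label values, e.g. ``format="symbolic"``.

        A condition value may be a scalar or a collection of admissible
        values; conditions combine conjunctively.
        """
        mask = np.ones(self.n_trials, dtype=bool)
        for col, value in conditions.items():
            if value is None:
                continue
            if col not in self.labels.columns:
                raise KeyError(f"unknown label column {col!r}")
            if isinstance(value, (list, tuple, set, frozenset, np.ndarray)):
                mask &= self.labels[col].isin(list(value)).to_numpy()
            else:
                mask &= (self.labels[col] == value).to_numpy()
        return replace(
            self,
            betas=self.betas[mask],
            labels=self.labels.loc[mask],
            voxel_provenance=list(self.voxel_provenance),
        )


@dataclass(frozen=True)
class VoxelSelection:
    """Top-k voxel choice from an activation t-map."""

    tstats: np.ndarray
    selected_indices: np.ndarray
    k: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_indices)
        if len(idx) != self.k or len(np.unique(idx)) != self.k:
            raise ValueError("selection must contain exactly k unique indices")
        if not np.all(np.diff(idx) > 0):
            raise ValueError("selected indices must be sorted ascending")


def znormalize_trials(ds: PatternDataset, ddof: int = 1) -> PatternDataset:
    """Z-score each trial pattern across voxels (row-wise).

    Subtracts the across-voxel mean and divides by the across-voxel standard
    deviation within each trial, so every trial pattern has mean 0 and SD 1.
    The sample SD (``ddof=1``) is the default divisor.

    Raises
    ------
    DegenerateTrialError
        If any trial is constant across voxels.
    """
    if ds.n_voxels < 2:
        raise ValueError("z-normalization needs at least 2 voxels")
    mu = ds.betas.mean(axis=1, keepdims=True)
    sd = ds.betas.std(axis=1, ddof=ddof, keepdims=True)
    bad = np.flatnonzero(sd[:, 0] == 0)
    if bad.size:
        raise DegenerateTrialError(
            f"trial(s) {bad.tolist()} are constant across voxels; "
            "cannot z-normalize"
        )
    out = replace(
        ds,
        betas=(ds.betas - mu) / sd,
        normalized=True,
        voxel_provenance=list(ds.voxel_provenance),
    )
    return out


def select_voxels(tstats: np.ndarray, k: int) -> VoxelSelection:
    """Select the ``k`` voxels with the largest t-statistics.

    Ties at the selection threshold are broken in favor of the lowest voxel
    index.  Indices are returned sorted ascending.
    """
    t = np.asarray(tstats, dtype=float).ravel()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > t.size:
        raise ValueError(
            f"cannot select k={k} voxels from a {t.size}-voxel map"
        )
    # stable lexsort: primary key descending t, secondary ascending index
    order = np.lexsort((np.arange(t.size), -t))
    chosen = np.sort(order[:k])
    return VoxelSelection(tstats=t, selected_indices=chosen, k=k)


def apply_selection(ds: PatternDataset, sel: VoxelSelection) -> PatternDataset:
    """Restrict a dataset to the selected voxel columns."""
    idx = sel.selected_indices
    return replace(
        ds,
        betas=ds.betas[:, idx],
        voxel_tstats=None if ds.voxel_tstats is None else ds.voxel_tstats[idx],
        voxel_provenance=[ds.voxel_provenance[j] for j in idx],
    )


def combine_rois(
    ds_a: PatternDataset, ds_b: PatternDataset, k_each: int = 300
) -> PatternDataset:
    """Build a combined region from the top ``k_each`` voxels of each parent.

    Both parents must carry ``voxel_tstats`` and identical trial labels (the
    same trials seen through two regions).  Voxel provenance records which
    parent each column came from, so the combined region never duplicates a
    column even for overlapping parents.
    """
    if k_each < 1:
        raise ValueError("k_each must be >= 1")
    for ds in (ds_a, ds_b):
        if ds.voxel_tstats is None:
            raise ValueError(f"{ds.roi_name}: voxel_tstats required")
        if ds.n_voxels < k_each:
            raise ValueError(
                f"{ds.roi_name} has {ds.n_voxels} voxels < k_each={k_each}"
            )
    if ds_a.n_trials != ds_b.n_trials:
        raise ValueError("parent regions must contain the same trials")
    sub_a = apply_selection(ds_a, select_voxels(ds_a.voxel_tstats, k_each))
    sub_b = apply_selection(ds_b, select_voxels(ds_b.voxel_tstats, k_each))
    return PatternDataset(
        betas=np.hstack([sub_a.betas, sub_b.betas]),
        labels=ds_a.labels.copy(),
        participant_id=ds_a.participant_id,
        roi_name=f"{ds_a.roi_name}+{ds_b.roi_name}",
        normalized=ds_a.normalized and ds_b.normalized,
        voxel_tstats=np.concatenate([sub_a.voxel_tstats, sub_b.voxel_tstats]),
        voxel_provenance=sub_a.voxel_provenance + sub_b.voxel_provenance,
    )
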