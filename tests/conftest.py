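import numpy as np
import pandas as pd
import pytest

from numdecode import (
    CohortConfig, apply_selection, select_voxels, simulate_cohort,
    znormalize_trials,
)
from numdecode.dataset import PatternDataset


def make_labeled_dataset(betas, numerosities, fmt="nonsymbolic",
                         task="identify", normalized=False, roi_name="roi",
                         voxel_tstats=None):
    """Build a PatternDataset from a matrix and per-trial numerosities."""
    betas = np.asarray(betas, dtype=float)
    labels = pd.DataFrame({
        "numerosity": numerosities,
        "format": fmt if isinstance(fmt, (list, np.ndarray))
        else [fmt] * len(numerosities),
        "task": task if isinstance(task, (list, np.ndarray))
        else [task] * len(numerosities),
    })
    return PatternDataset(betas=betas, labels=labels, normalized=normalized,
                          roi_name=roi_name, voxel_tstats=voxel_tstats)


def separated_dataset(n_per_class=6, n_voxels=20, gap=8.0, noise=0.3,
                      seed=0):
    """Four well-separated numerosity classes for exact-decoding checks."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    centers = {n: rng.normal(scale=gap, size=n_voxels)
               for n in (2, 4, 6, 8)}
    order = [n for _ in range(n_per_class) for n in (2, 4, 6, 8)]
    for n in order:
        rows.append(centers[n] + rng.normal(scale=noise, size=n_voxels))
        labels.append(n)
    ds = make_labeled_dataset(np.array(rows), labels)
    return znormalize_trials(ds)


@pytest.fixture(scope="session")
def small_cohort():
    """One small but fully structured cohort shared across read-only tests."""
    config = CohortConfig(n_participants=3, n_voxels_per_roi=150,
                          trials_per_cell=5, snr=1.5, rng_seed=42)
    return simulate_cohort(config, roi_names=("L_parietal", "L_NFA"))


@pytest.fixture(scope="session")
def prepared_dataset(small_cohort):
    """First participant's patterns, z-normalized with 100 voxels selected."""
    ds = small_cohort.patterns[("sub-00", "L_parietal")]
    z = znormalize_trials(ds)
    return apply_selection(z, select_voxels(ds.voxel_tstats, 100))
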