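"""Chunked cross-validated decoding and permutation nulls."""

import math

import numpy as np
import pytest
from scipy import stats

from numdecode import (
    CohortConfig, apply_selection, decode, enumerate_folds, make_chunks,
    permutation_null, select_voxels, simulate_cohort, znormalize_trials,
)
from tests.conftest import make_labeled_dataset, separated_dataset


def signal_free_dataset(n_per_class=10, n_voxels=40, seed=0):
    rng = np.random.default_rng(seed)
    labels = [n for _ in range(n_per_class) for n in (2, 4, 6, 8)]
    ds = make_labeled_dataset(
        rng.standard_normal((len(labels), n_voxels)), labels)
    return znormalize_trials(ds)


class TestChunks:
    def test_forty_per_class_gives_forty_chunks(self):
        labels = [n for _ in range(40) for n in (2, 4, 6, 8)]
        ds = make_labeled_dataset(np.random.default_rng(0).standard_normal(
            (160, 5)), labels)
        chunks = make_chunks(ds)
        assert chunks.n_chunks == 40
        # every chunk complete: one trial per class
        for c in range(40):
            in_chunk = ds.labels.loc[chunks.chunk_ids == c, "numerosity"]
            assert sorted(in_chunk) == [2, 4, 6, 8]

    def test_two_per_class(self):
        ds = make_labeled_dataset(np.zeros((8, 3)), [2, 4, 6, 8, 2, 4, 6, 8])
        assert make_chunks(ds).n_chunks == 2

    def test_imbalance_is_an_error(self):
        ds = make_labeled_dataset(np.zeros((9, 3)),
                                  [2, 2, 2, 4, 4, 6, 6, 8, 8])
        with pytest.raises(ValueError, match="unequal"):
            make_chunks(ds)

    def test_every_trial_in_exactly_one_chunk(self, prepared_dataset):
        sub = prepared_dataset.select_trials(format="nonsymbolic")
        chunks = make_chunks(sub)
        assert len(chunks.chunk_ids) == sub.n_trials
        ids, counts = np.unique(chunks.chunk_ids, return_counts=True)
        assert (counts == 4).all()


class TestFolds:
    def test_all_combinations_when_small(self):
        folds = enumerate_folds(5, k_out=3)
        assert len(folds) == 10  # C(5,3)
        for train, test in folds:
            assert len(test) == 3 and len(train) == 2
            assert not set(train) & set(test)

    def test_forty_chunks_uncapped_is_9880(self):
        folds = enumerate_folds(40, k_out=3, max_folds=None)
        assert len(folds) == math.comb(40, 3) == 9880

    def test_capped_subsample_is_seeded_and_distinct(self):
        a = enumerate_folds(40, k_out=3, max_folds=500, seed=7)
        b = enumerate_folds(40, k_out=3, max_folds=500, seed=7)
        assert len(a) == 500
        keys = {tuple(test) for _, test in a}
        assert len(keys) == 500
        for (tr_a, te_a), (tr_b, te_b) in zip(a, b):
            assert np.array_equal(te_a, te_b)

    def test_too_few_chunks_is_an_error(self):
        with pytest.raises(ValueError):
            enumerate_folds(3, k_out=3)


class TestDecode:
    def test_perfect_on_well_separated_patterns(self):
        ds = separated_dataset(n_per_class=6, gap=10.0, noise=0.1)
        cm = decode(ds, k_out=2)
        assert cm.mean_accuracy == 1.0

    def test_chance_on_signal_free_data(self):
        accs = [decode(signal_free_dataset(seed=s), seed=0).mean_accuracy
                for s in range(12)]
        # 12 independent signal-free runs: mean within MC error of 0.25
        assert np.mean(accs) == pytest.approx(0.25, abs=0.05)

    def test_requires_normalized_input(self):
        ds = separated_dataset()
        ds.normalized = False
        with pytest.raises(ValueError, match="normalized"):
            decode(ds)

    def test_confusion_rows_sum_to_one(self, prepared_dataset):
        cm = decode(prepared_dataset, {"format": "nonsymbolic"}, seed=0)
        assert np.allclose(cm.rates.sum(axis=1), 1.0, atol=1e-10)
        assert (cm.rates >= 0).all() and (cm.rates <= 1).all()

    def test_pooled_accuracy_equals_weighted_fold_mean(self, prepared_dataset):
        cm = decode(prepared_dataset, {"format": "symbolic"}, seed=1)
        pooled = cm.counts.trace() / cm.counts.sum()
        assert pooled == pytest.approx(np.mean(cm.fold_accuracies))

    def test_accuracy_nondecreasing_in_snr(self):
        # pipeline-level monotonicity over the snr grid, small cohorts
        means = []
        for snr in (0.0, 0.3, 1.0, 3.0):
            accs = []
            for seed in range(3):
                config = CohortConfig(n_participants=1, n_voxels_per_roi=80,
                                      trials_per_cell=5, snr=snr,
                                      rng_seed=100 + seed)
                cohort = simulate_cohort(config)
                raw = cohort.patterns[("sub-00", "L_parietal")]
                ds = apply_selection(znormalize_trials(raw),
                                     select_voxels(raw.voxel_tstats, 60))
                accs.append(decode(ds, {"format": "nonsymbolic"},
                                   max_folds=40, seed=0).mean_accuracy)
            means.append(np.mean(accs))
        tol = 0.06  # MC error at 3 replicates
        assert all(b >= a - tol for a, b in zip(means, means[1:]))
        assert means[-1] > means[0] + 0.2


class TestPermutationNull:
    def test_null_centers_on_chance(self):
        ds = separated_dataset(n_per_class=8, gap=5.0, noise=0.5)
        null = permutation_null(ds, n_perm=200, seed=0, max_folds=15)
        assert null.n_perm == 200
        assert null.mean == pytest.approx(0.25, abs=0.02)

    def test_single_permutation_reproducible(self):
        ds = separated_dataset(n_per_class=6)
        a = permutation_null(ds, n_perm=1, seed=5, max_folds=10)
        b = permutation_null(ds, n_perm=1, seed=5, max_folds=10)
        assert a.accuracies[0] == b.accuracies[0]

    def test_zero_permutations_rejected(self):
        ds = separated_dataset()
        with pytest.raises(ValueError):
            permutation_null(ds, n_perm=0)

    def test_null_p_values_calibrated_on_signal_free_data(self):
        # under no signal the observed accuracy is itself a null draw, so
        # its empirical p-value should be uniform across replicates
        pvals = []
        for seed in range(40):
            ds = signal_free_dataset(n_per_class=6, n_voxels=25, seed=seed)
            # same fold seed for observed and null: exchangeable under H0
            observed = decode(ds, max_folds=10, seed=seed).mean_accuracy
            null = permutation_null(ds, n_perm=99, seed=seed, max_folds=10)
            pvals.append(null.p_value(observed))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
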