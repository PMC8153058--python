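"""Synthetic study generator: design structure, neural statistics,
behavioral sessions, and covariates."""

import itertools

import numpy as np
import pytest
from scipy import stats

from numdecode import (
    CohortConfig, generate_behavior, generate_covariates, generate_design,
    simulate_cohort, weber_error,
)
from numdecode.cohort import (
    DesignError, ISI_LEVELS_MS, RATIO_PAIRS, _order_cells, generate_neural,
)


@pytest.fixture(scope="module")
def default_design():
    config = CohortConfig(n_participants=2, rng_seed=1)
    return config, generate_design(config)


class TestDesign:
    def test_trial_counts_at_defaults(self, default_design):
        _, design = default_design
        per = design.groupby(["participant", "task"]).size()
        assert (per == 160).all()
        assert design.groupby("participant").size().eq(320).all()

    def test_cell_counts_exact(self, default_design):
        _, design = default_design
        cells = design.groupby(
            ["participant", "task", "numerosity", "format"]).size()
        assert (cells == 20).all()

    def test_mean_isi_is_5300_exactly(self, default_design):
        _, design = default_design
        for _, task_df in design.groupby(["participant", "task"]):
            assert task_df["isi_ms"].mean() == 5300.0

    def test_isi_counterbalanced_within_cells(self, default_design):
        _, design = default_design
        counts = design.groupby(
            ["participant", "task", "numerosity", "format"])[
            "isi_ms"].value_counts()
        assert (counts == 4).all()  # 20 trials / 5 ISI levels
        assert set(design["isi_ms"]) == set(ISI_LEVELS_MS)

    def test_no_more_than_three_consecutive_repeats(self, default_design):
        _, design = default_design
        for _, task_df in design.groupby(["participant", "task"]):
            seq = list(zip(task_df["numerosity"], task_df["format"]))
            run = 1
            for prev, cur in itertools.pairwise(seq):
                run = run + 1 if cur == prev else 1
                assert run <= 3

    def test_single_trial_per_cell(self):
        config = CohortConfig(n_participants=1, trials_per_cell=1,
                              rng_seed=0)
        design = generate_design(config)
        assert design.groupby("task").size().eq(8).all()
        cells = design.groupby(["task", "numerosity", "format"]).size()
        assert (cells == 1).all()

    def test_unsatisfiable_ordering_reports_instead_of_looping(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DesignError):
            _order_cells([(2, "nonsymbolic")] * 5, rng, max_run=3)


class TestNeural:
    def test_same_seed_bit_identical(self):
        config = CohortConfig(n_participants=2, n_voxels_per_roi=60,
                              trials_per_cell=3, rng_seed=9)
        a = simulate_cohort(config)
        b = simulate_cohort(config)
        key = ("sub-01", "L_parietal")
        assert np.array_equal(a.patterns[key].betas, b.patterns[key].betas)
        assert a.design.equals(b.design)
        assert a.covariates.equals(b.covariates)

    def test_noise_sd_is_one_at_zero_snr(self):
        config = CohortConfig(n_participants=1, n_voxels_per_roi=400,
                              trials_per_cell=10, snr=0.0, rng_seed=2)
        design = generate_design(config)
        ds = generate_neural(config, design, "sub-00", "roi",
                             np.random.default_rng(5))
        assert ds.betas.std() == pytest.approx(1.0, abs=0.01)

    def test_pattern_scale_linear_in_snr(self):
        design_cfg = dict(n_participants=1, n_voxels_per_roi=200,
                          trials_per_cell=10, rng_seed=3)
        seps = []
        for snr in (1.0, 2.0):
            config = CohortConfig(snr=snr, **design_cfg)
            design = generate_design(config)
            ds = generate_neural(config, design, "sub-00", "roi",
                                 np.random.default_rng(7))
            means = np.stack([
                ds.betas[ds.labels["numerosity"] == n].mean(axis=0)
                for n in (2, 4, 6, 8)])
            seps.append(np.linalg.norm(means - means.mean(axis=0)))
        assert seps[1] / seps[0] == pytest.approx(2.0, rel=0.1)

    def test_tstat_surrogate_scales_with_snr(self):
        config = CohortConfig(n_participants=1, n_voxels_per_roi=100,
                              trials_per_cell=5, snr=2.0, rng_seed=4)
        design = generate_design(config)
        ds = generate_neural(config, design, "sub-00", "roi",
                             np.random.default_rng(0))
        assert ds.voxel_tstats is not None
        assert ds.voxel_tstats.mean() > 0.5  # energy surrogate tracks snr


class TestBehavior:
    def test_session_has_70_trials_at_defaults(self):
        session = generate_behavior(0.25, 10, 0)
        assert session.n_trials == 70
        assert len(session.per_ratio_accuracy()) == len(RATIO_PAIRS)

    def test_tiny_weber_fraction_gives_no_errors(self):
        session = generate_behavior(1e-4, 20, 1)
        assert all(t.correct for t in session.trials)

    def test_accuracies_match_weber_model_at_scale(self):
        # 10^4 repetitions per ratio: frequencies within binomial 99% CI
        session = generate_behavior(0.25, 10_000, 123)
        acc = session.per_ratio_accuracy()
        for (small, large), observed in acc.items():
            expected = 1.0 - weber_error(small, large, 0.25)
            half_ci = 2.576 * np.sqrt(expected * (1 - expected) / 10_000)
            assert abs(observed - expected) <= half_ci

    def test_side_counterbalanced(self):
        session = generate_behavior(0.2, 10, 7)
        larger_left = sum(t.n1 > t.n2 for t in session.trials)
        assert larger_left == session.n_trials // 2

    def test_invalid_w_rejected(self):
        with pytest.raises(ValueError):
            generate_behavior(0.0, 10, 0)


class TestCovariates:
    def test_independent_when_r_zero(self):
        config = CohortConfig(brain_behavior_r=0.0)
        rng = np.random.default_rng(11)
        alphas = np.clip(0.5 + 0.15 * rng.standard_normal(10_000), 0.02,
                         0.98)
        cov = generate_covariates(config, alphas, rng)
        assert abs(np.corrcoef(alphas, cov["math_score"])[0, 1]) < 0.03

    def test_latent_correlation_recovered(self):
        config = CohortConfig(brain_behavior_r=-0.5)
        rng = np.random.default_rng(12)
        alphas = np.clip(0.5 + 0.15 * rng.standard_normal(10_000), 0.02,
                         0.98)
        cov = generate_covariates(config, alphas, rng)
        r = np.corrcoef(alphas, cov["math_score"])[0, 1]
        assert r == pytest.approx(-0.5, abs=0.03)

    def test_score_count_and_scale(self):
        config = CohortConfig(n_participants=39)
        rng = np.random.default_rng(3)
        alphas = np.full(39, 0.5) + 0.1 * rng.standard_normal(39)
        cov = generate_covariates(config, alphas, rng)
        assert len(cov) == 39
        # standard-score scale: mean 100, SD 15 population parameters
        big = generate_covariates(
            config, 0.5 + 0.1 * rng.standard_normal(20_000), rng)
        assert big["math_score"].mean() == pytest.approx(100, abs=0.5)
        assert big["math_score"].std() == pytest.approx(15, abs=0.5)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(brain_behavior_r=1.5)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(snr=-0.1),
        dict(alpha_format=1.2),
        dict(alpha_task=-0.1),
        dict(trials_per_cell=0),
        dict(tuning_width=0.0),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)

    def test_cohort_carries_participant_covariates(self, small_cohort):
        cov = small_cohort.covariates
        assert set(cov.columns) >= {"participant", "math_score",
                                    "alpha_format", "w_true"}
        assert len(cov) == small_cohort.config.n_participants
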