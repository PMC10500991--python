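import numpy as np
import pytest

from decispeed import preprocess as pp
from decispeed import trial_reliability as tr
from decispeed.pipeline import ERP_RESPONSE_WINDOW_MS
from decispeed.synthetic_cohort import (
    CohortConfig,
    draw_cohort,
    simulate_behavior,
    synthesize_epochs,
)


class TestTaskTimeBudget:
    def test_average_scenario(self):
        plan = tr.task_time_budget(40, accuracy=0.96, rejection_fraction=0.15)
        assert plan.post_accuracy_trials == 42
        assert plan.presented_trials == 48
        assert plan.coherent_seconds == 144.0

    def test_average_scenario_total_corrects_source_slip(self):
        # 16 trials per interval: 28.8 + 44.8 + 60.8 = 134.4 -> total 278.4
        plan = tr.task_time_budget(40, accuracy=0.96, rejection_fraction=0.15)
        assert plan.random_seconds == pytest.approx(134.4)
        assert plan.total_seconds == pytest.approx(278.4)

    def test_worst_case_scenario(self):
        plan = tr.task_time_budget(40, accuracy=0.71, rejection_fraction=0.44)
        assert plan.post_accuracy_trials == 52
        assert plan.presented_trials == 75
        assert plan.coherent_seconds == 225.0
        assert plan.random_seconds == pytest.approx(210.0)
        assert plan.total_seconds == pytest.approx(435.0)

    def test_no_inflation_arithmetic(self):
        plan = tr.task_time_budget(39, accuracy=1.0, rejection_fraction=0.0)
        assert plan.presented_trials == 39
        assert plan.total_seconds == pytest.approx(39 * 3 + 13 * 8.4)

    def test_remainder_spread_shortest_first(self):
        plan = tr.task_time_budget(40, accuracy=1.0, rejection_fraction=0.0)
        # 40 = 14 + 13 + 13 with the extra trial on the 1.8 s interval
        assert plan.random_seconds == pytest.approx(14 * 1.8 + 13 * 2.8 + 13 * 3.8)

    def test_invariants(self):
        plan = tr.task_time_budget(40, accuracy=0.8, rejection_fraction=0.2)
        assert plan.presented_trials >= plan.post_accuracy_trials >= plan.required_valid
        assert plan.total_seconds == plan.coherent_seconds + plan.random_seconds

    def test_validation(self):
        with pytest.raises(ValueError):
            tr.task_time_budget(40, accuracy=0.0, rejection_fraction=0.1)
        with pytest.raises(ValueError):
            tr.task_time_budget(40, accuracy=0.9, rejection_fraction=1.0)


class TestEnumerateTrialTypes:
    def test_full_design(self):
        n, types = tr.enumerate_trial_types()
        assert n == 12
        assert len(set(types)) == 12

    def test_degenerate(self):
        assert tr.enumerate_trial_types([1.0], ["l"], ["u"])[0] == 1

    def test_two_cubed(self):
        assert tr.enumerate_trial_types([1, 2], ["l", "r"], ["u", "d"])[0] == 8


def _cohort_epochs(n_subjects=6, noise_sd=6.0, seed=4, trials=180):
    cfg = CohortConfig(
        n_older=n_subjects, n_younger=1, trials_per_subject=trials, noise_sd=noise_sd, seed=seed
    )
    out = {}
    for s in draw_cohort(cfg):
        if s.group != "older":
            continue
        beh = simulate_behavior(s, cfg)
        ep = synthesize_epochs(s, beh, cfg)
        out[s.subject_id] = pp.response_locked(ep, ERP_RESPONSE_WINDOW_MS, baseline_ms=None)
    return out


@pytest.fixture(scope="module")
def noisy_epochs():
    return _cohort_epochs()


def _noiseless_linear_cohort(n_subjects=5):
    """Constant-RT subjects whose planted slope is exactly linear in RT."""
    from conftest import make_behavior, make_subject

    cfg = CohortConfig(noise_sd=0.0, seed=0)
    out = {}
    for i in range(n_subjects):
        rt = 500.0 + 60.0 * i
        slope = 0.20 - 0.0002 * rt  # exact negative linear relation
        subj = make_subject(
            subject_id=f"lin{i}", cpp_slope_true=slope, cpp_onset_true=0.45 * rt
        )
        beh = make_behavior(n=132, rt_ms=rt, subject_id=subj.subject_id)
        ep = synthesize_epochs(subj, beh, cfg)
        out[subj.subject_id] = pp.response_locked(
            ep, ERP_RESPONSE_WINDOW_MS, baseline_ms=None
        )
    return out


class TestSubsampleEstimates:
    def test_pool_exhaustion_zero_sd(self, noisy_epochs):
        res = tr.subsample_estimates(
            noisy_epochs, bin_sizes=(129,), n_perm=20, pool_size=129, seed=0
        )
        assert np.all(res.rt_estimates.std(axis=2) < 1e-12)
        assert np.all(np.isnan(res.rt_snr))  # SD=0 flagged as undefined

    def test_noiseless_subject_constant_slope(self):
        # constant RT + no noise -> every trial carries the identical ramp,
        # so the slope estimate cannot vary across permutations
        eps = _noiseless_linear_cohort(n_subjects=3)
        res = tr.subsample_estimates(eps, bin_sizes=(20, 60), n_perm=30, pool_size=129, seed=1)
        assert np.all(res.slope_estimates.std(axis=2) < 1e-12)

    def test_draws_without_replacement(self, noisy_epochs):
        rng = np.random.default_rng(0)
        order = np.argsort(rng.random((50, 129)), axis=1)[:, :40]
        assert all(len(set(row)) == 40 for row in order)

    def test_insufficient_pool_skipped(self, noisy_epochs):
        eps = dict(noisy_epochs)
        small = next(iter(eps.values())).select_trials(np.arange(100))
        eps["tiny"] = small
        res = tr.subsample_estimates(eps, bin_sizes=(20,), n_perm=10, pool_size=129, seed=0)
        assert "tiny" in res.skipped
        assert "tiny" not in res.subjects

    def test_snr_monotone_and_r_attenuation(self, noisy_epochs):
        res = tr.subsample_estimates(
            noisy_epochs, bin_sizes=(20, 60, 120), n_perm=200, pool_size=129, seed=2
        )
        rt_snr = np.nanmean(res.rt_snr, axis=0)
        sl_snr = np.nanmean(res.slope_snr, axis=0)
        assert rt_snr[0] < rt_snr[1] < rt_snr[2]
        assert sl_snr[0] < sl_snr[1] < sl_snr[2]
        mean_r = res.r_by_bin.mean(axis=1)
        assert abs(mean_r[-1]) >= abs(mean_r[0])

    def test_bin_exceeding_pool_errors(self, noisy_epochs):
        with pytest.raises(ValueError, match="pool"):
            tr.subsample_estimates(noisy_epochs, bin_sizes=(200,), pool_size=129)


class TestDistributionShiftTests:
    def test_ks_statistic_bounds_and_inflation(self, noisy_epochs):
        res = tr.subsample_estimates(
            noisy_epochs, bin_sizes=(20, 120), n_perm=300, pool_size=129, seed=3
        )
        table = tr.distribution_shift_tests(res)
        assert ((table["ks_stat"] >= 0) & (table["ks_stat"] <= 1)).all()
        # variance inflation at 20 vs 120 trials is detectable
        assert (table["ks_p"] < 0.01).any()
        assert table.attrs["trend_p_rt"] < 0.05

    def test_identical_distributions_not_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        from scipy.stats import ks_2samp

        stat, p = ks_2samp(x[:1000], x[1000:])
        assert p > 0.01


class TestEffectSizeByBin:
    def test_perfect_linear_relation_gives_minus_one(self):
        eps = _noiseless_linear_cohort(n_subjects=5)
        res = tr.subsample_estimates(eps, bin_sizes=(20, 40), n_perm=20, pool_size=129, seed=0)
        np.testing.assert_allclose(res.r_by_bin, -1.0, atol=1e-6)

    def test_null_generator_r_near_zero(self):
        cfg = CohortConfig(
            n_older=6,
            n_younger=1,
            trials_per_subject=180,
            noise_sd=4.0,
            seed=13,
            moderation_coeffs=(600.0, 0.0, 0.0, 0.0),
            rt_noise_sd=0.0,
        )
        eps = {}
        for s in draw_cohort(cfg):
            if s.group != "older":
                continue
            beh = simulate_behavior(s, cfg)
            ep = synthesize_epochs(s, beh, cfg)
            eps[s.subject_id] = pp.response_locked(ep, ERP_RESPONSE_WINDOW_MS, baseline_ms=None)
        res = tr.subsample_estimates(eps, bin_sizes=(60,), n_perm=100, pool_size=129, seed=1)
        table = tr.effect_size_by_bin(res)
        assert abs(table.loc[0, "r_mean"]) < 0.6  # no planted coupling

    def test_bf_columns_present(self, noisy_epochs):
        res = tr.subsample_estimates(
            noisy_epochs, bin_sizes=(40,), n_perm=50, pool_size=129, seed=5
        )
        table = tr.effect_size_by_bin(res)
        assert np.isfinite(table["bf10_vs_threshold"]).all()
        assert set(table.columns) >= {"bin_size", "r_mean", "r_sd", "bf10_vs_threshold"}
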