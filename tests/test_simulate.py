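"""Generator contracts: schedule marginals, SDT observer, trajectories, determinism."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError
from scipy.stats import norm

from advisdt import (
    ExperimentConfig,
    ParticipantProfile,
    ProfileDistribution,
    sample_advice_schedule,
    simulate_experiment,
    simulate_response,
    simulate_self_reports,
)
from advisdt.config import BlockSpec
from conftest import small_config


def make_profile(**kw) -> ParticipantProfile:
    base = dict(participant_id="p1", condition="distrust",
                true_dprime_s1=1.0, true_dprime_s2_own=1.0, true_criterion=0.0,
                adoption_weight=0.5, trust_baseline=5.0, distrust_baseline=3.0,
                use_baseline=5.0, selfreport_error_shift=1.0)
    base.update(kw)
    return ParticipantProfile(**base)


class TestAdviceSchedule:
    def test_default_design_block_structure(self):
        cfg = ExperimentConfig()
        flags = sample_advice_schedule(cfg, rng_seed=0)
        assert flags.shape == (216,)
        assert [b.n_trials for b in cfg.blocks_session2] == [24] * 9
        assert [b.p_correct_advice for b in cfg.blocks_session2] == [
            0.9, 0.9, 0.9, 0.75, 0.6, 0.45, 0.9, 0.9, 0.9]

    def test_degenerate_probability_one_gives_all_correct(self):
        cfg = small_config()
        cfg = cfg.model_copy(update={"blocks_session2": tuple(
            BlockSpec(n_trials=8, p_correct_advice=1.0)
            for _ in cfg.blocks_session2)})
        assert sample_advice_schedule(cfg, rng_seed=3).all()

    def test_block_marginal_matches_bernoulli_expectation(self):
        """10,000 draws of a 24-trial p=0.75 block: mean within 3 SE of 0.75."""
        cfg = ExperimentConfig(blocks_session2=(
            BlockSpec(n_trials=24, p_correct_advice=0.75),) * 9)
        rng = np.random.default_rng(7)
        fracs = [
            sample_advice_schedule(cfg, int(rng.integers(2**31)))[:24].mean()
            for _ in range(10_000)
        ]
        se = np.sqrt(0.75 * 0.25 / (24 * 10_000))
        assert abs(np.mean(fracs) - 0.75) < 3 * se

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValidationError):
            BlockSpec(n_trials=24, p_correct_advice=1.5)

    def test_reproducible_under_fixed_seed(self):
        cfg = ExperimentConfig()
        a = sample_advice_schedule(cfg, 42)
        b = sample_advice_schedule(cfg, 42)
        assert (a == b).all()


class TestResponseModel:
    def test_unadvised_hit_rate_matches_gaussian_observer(self):
        """d=2, c=0: hit rate within 3 SE of Phi(1), FA rate of Phi(-1)."""
        rng = np.random.default_rng(1)
        n = 50_000
        truth = np.array(["signal"] * n + ["noise"] * n)
        advice = np.full(2 * n, "none")
        resp = simulate_response(2.0, 0.0, truth, advice, 0.5, rng)
        hit = (resp[:n] == "signal").mean()
        fa = (resp[n:] == "signal").mean()
        se = np.sqrt(norm.cdf(1) * norm.cdf(-1) / n)
        assert abs(hit - norm.cdf(1)) < 3 * se
        assert abs(fa - norm.cdf(-1)) < 3 * se

    def test_full_adoption_always_follows_advice(self):
        rng = np.random.default_rng(2)
        truth = np.repeat(["signal", "noise"], 500)
        advice = np.tile(["noise", "signal"], 500)
        resp = simulate_response(1.0, 0.2, truth, advice, 1.0, rng)
        assert (resp == advice).all()

    def test_zero_adoption_ignores_advice(self):
        """With adoption 0 the advised response distribution is the observer's."""
        truth = np.repeat(["signal", "noise"], 20_000)
        advice = np.where(truth == "signal", "noise", "signal")  # always wrong
        r0 = simulate_response(1.5, 0.0, truth, advice, 0.0,
                               np.random.default_rng(9))
        r1 = simulate_response(1.5, 0.0, truth, np.full(truth.shape, "none"), 0.0,
                               np.random.default_rng(9))
        assert (r0 == r1).all()


class TestSelfReports:
    def test_deterministic_step_trajectory(self):
        """Trust baseline 5, shift 2, no noise: ratings (5, 5, 3, 3, 3)."""
        profile = make_profile(trust_baseline=5.0, selfreport_error_shift=2.0)
        recs = simulate_self_reports(profile, small_config(),
                                     np.random.default_rng(0), noise_sd=0.0)
        trust = [r["rating"] for r in recs if r["item"] == "trust"]
        assert trust == [5, 5, 3, 3, 3]
        distrust = [r["rating"] for r in recs if r["item"] == "distrust"]
        assert distrust == [3, 3, 5, 5, 5]

    def test_zero_shift_zero_noise_is_flat(self):
        profile = make_profile(selfreport_error_shift=0.0, trust_baseline=4.4)
        recs = simulate_self_reports(profile, small_config(),
                                     np.random.default_rng(0), noise_sd=0.0)
        trust = [r["rating"] for r in recs if r["item"] == "trust"]
        assert trust == [4] * 5

    def test_mean_drop_matches_generative_shift(self):
        """1,000 participants, shift 0.5, noise SD 1: tp3 - tp1 mean ~ -0.5."""
        rng = np.random.default_rng(3)
        cfg = small_config()
        t1, t3 = [], []
        for i in range(1000):
            p = make_profile(participant_id=f"p{i}", selfreport_error_shift=0.5)
            recs = simulate_self_reports(p, cfg, rng, noise_sd=1.0)
            trust = {r["timepoint"]: r["rating"] for r in recs if r["item"] == "trust"}
            t1.append(trust[1])
            t3.append(trust[3])
        diff = np.mean(t3) - np.mean(t1)
        se = np.sqrt(np.var(t1) / 1000 + np.var(t3) / 1000)
        assert abs(diff + 0.5) < 3 * se

    def test_ratings_stay_on_likert_scale(self):
        rng = np.random.default_rng(4)
        profile = make_profile(trust_baseline=6.8, distrust_baseline=1.2,
                               selfreport_error_shift=4.0)
        recs = simulate_self_reports(profile, small_config(), rng, noise_sd=3.0)
        assert all(1 <= r["rating"] <= 7 for r in recs)


class TestSimulateExperiment:
    def test_counting_contract(self, tiny_config, tiny_dataset):
        trials, reports, profiles = tiny_dataset
        n = tiny_config.n_participants
        per = tiny_config.n_trials_session1 + tiny_config.n_trials_session2
        assert len(trials) == n * per
        assert len(reports) == n * 5 * 3
        assert len(profiles) == n

    def test_default_design_trial_count_at_study_scale(self):
        cfg = ExperimentConfig(n_participants_total=131)
        trials, reports, profiles = simulate_experiment(
            cfg, ProfileDistribution(), rng_seed=1)
        assert len(trials) == 131 * 432
        assert len(profiles) == 131
        sizes = pd.Series([p.condition for p in profiles]).value_counts()
        assert sorted(sizes) == [65, 66]

    def test_sessions_share_stimulus_identities(self, tiny_dataset):
        trials, _, _ = tiny_dataset
        for _, g in trials.groupby("participant_id"):
            s1 = g[g.session == 1]
            s2 = g[g.session == 2]
            assert set(s1.stimulus_id) == set(s2.stimulus_id)
            t1 = s1.set_index("stimulus_id").true_category
            t2 = s2.set_index("stimulus_id").true_category
            assert t1.sort_index().equals(t2.sort_index())

    def test_session1_has_no_advice_and_consistent_flags(self, tiny_dataset):
        trials, _, _ = tiny_dataset
        s1 = trials[trials.session == 1]
        assert (s1.advice_shown == "none").all()
        assert (s1.advice_correct == "n/a").all()
        s2 = trials[trials.session == 2]
        assert ((s2.advice_shown == s2.true_category)
                == (s2.advice_correct == "true")).all()
        assert (trials.response_correct
                == (trials.response == trials.true_category)).all()

    def test_seed_determinism_byte_identical(self, tiny_config):
        a = simulate_experiment(tiny_config, ProfileDistribution(), rng_seed=3)
        b = simulate_experiment(tiny_config, ProfileDistribution(), rng_seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert a[2] == b[2]

    def test_inconsistent_session_lengths_rejected(self, tiny_config):
        bad = tiny_config.model_copy(update={"n_trials_session1": 47})
        with pytest.raises(ValueError, match="same stimulus set"):
            simulate_experiment(bad, ProfileDistribution(), rng_seed=0)

    def test_cohort_dprime_recovered_by_closed_form(self):
        """Injected group d' ~ 2.0 recovered from pooled unadvised counts."""
        from advisdt import sdt_invert
        from advisdt.counts import loglinear_rates, tabulate_counts

        cfg = small_config(n_per_condition=40, block_len=24)
        dist = ProfileDistribution(dprime_mean=2.0, dprime_sd=0.0,
                                   criterion_sd=0.0)
        trials, _, _ = simulate_experiment(cfg, dist, rng_seed=8)
        counts = tabulate_counts(trials[trials.session == 1], "all")
        h, f = loglinear_rates(counts.hits.sum(), counts.n_signal_trials.sum(),
                               counts.false_alarms.sum(), counts.n_noise_trials.sum())
        d, _ = sdt_invert(h, f)
        assert abs(d - 2.0) < 0.1
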