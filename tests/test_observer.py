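import numpy as np
import pytest
from scipy import stats

from headingflow import (ExperimentDesign, StimulusCondition,
                         enumerate_design, estimate_sd, get_model,
                         run_condition, run_threshold_replicates, run_trial)
from headingflow.observer import FOLLOWUP_DOTS, run_psychometric


class TestEnumerateDesign:
    def test_paper_design(self):
        assert enumerate_design(ExperimentDesign()) == (480, 60, 16)

    def test_followup_design(self):
        design = ExperimentDesign(dots_levels=FOLLOWUP_DOTS)
        full, collapsed, reps = enumerate_design(design)
        assert full == 5 * 3 * 4 * 10 == 600
        assert collapsed == 75 and reps == 16

    def test_single_level_design(self):
        design = ExperimentDesign(dots_levels=(50,), noise_levels=(0.0,),
                                  offsets=(1.0,), target_locations=(0.0,),
                                  sessions=3)
        assert enumerate_design(design) == (1, 1, 3)

    def test_empty_levels_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDesign(dots_levels=())


class TestRunTrial:
    def test_deterministic_under_seed(self, stub_model):
        cond = StimulusCondition(dots_per_frame=20, noise_sd=7.5,
                                 foe_offset=1.0)
        a = run_trial(stub_model, cond, np.random.default_rng(5))
        b = run_trial(stub_model, cond, np.random.default_rng(5))
        assert a == b

    def test_correct_sign_convention(self, exact_model):
        for off in (4.0, -4.0):
            cond = StimulusCondition(dots_per_frame=10, foe_offset=off)
            res = run_trial(exact_model, cond, np.random.default_rng(0))
            assert res.correct
            assert res.response == ("right" if off > 0 else "left")
            assert res.n_valid_estimates == 7

    def test_degenerate_model_coin_flip(self, degenerate_model):
        cond = StimulusCondition(dots_per_frame=10, foe_offset=4.0)
        results = [run_trial(degenerate_model, cond, np.random.default_rng(s))
                   for s in range(200)]
        assert all(np.isnan(r.mean_estimate) for r in results)
        pc = np.mean([r.correct for r in results])
        assert 0.35 < pc < 0.65  # binomial CI around chance

    def test_noiseless_200_dots_all_models_correct(self, radial_field):
        cond = StimulusCondition(dots_per_frame=200, foe_offset=4.0)
        for name in ("lhp80", "p92", "hj92", "wc99"):
            res = run_trial(get_model(name), cond, np.random.default_rng(3))
            assert res.correct, name


class TestRunCondition:
    def test_single_trial_binary(self, stub_model):
        cond = StimulusCondition(dots_per_frame=10, foe_offset=2.0)
        pc, est = run_condition(stub_model, cond, 1, np.random.default_rng(1))
        assert pc in (0.0, 100.0) and len(est) == 1

    def test_zero_offset_is_chance(self, stub_model):
        cond = StimulusCondition(dots_per_frame=10, foe_offset=0.0)
        pc, _ = run_condition(stub_model, cond, 300, np.random.default_rng(2))
        assert 40 < pc < 60

    def test_large_offset_perfect(self, stub_model):
        cond = StimulusCondition(dots_per_frame=10, foe_offset=4.0)
        pc, _ = run_condition(stub_model, cond, 50, np.random.default_rng(3))
        assert pc == 100.0

    def test_percent_correct_monotone_in_offset(self, stub_model):
        rng = np.random.default_rng(4)
        pcs = []
        for off in (0.1, 0.5, 2.0):
            cond = StimulusCondition(dots_per_frame=10, foe_offset=off)
            pcs.append(run_condition(stub_model, cond, 200, rng)[0])
        assert pcs[0] <= pcs[1] + 5 <= pcs[2] + 10

    def test_mirror_symmetry_of_estimates(self):
        # mirroring the offset sign mirrors the estimate distribution
        model = get_model("p92")
        rng = np.random.default_rng(11)
        pos = run_condition(model, StimulusCondition(50, 7.5, 1.0), 60, rng)[1]
        neg = run_condition(model, StimulusCondition(50, 7.5, -1.0), 60, rng)[1]
        assert stats.ks_2samp(pos, -neg).pvalue > 0.01


class TestThresholdReplicates:
    def test_zero_variance_stops_immediately(self, exact_model):
        reps = run_threshold_replicates(exact_model, 20, 0.0,
                                        np.random.default_rng(0),
                                        trials_per_offset=4, min_reps=3)
        assert len(reps) == 3
        good = reps[np.isfinite(reps)]
        assert good.std(ddof=1) == pytest.approx(0.0, abs=1e-12)

    def test_stop_condition_honored(self, stub_model):
        reps = run_threshold_replicates(stub_model, 20, 0.0,
                                        np.random.default_rng(1),
                                        trials_per_offset=8, sem_stop=0.2,
                                        max_reps=40)
        good = reps[np.isfinite(reps)]
        if len(reps) < 40:
            assert good.std(ddof=1) / np.sqrt(len(good)) < 0.2

    def test_deterministic_replicate_list(self, stub_model):
        kw = dict(trials_per_offset=4, max_reps=5, sem_stop=0.01)
        a = run_threshold_replicates(stub_model, 10, 0.0,
                                     np.random.default_rng(2), **kw)
        b = run_threshold_replicates(stub_model, 10, 0.0,
                                     np.random.default_rng(2), **kw)
        np.testing.assert_array_equal(a, b)


class TestEstimateSd:
    def test_nonnegative_and_stable_across_halves(self, stub_model):
        sd1 = estimate_sd(stub_model, 20, 0.0, np.random.default_rng(3),
                          n_trials=500)
        sd2 = estimate_sd(stub_model, 20, 0.0, np.random.default_rng(4),
                          n_trials=500)
        assert sd1 > 0
        # stub per-trial mean has sd = 0.5/sqrt(7); halves agree within 15%
        assert abs(sd1 - sd2) / sd1 < 0.15
        assert sd1 == pytest.approx(0.5 / np.sqrt(7), rel=0.15)

    def test_noise_increases_wc99_sd(self):
        model = get_model("wc99")
        sd0 = estimate_sd(model, 100, 0.0, np.random.default_rng(5),
                          n_trials=120)
        sd2 = estimate_sd(model, 100, 15.0, np.random.default_rng(5),
                          n_trials=120)
        assert sd2 >= sd0

    def test_too_few_trials(self, stub_model):
        with pytest.raises(ValueError):
            estimate_sd(stub_model, 20, 0.0, 0, n_trials=1)


class TestRunPsychometric:
    def test_fit_shape_and_threshold(self, stub_model):
        fit = run_psychometric(stub_model, 20, 0.0, np.random.default_rng(6),
                               trials_per_offset=16)
        assert fit.ok
        # stub: per-trial mean est ~ N(offset, 0.5/sqrt(7)); 75% point near
        # 0.6745 * 0.189 = 0.13, well inside the offset range
        assert 0.0 <= fit.threshold75 < 1.0
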