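"""Behavioral fits: logistic, wrong-task mixture, SR, thresholds, neurometrics."""

import numpy as np
import pandas as pd
import pytest

from taskswitch import psychometrics as psy
from taskswitch import synthetic_mt as smt

LEVELS = np.array([-0.5, -0.125, 0.0, 0.125, 0.5])
BETA_DIR = np.array([0.0, 8.0, 1.5, 0.0])
BETA_DEP = np.array([0.0, 1.5, 6.0, 0.0])


def _fit(beta_dir=BETA_DIR, beta_dep=BETA_DEP, p_err=0.0, n=1000, seed=0):
    return psy.simulate_choices(beta_dir, beta_dep, p_err, LEVELS, n, seed)


class TestLogisticFit:
    def test_recovers_known_parameters_within_ci(self):
        truth = np.array([0.0, 10.0, 2.0, 0.0])
        trials = _fit(truth, BETA_DEP, n=1000, seed=1)
        fit = psy.fit_logistic_task(trials[trials["task"] == "direction"])
        assert fit.converged
        for b, bh, se in zip(truth, fit.beta, fit.bse):
            assert abs(bh - b) < 1.96 * se * 1.7  # generous CI band

    def test_null_data_recovers_zero_sensitivities(self):
        rng = np.random.default_rng(2)
        recs = []
        for cd in LEVELS:
            for cp in LEVELS:
                ups = rng.random(400) < 0.5
                recs.append(pd.DataFrame({
                    "task": "direction", "c_dir": cd, "c_dep": cp,
                    "trial": np.arange(400),
                    "choice": np.where(ups, "up", "down")}))
        fit = psy.fit_logistic_task(pd.concat(recs))
        assert abs(fit.beta[1]) < 3 * fit.bse[1]
        assert abs(fit.beta[2]) < 3 * fit.bse[2]

    def test_both_tasks_give_eight_parameters(self):
        fits = psy.fit_both_tasks(_fit(seed=3))
        assert sum(f.beta.size for f in fits.values()) == 8

    def test_single_condition_rejected(self):
        df = pd.DataFrame({"task": "direction", "c_dir": 0.0, "c_dep": 0.0,
                           "trial": range(10),
                           "choice": ["up", "down"] * 5})
        with pytest.raises(ValueError):
            psy.fit_logistic_task(df)

    def test_separation_flagged_not_silently_clipped(self):
        rng = np.random.default_rng(4)
        recs = []
        for cd in (-0.5, -0.25, 0.25, 0.5):
            recs.append(pd.DataFrame({
                "task": "direction", "c_dir": cd, "c_dep": 0.0,
                "trial": np.arange(50),
                "choice": "up" if cd > 0 else "down"}))
        # one mixed condition so both choices appear
        ups = rng.random(50) < 0.5
        recs.append(pd.DataFrame({
            "task": "direction", "c_dir": 0.0, "c_dep": 0.0,
            "trial": np.arange(50), "choice": np.where(ups, "up", "down")}))
        fit = psy.fit_logistic_task(pd.concat(recs))
        assert fit.separation
        assert np.isfinite(fit.beta).all()


class TestMixtureFit:
    def test_zero_error_rate_recovered_and_aic_penalty_respected(self):
        trials = _fit(p_err=0.0, seed=5)
        report = psy.compare_models(trials, seed=5)
        assert report["mixture"].p_err < 0.02
        assert report["aic_9param"] >= report["aic_8param"] - 2.0

    def test_moderate_error_rate_recovered(self):
        trials = _fit(p_err=0.2, seed=6)
        fit = psy.fit_mixture(trials, seed=6)
        assert 0.1 <= fit.p_err <= 0.3

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_mixture_nests_eight_parameter_model(self, seed):
        trials = _fit(p_err=0.1, n=300, seed=seed)
        report = psy.compare_models(trials, seed=seed)
        assert report["llf_9param"] >= report["llf_8param"] - 1e-6

    def test_error_rate_not_redundant_under_nonlinearity(self):
        # with strong sensitivities, wrong-task mixing is not absorbable by
        # a larger irrelevant slope: the mixture strictly improves the fit
        trials = _fit(p_err=0.2, n=2000, seed=10)
        report = psy.compare_models(trials, seed=10)
        assert report["llf_9param"] - report["llf_8param"] > 2.0
        assert report["aic_9param"] < report["aic_8param"]

    def test_requires_both_tasks(self):
        trials = _fit(seed=11)
        with pytest.raises(ValueError):
            psy.fit_mixture(trials[trials["task"] == "direction"])

    def test_parameter_ci_coverage_is_calibrated(self):
        truth = np.array([0.0, 6.0, 1.0, 0.0])
        hits = 0
        for i in range(100):
            trials = psy.simulate_choices(truth, BETA_DEP, 0.0, LEVELS, 200,
                                          seed=5000 + i)
            fit = psy.fit_logistic_task(trials[trials["task"] == "direction"])
            lo = fit.beta[1] - 1.96 * fit.bse[1]
            hi = fit.beta[1] + 1.96 * fit.bse[1]
            hits += lo <= truth[1] <= hi
        assert 90 <= hits <= 99


def _lf(task, beta):
    return psy.LogisticFit(task=task, beta=np.asarray(beta, float),
                           bse=np.zeros(4), cov=np.zeros((4, 4)), llf=-1.0,
                           converged=True, separation=False)


class TestSwitchRatio:
    def test_perfect_switching_is_one(self):
        sr = psy.switch_ratio(_lf("direction", [0, 5, 0, 0]),
                              _lf("depth", [0, 0, 5, 0]))
        assert sr.value == 1.0

    def test_oblivious_observer_is_zero(self):
        sr = psy.switch_ratio(_lf("direction", [0, 3, 3, 0]),
                              _lf("depth", [0, 3, 3, 0]))
        assert sr.value == 0.0

    def test_worked_arithmetic_example(self):
        # ((2-1)/(2+1) + (3-1)/(3+1)) / 2 = 0.41667
        sr = psy.switch_ratio(_lf("direction", [0, 2, 1, 0]),
                              _lf("depth", [0, 1, 3, 0]))
        assert sr.value == pytest.approx(0.41667, abs=1e-5)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            psy.switch_ratio(_lf("direction", [0, 1, -1, 0]),
                             _lf("depth", [0, -1, 1, 0]))


class TestThresholds:
    def _trials(self, p_correct_fn, n=300, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for c in (0.0625, 0.125, 0.25, 0.5):
            for sgn in (1, -1):
                correct = rng.random(n) < p_correct_fn(c)
                up = correct if sgn > 0 else ~correct
                recs.append(pd.DataFrame({
                    "task": "direction", "c_dir": sgn * c, "c_dep": 0.0,
                    "trial": np.arange(n),
                    "choice": np.where(up, "up", "down")}))
        return pd.concat(recs, ignore_index=True)

    def test_recovers_known_weibull_threshold(self):
        alpha, beta = 0.15, 1.8
        trials = self._trials(lambda c: 1 - 0.5 * np.exp(-(c / alpha) ** beta),
                              n=2000, seed=1)
        res = psy.threshold_75(trials)
        truth = alpha * np.log(2) ** (1 / beta)
        assert res.flag == "ok"
        assert res.threshold == pytest.approx(truth, rel=0.1)

    def test_perfect_observer_flagged_below_minimum(self):
        trials = self._trials(lambda c: 1.0, seed=2)
        res = psy.threshold_75(trials)
        assert res.flag == "below_min"
        assert res.threshold < 0.0625

    def test_chance_performance_flagged_above_maximum(self):
        trials = self._trials(lambda c: 0.5, seed=3)
        res = psy.threshold_75(trials)
        assert res.flag == "above_max" and res.threshold is None

    def test_direction_threshold_smaller_when_direction_gain_larger(self):
        # simulated observer more sensitive to direction than depth
        trials = psy.simulate_choices(BETA_DIR, BETA_DEP, 0.0,
                                      np.array([-0.5, -0.25, -0.0625, 0.0,
                                                0.0625, 0.25, 0.5]),
                                      500, seed=12)
        thr = {t: psy.threshold_75(trials[trials["task"] == t]).threshold
               for t in ("direction", "depth")}
        assert thr["direction"] < thr["depth"]

    def test_percent_correct_excludes_zero_strength(self):
        trials = self._trials(lambda c: 0.8, seed=4)
        zero = pd.DataFrame({"task": "direction", "c_dir": 0.0, "c_dep": 0.0,
                             "trial": np.arange(100), "choice": "up"})
        pc, se, n = psy.percent_correct(pd.concat([trials, zero]))
        assert n == len(trials)
        assert pc == pytest.approx(0.8, abs=3 * se)


class TestNeurometrics:
    def test_flat_responses_excluded(self):
        counts = pd.DataFrame({
            "signed_level": np.repeat([0.1, -0.1, 0.2, -0.2, 0.4, -0.4], 30),
            "count": 7,
        })
        res = psy.neurometric_threshold(counts, neuron_id=0, feature="dir")
        assert res.flag == "excluded" and res.threshold is None

    def test_tuned_neuron_threshold_tracks_gain(self):
        spec_hi = smt.NeuronSpec(0, "up", "far", 30.0, 60.0, 10.0)
        spec_lo = smt.NeuronSpec(1, "up", "far", 30.0, 20.0, 10.0)
        levels = np.array([0.0625, 0.125, 0.25, 0.5])
        thr = []
        for spec in (spec_hi, spec_lo):
            counts = smt.neuron_level_counts(spec, "dir", levels, 120, seed=5)
            thr.append(psy.neurometric_threshold(counts, spec.id, "dir").threshold)
        assert thr[0] < thr[1]

    def test_balanced_selection_equalizes_mean_thresholds(self, default_population):
        nm = psy.population_neurometrics(
            default_population, np.array([0.0625, 0.125, 0.25, 0.5]),
            n_trials=80, seed=22)
        ids = psy.select_balanced(nm, k=40)
        assert len(ids) == 40
        sel = nm[nm["neuron_id"].isin(ids)]
        mean_dir = sel["thr_dir"].mean()
        mean_dep = sel["thr_dep"].mean()
        assert abs(mean_dir - mean_dep) / np.mean([mean_dir, mean_dep]) <= 0.1

    def test_selected_subset_feeds_a_second_table(self):
        pop = smt.make_population(12, seed=23)
        ids = [s.id for s in pop[:8]]
        table = smt.build_rate_table(smt.subset_population(pop, ids),
                                     levels=[-0.25, 0.0, 0.25],
                                     trials_per_condition=3, seed=24)
        assert table.n_neurons == 8
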