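"""Synthetic MT population: tuning, Poisson front end, KDE, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from taskswitch import synthetic_mt as smt
from taskswitch.timebase import N_BINS, time_grid

from conftest import LEVELS5


class TestMakePopulation:
    def test_all_quadrants_present_at_117(self):
        pop = smt.make_population(117, seed=1)
        assert len(pop) == 117
        quads = {(s.pref_dir, s.pref_depth) for s in pop}
        assert len(quads) == 4

    def test_four_neurons_cover_each_quadrant_once(self):
        pop = smt.make_population(4, seed=0)
        quads = [(s.pref_dir, s.pref_depth) for s in pop]
        assert sorted(quads) == sorted(
            [("up", "far"), ("down", "far"), ("up", "near"), ("down", "near")])

    def test_direction_tuning_stronger_than_depth_by_default(self):
        pop = smt.make_population(117, seed=1)
        assert (np.mean([s.dir_gain for s in pop])
                > np.mean([s.depth_gain for s in pop]))

    def test_balanced_config_equalizes_sensitivities(self):
        pop = smt.make_population(40, seed=2, tuning=smt.TuningConfig.balanced())
        ratio = (np.mean([s.dir_gain for s in pop])
                 / np.mean([s.depth_gain for s in pop]))
        assert 0.9 <= ratio <= 1.1

    def test_deterministic_for_fixed_seed(self):
        assert smt.make_population(10, seed=5) == smt.make_population(10, seed=5)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            smt.make_population(0, seed=0)


class TestRateFunction:
    spec = smt.NeuronSpec(id=0, pref_dir="up", pref_depth="far",
                          baseline_rate=10.0, dir_gain=40.0, depth_gain=20.0,
                          latency=100.0, transient_amp=0.0)

    def test_baseline_before_latency(self):
        assert smt.rate_function(self.spec, 0.7, -0.3, 0.0) == pytest.approx(0.010)

    def test_linear_tuning_after_latency(self):
        # 10 + 40*0.5 = 30 spikes/s = 0.030 spikes/ms
        assert smt.rate_function(self.spec, 0.5, 0.0, 200.0) == pytest.approx(0.030)

    def test_negative_drive_clipped_to_zero(self):
        # 10 - 40 - 20 = -50 spikes/s -> 0
        assert smt.rate_function(self.spec, -1.0, -1.0, 200.0) == 0.0

    def test_out_of_range_strength_rejected(self):
        with pytest.raises(ValueError):
            smt.rate_function(self.spec, 1.2, 0.0, 200.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c1=st.floats(-1, 1), c2=st.floats(-1, 1),
           tau=st.floats(100, 550))
    def test_monotone_in_both_strengths(self, c1, c2, tau):
        lo, hi = sorted((c1, c2))
        assert (smt.rate_function(self.spec, lo, 0.0, tau)
                <= smt.rate_function(self.spec, hi, 0.0, tau))
        assert (smt.rate_function(self.spec, 0.0, lo, tau)
                <= smt.rate_function(self.spec, 0.0, hi, tau))


class TestGenerateSpikeTrain:
    def test_zero_rate_gives_no_spikes(self):
        assert smt.generate_spike_train(np.zeros(100), seed=0).sum() == 0

    def test_rate_above_one_per_bin_spikes_surely(self):
        assert (smt.generate_spike_train(np.full(50, 1.5), seed=0) == 1).all()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            smt.generate_spike_train(np.array([0.01, -0.01]), seed=0)

    def test_count_statistics_match_binomial(self):
        # 500 bins at 0.05 spikes/ms: counts ~ Binomial(500, 0.05)
        rng = np.random.default_rng(3)
        counts = np.array([
            smt.generate_spike_train(np.full(500, 0.05), rng).sum()
            for _ in range(10_000)])
        mean, var = 500 * 0.05, 500 * 0.05 * 0.95
        sem = np.sqrt(var / counts.size)
        assert abs(counts.mean() - mean) < 3 * sem
        assert abs(counts.var() - var) / var < 0.1

    def test_reproducible_for_fixed_seed(self):
        r = np.linspace(0, 0.2, 300)
        assert (smt.generate_spike_train(r, 11)
                == smt.generate_spike_train(r, 11)).all()


class TestKdeRate:
    def test_empty_train_is_zero(self):
        assert not smt.kde_rate(np.zeros(N_BINS, dtype=np.uint8)).any()

    def test_single_spike_symmetric_with_truncated_support(self):
        bins = np.zeros(N_BINS, dtype=np.uint8)
        t = time_grid()
        i = np.flatnonzero(t == 300)[0]
        rate = smt.kde_rate(bins | (t == 300).astype(np.uint8))
        assert rate[i - 60:i + 61] == pytest.approx(rate[i - 60:i + 61][::-1])
        assert not rate[t < 240 - 1].any() and not rate[t > 360].any()

    def test_truncated_kernel_mass_is_3_sigma_gaussian_mass(self):
        # the kernel is cut at +/-3 SD and not renormalized
        mass = smt.kde_kernel().sum()
        assert mass == pytest.approx(stats.norm.cdf(3) - stats.norm.cdf(-3),
                                     abs=1e-3)

    def test_total_mass_is_count_times_kernel_mass(self):
        bins = np.zeros(N_BINS, dtype=np.uint8)
        bins[200:600:17] = 1  # interior spikes, kernel support uncut
        total = smt.kde_rate(bins).sum()
        assert total == pytest.approx(bins.sum() * smt.kde_kernel().sum(),
                                      abs=1e-9)


def _constant_train(nid, task, cd, cp, rate, seed):
    rates = np.full(N_BINS, rate)
    return smt.SpikeTrain(neuron_id=nid, task=task, c_dir=cd, c_dep=cp,
                          bins=smt.generate_spike_train(rates, seed))


class TestAveragePopulationRates:
    def test_single_neuron_table_equals_its_kde(self):
        trains = [smt.SpikeTrain(0, task, 0.0, 0.0,
                                 smt.generate_spike_train(np.full(N_BINS, 0.02),
                                                          s))
                  for s, task in enumerate(("direction", "depth"))]
        table = smt.average_population_rates(trains, levels=[0.0])
        for tr in trains:
            assert table.lookup(0, 0, tr.task) == pytest.approx(
                smt.kde_rate(tr.bins))

    def test_two_constant_neurons_average(self):
        trains = []
        for nid, rate in ((0, 1.0), (1, 1.0)):
            for task in ("direction", "depth"):
                bins = np.full(N_BINS, nid)  # neuron 0 silent, neuron 1 tonic
                trains.append(smt.SpikeTrain(nid, task, 0.0, 0.0, bins))
        table = smt.average_population_rates(trains, levels=[0.0])
        mid = table.lookup(0, 0, "direction")[100:700]
        expected = 0.5 * smt.kde_kernel().sum()  # mean of 0 and ~1 spikes/ms
        assert mid == pytest.approx(expected, rel=1e-6)

    def test_missing_cell_is_named(self):
        trains = [_constant_train(0, "direction", 0.0, 0.0, 0.02, 1)]
        with pytest.raises(smt.MissingDataError, match="depth"):
            smt.average_population_rates(trains, levels=[0.0])

    def test_fast_table_build_matches_explicit_averaging(self):
        pop = smt.make_population(2, seed=3)
        levels = np.array([-0.25, 0.0, 0.25])
        fast = smt.build_rate_table(pop, levels=levels,
                                    trials_per_condition=40, seed=4)
        rng = np.random.default_rng(4)
        trains = []
        for spec in pop:
            for task in ("direction", "depth"):
                for cd in levels:
                    for cp in levels:
                        for _ in range(40):
                            trains.append(smt.SpikeTrain(
                                spec.id, task, cd, cp,
                                smt.generate_spike_train(
                                    smt.rate_series(spec, cd, cp), rng)))
        slow = smt.average_population_rates(trains, levels=levels)
        for task in ("direction", "depth"):
            # per-condition time-averaged rates agree to Monte-Carlo error
            a = fast.rates[task].mean(axis=2)
            b = slow.rates[task].mean(axis=2)
            assert np.allclose(a, b, atol=3e-3)

    def test_table_is_monotone_in_relevant_strength(self, default_table):
        win = slice(250, 600)
        hi = default_table.lookup(0.5, 0.0, "direction")[win].mean()
        lo = default_table.lookup(-0.5, 0.0, "direction")[win].mean()
        assert hi > lo

    def test_preference_symmetric_populations_give_similar_tables(self):
        # preferred-frame reduction: an all-up/far population and an
        # all-down/near population are statistically interchangeable
        cfg = smt.TuningConfig()
        pops = []
        for seed in (10, 11):
            pop = smt.make_population(40, seed=seed)
            pops.append([s for s in pop
                         if (s.pref_dir, s.pref_depth) in
                         ((("up", "far"),) if seed == 10
                          else (("down", "near"),))])
        tables = [smt.build_rate_table(p, levels=LEVELS5,
                                       trials_per_condition=20, seed=s)
                  for p, s in zip(pops, (12, 13))]
        win = slice(250, 600)
        for c in (0.5, -0.5):
            m = [t.lookup(c, 0.0, "direction")[win].mean() for t in tables]
            assert abs(m[0] - m[1]) / np.mean(m) < 0.25


class TestRateTableContainer:
    def test_lookup_off_grid_raises(self, small_table):
        with pytest.raises(LookupError):
            small_table.lookup(0.3, 0.0, "direction")

    def test_round_trip_through_long_frame(self, small_table):
        again = smt.PopulationRateTable.from_frame(small_table.to_frame())
        for task in ("direction", "depth"):
            assert np.allclose(again.rates[task], small_table.rates[task])
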