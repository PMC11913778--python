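"""Synchrony, PSTH entropy, evoked rate, rate residualization and decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gabashunt import spike_metrics as sm
from gabashunt.spike_metrics import SpikeRaster


def _raster(spikes, window=(0.0, 12.0), **kw):
    return SpikeRaster(
        [[np.asarray(t, float) for t in per] for per in spikes], window, **kw
    )


class TestSynchrony:
    def test_same_bin_gives_one(self):
        r = _raster([[[3.4]], [[3.6]]])
        np.testing.assert_allclose(sm.synchrony_per_neuron(r), [1.0, 1.0])

    def test_different_bins_give_half(self):
        r = _raster([[[3.4]], [[7.6]]])
        np.testing.assert_allclose(sm.synchrony_per_neuron(r), [0.5, 0.5])

    def test_single_neuron_reads_one(self):
        # a lone neuron spiking once per trial always reads the full
        # population response, whatever bin it lands in
        r = _raster([[[1.2], [5.5], [9.9]]])
        np.testing.assert_allclose(sm.synchrony_per_neuron(r), [1.0])

    def test_zero_spike_neuron_flagged_nan(self):
        r = _raster([[[3.0]], [[]]])
        out = sm.synchrony_per_neuron(r)
        assert out[0] == 1.0 and np.isnan(out[1])

    def test_bounded_and_neuron_relabel_invariant(self):
        rng = np.random.default_rng(0)
        spikes = [
            [np.sort(rng.uniform(0, 12, rng.integers(0, 5))) for _ in range(20)]
            for _ in range(8)
        ]
        r = _raster(spikes)
        s = sm.synchrony_per_neuron(r)
        valid = s[np.isfinite(s)]
        assert np.all((valid >= 0) & (valid <= 1))
        perm = rng.permutation(8)
        s_perm = sm.synchrony_per_neuron(_raster([spikes[j] for j in perm]))
        np.testing.assert_allclose(s_perm, s[perm])

    def test_empty_raster_errors(self):
        with pytest.raises(ValueError):
            sm.synchrony_per_neuron(SpikeRaster([], (0, 12)))

    def test_exclude_self_option_lowers_coupling(self):
        # a neuron spiking alone in its bin reads 1/total with self-inclusion
        # but 0 once its own spike is removed from the population response
        r = _raster([[[7.6]], [[3.5]]])
        with_self = sm.synchrony_per_neuron(r, include_self=True)
        without = sm.synchrony_per_neuron(r, include_self=False)
        assert with_self[0] == pytest.approx(0.5)
        assert without[0] == pytest.approx(0.0)


class TestEntropy:
    def test_single_bin_zero(self):
        r = _raster([[[3.1], [3.9], [3.5]]])
        assert sm.psth_entropy(r, 0) == pytest.approx(0.0)

    def test_uniform_12_bins(self):
        r = _raster([[np.arange(12) + 0.5]])
        assert sm.psth_entropy(r, 0) == pytest.approx(np.log(12), rel=1e-12)

    def test_two_equal_bins(self):
        r = _raster([[[2.5, 7.5]]])
        assert sm.psth_entropy(r, 0) == pytest.approx(np.log(2), rel=1e-12)

    def test_count_scaling_invariance(self):
        # doubling every bin count leaves the entropy unchanged
        single = _raster([[[1.5, 4.5, 4.6]]])
        double = _raster([[[1.5, 4.5, 4.6], [1.5, 4.5, 4.6]]])
        assert sm.psth_entropy(double, 0) == pytest.approx(sm.psth_entropy(single, 0))

    def test_zero_spikes_nan(self):
        r = _raster([[[]]])
        assert np.isnan(sm.psth_entropy(r, 0))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.01, 11.99), min_size=1, max_size=30))
    def test_bounded_by_log_nbins(self, times):
        r = _raster([[sorted(times)]])
        h = sm.psth_entropy(r, 0)
        assert -1e-12 <= h <= np.log(12) + 1e-12


class TestEvokedRate:
    def test_arithmetic(self):
        # 3 spikes over 30 trials in a 10 ms window -> 10 Hz
        spikes = [[[] for _ in range(30)]]
        spikes[0][0] = [3.0]
        spikes[0][10] = [4.0]
        spikes[0][29] = [9.0]
        r = _raster(spikes, window=(2.0, 12.0))
        assert sm.evoked_rate(r, 0) == pytest.approx(10.0)

    def test_zero_spikes(self):
        r = _raster([[[] for _ in range(5)]])
        assert sm.evoked_rate(r, 0) == 0.0


class TestRegressOutRate:
    def test_uncorrelated_metric_residuals_centered(self):
        rng = np.random.default_rng(1)
        rates = rng.uniform(1, 50, 200)
        metric = rng.normal(5.0, 1.0, 200)
        out = sm.regress_out_rate(metric, rates)
        resid = out["residuals_rate"]
        np.testing.assert_allclose(resid.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(resid, metric - metric.mean(), atol=0.5)

    def test_linear_metric_residuals_zero(self):
        rates = np.linspace(1, 10, 50)
        out = sm.regress_out_rate(2.0 * rates, rates)
        np.testing.assert_allclose(out["residuals_rate"], 0.0, atol=1e-9)

    def test_condition_difference_survives_residualization(self):
        # two conditions differing in the metric beyond what rate explains
        rng = np.random.default_rng(2)
        n = 120
        rate_a = rng.uniform(5, 20, n)
        rate_b = rate_a + rng.uniform(2, 6, n)  # condition b fires more
        common_slope = 0.01
        metric_a = 0.3 + common_slope * rate_a + rng.normal(0, 0.02, n)
        metric_b = 0.4 + common_slope * rate_b + rng.normal(0, 0.02, n)
        pooled = np.concatenate([metric_a, metric_b])
        rates = np.concatenate([rate_a, rate_b])
        resid = sm.regress_out_rate(pooled, rates)["residuals_rate"]
        test = sm.paired_test(resid[n:], resid[:n])
        assert test["p"] < 0.001 and test["mean_diff"] > 0

    def test_constant_rates_degenerate(self):
        with pytest.raises(np.linalg.LinAlgError):
            sm.regress_out_rate(np.arange(5.0), np.full(5, 3.0))


class TestDecoding:
    def test_perfectly_separated_one_hot(self):
        n_classes, per = 4, 10
        X = np.repeat(np.eye(n_classes) * 10, per, axis=0)
        y = np.repeat(np.arange(n_classes), per)
        out = sm.decode_patterns(X, y, k=3, seed=0)
        assert out["accuracy"] == 1.0

    def test_identical_vectors_at_chance(self):
        rng = np.random.default_rng(3)
        n_classes, per = 5, 40
        X = np.ones((n_classes * per, 10))
        y = np.repeat(np.arange(n_classes), per)
        out = sm.decode_patterns(X, y, k=5, seed=1)
        # all-tie votes: accuracy indistinguishable from chance = 1/5
        assert abs(out["accuracy"] - out["chance"]) < 0.12

    def test_label_shuffle_control(self):
        rng = np.random.default_rng(4)
        n_classes, per = 4, 30
        X = np.vstack([rng.normal(c, 0.3, (per, 8)) for c in range(n_classes)])
        y = np.repeat(np.arange(n_classes), per)
        assert sm.decode_patterns(X, y, seed=2)["accuracy"] > 0.9
        y_shuf = rng.permutation(y)
        acc = sm.decode_patterns(X, y_shuf, seed=2)["accuracy"]
        # binomial CI around chance (n = 120, p = 0.25)
        assert abs(acc - 0.25) < 4 * np.sqrt(0.25 * 0.75 / y.size)

    def test_stratification_error(self):
        X = np.zeros((6, 3))
        y = np.array([0, 0, 0, 0, 1, 1])  # class 1 has 2 < 5 members
        with pytest.raises(ValueError):
            sm.decode_patterns(X, y, folds=5)


class TestRasterIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        spikes = [
            [np.sort(rng.uniform(0, 12, rng.integers(0, 4))) for _ in range(6)]
            for _ in range(4)
        ]
        r = _raster(spikes, trial_labels=np.arange(6) % 3, condition="awake")
        path = tmp_path / "raster.tsv.gz"
        sm.write_raster(r, path)
        back = sm.read_raster(path)
        assert back.n_neurons == 4 and back.n_trials == 6
        assert back.condition == "awake"
        np.testing.assert_array_equal(back.trial_labels, r.trial_labels)
        for j in range(4):
            for t in range(6):
                np.testing.assert_allclose(back.spikes[j][t], spikes[j][t])
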