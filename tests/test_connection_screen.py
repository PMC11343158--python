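"""Synthetic PSC sweeps, averaging, and evoked-response classification."""

import numpy as np
import pytest

from patchwalk.connection_screen import (
    average_sweeps,
    build_stim_train,
    classify_connection,
    screen_pair,
    synthesize_sweep,
)
from patchwalk.connectivity_model import connection_probability


@pytest.fixture
def train():
    return build_stim_train()


class TestStimTrain:
    @pytest.mark.parametrize(
        "n, rate, expected",
        [
            (5, 20.0, [0, 50, 100, 150, 200]),
            (1, 7.0, [0]),
            (3, 10.0, [0, 100, 200]),
        ],
    )
    def test_spike_times(self, n, rate, expected):
        tr = build_stim_train(n, rate)
        assert tr.spike_times_ms == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_stim_train(0, 20.0)
        with pytest.raises(ValueError):
            build_stim_train(5, 0.0)


class TestSynthesizeSweep:
    def test_unconnected_noiseless_sweep_is_flat_zero(self, train):
        sw = synthesize_sweep(train, False, noise_sd_pa=0.0, seed=0)
        assert np.all(sw.current_pa == 0.0)

    def test_connected_noiseless_trough_equals_amplitude(self, train):
        sw = synthesize_sweep(train, True, psc_amplitude_pa=50.0, noise_sd_pa=0.0, seed=0)
        # residual decay from the preceding spike adds <1% at the next trough
        assert sw.current_pa.min() == pytest.approx(-50.0, rel=0.01)

    def test_seed_determinism(self, train):
        a = synthesize_sweep(train, True, noise_sd_pa=5.0, seed=42)
        b = synthesize_sweep(train, True, noise_sd_pa=5.0, seed=42)
        assert np.array_equal(a.current_pa, b.current_pa)


class TestAverageSweeps:
    def test_identical_sweeps_average_to_themselves(self, train):
        sw = synthesize_sweep(train, True, noise_sd_pa=0.0, seed=0)
        avg = average_sweeps([sw, sw, sw])
        np.testing.assert_allclose(avg.current_pa, sw.current_pa, atol=1e-12)

    def test_noise_shrinks_as_sqrt_k(self, train, rng):
        sweeps = [
            synthesize_sweep(train, False, noise_sd_pa=8.0, rng=rng) for _ in range(9)
        ]
        avg = average_sweeps(sweeps)
        assert np.std(avg.current_pa) == pytest.approx(8.0 / 3.0, rel=0.15)

    def test_mismatched_grids_rejected(self, train):
        a = synthesize_sweep(train, False, noise_sd_pa=0.0, sweep_ms=500.0)
        b = synthesize_sweep(train, False, noise_sd_pa=0.0, sweep_ms=400.0)
        with pytest.raises(ValueError):
            average_sweeps([a, b])


class TestClassify:
    def test_noiseless_connection_detected_with_full_amplitude(self, train):
        sw = synthesize_sweep(train, True, psc_amplitude_pa=50.0, noise_sd_pa=0.0)
        res = classify_connection(sw, train)
        assert res.connected
        assert res.mean_evoked_amplitude_pa == pytest.approx(50.0, rel=0.02)
        assert len(res.per_spike_amplitudes_pa) == train.n_spikes

    def test_pure_noise_not_classified_connected(self, train):
        sw = synthesize_sweep(train, False, noise_sd_pa=5.0, seed=11)
        assert not classify_connection(sw, train).connected

    def test_zero_amplitude_is_not_connected(self, train):
        sw = synthesize_sweep(train, True, psc_amplitude_pa=0.0, noise_sd_pa=0.0)
        assert not classify_connection(sw, train).connected

    def test_sweep_order_invariance(self, train, rng):
        sweeps = [
            synthesize_sweep(train, True, noise_sd_pa=5.0, rng=rng) for _ in range(3)
        ]
        fwd = classify_connection(average_sweeps(sweeps), train)
        rev = classify_connection(average_sweeps(sweeps[::-1]), train)
        assert fwd.connected == rev.connected
        assert fwd.mean_evoked_amplitude_pa == pytest.approx(
            rev.mean_evoked_amplitude_pa, abs=1e-9
        )

    def test_window_past_sweep_end_rejected(self, train):
        sw = synthesize_sweep(train, True, noise_sd_pa=0.0, sweep_ms=200.0)
        with pytest.raises(ValueError):
            classify_connection(sw, train)

    def test_false_positive_rate_below_5_percent(self, train, rng):
        hits = sum(
            classify_connection(
                average_sweeps(
                    [synthesize_sweep(train, False, noise_sd_pa=5.0, rng=rng)
                     for _ in range(3)]
                ),
                train,
            ).connected
            for _ in range(400)
        )
        assert hits / 400 < 0.05


class TestScreenPair:
    def test_one_directional_connection(self):
        ab, ba = screen_pair(1, 2, True, False, noise_sd_pa=2.0, seed=5)
        assert (ab.connected, ba.connected) == (True, False)
        assert (ab.pre, ab.post, ba.pre, ba.post) == (1, 2, 2, 1)

    def test_both_unconnected(self):
        ab, ba = screen_pair(1, 2, False, False, noise_sd_pa=2.0, seed=6)
        assert not ab.connected and not ba.connected

    def test_untested_direction_marked(self):
        ab, ba = screen_pair(1, 2, True, True, noise_sd_pa=0.0, untested=[(2, 1)], seed=0)
        assert ab.tested and ab.connected
        assert not ba.tested and not ba.connected

    def test_ground_truth_recovered_at_zero_noise(self, rng):
        for truth_ab in (False, True):
            for truth_ba in (False, True):
                ab, ba = screen_pair(3, 4, truth_ab, truth_ba, noise_sd_pa=0.0, rng=rng)
                assert (ab.connected, ba.connected) == (truth_ab, truth_ba)


def test_detection_rate_recovers_distance_model(train, rng):
    """Fraction of simulated screens classified connected matches the
    distance model within the binomial 95% interval (amplitude 50 pA,
    noise 5 pA, 2000 directed screens at 91.6 um)."""
    d = 91.6
    q = connection_probability(d)
    n = 2000
    truths = rng.random(n) < q
    hits = 0
    for truth in truths:
        sweeps = [
            synthesize_sweep(train, bool(truth), psc_amplitude_pa=50.0,
                             noise_sd_pa=5.0, rng=rng)
            for _ in range(3)
        ]
        hits += classify_connection(average_sweeps(sweeps), train).connected
    half_width = 1.96 * np.sqrt(q * (1 - q) / n)
    assert abs(hits / n - q) < half_width
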