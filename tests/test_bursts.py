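import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meadev.bursts import BurstParams, burst_statistics, detect_bursts
from meadev.spike_io import SpikeTrain

from conftest import train

DEFAULTS = BurstParams()


def reference_bursts(times, p):
    """Independent phase-by-phase simulation of the max-interval method.

    Deliberately naive: explicit state machine for phase 1, repeated
    single-merge passes for phase 2, then the filters.
    """
    times = list(times)
    n = len(times)
    cands = []
    i = 0
    while i < n - 1:
        if times[i + 1] - times[i] < p.max_begin_isi:
            j = i + 1
            while j + 1 < n and times[j + 1] - times[j] < p.max_end_isi:
                j += 1
            cands.append([i, j])
            i = j + 1
        else:
            i += 1
    changed = True
    while changed:
        changed = False
        for k in range(len(cands) - 1):
            if times[cands[k + 1][0]] - times[cands[k][1]] < p.min_ibi:
                cands[k][1] = cands[k + 1][1]
                del cands[k + 1]
                changed = True
                break
    return [
        (s, e)
        for s, e in cands
        if e - s + 1 >= p.min_spikes and times[e] - times[s] >= p.min_duration
    ]


def random_train(rng, n_max=200):
    """Random trains mixing burst-like and sparse ISIs."""
    n = int(rng.integers(0, n_max))
    isis = rng.choice(
        [0.02, 0.05, 0.09, 0.11, 0.2, 0.3, 0.5, 1.0, 2.0], size=n
    ) * rng.uniform(0.5, 1.5, n)
    times = np.cumsum(isis)
    return SpikeTrain(times, 0.0, float(times[-1] + 1.0) if n else 900.0)


class TestWorkedExamples:
    def test_six_spike_burst(self):
        t = train([0.0, 0.05, 0.10, 0.15, 0.20, 0.25])
        bs = detect_bursts(t, DEFAULTS)
        assert len(bs) == 1
        (b,) = bs
        assert b.n_spikes == 6
        assert b.duration == pytest.approx(0.25)

    def test_five_spikes_rejected(self):
        t = train([0.0, 0.05, 0.10, 0.15, 0.20])
        assert len(detect_bursts(t, DEFAULTS)) == 0

    def test_short_gap_merges_to_twelve_spikes(self):
        a = np.arange(6) * 0.05
        b = a + a[-1] + 0.5  # gap 0.5 s < min_ibi 0.8 s
        bs = detect_bursts(train(np.concatenate([a, b])), DEFAULTS)
        assert len(bs) == 1
        assert bs.bursts[0].n_spikes == 12

    def test_long_gap_stays_two_bursts(self):
        a = np.arange(6) * 0.05
        b = a + a[-1] + 2.0
        bs = detect_bursts(train(np.concatenate([a, b])), DEFAULTS)
        assert len(bs) == 2

    def test_empty_train(self):
        assert len(detect_bursts(train([]), DEFAULTS)) == 0

    def test_too_short_duration_rejected(self):
        # 6 spikes packed into 0.04 s < min_duration 0.05 s
        t = train(np.arange(6) * 0.008)
        assert len(detect_bursts(t, DEFAULTS)) == 0


class TestOracleEquivalence:
    def test_matches_reference_on_random_trains(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            t = random_train(rng)
            got = [(b.start_index, b.end_index) for b in detect_bursts(t, DEFAULTS)]
            assert got == reference_bursts(t.times, DEFAULTS)

    @given(st.lists(st.floats(0.001, 3.0), min_size=0, max_size=60), st.integers(0, 2**31))
    @settings(max_examples=60, deadline=None)
    def test_matches_reference_hypothesis(self, isis, seed):
        times = np.cumsum(np.asarray(isis))
        t = SpikeTrain(times, 0.0, float(times[-1] + 1) if len(isis) else 1.0)
        got = [(b.start_index, b.end_index) for b in detect_bursts(t, DEFAULTS)]
        assert got == reference_bursts(t.times, DEFAULTS)


class TestInvariants:
    def test_burstset_invariants_random(self):
        rng = np.random.default_rng(7)
        p = DEFAULTS
        for _ in range(100):
            t = random_train(rng)
            bs = detect_bursts(t, p)
            prev_end = -math.inf
            for b in bs:
                assert b.n_spikes >= p.min_spikes
                assert b.duration >= p.min_duration
                assert b.start_time - prev_end >= p.min_ibi or prev_end == -math.inf
                prev_end = b.end_time

    def test_distant_background_spikes_do_not_alter_bursts(self):
        core = np.arange(6) * 0.05
        bs0 = detect_bursts(train(core), DEFAULTS)
        # add spikes > max_end_isi from the burst and > max_begin_isi apart
        noisy = np.sort(np.concatenate([core, [5.0, 10.0, 20.0, 40.0]]))
        bs1 = detect_bursts(train(noisy), DEFAULTS)
        assert [(b.start_time, b.end_time) for b in bs0] == [
            (b.start_time, b.end_time) for b in bs1
        ]


class TestStatistics:
    def test_regular_bursts_cv_zero(self):
        times = np.concatenate([np.arange(6) * 0.05 + k * 10.0 for k in range(5)])
        t = train(times)
        bs = detect_bursts(t, DEFAULTS)
        assert len(bs) == 5
        stats = burst_statistics(t, bs)
        assert stats["cv_ibi"] == pytest.approx(0.0)
        assert stats["fraction_in_bursts"] == pytest.approx(1.0)

    def test_within_burst_rate_24hz(self):
        t = train(np.linspace(0, 0.25, 6))
        bs = detect_bursts(t, DEFAULTS)
        assert burst_statistics(t, bs)["within_burst_rate"] == pytest.approx(24.0)

    def test_burst_rate_per_minute(self):
        times = np.concatenate([np.arange(6) * 0.05 + k * 30.0 for k in range(30)])
        t = train(times, t_stop=900.0)
        stats = burst_statistics(t, detect_bursts(t, DEFAULTS))
        assert stats["burst_rate"] == pytest.approx(2.0)

    def test_no_bursts_gives_nan_not_zero(self):
        t = train([1.0, 5.0, 9.0])
        stats = burst_statistics(t, detect_bursts(t, DEFAULTS))
        assert all(math.isnan(v) for v in stats.values())

    def test_cv_needs_two_ibis(self):
        times = np.concatenate([np.arange(6) * 0.05, np.arange(6) * 0.05 + 10.0])
        t = train(times)
        stats = burst_statistics(t, detect_bursts(t, DEFAULTS))
        assert math.isnan(stats["cv_ibi"])
        assert not math.isnan(stats["burst_rate"])

    def test_onset_ibi_mode(self):
        times = np.concatenate([np.arange(6) * 0.05 + k * 10.0 for k in range(3)])
        t = train(times)
        bs = detect_bursts(t, DEFAULTS)
        np.testing.assert_allclose(bs.ibis("onset"), [10.0, 10.0])
        np.testing.assert_allclose(bs.ibis("gap"), [9.75, 9.75])


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BurstParams(max_begin_isi=0.3, max_end_isi=0.25)
        with pytest.raises(ValueError):
            BurstParams(min_ibi=-1.0)
        with pytest.raises(ValueError):
            BurstParams(min_spikes=0)

    def test_defaults_match_standard_set(self):
        p = BurstParams()
        assert (p.max_begin_isi, p.max_end_isi, p.min_ibi, p.min_duration, p.min_spikes) == (
            0.1,
            0.25,
            0.8,
            0.05,
            6,
        )
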