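"""Spike-train statistics, Poisson-surprise bursts, waveforms and sorting."""

import math
from itertools import permutations

import numpy as np
import pytest

from optoephys import spiketrains as spk
from optoephys import synthetic as syn


def exact_surprise_oracle(n, duration, rate):
    """-ln P(>= n | Poisson), by direct log-sum-exp over the tail (independent
    of scipy's survival function)."""
    lam = rate * duration
    terms = []
    k = n
    while True:
        logp = -lam + k * math.log(lam) - math.lgamma(k + 1)
        terms.append(logp)
        if k > lam and logp < max(terms) - 60:
            break
        k += 1
    m = max(terms)
    return -(m + math.log(sum(math.exp(t - m) for t in terms)))


class TestTrainStats:
    def test_rate_uses_recording_span(self):
        train = spk.SpikeTrain(np.linspace(0.5, 9.5, 100), (0.0, 10.0))
        assert spk.train_stats(train).rate == pytest.approx(10.0)

    def test_regular_train_has_zero_cv(self):
        train = spk.SpikeTrain(np.arange(1, 60, 1.0), (0.0, 60.0))
        st = spk.train_stats(train)
        assert st.cv_isi == pytest.approx(0.0, abs=1e-12)
        assert st.median_isi == pytest.approx(1.0)

    def test_poisson_train_cv_near_one(self):
        train = syn.gen_spike_train(10.0, 1000.0, seed=11)
        assert spk.train_stats(train).cv_isi == pytest.approx(1.0, abs=0.1)

    def test_empty_and_sparse_trains_flagged(self):
        st = spk.train_stats(spk.SpikeTrain(np.array([]), (0.0, 10.0)))
        assert st.rate == 0.0 and math.isnan(st.cv_isi) and not st.isi_defined
        st2 = spk.train_stats(spk.SpikeTrain(np.array([1.0, 2.0]), (0.0, 10.0)))
        assert not st2.isi_defined

    def test_time_shift_invariance(self):
        train = syn.gen_spike_train(5.0, 100.0, seed=3)
        a = spk.train_stats(train)
        b = spk.train_stats(train.shifted(123.0))
        assert a.rate == pytest.approx(b.rate)
        assert a.cv_isi == pytest.approx(b.cv_isi)
        assert a.median_isi == pytest.approx(b.median_isi)


class TestBurstDetection:
    def test_regular_train_has_no_bursts(self):
        train = spk.SpikeTrain(np.arange(0.5, 99.5, 0.1), (0.0, 100.0))
        assert len(spk.detect_bursts(train).bursts) == 0

    def test_dense_cluster_found_with_exact_surprise(self):
        rng = np.random.default_rng(0)
        background = np.sort(rng.uniform(0, 100, 100))
        cluster = 50.0 + np.arange(10) / 300.0
        times = np.unique(np.concatenate([background, cluster]))
        train = spk.SpikeTrain(times, (0.0, 100.0))
        bs = spk.detect_bursts(train)
        assert len(bs.bursts) == 1
        b = bs.bursts[0]
        assert b.start_s <= 50.0 and b.end_s >= cluster[-1]
        rate = train.n_spikes / 100.0
        assert b.surprise == pytest.approx(
            exact_surprise_oracle(b.n_spikes, b.end_s - b.start_s, rate), abs=1e-9
        )

    def test_homogeneous_poisson_false_positive_fraction(self):
        train = syn.gen_spike_train(10.0, 500.0, seed=21)
        bs = spk.detect_bursts(train)
        assert bs.fraction_in_bursts < 0.05

    def test_injected_burst_recovery(self):
        base = syn.gen_spike_train(1.0, 300.0, seed=5)
        train, wins = syn.inject_bursts(base, 0.2, spikes_per_burst=6, intra_isi=0.004, seed=6)
        bs = spk.detect_bursts(train)
        recovered = 0
        for s, e in wins:
            for b in bs.bursts:
                lo, hi = max(s, b.start_s), min(e, b.end_s)
                if hi > lo and (hi - lo) >= 0.5 * (e - s):
                    recovered += 1
                    break
        assert recovered / len(wins) >= 0.9

    def test_removing_burst_spikes_removes_bursts(self):
        base = syn.gen_spike_train(1.0, 300.0, seed=7)
        train, wins = syn.inject_bursts(base, 0.2, seed=8)
        keep = np.ones(train.times.size, dtype=bool)
        for s, e in wins:
            keep &= ~((train.times >= s - 1e-9) & (train.times <= e + 1e-9))
        stripped = spk.SpikeTrain(train.times[keep], train.span)
        assert len(spk.detect_bursts(stripped).bursts) <= 1

    def test_all_surprises_match_oracle(self):
        base = syn.gen_spike_train(8.0, 200.0, shape=1.0, seed=9)
        train, _ = syn.inject_bursts(base, 0.1, seed=10)
        bs = spk.detect_bursts(train)
        rate = train.n_spikes / train.span_length
        for b in bs.bursts:
            assert b.surprise == pytest.approx(
                exact_surprise_oracle(b.n_spikes, b.end_s - b.start_s, rate), abs=1e-9
            )

    def test_fraction_bounds(self):
        train = syn.gen_spike_train(20.0, 100.0, seed=12)
        bs = spk.detect_bursts(train)
        assert 0.0 <= bs.fraction_in_bursts <= 1.0


class TestWaveformExtraction:
    def test_noiseless_recovery(self):
        sig, truth = syn.gen_raw_trace(
            syn.default_templates(), [5.0, 5.0, 5.0], noise_sd=0.0, duration=5.0, seed=0
        )
        times, waves = spk.extract_waveforms(sig.samples, sig.fs, threshold=-40.0)
        assert times.size >= truth["times"].size
        for t in truth["times"]:
            assert np.min(np.abs(times - t)) < 0.0005

    def test_zero_signal_has_no_events(self):
        times, waves = spk.extract_waveforms(np.zeros(50_000), 25_000.0, threshold=-40.0)
        assert times.size == 0

    def test_high_snr_recovery_rate(self):
        sig, truth = syn.gen_raw_trace(
            syn.default_templates(), [5.0, 5.0, 5.0], noise_sd=10.0, duration=20.0, seed=1
        )
        times, _ = spk.extract_waveforms(sig.samples, sig.fs, threshold=-45.0)
        # spikes closer than the 1 ms refractory censor (cross-unit
        # collisions) cannot both be detected by design; exclude them
        tt = truth["times"]
        detectable = np.concatenate([[True], np.diff(tt) >= 0.001])
        hit = sum(np.min(np.abs(times - t)) < 0.0002 for t in tt[detectable])
        assert hit / detectable.sum() >= 0.99

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            spk.extract_waveforms(np.zeros(100), 1000.0, threshold=-40.0)


class TestSpikeSorting:
    def best_permutation_accuracy(self, labels, truth):
        k = int(max(labels.max(), truth.max())) + 1
        return max(
            np.mean(np.array([p[l] for l in labels]) == truth)
            for p in permutations(range(k))
        )

    def test_three_template_accuracy(self):
        sig, truth = syn.gen_raw_trace(
            syn.default_templates(), [5.0, 5.0, 5.0], noise_sd=10.0, duration=20.0, seed=2
        )
        times, waves = spk.extract_waveforms(sig.samples, sig.fs, threshold=-45.0)
        matched = []
        for t in times:
            j = int(np.argmin(np.abs(truth["times"] - t)))
            matched.append(truth["labels"][j] if abs(truth["times"][j] - t) < 5e-4 else -1)
        matched = np.asarray(matched)
        labels, _, sil = spk.sort_spikes(waves, k=3, seed=0)
        m = matched >= 0
        assert self.best_permutation_accuracy(labels[m], matched[m]) >= 0.95

    def test_identical_waveforms_single_cluster(self):
        waves = [spk.Waveform(np.ones(40), 25_000.0)] * 20
        labels, _, sil = spk.sort_spikes(waves, k=1, seed=0)
        assert np.all(labels == 0) and sil is None

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        waves = [spk.Waveform(rng.normal(size=40), 25_000.0) for _ in range(60)]
        a, _, _ = spk.sort_spikes(waves, k=3, seed=5)
        b, _, _ = spk.sort_spikes(waves, k=3, seed=5)
        assert np.array_equal(a, b)

    def test_invalid_k_rejected(self):
        waves = [spk.Waveform(np.ones(40), 25_000.0)] * 5
        with pytest.raises(ValueError):
            spk.sort_spikes(waves, k=0)


class TestWaveformWidth:
    def make(self, t2p_ms, fs=25_000.0):
        n = int(0.002 * fs)
        w = np.zeros(n)
        i_trough = n // 3
        w[i_trough] = -100.0
        w[i_trough + int(round(t2p_ms / 1000 * fs))] = 40.0
        return spk.Waveform(w, fs)

    @pytest.mark.parametrize(
        "t2p,expected", [(0.2, "narrow"), (0.6, "broad")],
    )
    def test_cutoff_classification(self, t2p, expected):
        assert spk.classify_width(self.make(t2p)) == expected

    def test_boundary_is_broad(self):
        # 0.35 ms trough-to-peak: strict < means broad
        fs = 40_000.0
        assert spk.classify_width(self.make(0.35, fs)) == "broad"

    def test_missing_peak_unclassifiable(self):
        w = spk.Waveform(np.linspace(0, -100, 50), 25_000.0)  # trough at the end
        assert spk.classify_width(w) is None
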