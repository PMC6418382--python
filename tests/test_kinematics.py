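"""Kinematics: rotational speed, immobility, trial classification, triggered
averages, peak rotations, and the resultant-vector alignment statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from optoephys import kinematics as kin
from optoephys import synthetic as syn
from optoephys.io import EventSeries


def make_record(gyro, fs=200.0):
    gyro = np.asarray(gyro, dtype=float)
    accel = np.tile([0.0, 0.0, -1.0], (gyro.shape[0], 1))
    return kin.InertialRecord(accel, gyro, fs)


class TestRotationalSpeed:
    def test_pythagorean_triple(self):
        rec = make_record([[3.0, 4.0, 0.0]])
        assert kin.rotational_speed(rec)[0] == 5.0

    def test_zero_vector(self):
        assert kin.rotational_speed(make_record([[0.0, 0.0, 0.0]]))[0] == 0.0

    def test_channel_permutation_invariance(self, rng):
        g = rng.normal(size=(100, 3))
        assert np.allclose(
            kin.rotational_speed(make_record(g)),
            kin.rotational_speed(make_record(g[:, [2, 0, 1]])),
        )

    def test_missing_channels_rejected(self):
        with pytest.raises(ValueError):
            kin.rotational_speed(np.zeros((10, 2)))


class TestImmobilitySegmentation:
    def test_constant_slow_speed_is_one_segment(self):
        segs = kin.segment_immobility(np.full(2000, 5.0), fs=200.0)
        assert segs.segments == [(0.0, 10.0)]

    def test_constant_fast_speed_has_no_segments(self):
        assert len(kin.segment_immobility(np.full(2000, 25.0), fs=200.0)) == 0

    def test_sub_second_dip_is_too_short(self):
        speed = np.full(2000, 25.0)
        speed[500:600] = 5.0  # 0.5 s below threshold
        assert len(kin.segment_immobility(speed, fs=200.0)) == 0

    def test_boundary_samples_excluded_by_strict_threshold(self):
        speed = np.full(400, 20.0)  # exactly at threshold -> not immobile
        assert len(kin.segment_immobility(speed, fs=200.0)) == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=400), st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_run_oracle(self, mask, seed):
        fs, min_dur = 10.0, 1.0
        speed = np.where(mask, 5.0, 25.0)
        got = kin.segment_immobility(speed, fs, min_duration=min_dur).segments
        # oracle: explicit scan over maximal runs
        expected, start = [], None
        for i, below in enumerate(mask + [False]):
            if below and start is None:
                start = i
            elif not below and start is not None:
                if (i - start) / fs >= min_dur:
                    expected.append((start / fs, i / fs))
                start = None
        assert got == pytest.approx(expected)


class TestTrialClassification:
    def test_flat_quiet_pre_second_is_rest(self):
        ev = EventSeries([5.0], [6.0])
        labels = kin.classify_trials(ev, np.zeros(2000), fs=200.0)
        assert labels == ["rest"]

    def test_single_fast_sample_makes_trial_active(self):
        speed = np.zeros(2000)
        speed[950] = 30.0  # inside [4 s, 5 s)
        ev = EventSeries([5.0], [6.0])
        assert kin.classify_trials(ev, speed, fs=200.0) == ["active"]

    def test_insufficient_history_is_excluded(self):
        ev = EventSeries([0.5], [1.5])
        assert kin.classify_trials(ev, np.zeros(2000), fs=200.0) == [None]

    def test_labels_match_generator_truth(self, sim_config, events):
        rec, truth = syn.gen_inertial(
            sim_config, events, kappa=1e9, baseline_speed=2.0, active_prob=0.5, seed=9
        )
        speed = kin.rotational_speed(rec)
        labels = kin.classify_trials(events, speed, rec.fs)
        expected = ["active" if a else "rest" for a in truth["active"]]
        assert labels == expected


class TestStimTriggeredAverage:
    def test_constant_signal_reproduced_with_zero_sd(self):
        ev = EventSeries([2.0, 4.0, 6.0], [3.0, 5.0, 7.0])
        avg = kin.stim_triggered_average(np.full(2000, 3.3), 200.0, ev, (-0.5, 0.5))
        assert np.allclose(avg.mean, 3.3) and np.allclose(avg.sd, 0.0)
        assert avg.n_trials == 3

    def test_white_noise_mean_shrinks_as_sqrt_n(self, rng):
        fs = 100.0
        onsets = np.arange(1.0, 257.0, 2.0)
        ev = EventSeries(onsets, onsets + 1.0)
        x = rng.normal(size=int(260 * fs))
        rms = {}
        for n in (4, 64):
            sub = EventSeries(onsets[:n], onsets[:n] + 1.0)
            avg = kin.stim_triggered_average(x, fs, sub, (0.0, 1.0))
            rms[n] = np.sqrt(np.mean(avg.mean ** 2))
        assert rms[4] / rms[64] == pytest.approx(4.0, rel=0.45)

    def test_zero_usable_trials_raises(self):
        ev = EventSeries([100.0], [101.0])
        with pytest.raises(ValueError):
            kin.stim_triggered_average(np.zeros(200), 100.0, ev, (0.0, 1.0))


class TestPeakRotationDetection:
    def test_recovers_injected_bump(self, sim_config, events):
        rec, _ = syn.gen_inertial(
            sim_config, events, kappa=1e9, peak_speed=38.0, latency=0.2,
            baseline_speed=0.0, seed=0,
        )
        for e in kin.detect_peak_rotation(rec, events, phase="post"):
            assert e.latency == pytest.approx(0.2, abs=0.005)
            assert e.peak_speed == pytest.approx(38.0, abs=1.0)

    def test_monotone_speed_peaks_at_window_end(self):
        n = 2000
        gyro = np.zeros((n, 3))
        gyro[:, 2] = np.linspace(0, 50, n)
        rec = make_record(gyro)
        ev = EventSeries([2.0], [3.0])
        (e,) = kin.detect_peak_rotation(rec, ev, phase="during")
        assert e.latency == pytest.approx(1.0, abs=0.01)

    def test_window_outside_recording_raises(self):
        rec = make_record(np.zeros((100, 3)))
        ev = EventSeries([0.2], [0.4])
        with pytest.raises(ValueError):
            kin.detect_peak_rotation(rec, ev, phase="post", window=(0.0, 5.0))

    def test_zero_gyro_is_flagged(self):
        rec = make_record(np.zeros((2000, 3)))
        ev = EventSeries([2.0], [3.0])
        (e,) = kin.detect_peak_rotation(rec, ev, phase="post")
        assert e.peak_speed == 0.0 and e.flagged


def ev(peak, axis):
    return kin.RotationEvent(0, "post", peak, 0.2, np.asarray(axis, dtype=float))


class TestResultantVector:
    def test_identical_axes_have_length_one(self):
        s = kin.resultant_vector([ev(40.0, [0, 0, 1])] * 10)
        assert s.length == pytest.approx(1.0, abs=1e-12)
        assert s.n_trials_used == 10

    def test_antipodal_axes_cancel(self):
        s = kin.resultant_vector([ev(40.0, [0, 0, 1]), ev(40.0, [0, 0, -1])])
        assert s.length == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_triple(self):
        s = kin.resultant_vector([ev(40.0, [1, 0, 0]), ev(40.0, [0, 1, 0]), ev(40.0, [0, 0, 1])])
        assert s.length == pytest.approx(np.sqrt(3) / 3, abs=1e-12)

    def test_slow_trials_excluded_strictly(self):
        events = [ev(40.0, [0, 0, 1]), ev(10.0, [1, 0, 0]), ev(5.0, [0, 1, 0])]
        s = kin.resultant_vector(events)  # 10 deg/s is not > 10
        assert s.n_trials_used == 1

    def test_no_qualifying_trials_raises(self):
        with pytest.raises(ValueError):
            kin.resultant_vector([ev(5.0, [0, 0, 1])])


class TestMonteCarloNull:
    def test_single_vector_length_is_one(self):
        null = kin.mc_null_resultant(n_max=3, n_samples=500, seed=0)
        assert null.mean_length[0] == pytest.approx(1.0, abs=1e-12)
        assert null.lo[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_vector_closed_form(self):
        null = kin.mc_null_resultant(n_max=2, n_samples=10_000, seed=1)
        assert null.mean_length[1] == pytest.approx(2.0 / 3.0, abs=0.01)

    def test_seeded_reproducibility(self):
        a = kin.mc_null_resultant(n_max=10, n_samples=1000, seed=42)
        b = kin.mc_null_resultant(n_max=10, n_samples=1000, seed=42)
        assert np.array_equal(a.mean_length, b.mean_length)
        assert np.array_equal(a.hi, b.hi)

    def test_mean_non_increasing_and_band_ordered(self):
        null = kin.mc_null_resultant(n_max=100, n_samples=2000, seed=2)
        assert np.all(np.diff(null.mean_length) <= 1e-12)
        assert np.all(null.lo <= null.mean_length + 1e-12)
        assert np.all(null.mean_length <= null.hi + 1e-12)


class TestAlignmentTest:
    def test_perfect_alignment_is_biased(self):
        null = kin.mc_null_resultant(n_max=30, n_samples=2000, seed=0)
        s = kin.resultant_vector([ev(40.0, [0, 0, 1])] * 20)
        assert kin.alignment_test(s, null) == "biased"

    def test_length_at_null_mean_is_unbiased(self):
        null = kin.mc_null_resultant(n_max=30, n_samples=2000, seed=0)
        s = kin.ResultantSummary(float(null.mean_length[19]), np.array([0, 0, 1.0]), 20)
        assert kin.alignment_test(s, null) == "unbiased"

    def test_n_outside_table_raises(self):
        null = kin.mc_null_resultant(n_max=10, n_samples=500, seed=0)
        s = kin.ResultantSummary(0.5, np.array([0, 0, 1.0]), 50)
        with pytest.raises(ValueError):
            kin.alignment_test(s, null)

    def test_biased_fraction_grows_with_concentration(self, rng):
        null = kin.mc_null_resultant(n_max=30, n_samples=4000, seed=3)
        fractions = []
        for kappa in (0.0, 50.0):
            biased = 0
            for _ in range(60):
                axes = syn.sample_axes_vmf([0, 0, 1.0], kappa, 20, rng)
                evs = [ev(40.0, a) for a in axes]
                if kin.alignment_test(kin.resultant_vector(evs), null) == "biased":
                    biased += 1
            fractions.append(biased / 60)
        assert fractions[0] < 0.2 and fractions[1] == 1.0


class TestGravityEstimation:
    def test_synthetic_gravity_angles(self, sim_config, events):
        rec, truth = syn.gen_inertial(sim_config, events, kappa=1e9, baseline_speed=2.0, seed=4)
        speed = kin.rotational_speed(rec)
        segs = kin.segment_immobility(speed, rec.fs)
        g = kin.estimate_gravity(rec, segs)
        assert kin.orientation_vs_vertical(g, truth["gravity_axis"]) < 2.0
        assert kin.orientation_vs_vertical([0, 0, -1.0], [0, 0, -1.0]) == pytest.approx(0.0)
        assert kin.orientation_vs_vertical([1, 0, 0.0], [0, 0, -1.0]) == pytest.approx(90.0)

    def test_no_immobility_raises(self):
        rec = make_record(np.full((400, 3), 50.0))
        with pytest.raises(ValueError):
            kin.estimate_gravity(rec, kin.ImmobilitySegments([]))
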