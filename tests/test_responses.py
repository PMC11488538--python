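import numpy as np
import pytest
from scipy import stats

from soundstates import responses as resp
from soundstates import simulate as sim
from soundstates.errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)
from soundstates.protocol import build_session_schedule
from soundstates.responses import ResponseChange, ResponseTensor, TuningCurve

from conftest import make_unit


def make_tensor(values, bin_s=0.01, window=(-0.3, 1.0)):
    v = np.asarray(values, dtype=np.float32)
    return ResponseTensor(v, list(range(v.shape[0])), list(range(v.shape[1])), bin_s, window)


class TestExtractResponseTensor:
    def test_empty_spike_train_all_zero(self, tone_set):
        schedule = build_session_schedule(tone_set, n_reps=3, block_size=28, n_natural=1, seed=0)
        t = resp.extract_response_tensor({0: np.array([])}, schedule)
        assert t.values.shape == (1, 28, 3, 130)
        assert np.all(t.values == 0)

    def test_constant_rate_cancels(self, tone_set):
        # baseline subtraction removes a stimulus-independent constant rate
        schedule = build_session_schedule(tone_set, n_reps=12, n_natural=2, seed=0)
        rate = np.full(int(schedule.end_s * 100) + 200, 25.0)
        train = sim.generate_spikes(rate, 0.01, seed=1)
        t = resp.extract_response_tensor({0: train.spike_times_s}, schedule)
        assert abs(t.values[0].mean()) < 0.5
        # per-trial baseline means vanish by construction
        baseline = t.values[0, :, :, : t.onset_bin].mean(axis=-1)
        assert np.allclose(baseline, 0.0, atol=1e-4)

    def test_driven_response_recovered(self, single_tone):
        # simulator ground truth: gain +20 at BF appears in the driven bins
        u = make_unit(gain=(20.0, 20.0), spont=(5.0, 5.0))
        t = sim.simulate_response_tensor([u], single_tone, "wake", n_trials=100, seed=0)
        sl = t.duration_bins(0.25)
        assert t.values[0, 0, :, sl].mean() == pytest.approx(20.0, abs=2.0)

    def test_bin_count_invariant(self, tone_set):
        schedule = build_session_schedule(tone_set, n_reps=3, block_size=28, n_natural=1, seed=0)
        t = resp.extract_response_tensor({0: np.array([10.0])}, schedule)
        assert t.n_bins == 130
        assert t.onset_bin == 30


class TestSpontaneousRate:
    def test_zero_spikes(self, schedule):
        assert resp.spontaneous_rate(np.array([]), schedule) == 0.0

    def test_default_denominator_284(self, schedule):
        # one spike inside every gap window -> 142 spikes / (142 * 2 s)
        times = np.sort([g.start_s + 0.5 for g in schedule.gaps])
        assert resp.spontaneous_rate(times, schedule) == pytest.approx(142 / 284)

    def test_constant_rate_recovered(self, schedule):
        rng = np.random.default_rng(0)
        n = rng.poisson(10.0 * schedule.end_s)
        times = np.sort(rng.uniform(0, schedule.end_s, n))
        assert resp.spontaneous_rate(times, schedule) == pytest.approx(10.0, abs=0.5)

    def test_spikes_outside_window_ignored(self, schedule):
        g = schedule.gaps[0]
        times = np.sort([g.start_s + 0.1, g.start_s + 0.5, g.start_s + 2.9])
        assert resp.spontaneous_rate(times, schedule) == pytest.approx(1 / 284)

    def test_no_gaps_rejected(self, tone_set):
        schedule = build_session_schedule(tone_set, n_reps=1, block_size=28, n_natural=0)
        with pytest.raises(InvalidInputError):
            resp.spontaneous_rate(np.array([1.0]), schedule)


class TestEvokedModulation:
    def test_zero_tensor(self):
        t = make_tensor(np.zeros((2, 3, 4, 130)))
        out = resp.evoked_modulation(t, {0: 0.2, 1: 0.2, 2: 0.2})
        assert np.allclose(out, 0.0)

    def test_suppressed_unit_negative(self, single_tone):
        u = make_unit(gain=(-5.0, -5.0), spont=(10.0, 10.0))
        t = sim.simulate_response_tensor([u], single_tone, "wake", n_trials=50, seed=1)
        assert resp.evoked_modulation(t, {0: 0.25})[0] < 0

    def test_silenced_unit_zero(self, single_tone):
        u = make_unit(remodel_class="silenced", spont=(10.0, 0.0), gain=(20.0, 0.0))
        t = sim.simulate_response_tensor([u], single_tone, "anesthesia", seed=2)
        assert resp.evoked_modulation(t, {0: 0.25})[0] == 0.0


class TestReliability:
    def test_identical_trials(self):
        rng = np.random.default_rng(0)
        one = rng.normal(0, 1, (1, 4, 1, 130))
        t = make_tensor(np.repeat(one, 5, axis=2))
        assert resp.reliability(t, 0) == pytest.approx(1.0)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(1)
        t = make_tensor(rng.normal(0, 1, (1, 20, 8, 130)))
        assert abs(resp.reliability(t, 0)) < 0.05

    def test_high_gain_more_reliable(self, tone_set):
        units = [
            make_unit(unit_id=0, gain=(40.0, 40.0), spont=(5.0, 5.0)),
            make_unit(unit_id=1, gain=(5.0, 5.0), spont=(5.0, 5.0)),
        ]
        t = sim.simulate_response_tensor(units, tone_set, "wake", seed=3)
        assert resp.reliability(t, 0) > resp.reliability(t, 1)

    def test_single_trial_rejected(self):
        t = make_tensor(np.zeros((1, 2, 1, 130)))
        with pytest.raises(InsufficientDataError):
            resp.reliability(t, 0)


class TestBestFrequency:
    def test_peak_recovered(self):
        tc = TuningCurve(np.array([2.0, 5.0, 10.95, 20.0]), np.array([1.0, 2.0, 9.0, 3.0]))
        assert resp.best_frequency(tc) == 10.95

    def test_flat_curve_tie_breaks_low(self):
        tc = TuningCurve(np.array([2.0, 4.0, 8.0]), np.array([1.0, 1.0, 1.0]))
        assert resp.best_frequency(tc) == 2.0


class TestHalfWidth:
    def test_triangle_exact_one_octave(self):
        # |r| linear in log2 f, reaching zero exactly one octave either side
        freqs = 8.0 * 2.0 ** np.linspace(-2, 2, 17)
        r = np.clip(1.0 - np.abs(np.log2(freqs / 8.0)), 0.0, None)
        hw = resp.half_width_octaves(TuningCurve(freqs, r))
        assert hw.octaves == pytest.approx(1.0, abs=1e-12)
        assert not hw.censored

    def test_symmetric_curve_symmetric_crossings(self):
        freqs = 8.0 * 2.0 ** np.linspace(-2, 2, 33)
        r = 2.0 ** (-((np.log2(freqs / 8.0) / 0.7) ** 2))
        hw = resp.half_width_octaves(TuningCurve(freqs, r))
        assert hw.octaves == pytest.approx(2 * 0.7, abs=0.01)

    def test_scale_invariance(self):
        freqs = np.geomspace(2, 60, 14)
        rng = np.random.default_rng(2)
        r = rng.uniform(0.1, 1.0, 14)
        a = resp.half_width_octaves(TuningCurve(freqs, r))
        b = resp.half_width_octaves(TuningCurve(freqs, 13.7 * r))
        assert b.octaves == pytest.approx(a.octaves, rel=1e-12)
        assert (b.censored_low, b.censored_high) == (a.censored_low, a.censored_high)

    def test_simulated_gaussian_recovery(self, tone_set):
        # noiseless analytic curve from the simulator's own tuning model
        u = make_unit(bf=8.0, hw=(0.6, 0.6), gain=(30.0, 30.0), spont=(0.0, 0.0))
        freqs = np.geomspace(2, 60, 14)
        r = 30.0 * 2.0 ** (-((np.log2(freqs / 8.0) / 0.6) ** 2))
        hw = resp.half_width_octaves(TuningCurve(freqs, r))
        assert hw.octaves == pytest.approx(2 * 0.6, abs=0.05)

    def test_censored_at_edge(self):
        freqs = np.geomspace(2, 60, 14)
        r = np.linspace(1.0, 0.2, 14)  # peak at the low edge
        hw = resp.half_width_octaves(TuningCurve(freqs, r))
        assert hw.censored_low and not hw.censored_high

    def test_nonpositive_peak_rejected(self):
        with pytest.raises(InvalidInputError):
            resp.half_width_octaves(TuningCurve(np.array([2.0, 4.0]), np.array([0.0, 0.0])))


class TestIntensityThreshold:
    def test_crossing_at_quarter_second_is_60db(self):
        psth = np.zeros(130)
        psth[:30] = np.random.default_rng(0).normal(0, 1.0, 30)
        psth[30 + 25 :] = 50.0  # first crossing at t = 0.25 s
        assert resp.intensity_threshold(psth, onset_bin=30) == pytest.approx(60.0, abs=0.5)

    def test_never_crossing_unresponsive(self):
        psth = np.zeros(130)
        psth[:30] = np.random.default_rng(1).normal(0, 1.0, 30)
        assert resp.intensity_threshold(psth, onset_bin=30) is None

    def test_zero_sd_floor(self):
        psth = np.zeros(130)
        psth[40] = 0.1
        assert resp.intensity_threshold(psth, onset_bin=30) is not None

    def test_recovery_on_simulated_ramps(self):
        # ground-truth threshold 55 dB, high gain -> median estimate within 1.5 dB
        from soundstates.protocol import SoundStimulus, StimulusSet

        ramp = SoundStimulus(0, "ramp", (50.0, 70.0), 0.5, {"frequencies_khz": [8.0]}, "up")
        rset = StimulusSet((ramp,))
        u = make_unit(gain=(60.0, 60.0), spont=(5.0, 5.0), threshold=(55.0, 55.0))
        estimates = []
        for seed in range(25):
            t = sim.simulate_response_tensor([u], rset, "wake", n_trials=36, seed=seed)
            est = resp.intensity_threshold(t.values[0, 0].mean(axis=0), t.onset_bin)
            assert est is not None
            estimates.append(est)
        assert np.median(estimates) == pytest.approx(55.0, abs=1.5)


class TestClassifyResponseChange:
    def test_identical_significant_responses_no_change(self):
        rng = np.random.default_rng(0)
        r = rng.normal(20.0, 1.0, 12)
        baseline = rng.normal(0.0, 1.0, 12)
        out = resp.classify_response_change(r, r.copy(), baseline, baseline.copy())
        assert out is ResponseChange.NO_CHANGE

    def test_nonresponsive(self):
        rng = np.random.default_rng(1)
        out = resp.classify_response_change(
            rng.normal(0, 1, 12), rng.normal(0, 1, 12), rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        )
        assert out is ResponseChange.NONRESPONSIVE

    def test_too_few_trials_rejected(self):
        with pytest.raises(InsufficientDataError):
            resp.classify_response_change(
                np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]), np.zeros(5), np.zeros(5)
            )

    def test_sign_change_power(self, single_tone):
        # power simulation: suppressed wake / excited anesthesia unit with 12
        # trials is labeled sign_change in >= 90% of seeds
        u = make_unit(
            remodel_class="sign_change",
            spont=(30.0, 15.0),
            gain=(-18.0, 18.0),
            hw=(0.4, 0.4),
        )
        hits = 0
        for seed in range(30):
            tw = sim.simulate_response_tensor([u], single_tone, "wake", seed=seed)
            ta = sim.simulate_response_tensor([u], single_tone, "anesthesia", seed=seed + 500)
            rw, blw = resp.trial_responses_at_sound(tw, 0, 0, 0.25)
            ra, bla = resp.trial_responses_at_sound(ta, 0, 0, 0.25)
            hits += (
                resp.classify_response_change(rw, ra, blw, bla) is ResponseChange.SIGN_CHANGE
            )
        assert hits >= 27

    def test_decrease_detected(self, single_tone):
        u = make_unit(remodel_class="decrease", spont=(5.0, 3.0), gain=(35.0, 6.0))
        tw = sim.simulate_response_tensor([u], single_tone, "wake", seed=0)
        ta = sim.simulate_response_tensor([u], single_tone, "anesthesia", seed=1)
        rw, blw = resp.trial_responses_at_sound(tw, 0, 0, 0.25)
        ra, bla = resp.trial_responses_at_sound(ta, 0, 0, 0.25)
        out = resp.classify_response_change(rw, ra, blw, bla)
        assert out is ResponseChange.DECREASE


class TestPopulationDistributions:
    def test_anesthesia_shifted_spontaneous_cdf(self):
        # Kolmogorov-Smirnov on spontaneous rates at n = 150 with silencing
        pop = sim.sample_population(150, silenced_frac=0.4, seed=0)
        wake = [u.wake.spont_rate for u in pop]
        anes = [u.anesthesia.spont_rate for u in pop]
        assert stats.ks_2samp(wake, anes).pvalue < 0.05
        assert np.median(anes) < np.median(wake)
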