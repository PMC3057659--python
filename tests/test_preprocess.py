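"""Waveform reduction: segmentation, baseline alignment, beat averaging."""

import numpy as np
import pytest
from numpy.polynomial import Polynomial

from pulsedepth import preprocess as pre
from pulsedepth import synthetic as syn
from pulsedepth.preprocess import BeatDetectionError, SegmentationError
from pulsedepth.records import Location, RawPulseRecord

FS = 200.0
LEVELS = (37.0, 73.0, 108.0, 143.0, 181.0)


def _staircase_record(noise_sd=0.0, n_levels=5, seed=0, step_s=5.0):
    rng = np.random.default_rng(seed)
    n = int(step_s * FS)
    trace = np.concatenate([np.full(n, p) for p in LEVELS[:n_levels]])
    trace = trace + rng.normal(0, noise_sd, trace.size)
    return RawPulseRecord(
        samples=np.zeros(trace.size),
        sampling_rate=FS,
        location=Location.GWAN,
        pressure_trace=trace,
    )


class TestSegmentSteps:
    def test_explicit_boundaries_pass_through(self):
        bounds = [(i * 100, (i + 1) * 100) for i in range(5)]
        rec = RawPulseRecord(
            samples=np.zeros(500),
            sampling_rate=FS,
            location=Location.CHON,
            step_boundaries=bounds,
        )
        intervals, pressures = pre.segment_steps(rec)
        assert intervals == bounds
        assert pressures == pytest.approx(pre.DEFAULT_STEP_PRESSURES)

    def test_perfect_staircase_recovers_levels(self):
        intervals, pressures = pre.segment_steps(_staircase_record())
        assert len(intervals) == 5
        assert pressures == pytest.approx(LEVELS)

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_staircase_within_1_mmhg(self, seed):
        _, pressures = pre.segment_steps(_staircase_record(noise_sd=2.0, seed=seed))
        assert np.all(np.abs(pressures - np.array(LEVELS)) < 1.0)

    def test_wrong_plateau_count_names_count(self):
        with pytest.raises(SegmentationError, match="found 4"):
            pre.segment_steps(_staircase_record(n_levels=4))


def _beat_train(n_beats=6, n_period=150, amplitude=1.0, width=0.05):
    tau = np.arange(n_period) / n_period
    beat = np.exp(-(((tau - 0.3) / width) ** 2) / 2)
    beat = beat / (beat.max() - beat.min()) * amplitude
    return np.tile(beat, n_beats)


class TestDetrendBaseline:
    def test_pure_polynomial_removed(self, rng):
        x = np.arange(1000, dtype=float)
        signal = Polynomial(rng.normal(size=6))(x / 1000)
        out = pre.detrend_baseline(signal, 5)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_constant_signal_zeroed(self):
        out = pre.detrend_baseline(np.full(100, 42.0), 5)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_output_mean_near_zero(self, rng):
        signal = _beat_train() + rng.normal(0, 0.1, 900)
        out = pre.detrend_baseline(signal, 5)
        assert abs(out.mean()) < 1e-10

    def test_sample_anchor_equals_direct_fit_subtraction(self, rng):
        """Pulse train + drift -> exactly the train minus its own LS fit."""
        train = _beat_train()
        x = np.arange(train.size, dtype=float)
        drift = 0.8 * np.sin(2 * np.pi * x / train.size)
        signal = train + drift
        expected = signal - Polynomial.fit(x, signal, 5)(x)
        out = pre.detrend_baseline(signal, 5, anchor="samples")
        assert np.allclose(out, expected, atol=1e-9)

    def test_foot_anchor_preserves_amplitude_under_drift(self, rng):
        train = _beat_train()
        x = np.linspace(-1, 1, train.size)
        drift = Polynomial(rng.normal(size=6))(x)
        drift = drift / np.abs(drift).max() * 0.9  # drift magnitude < amplitude
        out = pre.detrend_baseline(train + drift, 5, anchor="feet", sampling_rate=FS)
        amp = pre.pulse_strength(pre.average_beat(out, FS))
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_idempotent(self, rng):
        signal = _beat_train() + rng.normal(0, 0.05, 900)
        once = pre.detrend_baseline(signal, 5)
        twice = pre.detrend_baseline(once, 5)
        assert np.allclose(once, twice, atol=1e-9)

    def test_too_short_segment_raises(self):
        with pytest.raises(ValueError, match="too short"):
            pre.detrend_baseline(np.zeros(5), 5)

    def test_unknown_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            pre.detrend_baseline(np.zeros(100), 5, anchor="knees")


class TestAverageBeat:
    def test_identical_beats_average_to_one_beat(self):
        train = _beat_train(n_beats=6)
        avg = pre.average_beat(train, FS)
        assert avg.size == 150
        peak = int(np.argmax(avg))
        single = _beat_train(n_beats=1)
        assert avg.max() - avg.min() == pytest.approx(
            single.max() - single.min(), abs=1e-12
        )

    def test_noise_shrinks_like_sqrt_n(self, rng):
        """Residual noise of the averaged beat ~ sigma / sqrt(n_beats).

        Measured on the diastolic floor of the averaged beat (template
        ~ 0 and flat there), where peak-alignment jitter cannot leak in.
        """
        sigma, n_beats, reps = 0.05, 8, 40
        tau = np.arange(150) / 150
        beat = np.exp(-(((tau - 0.5) / 0.05) ** 2) / 2)
        train = np.tile(beat / (beat.max() - beat.min()), n_beats)
        resid = []
        for _ in range(reps):
            noisy = train + rng.normal(0, sigma, train.size)
            avg = pre.average_beat(noisy, FS)
            resid.append(np.std(avg[:20]))
        expected = sigma / np.sqrt(n_beats)
        assert np.mean(resid) == pytest.approx(expected, rel=0.35)

    def test_single_beat_raises(self):
        with pytest.raises(BeatDetectionError, match="1 beat"):
            pre.average_beat(_beat_train(n_beats=1), FS)


class TestPulseStrength:
    def test_flat_beat_is_zero(self):
        assert pre.pulse_strength(np.zeros(50)) == 0.0

    @pytest.mark.parametrize("amplitude", [1.0, 7.5, 130.0])
    def test_template_amplitude_recovered(self, amplitude):
        beat = _beat_train(n_beats=1, amplitude=amplitude)
        assert pre.pulse_strength(beat) == pytest.approx(amplitude)

    def test_noisy_template_within_10pct(self, rng):
        amplitude, sigma, n_beats = 10.0, 0.5, 8
        train = _beat_train(n_beats=n_beats, amplitude=amplitude)
        noisy = train + rng.normal(0, sigma, train.size)
        h = pre.pulse_strength(pre.average_beat(noisy, FS))
        assert h == pytest.approx(amplitude, rel=0.10)

    def test_empty_beat_raises(self):
        with pytest.raises(ValueError):
            pre.pulse_strength(np.array([]))


class TestBuildProfile:
    def test_recovers_injected_envelope(self, clean_params):
        rng = np.random.default_rng(3)
        subject = syn.draw_subject("floating", clean_params, rng, "S1")
        record, truth = syn.simulate_record(subject, "Gwan", clean_params, seed=11)
        profile = pre.build_profile(record)
        rel = np.abs(profile.strengths - truth.injected_strengths)
        rel /= truth.injected_strengths
        assert rel.max() < 2e-2
        assert profile.pressures == pytest.approx(truth.step_pressures)

    def test_amplitude_linearity(self, clean_params):
        rng = np.random.default_rng(4)
        subject = syn.draw_subject("sunken", clean_params, rng, "S2")
        record, _ = syn.simulate_record(subject, "Chon", clean_params, seed=9)
        p1 = pre.build_profile(record)
        record.samples = record.samples * 3.0
        p3 = pre.build_profile(record)
        assert p3.strengths == pytest.approx(3.0 * p1.strengths, rel=1e-9)

    def test_missing_plateau_propagates(self):
        rec = _staircase_record(n_levels=4)
        with pytest.raises(SegmentationError):
            pre.build_profile(rec)


class TestLocationAverage:
    def _profile(self, loc, strengths):
        from pulsedepth.records import StepStrengthProfile

        return StepStrengthProfile(
            location=loc,
            pressures=np.array(LEVELS),
            strengths=np.asarray(strengths, dtype=float),
        )

    def test_elementwise_mean(self):
        profiles = [
            self._profile(Location.CHON, [3, 3, 3, 3, 3]),
            self._profile(Location.GWAN, [6, 6, 6, 6, 6]),
            self._profile(Location.CHEOK, [9, 9, 9, 9, 9]),
        ]
        _, strengths = pre.location_average(profiles)
        assert strengths == pytest.approx([6, 6, 6, 6, 6])

    def test_order_invariant(self, rng):
        profiles = [
            self._profile(loc, rng.uniform(1, 10, 5))
            for loc in (Location.CHON, Location.GWAN, Location.CHEOK)
        ]
        _, s1 = pre.location_average(profiles)
        _, s2 = pre.location_average(profiles[::-1])
        assert s1 == pytest.approx(s2)

    def test_missing_location_raises(self):
        profiles = [
            self._profile(Location.CHON, np.ones(5)),
            self._profile(Location.GWAN, np.ones(5)),
        ]
        with pytest.raises(ValueError, match="Cheok"):
            pre.location_average(profiles)


@pytest.mark.parametrize(
    "strengths, expected",
    [([1, 5, 3, 2, 1], 5.0), ([2, 2, 2, 2, 2], 2.0), ([170.2, 160.5, 80.0, 40.1, 10.0], 170.2)],
)
def test_h_max(strengths, expected):
    assert pre.h_max(np.array(strengths, dtype=float)) == expected
    assert pre.h_max(np.array(strengths, dtype=float)) == max(strengths)
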