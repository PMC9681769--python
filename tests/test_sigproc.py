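"""Signal chain: background subtraction, filtering, peaks, events, gating."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as scipy_signal

from dropsort import sigproc, stream_sim
from dropsort.sigproc import (
    FilterSettings,
    Gate,
    GridMismatchError,
    Peak,
    PeakCriteria,
    apply_gate,
    denoise,
    detect_peaks,
    peak_histogram,
    quantile_gate,
    segment_events,
    subtract_background,
)

GRID = np.arange(450.0, 650.25, 0.5)


def _gaussian(center, amplitude, sd=10.0):
    return amplitude * np.exp(-((GRID - center) ** 2) / (2 * sd**2))


def _peak(wl=515.0, intensity=500.0, t=0.0):
    return Peak(frame_time=t, wavelength=wl, intensity=intensity,
                base_width=20.0, prominence=intensity)


class TestBackgroundSubtraction:
    def test_accumulate_recurrence_from_zero(self):
        # |0 + (100 - 40)| = 60
        out = subtract_background(np.full(8, 100.0), np.full(8, 40.0),
                                  previous=np.zeros(8), mode="accumulate")
        assert np.allclose(out, 60.0)

    def test_accumulate_recurrence_running(self):
        # |60 + (90 - 40)| = 110
        out = subtract_background(np.full(8, 90.0), np.full(8, 40.0),
                                  previous=np.full(8, 60.0), mode="accumulate")
        assert np.allclose(out, 110.0)

    def test_plain_zeroes_on_dark_input(self):
        dark = np.linspace(90.0, 110.0, 16)
        assert np.allclose(subtract_background(dark, dark), 0.0)

    def test_output_non_negative_in_both_modes(self, rng):
        raw = rng.normal(100.0, 20.0, size=64)
        dark = np.full(64, 110.0)
        assert np.all(subtract_background(raw, dark) >= 0.0)
        assert np.all(subtract_background(raw, dark, previous=np.zeros(64),
                                          mode="accumulate") >= 0.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            subtract_background(np.zeros(10), np.zeros(11))


class TestDenoise:
    def test_dc_gain_unity_on_constant(self):
        out = denoise(np.full(401, 321.5))
        assert np.allclose(out, 321.5, atol=1e-6)

    def test_attenuation_matches_analytic_response(self):
        # steady-state amplitude ratio equals |H(e^{j pi f})| of the
        # designed digital filter; at f = fc this is 1/sqrt(2)
        b, a = scipy_signal.butter(3, 0.1)
        n = 8000
        t = np.arange(n)
        for f in (0.1, 0.4):
            out = denoise(np.sin(np.pi * f * t) + 1000.0, FilterSettings()) - 1000.0
            measured = np.sqrt(2.0) * out[n // 2:].std()
            _, h = scipy_signal.freqz(b, a, worN=[np.pi * f])
            assert measured == pytest.approx(abs(h[0]), abs=0.002)
        out = denoise(np.sin(np.pi * 0.1 * t) + 1000.0, FilterSettings()) - 1000.0
        assert np.sqrt(2.0) * out[n // 2:].std() == pytest.approx(0.7071, abs=0.01)

    def test_long_constant_mean_preserved(self):
        x = np.full(10_000, 57.0)
        assert abs(denoise(x).mean() / 57.0 - 1.0) < 1e-6

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="short"):
            denoise(np.ones(9), FilterSettings(order=3))

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            FilterSettings(order=0)
        with pytest.raises(ValueError):
            FilterSettings(cutoff=1.5)


class TestDetectPeaks:
    def test_flat_spectrum_no_peaks(self):
        assert detect_peaks(np.full(GRID.size, 10.0), GRID,
                            PeakCriteria(min_height=100.0)) == []

    def test_single_gaussian_recovered(self):
        pks = detect_peaks(_gaussian(515.0, 1000.0), GRID,
                           PeakCriteria(min_height=100.0))
        assert len(pks) == 1
        assert abs(pks[0].wavelength - 515.0) <= 0.5
        assert pks[0].intensity == pytest.approx(1000.0, rel=0.01)

    def test_two_separated_gaussians_both_reported(self):
        spec = _gaussian(505.0, 800.0) + _gaussian(560.0, 600.0)
        pks = detect_peaks(spec, GRID, PeakCriteria(min_height=100.0,
                                                    min_distance=10.0))
        assert [round(p.wavelength) for p in pks] == [505, 560]

    def test_criteria_satisfied_and_sorted(self, rng):
        # the chain always feeds |I - dark|, so the spectrum is non-negative
        spec = np.abs(_gaussian(480.0, 300.0, 6.0) + _gaussian(530.0, 900.0, 12.0)
                      + rng.normal(0, 2.0, GRID.size))
        crit = PeakCriteria(min_height=100.0, min_base_width=3.0,
                            min_distance=5.0, min_prominence=50.0)
        pks = detect_peaks(spec, GRID, crit)
        assert len(pks) >= 2
        wls = [p.wavelength for p in pks]
        assert wls == sorted(wls)
        for p in pks:
            assert p.intensity >= crit.min_height
            assert p.prominence >= crit.min_prominence
            assert p.base_width >= crit.min_base_width
            assert p.prominence <= p.intensity  # topographic bound


class TestSegmentEvents:
    def test_consecutive_hot_frames_merge(self):
        frames = [(0.01 * i, [_peak(t=0.01 * i)]) for i in range(4)]
        events = segment_events(frames, refractory=0.05)
        assert len(events) == 1
        assert events[0].n_frames == 4

    def test_transits_beyond_refractory_split(self):
        frames = [(0.0, [_peak()]), (0.143, [_peak()])]
        assert len(segment_events(frames, refractory=0.05)) == 2

    def test_no_hot_frames_no_events(self):
        assert segment_events([], refractory=0.05) == []
        assert segment_events([(0.0, []), (0.01, [])]) == []

    def test_event_peak_is_max_intensity(self):
        frames = [(0.00, [_peak(intensity=100.0)]),
                  (0.01, [_peak(intensity=900.0)]),
                  (0.02, [_peak(intensity=300.0)])]
        ev, = segment_events(frames)
        assert ev.peak.intensity == 900.0
        assert (ev.start_time, ev.end_time) == (0.0, 0.02)

    def test_unordered_frames_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            segment_events([(0.1, [_peak()]), (0.05, [_peak()])])


class TestGating:
    def test_in_window_peak_gated(self):
        ev = segment_events([(0.0, [_peak(wl=515.0, intensity=500.0)])])
        apply_gate(ev, Gate(510.0, 520.0, intensity_min=100.0))
        assert ev[0].gated

    def test_boundary_convention_closed_interval_strict_noise(self):
        gate = Gate(510.0, 520.0, intensity_min=100.0, noise_level=100.0)
        just_out = segment_events([(0.0, [_peak(wl=509.9, intensity=500.0)])])
        on_edge = segment_events([(0.0, [_peak(wl=510.0, intensity=500.0)])])
        at_noise = segment_events([(0.0, [_peak(wl=515.0, intensity=100.0)])])
        apply_gate(just_out + on_edge + at_noise, gate)
        assert not just_out[0].gated
        assert on_edge[0].gated
        assert not at_noise[0].gated  # must be strictly above the noise level

    def test_empty_event_list(self):
        assert apply_gate([], Gate()) == []

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(wl=st.floats(450.0, 650.0), inten=st.floats(0.0, 5000.0))
    def test_gate_pure_and_idempotent(self, wl, inten):
        gate = Gate(510.0, 520.0, intensity_min=50.0, noise_level=10.0)
        ev = segment_events([(0.0, [_peak(wl=wl, intensity=inten)])])
        first = apply_gate(ev, gate)[0].gated
        second = apply_gate(ev, gate)[0].gated
        assert first == second
        assert first == gate.contains(ev[0].peak)

    def test_invalid_gate_rejected(self):
        with pytest.raises(ValueError):
            Gate(520.0, 510.0)
        with pytest.raises(ValueError):
            Gate(intensity_min=5.0, noise_level=10.0)


class TestQuantileGate:
    def test_linear_interpolation_threshold(self):
        gate = quantile_gate(np.arange(1.0, 11.0), q=0.9)
        assert gate.intensity_min == pytest.approx(9.1)
        assert np.isinf(gate.intensity_max)

    def test_degenerate_all_equal(self):
        gate = quantile_gate(np.full(100, 7.0), q=0.9)
        assert gate.intensity_min == 7.0
        assert np.sum(np.full(100, 7.0) > gate.intensity_min) == 0

    def test_continuous_population_top_fraction(self, rng):
        values = rng.lognormal(5.0, 1.0, size=10_000)
        gate = quantile_gate(values, q=0.9)
        frac = np.mean(values > gate.intensity_min)
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            quantile_gate([1.0], q=0.9)


class TestPeakHistogram:
    def test_counts_conserved(self, rng):
        events = segment_events(
            [(0.1 * i, [_peak(intensity=v, t=0.1 * i)])
             for i, v in enumerate(rng.lognormal(5, 0.5, 500))]
        )
        hist = peak_histogram(events)
        assert hist["counts"].sum() == 500
        assert hist["n"] == 500

    def test_single_event_single_bin(self):
        hist = peak_histogram(segment_events([(0.0, [_peak()])]), bins=10)
        assert (hist["counts"] > 0).sum() == 1

    def test_bimodal_standards_separate(self, detector):
        # 5 uM vs 50 uM standards: supports must not overlap at default noise
        trains = {}
        for conc in (5.0, 50.0):
            train = stream_sim.generate_calibration_train(
                60, droplet_rate=2.0, positive_conc_uM=conc,
                positive_fraction=1.0, seed=13)
            stream = stream_sim.synthesize_stream(train, detector,
                                                  droplet_rate=2.0, seed=13)
            evs = sigproc.process_stream(stream, detector.dark_spectrum)
            trains[conc] = [e.peak.intensity for e in evs
                            if 510 <= e.peak.wavelength <= 520]
        assert len(trains[5.0]) == 60 and len(trains[50.0]) == 60
        assert max(trains[5.0]) < min(trains[50.0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            peak_histogram([])


class TestFullChain:
    def test_event_count_matches_truth_on_clean_stream(self, detector):
        train = stream_sim.generate_calibration_train(
            8, droplet_rate=2.0, positive_conc_uM=50.0, positive_fraction=1.0,
            seed=3)
        stream = stream_sim.synthesize_stream(train, detector, droplet_rate=2.0,
                                              seed=3)
        events = sigproc.process_stream(stream, detector.dark_spectrum)
        assert len(events) == len(train)

    def test_accumulate_mode_integrates_signal(self, detector):
        # the literal running recurrence has no reset rule: signal (and
        # folded noise) integrates across frames, so the detected peak far
        # exceeds the single-frame amplitude and transits merge
        train = stream_sim.generate_calibration_train(
            3, droplet_rate=2.0, positive_conc_uM=50.0, positive_fraction=1.0,
            seed=4)
        stream = stream_sim.synthesize_stream(train, detector, droplet_rate=2.0,
                                              seed=4)
        plain = sigproc.process_stream(stream, detector.dark_spectrum)
        accum = sigproc.process_stream(stream, detector.dark_spectrum,
                                       background_mode="accumulate")
        assert len(accum) >= 1
        assert max(e.peak.intensity for e in accum) > \
            5 * max(e.peak.intensity for e in plain)
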