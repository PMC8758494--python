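"""Phase-coupling chain: zero-phase filtering, Hilbert phase convention,
spike detection, resultant-vector statistics, Rayleigh calibration."""

import numpy as np
import pytest
from scipy import signal, special

import spikegamma as sg
from spikegamma.core import ParameterError
from spikegamma.coupling import (
    CouplingConfig,
    FilterConfig,
    SpikeDetectConfig,
    analyze_cell,
    bandpass_filter,
    coupling_statistics,
    detect_spikes,
    instantaneous_phase,
    rayleigh_test,
    resultant_vector,
    spike_phase_angles,
)
from .conftest import make_tone


class TestBandpassFilter:
    def test_zero_phase_no_lag(self, fs):
        tone = make_tone(30.0, duration=10.0)
        out = bandpass_filter(tone)
        core = slice(int(fs), -int(fs))
        xc = signal.correlate(out.samples[core], tone.samples[core], mode="full")
        lag = np.argmax(xc) - (len(out.samples[core]) - 1)
        assert abs(lag) <= 1

    def test_dc_rejected(self, fs):
        dc = sg.TimeSeries(np.full(int(5 * fs), 3.0), fs)
        out = bandpass_filter(dc)
        assert np.sqrt(np.mean(out.samples**2)) < 1e-6 * 3.0

    @pytest.mark.parametrize("freq", [5.0, 100.0])
    def test_stopband_matches_squared_butterworth(self, freq, fs):
        """Attenuation equals the squared magnitude response of the
        underlying Butterworth design (the filter runs in both directions)."""
        tone = make_tone(freq, duration=10.0)
        out = bandpass_filter(tone)
        sos = signal.butter(4, [20, 40], btype="bandpass", fs=fs, output="sos")
        _, h = signal.sosfreqz(sos, worN=[2 * np.pi * freq / fs])
        predicted = np.abs(h[0]) ** 2
        core = slice(int(fs), -int(fs))
        ratio = np.std(out.samples[core]) / np.std(tone.samples[core])
        assert ratio == pytest.approx(predicted, rel=0.1)
        assert ratio < 0.05

    def test_band_vs_nyquist(self, fs):
        tone = make_tone(30.0, duration=1.0)
        with pytest.raises(ParameterError, match="Nyquist"):
            bandpass_filter(tone, FilterConfig(low_cut=20, high_cut=3000))

    def test_passband_preserved(self, fs):
        tone = make_tone(30.0, duration=10.0)
        out = bandpass_filter(tone)
        core = slice(int(fs), -int(fs))
        assert np.std(out.samples[core]) == pytest.approx(
            np.std(tone.samples[core]), rel=0.02)


class TestSpikeDetection:
    def test_injected_spikes_recovered_at_peaks(self, fs):
        true_times = np.round(np.arange(0.5, 10.0, 1.0) * fs) / fs
        st = sg.SpikeTrain(true_times, duration=10.0)
        trace = sg.render_spike_trace(st, fs, noise_sd=0.5, seed=4)
        det = detect_spikes(trace, SpikeDetectConfig(threshold=0.0))
        assert len(det) == 10
        assert np.max(np.abs(det.times - true_times)) <= 1.0 / fs

    def test_subthreshold_trace_empty(self, fs):
        trace = sg.TimeSeries(np.full(1000, -60.0), fs)
        assert len(detect_spikes(trace)) == 0

    def test_noisy_crest_counted_once(self, fs):
        # double crossing within min_interval: one spike
        v = np.full(1000, -60.0)
        v[500:505] = 10.0
        v[505] = -1.0  # dips below threshold for one sample
        v[506:510] = 12.0
        trace = sg.TimeSeries(v, fs)
        det = detect_spikes(trace, SpikeDetectConfig(threshold=0.0, min_interval=0.002))
        assert len(det) == 1
        assert det.times[0] == pytest.approx(506 / fs)  # global crest of the epoch


class TestInstantaneousPhase:
    def test_peak_zero_trough_pi(self, fs):
        t = np.arange(int(10 * fs)) / fs
        tone = sg.TimeSeries(np.cos(2 * np.pi * 30 * t), fs)
        phase = instantaneous_phase(tone)
        core = slice(int(fs), -int(fs))
        x = tone.samples
        maxima = signal.argrelmax(x[core])[0] + core.start
        minima = signal.argrelmin(x[core])[0] + core.start
        assert np.max(np.abs(phase.phases[maxima])) < 0.05
        assert np.max(np.pi - np.abs(phase.phases[minima])) < 0.05

    def test_unwrapped_phase_monotone(self, fs):
        t = np.arange(int(5 * fs)) / fs
        tone = sg.TimeSeries(np.cos(2 * np.pi * 30 * t), fs)
        phase = instantaneous_phase(tone)
        unwrapped = np.unwrap(phase.phases)[int(fs) : -int(fs)]
        assert np.all(np.diff(unwrapped) > 0)

    def test_constant_input_error(self, fs):
        with pytest.raises(ParameterError, match="constant"):
            instantaneous_phase(sg.TimeSeries(np.ones(1000), fs))


@pytest.fixture(scope="module")
def filtered_phase():
    tone = make_tone(30.0, duration=10.0)
    return instantaneous_phase(bandpass_filter(tone)), tone


@pytest.fixture(scope="module")
def coupled_pair(quiet_lfp_params):
    lfp, phase = sg.simulate_gamma_lfp(quiet_lfp_params)
    spikes = sg.simulate_coupled_spikes(
        phase, sg.CouplingParams(mean_rate=20, kappa=4, mu=0.5, seed=3))
    cell = sg.render_spike_trace(spikes, lfp.sampling_rate, seed=4)
    return lfp, cell, spikes


class TestSpikePhaseAngles:
    def test_spikes_at_peaks_give_zero(self, filtered_phase, fs):
        phase, tone = filtered_phase
        peaks = signal.argrelmax(tone.samples)[0]
        peaks = peaks[(peaks > fs) & (peaks < len(tone.samples) - fs)]
        st = sg.SpikeTrain(peaks[:50] / fs, duration=10.0)
        angles = spike_phase_angles(phase, st)
        assert np.max(np.abs(angles)) < 0.1

    def test_spikes_at_troughs_give_pi(self, filtered_phase, fs):
        phase, tone = filtered_phase
        troughs = signal.argrelmin(tone.samples)[0]
        troughs = troughs[(troughs > fs) & (troughs < len(tone.samples) - fs)]
        st = sg.SpikeTrain(troughs[:50] / fs, duration=10.0)
        angles = spike_phase_angles(phase, st)
        assert np.max(np.pi - np.abs(angles)) < 0.1

    def test_empty_train_empty_angles(self, filtered_phase):
        phase, _ = filtered_phase
        st = sg.SpikeTrain(np.empty(0), duration=10.0)
        assert spike_phase_angles(phase, st).size == 0

    def test_out_of_span_spike_listed(self, filtered_phase):
        phase, _ = filtered_phase
        st = sg.SpikeTrain(np.array([5.0, 10.0 - 1e-5]), duration=10.5)
        with pytest.raises(ParameterError, match="outside"):
            phase.at_times(np.array([11.0]))
        # in-span times fine
        assert spike_phase_angles(phase, st).size == 2


class TestCouplingStatistics:
    def test_perfect_coupling(self):
        res = coupling_statistics(np.full(50, np.pi / 4), duration=10.0)
        assert res.vector_length == pytest.approx(1.0)
        assert res.phase_angle == pytest.approx(np.pi / 4)
        assert res.rayleigh_p < 1e-10
        assert res.included
        assert res.firing_rate == pytest.approx(5.0)

    def test_uniform_grid_zero_vector(self):
        angles = sg.wrap_phase(np.arange(100) * 2 * np.pi / 100)
        r, _ = resultant_vector(angles)
        assert r < 1e-10

    def test_von_mises_sample_matches_bessel_ratio(self):
        rng = np.random.default_rng(8)
        angles = rng.vonmises(0.0, 2.0, size=1000)
        res = coupling_statistics(angles, duration=100.0)
        expected = special.i1(2.0) / special.i0(2.0)
        assert res.vector_length == pytest.approx(expected, abs=0.03)

    def test_too_few_spikes_excluded_not_raised(self):
        res = coupling_statistics(np.array([0.1, 0.2]), duration=10.0)
        assert not res.included
        assert "n < n_min" in res.exclusion_reason
        assert np.isnan(res.vector_length)
        assert res.firing_rate == pytest.approx(0.2)


class TestRayleigh:
    def test_identical_angles_tiny_p(self):
        assert rayleigh_test(np.full(30, 1.0)) < 1e-8

    def test_needs_two_angles(self):
        with pytest.raises(ParameterError):
            rayleigh_test(np.array([0.5]))

    def test_calibration_under_uniform_null(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            rayleigh_test(rng.uniform(-np.pi, np.pi, 50)) < 0.05
            for _ in range(2000)
        )
        assert 0.04 <= rejections / 2000 <= 0.065

    def test_agrees_with_monte_carlo_null(self):
        """p for (n=30, r=0.3) vs a 10^5-draw simulation of the null."""
        rng = np.random.default_rng(42)
        draws = rng.uniform(-np.pi, np.pi, (100_000, 30))
        r_null = np.abs(np.exp(1j * draws).mean(axis=1))
        mc_p = np.mean(r_null >= 0.3)
        # a sample with resultant length exactly 0.3: 9 spikes at angle 0
        # plus 21 on a uniform grid (whose resultant cancels)
        grid = sg.wrap_phase(np.arange(21) * 2 * np.pi / 21)
        angles = np.concatenate([np.zeros(9), grid])
        r, _ = resultant_vector(angles)
        assert r == pytest.approx(0.3, abs=1e-12)
        assert rayleigh_test(angles) == pytest.approx(mc_p, rel=0.10)


class TestAnalyzeCell:
    def test_coupled_cell_included(self, coupled_pair):
        lfp, cell, _ = coupled_pair
        res = analyze_cell(lfp, cell)
        assert res.included
        assert res.vector_length > 0.5
        assert res.phase_angle == pytest.approx(0.5, abs=0.15)

    def test_uncoupled_cell_mostly_excluded(self, quiet_lfp_params):
        from dataclasses import replace
        included = 0
        for seed in range(10):
            lfp, phase = sg.simulate_gamma_lfp(replace(quiet_lfp_params, seed=seed))
            spikes = sg.simulate_coupled_spikes(
                phase, sg.CouplingParams(mean_rate=12, kappa=0, seed=seed))
            cell = sg.render_spike_trace(spikes, lfp.sampling_rate, seed=seed + 100)
            included += analyze_cell(lfp, cell).included
        assert included <= 1  # >= 90% excluded under kappa=0

    def test_spike_free_cell_excluded_with_reason(self, quiet_lfp_params):
        lfp, _ = sg.simulate_gamma_lfp(quiet_lfp_params)
        quiet = sg.TimeSeries(np.full(len(lfp), -60.0), lfp.sampling_rate)
        res = analyze_cell(lfp, quiet)
        assert not res.included
        assert "n < n_min" in res.exclusion_reason

    def test_dc_offset_invariance(self, coupled_pair):
        lfp, cell, _ = coupled_pair
        base = analyze_cell(lfp, cell)
        shifted = analyze_cell(lfp.with_samples(lfp.samples + 5.0), cell)
        assert shifted.vector_length == pytest.approx(base.vector_length, abs=1e-12)
        assert shifted.phase_angle == pytest.approx(base.phase_angle, abs=1e-12)
        assert shifted.rayleigh_p == pytest.approx(base.rayleigh_p, rel=1e-9)

    def test_quarter_cycle_rotation_equivariance(self, coupled_pair, quiet_lfp_params):
        """Shifting all spikes by a quarter gamma cycle rotates the phase
        angle by ~pi/2 and leaves the vector length unchanged."""
        lfp, cell, spikes = coupled_pair
        base = analyze_cell(lfp, cell)
        shift = 1.0 / (4.0 * quiet_lfp_params.carrier_freq)
        moved = sg.SpikeTrain(
            spikes.times[spikes.times + shift < spikes.duration] + shift,
            duration=spikes.duration)
        cell2 = sg.render_spike_trace(moved, lfp.sampling_rate, seed=4)
        rot = analyze_cell(lfp, cell2)
        assert rot.vector_length == pytest.approx(base.vector_length, abs=0.02)
        delta = sg.wrap_phase(rot.phase_angle - base.phase_angle)
        assert abs(delta) == pytest.approx(np.pi / 2, abs=0.1)

    def test_mismatched_inputs_rejected(self, coupled_pair):
        lfp, cell, _ = coupled_pair
        with pytest.raises(ParameterError, match="length mismatch"):
            analyze_cell(lfp, sg.TimeSeries(cell.samples[:-10], cell.sampling_rate))
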