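"""Φ-OTDR forward model: determinism, geometry, localization, waveform spectra."""

import numpy as np
import pytest

from palmdas import dsp
from palmdas.fiber import (
    AcousticScene,
    BurstSource,
    FiberLayout,
    InstrumentNoise,
    PulseConfig,
    TreeSpec,
    WindModel,
    larvae_waveform,
    realize_fiber,
    synthesize_traces,
    wind_shaping_gain,
    wind_waveform,
)


class TestRealizeFiber:
    def test_deterministic_in_seed(self, small_layout, pulse):
        a = realize_fiber(small_layout, pulse, seed=11)
        b = realize_fiber(small_layout, pulse, seed=11)
        np.testing.assert_array_equal(a.amp, b.amp)
        np.testing.assert_array_equal(a.phase, b.phase)
        np.testing.assert_array_equal(a.unperturbed_trace(), b.unperturbed_trace())
        c = realize_fiber(small_layout, pulse, seed=12)
        assert not np.array_equal(a.amp, c.amp)

    def test_default_layout_has_2000_bins(self, pulse):
        layout = FiberLayout()  # 1 km at 0.5 m
        state = realize_fiber(layout, pulse, seed=0)
        assert layout.n_bins == 2000
        assert state.unperturbed_trace().shape == (2000,)

    def test_fresnel_spike_dominates_trace(self, small_layout, pulse):
        state = realize_fiber(small_layout, pulse, seed=3, fresnel_factor=50.0)
        trace = state.unperturbed_trace()
        assert trace[0] > np.median(trace)

    def test_pulse_shorter_than_bin_rejected(self, small_layout):
        # 1-ns pulse -> ~0.1 m gauge < 0.5 m sampling
        with pytest.raises(ValueError, match="gauge"):
            realize_fiber(small_layout, PulseConfig(pulse_width=1e-9), seed=0)

    def test_pulse_overlap_rejected(self):
        # 50-km fiber at 5 kHz: round trip ~0.5 ms * ... exceeds pulse period
        layout = FiberLayout(fiber_length=50_000.0)
        with pytest.raises(ValueError, match="overlap"):
            realize_fiber(layout, PulseConfig(rep_rate=5000.0), seed=0)

    def test_spatial_resolution_about_5m(self):
        assert PulseConfig().spatial_resolution(1.468) == pytest.approx(5.0, abs=0.5)


class TestSynthesizeTraces:
    def test_null_scene_traces_equal_reference_bitexact(self, small_state, pulse):
        scene = AcousticScene(duration=0.2, instrument_noise=None)
        ts = synthesize_traces(small_state, scene, pulse, seed=1)
        ref = small_state.unperturbed_trace()
        assert np.all(ts.traces == ref[None, :])

    def test_zero_amplitude_sources_give_constant_traces(self, small_state, pulse):
        scene = AcousticScene(
            duration=0.2,
            larvae_sources=(BurstSource("I1", amplitude=0.0),),
            instrument_noise=None,
        )
        ts = synthesize_traces(small_state, scene, pulse, seed=1)
        assert np.all(ts.traces == ts.traces[0][None, :])

    def test_pulse_count_and_axes(self, small_state, pulse, larvae_scene):
        ts = synthesize_traces(small_state, larvae_scene, pulse, seed=5)
        assert ts.n_pulses == 5000  # 1 s at 5 kHz
        assert ts.n_bins == 200    # 100 m / 0.5 m
        assert np.all(ts.traces >= 0)
        np.testing.assert_allclose(np.diff(ts.time_axis), 1.0 / 5000.0)

    def test_perturbation_localized_to_source_tree(self, small_state, small_layout, pulse):
        scene = AcousticScene(
            duration=0.5,
            larvae_sources=(BurstSource("I1", burst_rate=8.0, amplitude=0.08,
                                        duty_pattern=(np.inf, 0.0)),),
            instrument_noise=None,
        )
        ts = synthesize_traces(small_state, scene, pulse, seed=5)
        var = ts.traces.astype(np.float64).var(axis=0)
        inside = small_layout.tree_bins("I1")
        outside = np.setdiff1d(np.arange(small_layout.n_bins), inside)
        assert var[outside].max() == 0.0  # noise-free run: nothing moves off-tree
        assert var[inside].max() > 0.0

    def test_unknown_source_tree_rejected(self, small_state, pulse):
        scene = AcousticScene(duration=0.2, larvae_sources=(BurstSource("nope"),))
        with pytest.raises(KeyError):
            synthesize_traces(small_state, scene, pulse, seed=0)

    def test_band_above_nyquist_rejected(self, small_state, pulse):
        scene = AcousticScene(
            duration=0.2, larvae_sources=(BurstSource("I1", band=(100.0, 3000.0)),))
        with pytest.raises(ValueError, match="Nyquist|band"):
            synthesize_traces(small_state, scene, pulse, seed=0)

    def test_deterministic_in_seed(self, small_state, pulse, larvae_scene):
        a = synthesize_traces(small_state, larvae_scene, pulse, seed=9)
        b = synthesize_traces(small_state, larvae_scene, pulse, seed=9)
        np.testing.assert_array_equal(a.traces, b.traces)

    def test_small_signal_matches_exact_sum(self, small_state, pulse):
        """Second-order expansion agrees with the explicit scatterer sum at
        the phase amplitudes used throughout (<~0.1 rad)."""
        scene = AcousticScene(
            duration=0.2,
            larvae_sources=(BurstSource("I1", burst_rate=8.0, amplitude=0.05,
                                        duty_pattern=(np.inf, 0.0)),),
            instrument_noise=None,
        )
        fast = synthesize_traces(small_state, scene, pulse, seed=4, method="small_signal")
        exact = synthesize_traces(small_state, scene, pulse, seed=4, method="exact", block=256)
        scale = float(np.median(exact.traces))
        assert np.max(np.abs(fast.traces.astype(float) - exact.traces.astype(float))) < 2e-2 * scale


class TestLarvaeWaveform:
    def test_zero_amplitude_is_silent(self):
        x = larvae_waveform(6.0, 0.025, (100.0, 800.0), 0.0, 1.0, seed=0)
        assert x.shape == (5000,)
        assert np.all(x == 0)

    def test_fully_silent_duty_is_silent(self):
        x = larvae_waveform(6.0, 0.025, (100.0, 800.0), 0.1, 1.0, seed=0,
                            duty_pattern=(0.0, 1.0))
        assert np.all(x == 0)

    def test_energy_concentrated_in_band(self):
        x = larvae_waveform(8.0, 0.025, (100.0, 800.0), 0.1, 4.0, seed=1)
        assert dsp.band_energy_fraction(x, 5000.0, (100.0, 800.0)) >= 0.9

    def test_overlapping_saturation_rejected(self):
        with pytest.raises(ValueError, match="saturation"):
            larvae_waveform(50.0, 0.05, (100.0, 800.0), 0.1, 1.0, seed=0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            larvae_waveform(6.0, 0.025, (100.0, 4000.0), 0.1, 1.0, seed=0)


class TestWindWaveform:
    def test_zero_speed_is_silent(self):
        assert np.all(wind_waveform(0.0, 100.0, 40.0, 1.0, seed=0) == 0)

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            wind_waveform(-1.0, 100.0, 40.0, 1.0, seed=0)

    def test_in_band_power_grows_with_speed(self):
        """Stronger wind leaks more power into the 100-800 Hz larvae band."""
        from scipy.signal import welch
        def in_band(speed):
            x = wind_waveform(speed, 100.0, 40.0, 8.0, seed=3)
            f, p = welch(x, fs=5000.0, nperseg=1024)
            sel = (f >= 100) & (f <= 800)
            return np.trapezoid(p[sel], f[sel])
        assert in_band(14.0) > in_band(4.0) > in_band(1.0)

    def test_spectral_rolloff_contract(self):
        """>= 20 dB more power at 50 Hz than at 400 Hz under the default slope,
        checked on the shaping response and on an empirical periodogram."""
        g = wind_shaping_gain(np.array([50.0, 400.0]), 100.0, 40.0)
        assert 20 * np.log10(g[0] / g[1]) >= 20.0
        from scipy.signal import welch
        x = wind_waveform(8.0, 100.0, 40.0, 16.0, seed=2, gustiness=0.0)
        f, p = welch(x, fs=5000.0, nperseg=2048)
        p50 = p[np.argmin(np.abs(f - 50.0))]
        p400 = p[np.argmin(np.abs(f - 400.0))]
        assert 10 * np.log10(p50 / p400) >= 20.0

    def test_deterministic_and_rms_scaling(self):
        a = wind_waveform(5.0, 100.0, 40.0, 2.0, seed=7)
        b = wind_waveform(5.0, 100.0, 40.0, 2.0, seed=7)
        np.testing.assert_array_equal(a, b)
        # power ∝ speed³ ⇒ doubling speed scales RMS by 2**1.5
        c = wind_waveform(10.0, 100.0, 40.0, 2.0, seed=7)
        assert np.std(c) / np.std(a) == pytest.approx(2**1.5, rel=1e-6)


class TestLayoutGeometry:
    def test_tree_loop_is_10_bins_at_defaults(self, small_layout):
        assert small_layout.points_per_tree("I1") == 10

    def test_overlapping_loops_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            FiberLayout(fiber_length=100.0, trees=(
                TreeSpec("a", 10.0), TreeSpec("b", 12.0)))

    def test_loop_outside_fiber_rejected(self):
        with pytest.raises(ValueError, match="within"):
            FiberLayout(fiber_length=100.0, trees=(TreeSpec("a", 98.0),))

    def test_instrument_noise_keeps_traces_nonnegative(self, small_state, pulse):
        scene = AcousticScene(duration=0.2,
                              instrument_noise=InstrumentNoise(white_floor=0.5, hf_level=0.2))
        ts = synthesize_traces(small_state, scene, pulse, seed=2)
        assert np.all(ts.traces >= 0)
        assert ts.traces.var(axis=0).max() > 0
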