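import math

import numpy as np
import pytest
from scipy import signal

from eisim import (
    ac_dc_ratio,
    apply_gating_and_level,
    gen_electric_train,
    gen_filtered_clicks,
    gen_ge_train,
    gen_sam_tone,
    gen_transposed_tone,
    greenwood_erb,
    HUMAN_MAP,
)
from eisim.stimuli import AcousticStimulus, P_REF, constant_q_corners


def steady_rms_db(stim):
    n_ramp = int(round(stim.ramp * stim.sample_rate))
    seg = stim.samples[n_ramp : len(stim.samples) - n_ramp]
    return 20 * np.log10(np.sqrt(np.mean(seg**2)) / P_REF)


class TestSamTone:
    def test_three_line_spectrum(self):
        """A SAM tone holds exactly the carrier and two half-amplitude sidebands."""
        stim = gen_sam_tone(8000, 100, duration=1.0, level=30)
        spec = np.abs(np.fft.rfft(stim.samples)) / len(stim.samples)
        freqs = np.fft.rfftfreq(len(stim.samples), 1 / stim.sample_rate)
        a_c = spec[np.argmin(np.abs(freqs - 8000))]
        a_lo = spec[np.argmin(np.abs(freqs - 7900))]
        a_hi = spec[np.argmin(np.abs(freqs - 8100))]
        assert a_lo / a_c == pytest.approx(0.5, rel=0.02)
        assert a_hi / a_c == pytest.approx(0.5, rel=0.02)
        # everything else is gating spillage, far below the lines
        mask = np.ones_like(spec, bool)
        for f in (7900, 8000, 8100):
            mask[np.abs(freqs - f) < 20] = False
        assert spec[mask].max() < 0.01 * a_c

    def test_envelope_zeros_at_modulator_zeros(self):
        """1 - cos(2 pi f_m t) vanishes at t = 0 and peaks at half the period."""
        stim = gen_sam_tone(8000, 100, duration=1.0, level=30, ramp=0.0)
        env = np.abs(signal.hilbert(stim.samples))
        t = stim.times
        # envelope at modulation-cycle start ~ 0, at half-cycle ~ max
        starts = ((t * 100) % 1.0) < 0.002
        mids = np.abs((t * 100) % 1.0 - 0.5) < 0.002
        assert env[starts].mean() < 0.05 * env.max()
        assert env[mids].mean() > 0.9 * env.max()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(f_c=8000, f_m=100, sample_rate=20_000),  # aliasing
            dict(f_c=8000, f_m=5000),                      # f_m >= f_c/2
        ],
    )
    def test_rejects_bad_inputs(self, kwargs):
        with pytest.raises(ValueError):
            gen_sam_tone(**{"duration": 0.1, "level": 30, **kwargs})


class TestTransposedTone:
    def test_sharper_envelope_than_sam(self):
        """Transposed tones carry more envelope AC per unit DC than SAM tones."""
        sam = gen_sam_tone(4000, 128, level=30)
        tran = gen_transposed_tone(4000, 128, level=30)
        assert ac_dc_ratio(tran) > ac_dc_ratio(sam)

    def test_rectified_sine_dc_is_one_over_pi(self):
        t = np.arange(100_000) / 100_000
        m = np.maximum(np.sin(2 * np.pi * 128 * t), 0.0)
        assert m.mean() == pytest.approx(1 / np.pi, rel=1e-3)

    def test_rejects_f_m_above_lowpass(self):
        with pytest.raises(ValueError):
            gen_transposed_tone(8000, 2500, duration=0.1, level=30)


class TestGreenwood:
    def test_round_trip(self):
        f = np.geomspace(100, 16_000, 50)
        back = HUMAN_MAP.frequency(HUMAN_MAP.position(f))
        assert np.allclose(back, f, rtol=1e-4)

    def test_apex_frequency_is_zero(self):
        assert HUMAN_MAP.frequency(0.0) == pytest.approx(0.0, abs=1e-9)

    def test_printed_bandwidth_pair(self):
        """1.5 mm at the 8-kHz place spans ~1691 Hz; its inverse is ~0.6 ms."""
        erb = greenwood_erb(8000, 1.5)
        assert erb == pytest.approx(1691, rel=0.01)
        assert round(1e3 / erb, 1) == 0.6

    def test_zero_span(self):
        assert greenwood_erb(8000, 0.0) == 0.0

    def test_strictly_increasing(self):
        spans = [greenwood_erb(8000, s) for s in (0.5, 1.0, 1.5, 2.0)]
        assert np.all(np.diff(spans) > 0)
        fcs = [greenwood_erb(f, 1.5) for f in (1000, 2000, 4000, 8000)]
        assert np.all(np.diff(fcs) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            greenwood_erb(25_000, 1.5)


class TestGETrain:
    def test_pulse_count(self):
        stim = gen_ge_train(8000, 100, duration=1.0, level=30, ramp=0.0)
        env = np.abs(signal.hilbert(stim.samples))
        peaks, _ = signal.find_peaks(env, height=0.5 * env.max(), distance=100)
        assert len(peaks) == 100

    def test_envelope_erd_matches_bandwidth(self):
        """Equivalent rectangular duration of one pulse envelope = 1/ERB."""
        stim = gen_ge_train(8000, 20, duration=0.5, level=30, ramp=0.0)
        env = np.abs(signal.hilbert(stim.samples))
        # isolate the single pulse centred at 0.225 s
        fs = stim.sample_rate
        i0, i1 = int(0.2 * fs), int(0.25 * fs)
        seg = env[i0:i1]
        erd = seg.sum() / seg.max() / fs
        assert erd * 1e3 == pytest.approx(1e3 / greenwood_erb(8000, 1.5), rel=0.05)


class TestFilteredClicks:
    def test_constant_q_corners(self):
        f_lo, f_hi = constant_q_corners(8000, 0.5)
        assert f_lo == pytest.approx(8000 * (math.sqrt(2) - 1), rel=1e-9)
        assert f_hi == pytest.approx(8000 * (math.sqrt(2) + 1), rel=1e-9)
        assert f_lo * f_hi == pytest.approx(8000**2)
        assert f_hi - f_lo == pytest.approx(8000 / 0.5)

    def test_pulse_count(self):
        stim = gen_filtered_clicks(8000, 40, duration=1.0, level=30, ramp=0.0)
        env = np.abs(signal.hilbert(stim.samples))
        peaks, _ = signal.find_peaks(env, height=0.4 * env.max(), distance=1000)
        assert len(peaks) == 40

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_filtered_clicks(8000, 40, sample_rate=100_000, level=30)


class TestGatingAndLevel:
    def test_level_reference(self):
        stim = gen_sam_tone(8000, 100, level=0.0)
        n_ramp = int(round(stim.ramp * stim.sample_rate))
        seg = stim.samples[n_ramp:-n_ramp]
        assert np.sqrt(np.mean(seg**2)) == pytest.approx(P_REF, rel=1e-3)

    def test_ramp_midpoint_half_amplitude(self):
        flat = AcousticStimulus(np.ones(10_000), 10_000.0, "sam", 100.0, 10.0, 0.0, 1.0)
        gated = apply_gating_and_level(flat, level=60, ramp=0.1)
        i_mid = 500  # halfway up the 1000-sample ramp
        steady = gated.samples[5000]
        assert gated.samples[i_mid] == pytest.approx(0.5 * steady, rel=0.01)

    def test_relevel_idempotent(self):
        stim = gen_sam_tone(8000, 100, level=30)
        again = apply_gating_and_level(stim, level=30)
        assert abs(steady_rms_db(again) - steady_rms_db(stim)) < 0.01

    def test_ramp_too_long_rejected(self):
        stim = gen_sam_tone(8000, 100, duration=0.1, level=30)
        with pytest.raises(ValueError):
            apply_gating_and_level(stim, level=30, ramp=0.06)

    def test_all_generators_hit_target_level(self):
        stims = [
            gen_sam_tone(4000, 128, level=30),
            gen_transposed_tone(4000, 128, level=30),
            gen_ge_train(4000, 128, level=30),
            gen_filtered_clicks(4000, 128, level=30),
        ]
        for s in stims:
            assert abs(steady_rms_db(s) - 30.0) < 0.1


class TestAcDcRatio:
    def test_constant_signal(self):
        flat = AcousticStimulus(np.ones(1000), 1000.0, "sam", 10.0, 1.0, 0.0, 1.0)
        assert ac_dc_ratio(flat) == pytest.approx(0.0, abs=1e-9)

    def test_halfwave_sine_closed_form(self):
        t = np.arange(100_000) / 100_000
        s = AcousticStimulus(np.sin(2 * np.pi * 50 * t), 100_000.0, "sam", 50.0, 1.0, 0.0, 1.0)
        expected = math.pi * math.sqrt(0.25 - 1 / math.pi**2)
        assert ac_dc_ratio(s) == pytest.approx(expected, rel=1e-3)

    def test_zero_signal_rejected(self):
        z = AcousticStimulus(np.zeros(100), 100.0, "sam", 10.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            ac_dc_ratio(z)

    def test_envelope_sharpness_ordering(self):
        """Clicks and GE tones have sharper envelopes than transposed and SAM."""
        r = {
            "sam": ac_dc_ratio(gen_sam_tone(4000, 128, level=30)),
            "transposed": ac_dc_ratio(gen_transposed_tone(4000, 128, level=30)),
            "ge": ac_dc_ratio(gen_ge_train(4000, 128, level=30)),
            "clicks": ac_dc_ratio(gen_filtered_clicks(4000, 128, level=30)),
        }
        assert r["clicks"] >= r["ge"] > r["transposed"] > r["sam"]


class TestElectricTrain:
    def test_basic_unmodulated(self):
        tr = gen_electric_train(40.0, level=0.0, reference_current=240.0)
        assert len(tr.pulse_times) == 24
        assert np.allclose(np.diff(tr.pulse_times), 1 / 40.0)
        # outside the 10-ms gating ramps every pulse has the reference amplitude
        inner = (tr.pulse_times >= 0.010) & (tr.pulse_times <= 0.590)
        assert np.allclose(tr.amplitudes[inner], 240.0)

    def test_level_scaling(self):
        tr = gen_electric_train(40.0, level=6.0, reference_current=240.0)
        inner = (tr.pulse_times >= 0.010) & (tr.pulse_times <= 0.590)
        assert np.allclose(tr.amplitudes[inner], 240.0 * 10 ** (6 / 20))

    def test_sam_envelope_values(self):
        tr = gen_electric_train(1000.0, level=0.0, f_m=50.0, reference_current=100.0)
        # envelope zero at t=0, unity at half the modulation period (10 ms,
        # exactly on the pulse grid and at the end of the gating ramp)
        assert tr.amplitudes[0] == pytest.approx(0.0, abs=1e-9)
        i_half = np.argmin(np.abs(tr.pulse_times - 0.010))
        assert tr.amplitudes[i_half] == pytest.approx(100.0, rel=1e-6)

    def test_sam_periodicity(self):
        """Amplitude sequence repeats every carrier_rate/f_m pulses (ratio integer)."""
        tr = gen_electric_train(1000.0, level=0.0, f_m=40.0, reference_current=100.0)
        period = 25  # 1000 / 40
        inner = (tr.pulse_times >= 0.010) & (tr.pulse_times <= 0.590 - 0.025)
        idx = np.nonzero(inner)[0]
        assert np.allclose(tr.amplitudes[idx], tr.amplitudes[idx + period], rtol=1e-9)

    def test_fm_limit_rejected(self):
        with pytest.raises(ValueError):
            gen_electric_train(1000.0, f_m=500.0)
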