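"""Interface physics, attenuation, transducer and receiver models."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import signal as sig

from golayscan import (
    AIR,
    ChannelConfig,
    DefectRegion,
    Medium,
    ModulationSpec,
    ReceiverChain,
    Specimen,
    TransducerModel,
    Waveform,
    modulate_square_carrier,
    receiver_filter,
    reflection_coefficient,
    simulate_received,
    through_transmission_gain,
    transducer_response,
    transmission_coefficient,
)

impedances = st.floats(min_value=1.0, max_value=1e8)


class TestInterfaceCoefficients:
    def test_air_wood_reflection_is_nearly_total(self):
        r = reflection_coefficient(400, 1.6e6)
        assert r == pytest.approx(0.99950012, abs=1e-8)
        assert r >= 0.99  # "roughly 99%" as a fraction

    def test_matched_media(self):
        assert reflection_coefficient(7.5, 7.5) == 0.0
        assert transmission_coefficient(7.5, 7.5) == 1.0

    def test_reversal_antisymmetry(self):
        assert reflection_coefficient(1.6e6, 400) == pytest.approx(
            -reflection_coefficient(400, 1.6e6))

    def test_air_to_wood_transmission(self):
        assert transmission_coefficient(400, 1.6e6) == pytest.approx(
            1.99950012, abs=1e-8)

    @given(z1=impedances, z2=impedances)
    def test_t_equals_one_plus_r(self, z1, z2):
        t = transmission_coefficient(z1, z2)
        r = reflection_coefficient(z1, z2)
        assert t - r == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("z1,z2", [(0, 400), (400, -1)])
    def test_nonpositive_impedance_rejected(self, z1, z2):
        with pytest.raises(ValueError):
            reflection_coefficient(z1, z2)
        with pytest.raises(ValueError):
            transmission_coefficient(z1, z2)


class TestThroughTransmissionGain:
    def test_defect_gain_ordering(self, board):
        cfg = ChannelConfig()
        sound = through_transmission_gain(board, 0.005, 0.005, cfg, 75e3)
        knot = through_transmission_gain(board, 0.018, 0.018, cfg, 75e3)
        pit = through_transmission_gain(board, 0.042, 0.042, cfg, 75e3)
        assert pit > sound > knot > 0

    def test_transparent_medium_gain_is_one(self):
        lossless = Medium(impedance=400.0, sound_speed=1500.0,
                          attenuation_coeff=0.0)
        board = Specimen(nominal_thickness=0.01, width=0.1, height=0.1,
                         base=lossless)
        cfg = ChannelConfig(air=Medium(impedance=400.0, sound_speed=343.0,
                                       attenuation_coeff=0.0))
        gain = through_transmission_gain(board, 0.05, 0.05, cfg, 75e3)
        assert gain == pytest.approx(1.0)

    def test_monotone_in_impedance_multiplier(self, board):
        cfg = ChannelConfig()
        gains = []
        for mult in (1.5, 2.0, 4.0, 8.0):
            knot = DefectRegion(shape="circle", center=(0.05, 0.05),
                                size=0.01, label="knot",
                                impedance_multiplier=mult)
            b = Specimen(nominal_thickness=0.01, width=0.1, height=0.1,
                         defects=(knot,))
            gains.append(
                through_transmission_gain(b, 0.05, 0.05, cfg, 75e3))
        assert all(a > b for a, b in zip(gains, gains[1:]))

    def test_monotone_in_thickness(self, board):
        cfg = ChannelConfig()
        gains = []
        for frac in (0.8, 0.6, 0.4, 0.2):
            pit = DefectRegion(shape="circle", center=(0.05, 0.05),
                               size=0.01, label="pit",
                               thickness_fraction=frac)
            b = Specimen(nominal_thickness=0.01, width=0.1, height=0.1,
                         defects=(pit,))
            gains.append(
                through_transmission_gain(b, 0.05, 0.05, cfg, 75e3))
        assert all(a < b for a, b in zip(gains, gains[1:]))

    def test_point_off_board_rejected(self, board):
        with pytest.raises(ValueError):
            through_transmission_gain(board, 0.1, 0.0, ChannelConfig(),
                                      75e3)


class TestTransducer:
    def test_impulse_rings_at_center_frequency(self):
        model = TransducerModel()
        fs = 4.8e6
        x = np.zeros(8192)
        x[0] = 1.0
        out = transducer_response(Waveform(samples=x, fs=fs), model)
        f = np.fft.rfftfreq(8192, 1 / fs)
        peak_freq = f[np.argmax(np.abs(np.fft.rfft(out.samples)))]
        assert peak_freq == pytest.approx(75e3, rel=0.02)

    def test_ring_down_grows_with_quality_factor(self):
        fs = 4.8e6
        x = np.zeros(16384)
        x[0] = 1.0
        durations = []
        for q in (5.0, 10.0, 20.0):
            model = TransducerModel(quality_factor=q)
            out = transducer_response(Waveform(samples=x, fs=fs), model)
            mag = np.abs(out.samples)
            above = np.nonzero(mag > 0.1 * mag.max())[0]
            durations.append(above[-1])
        assert durations[0] < durations[1] < durations[2]

    def test_zero_in_zero_out(self):
        out = transducer_response(
            Waveform(samples=np.zeros(100), fs=4.8e6), TransducerModel())
        assert np.all(out.samples == 0.0)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            transducer_response(Waveform(samples=np.ones(10), fs=100e3),
                                TransducerModel())


class TestReceiverChain:
    def test_bandpass_meets_printed_spec(self):
        fs = 4.8e6
        chain = ReceiverChain()
        sos = chain.bandpass_sos(fs)
        f = np.linspace(40e3, 110e3, 40001)
        _, h = sig.sosfreqz(sos, worN=2 * np.pi * f / fs)
        mag = np.abs(h)
        center = f[np.argmax(mag)]
        above = f[mag >= mag.max() / np.sqrt(2)]
        bw = above.max() - above.min()
        assert center == pytest.approx(75e3, rel=0.02)
        assert bw == pytest.approx(14e3, rel=0.02)

    def test_cascade_order_preserves_bandwidth(self):
        fs = 4.8e6
        chain = ReceiverChain(filter_order=4)
        sos = chain.bandpass_sos(fs)
        f = np.linspace(40e3, 110e3, 40001)
        _, h = sig.sosfreqz(sos, worN=2 * np.pi * f / fs)
        mag = np.abs(h)
        above = f[mag >= mag.max() / np.sqrt(2)]
        assert above.max() - above.min() == pytest.approx(14e3, rel=0.02)

    def test_tone_in_passband_sees_full_gain(self):
        fs = 4.8e6
        chain = ReceiverChain(gain=5.0)
        t = np.arange(int(fs * 0.004)) / fs
        tone = np.sin(2 * np.pi * 75e3 * t)
        out = receiver_filter(Waveform(samples=tone, fs=fs), chain)
        steady = out.samples[len(out.samples) // 2 :]
        assert np.max(np.abs(steady)) == pytest.approx(5.0, rel=0.02)

    def test_dc_offset_removed(self):
        fs = 4.8e6
        chain = ReceiverChain()
        x = np.full(40000, 0.7)
        out = receiver_filter(Waveform(samples=x, fs=fs), chain)
        assert abs(np.mean(out.samples[20000:])) < 1e-3

    def test_out_of_band_tone_attenuated(self):
        fs = 4.8e6
        chain = ReceiverChain()
        t = np.arange(int(fs * 0.004)) / fs

        def steady_peak(freq):
            out = receiver_filter(
                Waveform(samples=np.sin(2 * np.pi * freq * t), fs=fs),
                chain)
            return np.max(np.abs(out.samples[len(out.samples) // 2 :]))

        assert steady_peak(200e3) < 0.2 * steady_peak(75e3)

    def test_sampling_theorem_guard(self):
        with pytest.raises(ValueError):
            receiver_filter(Waveform(samples=np.ones(10), fs=150e3),
                            ReceiverChain())

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ReceiverChain(bp_center=5e3, bp_bandwidth_3db=14e3)
        with pytest.raises(ValueError):
            ReceiverChain(filter_order=3)


@pytest.fixture(scope="module")
def parts(fast_carrier_spec, pair8):
    exc = modulate_square_carrier(pair8.a, fast_carrier_spec)
    return exc, TransducerModel(), TransducerModel(), ReceiverChain()


class TestSimulateReceived:

    def test_zero_excitation_zero_output(self, board, parts):
        exc, tx, rx, chain = parts
        silent = Waveform(samples=np.zeros_like(exc.samples), fs=exc.fs)
        out = simulate_received(silent, board, 0.005, 0.005, tx, rx,
                                chain, ChannelConfig(noise_sigma=0.0))
        assert np.all(out.samples == 0.0)

    def test_linearity_in_amplitude(self, board, parts):
        exc, tx, rx, chain = parts
        cfg = ChannelConfig(noise_sigma=0.0)
        out1 = simulate_received(exc, board, 0.005, 0.005, tx, rx, chain,
                                 cfg)
        exc2 = Waveform(samples=2 * exc.samples, fs=exc.fs)
        out2 = simulate_received(exc2, board, 0.005, 0.005, tx, rx,
                                 chain, cfg)
        assert np.allclose(out2.samples, 2 * out1.samples, atol=1e-12)

    def test_seed_reproducibility(self, board, parts):
        exc, tx, rx, chain = parts
        cfg = ChannelConfig(noise_sigma=1e-5, rng_seed=42)
        a = simulate_received(exc, board, 0.005, 0.005, tx, rx, chain,
                              cfg)
        b = simulate_received(exc, board, 0.005, 0.005, tx, rx, chain,
                              cfg)
        assert np.array_equal(a.samples, b.samples)

    def test_noiseless_is_seed_independent(self, board, parts):
        exc, tx, rx, chain = parts
        outs = [
            simulate_received(exc, board, 0.005, 0.005, tx, rx, chain,
                              ChannelConfig(noise_sigma=0.0, rng_seed=s))
            for s in (1, 99)
        ]
        assert np.array_equal(outs[0].samples, outs[1].samples)


class TestGroundTruthMask:
    def test_area_fraction_converges(self, board):
        # (pi*8^2 + pi*6^2) / 60^2 of the board area is defective
        res = 0.25e-3
        xs = np.arange(0, board.width + res / 2, res)
        ys = np.arange(0, board.height + res / 2, res)
        labels = board.label_grid(xs, ys)
        frac = np.mean(labels != "sound")
        expected = (np.pi * (0.008**2 + 0.006**2)) / (0.06 * 0.06)
        assert frac == pytest.approx(expected, rel=0.02)

    def test_local_geometry(self, board):
        assert board.local_thickness(0.042, 0.042) == pytest.approx(
            0.006)
        assert board.label_at(0.001, 0.001) == "sound"
        assert board.label_at(0.018, 0.018) == "knot"
        assert board.local_impedance(0.018, 0.018) == pytest.approx(
            2 * board.base.impedance)

    def test_defect_validation(self):
        with pytest.raises(ValueError):
            DefectRegion(shape="circle", center=(0, 0), size=0.01,
                         label="knot", impedance_multiplier=1.0)
        with pytest.raises(ValueError):
            DefectRegion(shape="circle", center=(0, 0), size=0.01,
                         label="pit", thickness_fraction=1.2)
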