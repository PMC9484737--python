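import numpy as np
import pytest

from eegensemble.preprocess import (
    MONTAGE_3CH,
    MONTAGE_18CH,
    MissingElectrodeError,
    MontageSpec,
    Recording,
    SegmentSet,
    derive_montage,
    filter_and_resample,
    flag_zero_voltage,
    rescale_int16,
    segment,
)


def _rec(signals, rate=256.0, names=None):
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    names = names or [f"e{i}" for i in range(signals.shape[0])]
    return Recording("p", signals, rate, names)


class TestMontage:
    def test_self_pair_is_zero(self):
        rec = _rec(np.random.default_rng(0).normal(size=(1, 100)), names=["A"])
        out = derive_montage(rec, MontageSpec(pairs=[("A", "A")]))
        assert np.all(out.signals == 0)

    def test_constant_difference(self):
        rec = _rec([np.full(50, 5.0), np.full(50, 2.0)], names=["F3", "P3"])
        out = derive_montage(rec, MontageSpec(pairs=[("F3", "P3")]))
        assert np.all(out.signals == 3.0)
        assert out.channel_names == ["F3-P3"]

    def test_missing_electrode_named_in_error(self):
        rec = _rec(np.zeros((1, 10)), names=["F3"])
        with pytest.raises(MissingElectrodeError, match="T7"):
            derive_montage(rec, MontageSpec(pairs=[("F3", "T7")]))

    def test_linearity(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=(4, 64))
        names = ["F3", "P3", "F4", "P4"]
        spec = MontageSpec(pairs=[("F3", "P3"), ("F4", "P4")])
        m1 = derive_montage(_rec(sig, names=names), spec).signals
        m2 = derive_montage(_rec(3.5 * sig, names=names), spec).signals
        np.testing.assert_allclose(m2, 3.5 * m1)

    def test_standard_montages_shape(self):
        assert len(MONTAGE_18CH.pairs) == 18
        assert len(MONTAGE_3CH.pairs) == 3


class TestFilterResample:
    def _tone(self, freq, dur=60.0, rate=256.0):
        t = np.arange(int(dur * rate)) / rate
        return _rec(np.sin(2 * np.pi * freq * t)[None, :], rate=rate)

    @staticmethod
    def _central_rms(x):
        n = x.shape[-1]
        return float(np.sqrt(np.mean(x[..., n // 4 : -n // 4] ** 2)))

    def test_stopband_tone_strongly_attenuated(self):
        rec = self._tone(0.1)
        out = filter_and_resample(rec)
        ratio = self._central_rms(out.signals) / self._central_rms(rec.signals)
        assert ratio < 10 ** (-40 / 20)  # at least the design attenuation

    def test_passband_tone_preserved(self):
        rec = self._tone(5.0)
        out = filter_and_resample(rec)
        ratio = self._central_rms(out.signals) / self._central_rms(rec.signals)
        assert 0.9 < ratio < 1.05

    def test_zero_in_zero_out(self):
        out = filter_and_resample(_rec(np.zeros((2, 2560))))
        assert np.allclose(out.signals, 0)
        assert out.sample_rate_hz == 32

    def test_output_length(self):
        out = filter_and_resample(_rec(np.zeros((1, 1000)), rate=256.0))
        assert out.signals.shape[1] == int(np.floor(1000 * 32 / 256))

    def test_rate_below_target_rejected(self):
        with pytest.raises(ValueError):
            filter_and_resample(_rec(np.zeros((1, 100)), rate=16.0))

    def test_passband_idempotence_within_ripple(self):
        # keep the rate at 256 Hz so only the band-pass is applied twice
        rec = self._tone(5.0, rate=256.0)
        once = filter_and_resample(rec, target_rate_hz=256)
        twice = filter_and_resample(once, target_rate_hz=256)
        r0 = self._central_rms(rec.signals)
        r1 = self._central_rms(once.signals)
        r2 = self._central_rms(twice.signals)
        single_pass_deviation = abs(r1 / r0 - 1.0)
        assert abs(r2 - r1) / r1 < 2 * single_pass_deviation + 1e-3


class TestRescale:
    def test_range_endpoint(self):
        out = rescale_int16(_rec([[500.0]]), full_scale_uv=500.0)
        assert out.signals[0, 0] == 32767

    def test_zero_maps_to_zero(self):
        out = rescale_int16(_rec([[0.0]]))
        assert out.signals[0, 0] == 0

    def test_clipping(self):
        out = rescale_int16(_rec([[1000.0]]), full_scale_uv=500.0)
        assert out.signals[0, 0] == 32767

    def test_roundtrip_within_quantization_step(self):
        rng = np.random.default_rng(2)
        sig = rng.uniform(-400, 400, size=(3, 256))
        out = rescale_int16(_rec(sig), full_scale_uv=500.0)
        recovered = out.signals.astype(float) * out.scale_uv
        assert np.max(np.abs(recovered - sig)) <= 500.0 / 32767.0

    def test_invalid_full_scale(self):
        with pytest.raises(ValueError):
            rescale_int16(_rec([[1.0]]), full_scale_uv=0.0)


class TestSegmentation:
    def _rec32(self, dur_s, channels=2):
        n = int(dur_s * 32)
        return _rec(np.arange(channels * n).reshape(channels, n), rate=32.0)

    def test_60s_gives_12_segments(self):
        seg = segment(self._rec32(60))
        assert len(seg) == 12
        assert seg.start_s.tolist() == list(range(0, 48, 4))

    def test_exactly_one_window(self):
        assert len(segment(self._rec32(16))) == 1

    def test_too_short_is_empty(self):
        assert len(segment(self._rec32(12))) == 0

    def test_window_shape(self):
        seg = segment(self._rec32(60, channels=3))
        assert seg.data.shape == (12, 3, 512)

    def test_interior_frame_covered_by_exactly_four_windows(self):
        seg = segment(self._rec32(120))
        n_frames = 120 // 4
        coverage = np.zeros(n_frames, dtype=int)
        for t0 in seg.start_s:
            k0 = int(t0) // 4
            coverage[k0 : k0 + 4] += 1
        # closed form min(4, k+1, n_frames - k); edges ramp up/down, the
        # interior is covered by exactly 4 overlapping windows
        for k in range(n_frames):
            assert coverage[k] == min(4, k + 1, n_frames - k)
        assert (coverage[3 : n_frames - 3] == 4).all()


class TestZeroVoltageFlag:
    def _seg_with_run(self, run_samples):
        data = np.ones((1, 2, 512), dtype=np.int16)
        data[0, 1, 100 : 100 + run_samples] = 0
        return SegmentSet(
            patient_id="p",
            start_s=np.array([0.0]),
            data=data,
            valid=np.array([True]),
        )

    def test_two_second_run_invalid(self):
        assert not flag_zero_voltage(self._seg_with_run(64)).valid[0]

    def test_half_second_run_valid(self):
        assert flag_zero_voltage(self._seg_with_run(16)).valid[0]

    def test_exactly_one_second_is_valid(self):
        # "more than 1 sec" is strict: 32 zeros at 32 Hz survive
        assert flag_zero_voltage(self._seg_with_run(32)).valid[0]
        assert not flag_zero_voltage(self._seg_with_run(33)).valid[0]

    def test_all_nonzero_valid(self):
        assert flag_zero_voltage(self._seg_with_run(0)).valid[0]
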