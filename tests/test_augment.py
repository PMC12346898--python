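import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lungsound.audio_io import AudioSignal, MultiChannelRecording
from lungsound.augment import (
    AugmentRanges,
    AugmentationConfig,
    BalancePolicy,
    add_gaussian_noise,
    amplitude_shift,
    mask_noise,
    mix_background,
    pitch_shift,
    rebalance,
    time_shift,
    time_stretch,
)


def _sig(x, fs=4000):
    return AudioSignal(np.asarray(x, dtype=float), fs)


def _tone(freq, fs=4000, seconds=2.0):
    t = np.arange(int(seconds * fs)) / fs
    return _sig(0.5 * np.sin(2 * np.pi * freq * t), fs)


def _peak_hz(x, fs):
    spec = np.abs(np.fft.rfft(x))
    return np.fft.rfftfreq(x.size, 1 / fs)[np.argmax(spec)]


class TestMixBackground:
    @given(
        w=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**16),
    )
    def test_convex_mix_is_exact(self, w, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-1, 1, 500)
        b = rng.uniform(-1, 1, 500)
        out = mix_background(_sig(a), _sig(b), w)
        assert np.array_equal(out.samples, (1 - w) * a + w * b)
        assert np.max(np.abs(out.samples)) <= 1.0  # convexity

    def test_limits_return_inputs(self, rng):
        a = rng.uniform(-1, 1, 100)
        b = rng.uniform(-1, 1, 100)
        assert np.array_equal(mix_background(_sig(a), _sig(b), 0.0).samples, a)
        assert np.array_equal(mix_background(_sig(a), _sig(b), 1.0).samples, b)

    def test_constant_arithmetic(self):
        out = mix_background(_sig(np.full(10, 0.8)), _sig(np.full(10, -0.4)), 0.25)
        assert np.allclose(out.samples, 0.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            mix_background(_sig(np.ones(10)), _sig(np.ones(11)), 0.5)
        with pytest.raises(ValueError):
            mix_background(_sig(np.ones(10)), AudioSignal(np.ones(10), 8000), 0.5)
        with pytest.raises(ValueError):
            mix_background(_sig(np.ones(10)), _sig(np.ones(10)), 1.5)


class TestTimeStretch:
    def test_identity_factor(self, sine_signal):
        out = time_stretch(sine_signal, 1.0)
        assert np.array_equal(out.samples, sine_signal.samples)

    @pytest.mark.parametrize("factor,expected", [(2.0, 20000), (0.5, 80000)])
    def test_length_arithmetic(self, factor, expected):
        sig = _sig(np.random.default_rng(0).standard_normal(40000) * 0.1)
        out = time_stretch(sig, factor)
        assert abs(out.samples.size - expected) <= 64  # within one hop

    def test_pitch_preserved(self):
        out = time_stretch(_tone(440.0), 1.5)
        assert abs(_peak_hz(out.samples, 4000) - 440.0) <= 5.0

    def test_bad_factor(self, sine_signal):
        with pytest.raises(ValueError):
            time_stretch(sine_signal, 0.0)


class TestPitchShift:
    def test_zero_semitones_identity(self, sine_signal):
        out = pitch_shift(sine_signal, 0.0)
        assert np.array_equal(out.samples, sine_signal.samples)

    def test_octave_up(self):
        out = pitch_shift(_tone(200.0), 12.0)
        assert abs(_peak_hz(out.samples, 4000) - 400.0) <= 10.0

    def test_length_preserved(self):
        sig = _tone(300.0)
        for semis in (-3.0, 2.5, 7.0):
            assert pitch_shift(sig, semis).samples.size == sig.samples.size

    def test_range_limit(self, sine_signal):
        with pytest.raises(ValueError):
            pitch_shift(sine_signal, 13.0)


class TestSimpleTransforms:
    def test_zero_sigma_identity(self, sine_signal):
        out = add_gaussian_noise(sine_signal, 0.0, seed=1)
        assert np.array_equal(out.samples, sine_signal.samples)

    def test_noise_is_seeded(self, sine_signal):
        a = add_gaussian_noise(sine_signal, 0.01, seed=5)
        b = add_gaussian_noise(sine_signal, 0.01, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_gain_doubles_rms(self, sine_signal):
        out = amplitude_shift(sine_signal, 2.0)
        rms = lambda x: np.sqrt(np.mean(x**2))
        assert rms(out.samples) == pytest.approx(2 * rms(sine_signal.samples), rel=1e-12)

    def test_time_shift_is_circular(self, sine_signal):
        out = time_shift(sine_signal, 250.0)  # 1000 samples at 4 kHz
        assert np.array_equal(out.samples, np.roll(sine_signal.samples, 1000))

    def test_mask_fraction_exact_count(self):
        sig = _sig(np.ones(40000))
        out = mask_noise(sig, 0.1, seed=3)
        assert int((out.samples == 0).sum()) == 4000  # without replacement

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AugmentationConfig(w=1.2)
        with pytest.raises(ValueError):
            AugmentationConfig(mask_fraction=1.0)
        with pytest.raises(ValueError):
            AugmentationConfig(stretch_factor=0.0)


def _tiny_dataset(rng, counts):
    """counts: label -> n; two-channel 1-s recordings."""
    out = []
    i = 0
    for label, n in counts.items():
        for _ in range(n):
            x = rng.standard_normal(4000) * 0.05
            out.append(
                MultiChannelRecording(
                    channels={
                        "BRUL": AudioSignal(x, 4000, "BRUL"),
                        "BLUL": AudioSignal(x.copy(), 4000, "BLUL"),
                    },
                    label=label,
                    subject_id=f"S{i}",
                )
            )
            i += 1
    return out


class TestRebalance:
    def test_multiplicity_arithmetic(self, rng):
        dataset = _tiny_dataset(rng, {"normal": 4, "wheeze": 2, "fine_crackle": 1})
        policy = BalancePolicy({"wheeze": 30, "fine_crackle": 4})
        out = rebalance(dataset, policy, seed=0)
        labels = [r.label for r in out]
        # n extra copies per original, originals retained
        assert labels.count("normal") == 4
        assert labels.count("wheeze") == 2 * 31
        assert labels.count("fine_crackle") == 1 * 5

    def test_zero_policy_is_identity(self, rng):
        dataset = _tiny_dataset(rng, {"normal": 2})
        out = rebalance(dataset, BalancePolicy({}), seed=0)
        assert out == dataset

    def test_seeded_determinism(self, rng):
        dataset = _tiny_dataset(rng, {"wheeze": 2})
        policy = BalancePolicy({"wheeze": 3})
        a = rebalance(dataset, policy, seed=42)
        b = rebalance(dataset, policy, seed=42)
        assert len(a) == len(b) == 8
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.as_array(), rb.as_array())

    def test_channels_share_transform_parameters(self, rng):
        """Identical input channels must stay identical after augmentation —
        the transform draw is per-recording, not per-channel."""
        dataset = _tiny_dataset(rng, {"wheeze": 1})
        out = rebalance(dataset, BalancePolicy({"wheeze": 8}), seed=7)
        for rec in out[1:]:
            arr = rec.as_array()
            assert rec.augmented
            assert np.array_equal(arr[0], arr[1])

    def test_augmented_flagged_with_derived_ids(self, rng):
        dataset = _tiny_dataset(rng, {"fine_crackle": 1})
        out = rebalance(dataset, BalancePolicy({"fine_crackle": 2}), seed=1)
        assert [r.subject_id for r in out[1:]] == ["S0-aug0", "S0-aug1"]
        assert not out[0].augmented
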