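"""Audio augmentation and class rebalancing.

The centrepiece is the convex background mixer

    I_out = (1 - w) * I_in + w * I_noise,   0 <= w <= 1,

which blends a recording with synthetic ward contamination (ventilator hum,
speech babble, rustling) sample-for-sample — exactly, with no hidden
normalisation. The remaining transforms are the standard audio-augmentation
suite: phase-vocoder time stretching (pitch-preserving), pitch shifting
(duration-preserving), additive Gaussian noise, amplitude scaling, circular
time shifting and random sample masking.

Class rebalancing applies a per-class multiplicity (the imbalance policy:
30 extra copies per wheeze recording, 4 per fine-crackle recording, none
for normal); every augmented variant draws ONE transform with seeded random
parameters and applies it with identical parameters to all channels of the
recording, so channel alignment survives. Augmented recordings are flagged
and carry ``<subject>-aug<k>`` ids so splits can quarantine them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.fft import irfft, rfft

from .audio_io import AudioSignal, MultiChannelRecording
from .synth import BACKGROUND_KINDS, synthesize_background
from .vocab import LABELS

__all__ = [
    "AugmentationConfig",
    "AugmentRanges",
    "BalancePolicy",
    "mix_background",
    "time_stretch",
    "pitch_shift",
    "add_gaussian_noise",
    "amplitude_shift",
    "time_shift",
    "mask_noise",
    "rebalance",
]


@dataclass(frozen=True)
class AugmentationConfig:
    """One concrete draw of transform parameters."""

    w: float = 0.2
    stretch_factor: float = 1.0
    pitch_semitones: float = 0.0
    gauss_sigma: float = 0.0
    shift_ms: float = 0.0
    mask_fraction: float = 0.0
    amplitude_gain: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must be in [0, 1], got {self.w}")
        if self.stretch_factor <= 0:
            raise ValueError("stretch_factor must be > 0")
        if not 0.0 <= self.mask_fraction < 1.0:
            raise ValueError("mask_fraction must be in [0, 1)")
        if self.amplitude_gain <= 0:
            raise ValueError("amplitude_gain must be > 0")


@dataclass(frozen=True)
class BalancePolicy:
    """Extra augmented copies per original, by class."""

    multiplicity: Mapping[str, int] = field(
        default_factory=lambda: {"wheeze": 30, "fine_crackle": 4}
    )

    def __post_init__(self):
        for lab, m in self.multiplicity.items():
            if lab not in LABELS:
                raise ValueError(f"unknown class {lab!r} in policy")
            if m < 0:
                raise ValueError("multiplicities must be >= 0")

    def copies(self, label: str) -> int:
        return int(self.multiplicity.get(label, 0))


def mix_background(i_in: AudioSignal, i_noise: AudioSignal, w: float) -> AudioSignal:
    """Sample-wise convex mix ``(1 - w) * i_in + w * i_noise``.

    Exact by construction: w = 0 returns the signal, w = 1 the noise, and
    bounded inputs stay bounded (convexity).
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must be in [0, 1], got {w}")
    if i_in.sample_rate != i_noise.sample_rate:
        raise ValueError(
            f"sample-rate mismatch: {i_in.sample_rate} vs {i_noise.sample_rate}"
        )
    if i_in.samples.size != i_noise.samples.size:
        raise ValueError(
            f"length mismatch: {i_in.samples.size} vs {i_noise.samples.size}"
        )
    out = (1.0 - w) * i_in.samples + w * i_noise.samples
    return i_in.with_samples(out)


# ---------------------------------------------------------------------------
# phase vocoder

_PV_WIN = 256
_PV_HOP = 64


def _stft_frames(x: np.ndarray, win: np.ndarray, positions: np.ndarray) -> np.ndarray:
    n = win.size
    pad = np.concatenate([x, np.zeros(n)])
    return np.stack([pad[int(p) : int(p) + n] * win for p in positions])


def time_stretch(signal: AudioSignal, factor: float) -> AudioSignal:
    """Phase-vocoder time stretch: output duration = input / factor, pitch
    preserved. ``factor`` > 1 shortens, < 1 lengthens."""
    if factor <= 0:
        raise ValueError(f"stretch factor must be > 0, got {factor}")
    x = signal.samples
    n_out = int(round(x.size / factor))
    if factor == 1.0:
        return signal.with_samples(x.copy())
    win = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(_PV_WIN) / _PV_WIN)
    n_frames = max(2, 1 + int(np.floor((n_out - _PV_WIN) / _PV_HOP))) if n_out > _PV_WIN else 2
    # analysis positions advance by factor * hop; synthesis by hop
    ana = np.minimum(np.arange(n_frames) * _PV_HOP * factor, max(x.size - 1, 0))
    ana_floor = np.floor(ana).astype(int)
    frac = (ana - ana_floor)[:, None]
    sp0 = rfft(_stft_frames(x, win, ana_floor), axis=1)
    sp1 = rfft(_stft_frames(x, win, ana_floor + 1), axis=1)
    mag = (1 - frac) * np.abs(sp0) + frac * np.abs(sp1)

    omega = 2 * np.pi * np.arange(_PV_WIN // 2 + 1) / _PV_WIN  # rad / sample
    expected = omega * _PV_HOP * factor
    phase = np.angle(sp0[0])
    out = np.zeros(n_frames * _PV_HOP + _PV_WIN)
    norm = np.zeros_like(out)
    for k in range(n_frames):
        if k > 0:
            dphi = np.angle(sp0[k]) - np.angle(sp0[k - 1]) - expected
            dphi -= 2 * np.pi * np.round(dphi / (2 * np.pi))
            phase = phase + expected / factor + dphi / factor
        frame = irfft(mag[k] * np.exp(1j * phase), n=_PV_WIN)
        pos = k * _PV_HOP
        out[pos : pos + _PV_WIN] += frame * win
        norm[pos : pos + _PV_WIN] += win**2
    out /= np.maximum(norm, 1e-8)
    out = out[:n_out]
    if out.size < n_out:
        out = np.concatenate([out, np.zeros(n_out - out.size)])
    return signal.with_samples(out)


def pitch_shift(signal: AudioSignal, semitones: float) -> AudioSignal:
    """Shift pitch by ``semitones`` (|semitones| <= 12), duration preserved.

    Resampling changes pitch and duration together; the phase vocoder then
    restores the original duration.
    """
    if abs(semitones) > 12:
        raise ValueError("pitch shift limited to +/- one octave")
    if semitones == 0:
        return signal.with_samples(signal.samples.copy())
    ratio = 2.0 ** (semitones / 12.0)
    n = signal.samples.size
    n_fast = int(round(n / ratio))
    # linear-phase resample to n_fast samples (playback-rate change)
    t_old = np.arange(n)
    t_new = np.linspace(0, n - 1, n_fast)
    y = np.interp(t_new, t_old, signal.samples)
    stretched = time_stretch(signal.with_samples(y), factor=n_fast / n)
    out = stretched.samples
    if out.size != n:
        out = out[:n] if out.size > n else np.concatenate([out, np.zeros(n - out.size)])
    return signal.with_samples(out)


# ---------------------------------------------------------------------------
# simple sample-domain transforms


def add_gaussian_noise(signal: AudioSignal, sigma: float, seed: int) -> AudioSignal:
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return signal.with_samples(signal.samples.copy())
    rng = np.random.default_rng(seed)
    return signal.with_samples(signal.samples + sigma * rng.standard_normal(signal.samples.size))


def amplitude_shift(signal: AudioSignal, gain: float) -> AudioSignal:
    if gain <= 0:
        raise ValueError("gain must be > 0")
    return signal.with_samples(gain * signal.samples)


def time_shift(signal: AudioSignal, shift_ms: float) -> AudioSignal:
    """Circular shift by ``shift_ms`` (positive = later)."""
    n = int(round(shift_ms * signal.sample_rate / 1000.0))
    return signal.with_samples(np.roll(signal.samples, n))


def mask_noise(signal: AudioSignal, mask_fraction: float, seed: int) -> AudioSignal:
    """Zero a random ``mask_fraction`` of samples, drawn without replacement."""
    if not 0.0 <= mask_fraction < 1.0:
        raise ValueError("mask_fraction must be in [0, 1)")
    out = signal.samples.copy()
    k = int(round(mask_fraction * out.size))
    if k:
        rng = np.random.default_rng(seed)
        idx = rng.choice(out.size, size=k, replace=False)
        out[idx] = 0.0
    return signal.with_samples(out)


# ---------------------------------------------------------------------------
# rebalancing


@dataclass(frozen=True)
class AugmentRanges:
    """Parameter ranges the rebalancer draws from, one transform per variant."""

    transforms: tuple[str, ...] = (
        "background",
        "stretch",
        "pitch",
        "gaussian",
        "shift",
        "mask",
        "gain",
    )
    w: tuple[float, float] = (0.05, 0.30)
    background_kinds: tuple[str, ...] = BACKGROUND_KINDS
    stretch: tuple[float, float] = (0.8, 1.25)
    pitch: tuple[float, float] = (-2.0, 2.0)
    sigma: tuple[float, float] = (0.002, 0.02)
    shift_ms: tuple[float, float] = (-1000.0, 1000.0)
    mask_fraction: tuple[float, float] = (0.02, 0.10)
    gain: tuple[float, float] = (0.7, 1.4)


def _augment_once(
    rec: MultiChannelRecording, ranges: AugmentRanges, rng: np.random.Generator, tag: str
) -> MultiChannelRecording:
    """Apply one randomly drawn transform, identically to every channel."""
    name = ranges.transforms[rng.integers(len(ranges.transforms))]
    fs = rec.sample_rate
    if name == "background":
        w = rng.uniform(*ranges.w)
        kind = ranges.background_kinds[rng.integers(len(ranges.background_kinds))]
        noise_seed = int(rng.integers(2**31))
        noise = synthesize_background(kind, rec.n_samples / fs, fs, noise_seed)
        op = lambda sig: mix_background(sig, noise.with_samples(noise.samples), w)
    elif name == "stretch":
        factor = rng.uniform(*ranges.stretch)
        op = lambda sig: time_stretch(sig, factor)
    elif name == "pitch":
        semis = rng.uniform(*ranges.pitch)
        op = lambda sig: pitch_shift(sig, semis)
    elif name == "gaussian":
        sigma = rng.uniform(*ranges.sigma)
        seed = int(rng.integers(2**31))
        op = lambda sig: add_gaussian_noise(sig, sigma, seed)
    elif name == "shift":
        ms = rng.uniform(*ranges.shift_ms)
        op = lambda sig: time_shift(sig, ms)
    elif name == "mask":
        frac = rng.uniform(*ranges.mask_fraction)
        seed = int(rng.integers(2**31))
        op = lambda sig: mask_noise(sig, frac, seed)
    elif name == "gain":
        g = rng.uniform(*ranges.gain)
        op = lambda sig: amplitude_shift(sig, g)
    else:  # pragma: no cover - enum guard
        raise ValueError(f"unknown transform {name!r}")
    channels = {pos: op(sig) for pos, sig in rec.channels.items()}
    return MultiChannelRecording(
        channels=channels,
        label=rec.label,
        subject_id=f"{rec.subject_id}-{tag}",
        augmented=True,
    )


def rebalance(
    dataset: Sequence[MultiChannelRecording],
    policy: BalancePolicy | None = None,
    ranges: AugmentRanges | None = None,
    seed: int = 0,
) -> list[MultiChannelRecording]:
    """Originals plus ``policy[class]`` augmented variants per original.

    Deterministic per (seed, dataset order): each original gets its own
    spawned random stream. Intended to run on the training partition after
    splitting; a pipeline that wants the augment-then-split ordering can
    simply call it before the split instead.
    """
    if not dataset:
        raise ValueError("cannot rebalance an empty dataset")
    policy = policy or BalancePolicy()
    ranges = ranges or AugmentRanges()
    ss = np.random.SeedSequence(seed)
    out = list(dataset)
    for rec, child in zip(dataset, ss.spawn(len(dataset))):
        n_copies = policy.copies(rec.label)
        if not n_copies:
            continue
        rng = np.random.default_rng(child)
        for k in range(n_copies):
            out.append(_augment_once(rec, ranges, rng, tag=f"aug{k}"))
    return out
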