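"""Seeded synthetic multi-channel lung-sound generator.

The clinical recordings this pipeline was designed for (simultaneous
electronic-stethoscope auscultation at several chest positions, labelled
normal / wheeze / fine crackle) are not redistributable, so the package
carries a generator that reproduces the *statistical structure* the pipeline
relies on rather than the physiology:

* a breath envelope with distinct inspiratory/expiratory phases;
* **normal** breath sound: envelope-modulated band-limited noise;
* **wheeze**: the normal sound plus a continuous envelope-modulated tonal
  component (>= 100 ms segments) at a subject-specific frequency;
* **fine crackle**: the normal sound plus short (<= 20 ms) exponentially
  damped oscillatory transients placed during inspirations, with a Poisson
  count per inspiration;
* multi-position channels derived from ONE shared source through per-channel
  gain, delay and a position-dependent low-pass tilt, plus independent
  sensor noise at a configurable SNR;
* cohort-level class imbalance mirroring a realistic ward population
  (default proportions 0.789 / 0.193 / 0.019 for normal / wheeze / crackle).

Everything is driven by :class:`numpy.random.Generator` seeded through
``numpy.random.SeedSequence`` so identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .audio_io import AudioSignal, Manifest, MultiChannelRecording, write_recording
from .vocab import LABELS, canonical_order, validate_label

__all__ = [
    "SyntheticSpec",
    "CohortSpec",
    "synthesize_breath_envelope",
    "synthesize_source",
    "synthesize_recording",
    "synthesize_cohort",
    "synthesize_background",
    "write_cohort",
]

#: Default four-position montage: the posterior sites with the most clinical
#: coverage in multi-site auscultation studies.
DEFAULT_POSITIONS = ("BRUL", "BLUL", "BLLL", "BRLL")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic subject's recording.

    ``cue_gains`` scales only the adventitious (wheeze/crackle) component per
    position, which lets a cohort plant class cues on specific channels while
    the breath sound stays shared — the construction behind the
    channel-complementarity benchmarks.
    """

    label: str = "normal"
    breath_rate: float = 15.0  # cycles / minute
    crackle_density: float = 0.0  # expected transients per inspiration
    wheeze_freq: float = 0.0  # Hz; 0 disables the tonal component
    base_noise_band: tuple[float, float] = (100.0, 1000.0)
    snr_db: float | None = 30.0  # sensor noise; None = noiseless channels
    channel_gains: Mapping[str, float] | None = None
    channel_delays_ms: Mapping[str, float] | None = None
    cue_gains: Mapping[str, float] | None = None
    position_tilt: bool = True
    duration_s: float = 10.0
    sample_rate: int = 4000

    def __post_init__(self):
        validate_label(self.label)
        lo, hi = self.base_noise_band
        if not (0 < lo < hi < self.sample_rate / 2):
            raise ValueError(
                f"base_noise_band must satisfy 0 < low < high < Nyquist, got {self.base_noise_band}"
            )
        if self.crackle_density < 0:
            raise ValueError("crackle_density must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate))


@dataclass
class CohortSpec:
    """A population of synthetic subjects.

    ``class_proportions`` is ordered (normal, wheeze, fine_crackle); counts
    are assigned by largest-remainder rounding. ``cue_positions`` optionally
    maps a class to the position (or positions) carrying that class's full
    adventitious cue; all other channels receive ``off_cue_gain`` of it.
    """

    n_subjects: int = 100
    # clinical class imbalance: 1827 normal / 447 wheeze / 43 fine crackle
    class_proportions: tuple[float, float, float] = (1827 / 2317, 447 / 2317, 43 / 2317)
    positions: tuple[str, ...] = DEFAULT_POSITIONS
    seed: int = 0
    snr_db: float | None = 30.0
    duration_s: float = 10.0
    sample_rate: int = 4000
    cue_positions: Mapping[str, str] | None = None
    off_cue_gain: float = 0.1

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.size != len(LABELS) or np.any(props < 0) or not np.isclose(props.sum(), 1.0):
            raise ValueError(
                f"class_proportions must be {len(LABELS)} non-negative values summing to 1, got {self.class_proportions}"
            )
        self.positions = tuple(canonical_order(self.positions))


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Integer counts summing to n, proportional by largest-remainder rounding.

    Ties in the remainders are broken toward lower indices.
    """
    props = np.asarray(proportions, dtype=float)
    exact = n * props / props.sum()
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n - counts.sum()
    # stable sort => ties go to the earlier class
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1
    return counts


# ---------------------------------------------------------------------------
# breath envelope and source construction


def _breath_phases(spec: SyntheticSpec, rng: np.random.Generator):
    """Envelope in [0,1] plus a boolean inspiration mask, same length.

    One breath cycle = inspiration (40%), expiration (35%), pause (25%).
    Inspiration reaches amplitude 1, expiration 0.6 (inspiration is the
    louder phase at the chest wall); each cycle's amplitude is jittered a
    few percent so the signal is not exactly periodic.
    """
    n = spec.n_samples
    t = np.arange(n) / spec.sample_rate
    period = 60.0 / spec.breath_rate
    phase = (t % period) / period
    cycle_idx = (t // period).astype(int)
    jitter = 1.0 + 0.05 * rng.standard_normal(cycle_idx.max() + 1)
    amp = np.clip(jitter, 0.8, 1.2)[cycle_idx]

    env = np.zeros(n)
    insp = phase < 0.40
    exp = (phase >= 0.40) & (phase < 0.75)
    env[insp] = np.sin(np.pi * phase[insp] / 0.40) ** 2
    env[exp] = 0.6 * np.sin(np.pi * (phase[exp] - 0.40) / 0.35) ** 2
    env *= amp
    return np.clip(env, 0.0, 1.0), insp


def synthesize_breath_envelope(spec: SyntheticSpec, seed: int) -> np.ndarray:
    """Non-negative amplitude envelope, periodic at ``breath_rate``."""
    rng = np.random.default_rng(seed)
    env, _ = _breath_phases(spec, rng)
    return env


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _crackle_burst(fs: float, f0: float, dur_s: float) -> np.ndarray:
    """Exponentially damped sinusoid; decays to ~1% over its duration."""
    n = max(int(round(dur_s * fs)), 8)
    t = np.arange(n) / fs
    decay = np.exp(-t / (dur_s / 4.6))  # ln(0.01) ~ -4.6
    return decay * np.sin(2 * np.pi * f0 * t)


def _synthesize_components(spec: SyntheticSpec, seed: int):
    """(breath, adventitious, envelope) arrays before mixing/normalisation.

    The adventitious component is empty (zeros) for the normal class. The
    two components are returned separately so multi-channel synthesis can
    apply per-position cue gains to the adventitious part alone.
    """
    ss = np.random.SeedSequence(seed)
    rng_env, rng_noise, rng_adv = (np.random.default_rng(s) for s in ss.spawn(3))
    env, insp = _breath_phases(spec, rng_env)
    n, fs = spec.n_samples, spec.sample_rate

    breath = env * _bandpass(rng_noise.standard_normal(n), spec.base_noise_band, fs)
    breath_rms = float(np.sqrt(np.mean(breath**2))) or 1.0

    adventitious = np.zeros(n)
    if spec.label == "wheeze" and spec.wheeze_freq > 0:
        phase0 = rng_adv.uniform(0, 2 * np.pi)
        tone = np.sin(2 * np.pi * spec.wheeze_freq * np.arange(n) / fs + phase0)
        # gate to envelope-active regions; contiguous runs are >= 100 ms by
        # construction because the envelope varies on the breath timescale
        gate = (env > 0.25).astype(float)
        adventitious = 2.0 * breath_rms * np.sqrt(2.0) * tone * env * gate
    elif spec.label == "fine_crackle" and spec.crackle_density > 0:
        # one Poisson draw per inspiration, bursts placed inside that phase;
        # fine crackles are distinctly audible above the vesicular base, so
        # burst amplitude scales with the breath PEAK, not its RMS
        breath_peak = float(np.max(np.abs(breath))) or 1.0
        starts = np.flatnonzero(np.diff(np.concatenate([[0], insp.astype(int)])) == 1)
        ends = np.flatnonzero(np.diff(np.concatenate([insp.astype(int), [0]])) == -1)
        for s, e in zip(starts, ends):
            if e - s < int(0.05 * fs):
                continue
            for _ in range(rng_adv.poisson(spec.crackle_density)):
                f0 = rng_adv.uniform(200.0, 1000.0)
                dur = rng_adv.uniform(0.008, 0.020)
                burst = _crackle_burst(fs, f0, dur)
                pos = rng_adv.integers(s, max(e - burst.size, s + 1))
                seg = slice(pos, min(pos + burst.size, n))
                amp = breath_peak * rng_adv.uniform(1.2, 2.0)
                adventitious[seg] += amp * burst[: seg.stop - seg.start]
    return breath, adventitious, env


def synthesize_source(spec: SyntheticSpec, seed: int) -> AudioSignal:
    """The shared acoustic source for one subject, peak-normalised to 0.9."""
    breath, adventitious, _ = _synthesize_components(spec, seed)
    x = breath + adventitious
    peak = float(np.max(np.abs(x))) or 1.0
    return AudioSignal(0.9 * x / peak, spec.sample_rate)


_TILT_CUTOFFS_HZ = {  # mild position-dependent low-pass: deeper sites darker
    "UL": 1800.0,
    "ML": 1500.0,
    "LL": 1200.0,
}


def _tilt_cutoff(position: str) -> float:
    return _TILT_CUTOFFS_HZ[position[-2:]]


def _delay(x: np.ndarray, n: int) -> np.ndarray:
    """Shift right by n samples, zero-filling (non-circular)."""
    if n == 0:
        return x
    out = np.zeros_like(x)
    out[n:] = x[: x.size - n]
    return out


def synthesize_recording(
    spec: SyntheticSpec, positions: Sequence[str], seed: int, subject_id: str = "S0"
) -> MultiChannelRecording:
    """Derive all requested channels from one shared source.

    Channel i = gain_i * lowpass_i(delay_i(breath + cue_gain_i * adventitious))
    + sensor noise at ``spec.snr_db`` (independent per channel).
    """
    if not positions:
        raise ValueError("positions must be non-empty")
    positions = canonical_order(positions)
    ss = np.random.SeedSequence([seed, 0xC0DE])
    src_seed = seed
    breath, adventitious, _ = _synthesize_components(spec, src_seed)
    peak = float(np.max(np.abs(breath + adventitious))) or 1.0
    breath = 0.9 * breath / peak
    adventitious = 0.9 * adventitious / peak

    noise_rngs = {p: np.random.default_rng(s) for p, s in zip(positions, ss.spawn(len(positions)))}
    gains = dict(spec.channel_gains or {})
    delays = dict(spec.channel_delays_ms or {})
    cues = dict(spec.cue_gains or {})
    fs = spec.sample_rate

    channels = {}
    for pos in positions:
        g = float(gains.get(pos, 1.0))
        d = int(round(float(delays.get(pos, 0.0)) * fs / 1000.0))
        cg = float(cues.get(pos, 1.0))
        x = _delay(breath, d) + cg * _delay(adventitious, d)
        if spec.position_tilt:
            sos = sps.butter(1, _tilt_cutoff(pos), btype="lowpass", fs=fs, output="sos")
            x = sps.sosfilt(sos, x)
        x = g * x
        if spec.snr_db is not None:
            rms = float(np.sqrt(np.mean(x**2))) or 1.0
            sigma = rms / (10.0 ** (spec.snr_db / 20.0))
            x = x + sigma * noise_rngs[pos].standard_normal(x.size)
        channels[pos] = AudioSignal(x, fs, pos)
    return MultiChannelRecording(
        channels=channels, label=spec.label, subject_id=subject_id
    )


# ---------------------------------------------------------------------------
# cohorts


def _subject_spec(label: str, cohort: CohortSpec, rng: np.random.Generator) -> SyntheticSpec:
    """Draw subject-level acoustic parameters for one class."""
    spec = SyntheticSpec(
        label=label,
        breath_rate=rng.uniform(12.0, 20.0),
        crackle_density=rng.uniform(6.0, 10.0) if label == "fine_crackle" else 0.0,
        wheeze_freq=rng.uniform(200.0, 800.0) if label == "wheeze" else 0.0,
        snr_db=cohort.snr_db,
        duration_s=cohort.duration_s,
        sample_rate=cohort.sample_rate,
        channel_gains={p: rng.uniform(0.7, 1.0) for p in cohort.positions},
        channel_delays_ms={p: rng.uniform(0.0, 3.0) for p in cohort.positions},
    )
    if cohort.cue_positions and label in cohort.cue_positions:
        cue_at = cohort.cue_positions[label]
        cue_set = {cue_at} if isinstance(cue_at, str) else set(cue_at)
        spec = replace(
            spec,
            cue_gains={
                p: (1.0 if p in cue_set else cohort.off_cue_gain)
                for p in cohort.positions
            },
        )
    return spec


def synthesize_cohort(cohort: CohortSpec) -> tuple[list[MultiChannelRecording], Manifest]:
    """Generate a labelled cohort plus its manifest.

    Class counts follow ``class_proportions`` by largest-remainder rounding;
    per-subject seeds derive deterministically from the cohort seed. Manifest
    paths follow the layout :func:`write_cohort` uses, so the pair can be
    written to disk and read back through ``audio_io`` unchanged.
    """
    counts = largest_remainder_counts(cohort.n_subjects, cohort.class_proportions)
    labels = [lab for lab, c in zip(LABELS, counts) for _ in range(c)]
    ss = np.random.SeedSequence(cohort.seed)
    children = ss.spawn(cohort.n_subjects)
    # interleave classes so truncated prefixes of a cohort stay mixed
    order = np.random.default_rng(ss.spawn(1)[0]).permutation(cohort.n_subjects)

    recordings, rows = [], []
    for k, idx in enumerate(order):
        sid = f"S{k:04d}"
        label = labels[idx]
        child = children[idx]
        rng = np.random.default_rng(child)
        spec = _subject_spec(label, cohort, rng)
        rec_seed = int(child.generate_state(1, np.uint32)[0])
        rec = synthesize_recording(spec, cohort.positions, rec_seed, subject_id=sid)
        recordings.append(rec)
        for pos in rec.positions:
            rows.append((sid, pos, f"{sid}_{pos}.wav", label))
    manifest = Manifest(pd.DataFrame(rows, columns=list(Manifest.COLUMNS)))
    return recordings, manifest


def write_cohort(recordings, manifest: Manifest, directory, bit_depth="32-float") -> Path:
    """Write per-channel WAVs and ``manifest.csv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, directory, bit_depth)
    out = directory / "manifest.csv"
    manifest.to_csv(out)
    return out


# ---------------------------------------------------------------------------
# background contamination (for augmentation)

BACKGROUND_KINDS = ("ventilation", "babble", "rustle")


def synthesize_background(
    kind: str, duration_s: float, sample_rate: int, seed: int
) -> AudioSignal:
    """ICU-style contamination: ventilator hum, speech-band babble, rustling.

    All synthetic (narrow-band tones + filtered noise); no recorded noise is
    shipped. Peak-normalised to 0.9.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    if kind == "ventilation":
        f0 = rng.uniform(45.0, 75.0)
        x = sum(
            (0.6**h) * np.sin(2 * np.pi * f0 * (h + 1) * t + rng.uniform(0, 2 * np.pi))
            for h in range(3)
        )
        sos = sps.butter(2, 200.0, btype="lowpass", fs=sample_rate, output="sos")
        x = x + 0.3 * sps.sosfilt(sos, rng.standard_normal(n))
    elif kind == "babble":
        x = _bandpass(rng.standard_normal(n), (120.0, 900.0), sample_rate)
        mod = 0.5 + 0.5 * np.clip(
            _bandpass_low(rng.standard_normal(n), 6.0, sample_rate) * 3.0, -1, 1
        )
        x = x * mod
    elif kind == "rustle":
        x = np.zeros(n)
        for _ in range(rng.poisson(duration_s * 1.5) + 1):
            start = rng.integers(0, max(n - 1, 1))
            dur = int(rng.uniform(0.05, 0.3) * sample_rate)
            seg = slice(start, min(start + dur, n))
            burst = rng.standard_normal(seg.stop - seg.start)
            win = np.hanning(burst.size) if burst.size > 1 else np.ones(1)
            x[seg] += burst * win
    else:
        raise ValueError(f"unknown background kind {kind!r}; expected {BACKGROUND_KINDS}")
    peak = float(np.max(np.abs(x))) or 1.0
    return AudioSignal(0.9 * x / peak, sample_rate)


def _bandpass_low(x: np.ndarray, cutoff: float, fs: float) -> np.ndarray:
    sos = sps.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    return sps.sosfilt(sos, x)
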