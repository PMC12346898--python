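"""WAV input/output and assembly of labelled multi-channel recordings.

A recording session places one single-sensor (mono) stethoscope at each of
several chest-wall positions and captures ~10 s of breathing simultaneously
at every site. On disk that is one mono WAV file per position plus a CSV
manifest mapping ``(subject_id, position)`` to a file and a class label; in
memory it is a :class:`MultiChannelRecording` holding aligned
:class:`AudioSignal` channels and a single label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .vocab import (
    LABELS,
    UNKNOWN_POSITION,
    canonical_order,
    canonicalize_position,
    position_sort_key,
    validate_label,
)

__all__ = [
    "AudioSignal",
    "MultiChannelRecording",
    "Manifest",
    "AudioIOError",
    "NonMonoError",
    "UnsupportedEncodingError",
    "read_wav",
    "write_wav",
    "resample",
    "load_recording_set",
]


class AudioIOError(Exception):
    """Base class for audio file errors."""


class NonMonoError(AudioIOError):
    """The WAV file holds more than one interleaved channel."""


class UnsupportedEncodingError(AudioIOError):
    """The WAV encoding is not 8/16/32-bit PCM or IEEE float."""


@dataclass
class AudioSignal:
    """One position's waveform.

    Parameters
    ----------
    samples : ndarray
        1-D float array, dimensionless amplitudes nominally in [-1, 1].
    sample_rate : int
        Sampling rate in Hz, > 0.
    position : str
        Auscultation position code or ``"unknown"``.
    """

    samples: np.ndarray
    sample_rate: int
    position: str = UNKNOWN_POSITION

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if int(self.sample_rate) <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        self.sample_rate = int(self.sample_rate)
        self.position = canonicalize_position(self.position)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def with_samples(self, samples: np.ndarray) -> "AudioSignal":
        return replace(self, samples=samples)


@dataclass
class MultiChannelRecording:
    """Aligned per-position signals sharing one class label.

    Channels are stored in canonical position order and must agree in sample
    rate and sample count.
    """

    channels: dict[str, AudioSignal]
    label: str
    subject_id: str
    augmented: bool = False

    def __post_init__(self):
        if not self.channels:
            raise ValueError("a recording needs at least one channel")
        validate_label(self.label)
        ordered = {}
        for pos in canonical_order(self.channels.keys()):
            sig = self.channels[pos]
            if sig.position != pos:
                sig = replace(sig, position=pos)
            ordered[pos] = sig
        self.channels = ordered
        rates = {s.sample_rate for s in self.channels.values()}
        if len(rates) != 1:
            raise ValueError(f"channels disagree on sample rate: {sorted(rates)}")
        lengths = {s.samples.size for s in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channels disagree on sample count: {sorted(lengths)}")

    @property
    def positions(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def sample_rate(self) -> int:
        return next(iter(self.channels.values())).sample_rate

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).samples.size

    def as_array(self) -> np.ndarray:
        """Channels stacked into a (n_channels, n_samples) array."""
        return np.stack([s.samples for s in self.channels.values()])

    def subset(self, positions) -> "MultiChannelRecording":
        """Restrict to the given positions (all must be present)."""
        keep = canonical_order(positions)
        missing = [p for p in keep if p not in self.channels]
        if missing:
            raise KeyError(f"recording {self.subject_id} lacks positions {missing}")
        return MultiChannelRecording(
            channels={p: self.channels[p] for p in keep},
            label=self.label,
            subject_id=self.subject_id,
            augmented=self.augmented,
        )


@dataclass
class Manifest:
    """Table of (subject_id, position, path, label) rows."""

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["subject_id", "position", "path", "label"]))

    COLUMNS = ("subject_id", "position", "path", "label")

    def __post_init__(self):
        df = pd.DataFrame(self.rows, columns=list(self.COLUMNS)).copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["position"] = [canonicalize_position(p) for p in df["position"]]
        for lab in df["label"]:
            validate_label(lab)
        dup = df.duplicated(subset=["subject_id", "position"])
        if dup.any():
            pairs = df.loc[dup, ["subject_id", "position"]].to_records(index=False)
            raise ValueError(f"duplicate (subject_id, position) pairs: {list(pairs)}")
        self.rows = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_csv(cls, path) -> "Manifest":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def subjects_with(self, positions) -> list[str]:
        """Subject ids having every one of the requested positions."""
        wanted = set(canonical_order(positions))
        have = self.rows.groupby("subject_id")["position"].agg(set)
        return sorted(sid for sid, got in have.items() if wanted <= got)


_INT_SCALES = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_wav(path) -> AudioSignal:
    """Read a mono PCM/float WAV file into a normalised :class:`AudioSignal`.

    Integer PCM is scaled by the full-scale value of its bit depth so that
    amplitudes land in [-1, 1]; float data is taken as-is. The position tag
    is left as ``"unknown"``.

    Raises
    ------
    FileNotFoundError, NonMonoError, UnsupportedEncodingError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy chirps about non-data chunks
            rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise UnsupportedEncodingError(f"{path}: {exc}") from exc
    if data.ndim != 1:
        raise NonMonoError(
            f"{path}: expected mono, found {data.shape[1]} interleaved channels"
        )
    if data.dtype in _INT_SCALES:
        samples = data.astype(np.float64) / _INT_SCALES[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.dtype(np.float32), np.dtype(np.float64)):
        samples = data.astype(np.float64)
    else:
        raise UnsupportedEncodingError(f"{path}: unsupported sample dtype {data.dtype}")
    return AudioSignal(samples=samples, sample_rate=int(rate))


def write_wav(signal: AudioSignal, path, bit_depth: str | int = 16) -> None:
    """Write a signal as 16-bit PCM (``16``) or 32-bit IEEE float (``"32-float"``).

    16-bit samples are quantised as ``round(x * 32768)`` clipped to the int16
    range, which bounds the round-trip error by one least-significant bit
    (2**-15 at full scale).
    """
    path = Path(path)
    if bit_depth in (16, "16"):
        q = np.round(signal.samples * 32768.0)
        data = np.clip(q, -32768, 32767).astype(np.int16)
    elif bit_depth in ("32-float", "32f", 32):
        data = signal.samples.astype(np.float32)
    else:
        raise ValueError(f"bit_depth must be 16 or '32-float', got {bit_depth!r}")
    try:
        wavfile.write(str(path), signal.sample_rate, data)
    except OSError as exc:
        raise AudioIOError(f"cannot write {path}: {exc}") from exc


def resample(signal: AudioSignal, target_rate: int) -> AudioSignal:
    """Band-limited resampling to ``target_rate`` (polyphase filtering).

    Returns the input object unchanged when it is already at the target rate.
    Duration is preserved to within one sample period.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if signal.sample_rate == target_rate:
        return signal
    frac = Fraction(int(target_rate), int(signal.sample_rate))
    out = resample_poly(signal.samples, frac.numerator, frac.denominator)
    return AudioSignal(out, target_rate, signal.position)


def _fit_length(samples: np.ndarray, n: int) -> np.ndarray:
    """Truncate from the end / zero-pad at the end to exactly n samples."""
    if samples.size >= n:
        return samples[:n]
    return np.concatenate([samples, np.zeros(n - samples.size)])


def load_recording_set(
    manifest: Manifest,
    positions,
    duration_s: float = 10.0,
    sample_rate: int = 4000,
    root: Path | str | None = None,
) -> list[MultiChannelRecording]:
    """Assemble multi-channel recordings for every subject that has ALL
    requested positions.

    Each channel is resampled to ``sample_rate`` and trimmed (from the end)
    or zero-padded (at the end) to exactly ``duration_s`` seconds. File paths
    in the manifest are resolved against ``root`` when given. An empty result
    is reported with a warning rather than returned silently.
    """
    if not positions:
        raise ValueError("positions must be a non-empty subset of the vocabulary")
    wanted = canonical_order(positions)
    n_target = int(round(duration_s * sample_rate))
    rows = manifest.rows
    recordings = []
    for sid in manifest.subjects_with(wanted):
        sub = rows[rows["subject_id"] == sid]
        labels = set(sub["label"])
        if len(labels) != 1:
            raise ValueError(f"subject {sid} has conflicting labels {sorted(labels)}")
        channels = {}
        for pos in wanted:
            rel = sub.loc[sub["position"] == pos, "path"].iloc[0]
            fpath = Path(root) / rel if root is not None else Path(rel)
            sig = resample(read_wav(fpath), sample_rate)
            channels[pos] = AudioSignal(_fit_length(sig.samples, n_target), sample_rate, pos)
        recordings.append(
            MultiChannelRecording(channels=channels, label=labels.pop(), subject_id=sid)
        )
    if not recordings:
        warnings.warn(
            f"no subject in the manifest has all of {wanted}; returning an empty set",
            stacklevel=2,
        )
    return recordings


def write_recording(recording: MultiChannelRecording, directory, bit_depth=16) -> list[Path]:
    """Write one WAV per channel as ``<subject>_<position>.wav``; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for pos, sig in recording.channels.items():
        p = directory / f"{recording.subject_id}_{pos}.wav"
        write_wav(sig, p, bit_depth)
        paths.append(p)
    return paths
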