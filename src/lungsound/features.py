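"""MFCC extraction and fusion of per-channel features into the model input.

The front end is a standard mel-frequency cepstral pipeline at auscultation
settings: 4 kHz audio, 25 ms windows, 10 ms hop, 40 triangular mel filters,
keeping cepstral coefficients 1..13 (the 0th, which carries overall log
energy, is dropped so features are invariant to global gain).

Conventions fixed here (the extraction is silent on them otherwise and they
are recorded in ``MfccParams`` so every matrix carries its provenance):

* frames are taken without centre padding: ``n_frames = 1 + (N - win)//hop``;
* a periodic Hann window; FFT size = next power of two >= the window length
  (128 samples at 4 kHz);
* unnormalised triangular mel filters (unit peak) on the HTK mel scale;
* ``log(energy + log_floor)`` with ``log_floor = 1e-12``;
* orthonormal DCT-II along the mel axis.

Per-channel matrices are stacked row-wise in canonical position order and the
stacked grid is bilinearly resized to the fixed 128 x 350 network input, then
standardised to zero mean / unit variance per grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.fft import dct, rfft

from .audio_io import AudioSignal, MultiChannelRecording, resample
from .vocab import canonical_order

__all__ = [
    "MfccParams",
    "MfccMatrix",
    "ModelInput",
    "mel_filterbank",
    "compute_mfcc",
    "concatenate_channels",
    "to_model_input",
    "recording_to_model_input",
    "timeseries_to_model_input",
    "MODEL_INPUT_SHAPE",
]

MODEL_INPUT_SHAPE = (128, 350)


def hz_to_mel(f):
    """HTK mel scale."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


@dataclass(frozen=True)
class MfccParams:
    sample_rate: int = 4000
    window_ms: float = 25.0
    hop_ms: float = 10.0
    n_mels: int = 40
    n_coeffs_kept: int = 13  # cepstral indices 1..13; the 0th is excluded
    fft_size: int | None = None  # None -> next power of two >= window
    log_floor: float = 1e-12

    def __post_init__(self):
        if self.n_coeffs_kept >= self.n_mels:
            raise ValueError("n_coeffs_kept must be < n_mels")
        if self.window_samples > self.nfft:
            raise ValueError("window longer than fft_size")

    @property
    def window_samples(self) -> int:
        return int(round(self.sample_rate * self.window_ms / 1000.0))

    @property
    def hop_samples(self) -> int:
        return int(round(self.sample_rate * self.hop_ms / 1000.0))

    @property
    def nfft(self) -> int:
        if self.fft_size is not None:
            return self.fft_size
        return 1 << int(np.ceil(np.log2(self.window_samples)))

    def n_frames(self, n_samples: int) -> int:
        """Frame count under the no-centre-padding convention."""
        if n_samples < self.window_samples:
            raise ValueError(
                f"signal of {n_samples} samples is shorter than one "
                f"{self.window_samples}-sample window"
            )
        return 1 + (n_samples - self.window_samples) // self.hop_samples


@dataclass
class MfccMatrix:
    """Kept cepstral coefficients (rows) by frames (columns) for one channel."""

    values: np.ndarray
    params: MfccParams
    position: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.params.n_coeffs_kept:
            raise ValueError(
                f"expected ({self.params.n_coeffs_kept}, n_frames) matrix, got {self.values.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class ModelInput:
    """Fixed-size standardised grid fed to the network."""

    grid: np.ndarray
    channel_order: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.shape != MODEL_INPUT_SHAPE:
            raise ValueError(f"model input must be {MODEL_INPUT_SHAPE}, got {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("model input contains non-finite values")


def mel_filterbank(params: MfccParams) -> np.ndarray:
    """(n_mels, nfft//2 + 1) triangular filters, uniform on the mel axis.

    Triangles have unit peak (no area normalisation); centre frequencies are
    strictly increasing and span 0..Nyquist.
    """
    n_bins = params.nfft // 2 + 1
    bin_freqs = np.arange(n_bins) * params.sample_rate / params.nfft
    mel_pts = np.linspace(
        hz_to_mel(0.0), hz_to_mel(params.sample_rate / 2.0), params.n_mels + 2
    )
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((params.n_mels, n_bins))
    for m in range(params.n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bin_freqs - lo) / (ctr - lo)
        down = (hi - bin_freqs) / (hi - ctr)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def _hann_periodic(n: int) -> np.ndarray:
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)


def compute_mfcc(signal: AudioSignal, params: MfccParams | None = None) -> MfccMatrix:
    """Framing -> Hann -> power spectrum -> mel -> log -> DCT-II -> rows 1..13.

    The signal is resampled to ``params.sample_rate`` first if needed.
    """
    params = params or MfccParams()
    signal = resample(signal, params.sample_rate)
    x = signal.samples
    n_frames = params.n_frames(x.size)
    win, hop = params.window_samples, params.hop_samples
    idx = hop * np.arange(n_frames)[:, None] + np.arange(win)[None, :]
    frames = x[idx] * _hann_periodic(win)[None, :]
    spectrum = rfft(frames, n=params.nfft, axis=1)
    power = np.abs(spectrum) ** 2
    mel_energy = power @ mel_filterbank(params).T  # (frames, mels)
    log_mel = np.log(mel_energy + params.log_floor)
    ceps = dct(log_mel, type=2, norm="ortho", axis=1)
    kept = ceps[:, 1 : params.n_coeffs_kept + 1].T  # (coeffs, frames)
    return MfccMatrix(values=kept, params=params, position=signal.position)


def concatenate_channels(
    mfccs: Sequence[MfccMatrix], order: Sequence[str] | None = None
) -> np.ndarray:
    """Stack per-channel matrices row-wise in canonical position order.

    ``order`` may restate the expected positions (any ordering); the output
    row order is always canonical regardless of the input list order, so
    feature grids are independent of how channels were enumerated.
    """
    if not mfccs:
        raise ValueError("no MFCC matrices to concatenate")
    by_pos = {m.position: m for m in mfccs}
    if len(by_pos) != len(mfccs):
        raise ValueError("duplicate channel positions")
    if order is not None and set(canonical_order(order)) != set(by_pos):
        raise ValueError(f"declared order {tuple(order)} does not cover positions {tuple(by_pos)}")
    frames = {m.n_frames for m in mfccs}
    if len(frames) != 1:
        raise ValueError(f"channels disagree on frame count: {sorted(frames)}")
    pars = {m.params for m in mfccs}
    if len(pars) != 1:
        raise ValueError("channels disagree on MFCC parameters")
    ordered = canonical_order(by_pos.keys())
    return np.vstack([by_pos[p].values for p in ordered])


def _axis_weights(in_n: int, out_n: int) -> np.ndarray:
    """(out_n, in_n) triangle-filter resampling weights, pixel-centre convention.

    For downscaling the kernel support widens to the scale factor so every
    input sample contributes (anti-aliasing); at equal size the matrix is
    the identity. This is the scale-aware bilinear filter high-quality image
    resizers use.
    """
    scale = in_n / out_n
    support = max(scale, 1.0)
    centres = (np.arange(out_n) + 0.5) * scale - 0.5
    d = (centres[:, None] - np.arange(in_n)[None, :]) / support
    w = np.maximum(0.0, 1.0 - np.abs(d))
    return w / w.sum(axis=1, keepdims=True)


def _resize_bilinear(grid: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Separable bilinear (triangle-kernel) resize; identity when shapes match."""
    h, w = grid.shape
    oh, ow = out_shape
    if h < 2 or w < 2:
        raise ValueError(f"cannot resize degenerate grid of shape {grid.shape}")
    out = grid
    if h != oh:
        out = _axis_weights(h, oh) @ out
    if w != ow:
        out = out @ _axis_weights(w, ow).T
    return out


def to_model_input(
    stacked: np.ndarray,
    channel_order: Sequence[str] = (),
    out_shape: tuple[int, int] = MODEL_INPUT_SHAPE,
) -> ModelInput:
    """Resize a stacked feature grid to the network input and standardise it.

    Deterministic align-corners bilinear resize to ``out_shape`` followed by
    per-grid standardisation to zero mean / unit variance (variance floored,
    so a constant grid maps to all zeros).
    """
    stacked = np.asarray(stacked, dtype=np.float64)
    if stacked.ndim != 2 or stacked.size == 0:
        raise ValueError("stacked grid must be a non-empty 2-D array")
    resized = _resize_bilinear(stacked, out_shape)
    mu = resized.mean()
    sd = resized.std()
    if sd <= 1e-6 * max(1.0, abs(mu)):  # variance floor: constant -> zeros
        grid = np.zeros(out_shape)
    else:
        grid = (resized - mu) / sd
    return ModelInput(
        grid=grid,
        channel_order=tuple(channel_order),
        provenance={"source_shape": stacked.shape, "resize": "bilinear-triangle"},
    )


def recording_to_model_input(
    recording: MultiChannelRecording, params: MfccParams | None = None
) -> ModelInput:
    """MFCC per channel -> row-wise concatenation -> fixed-size input."""
    params = params or MfccParams()
    mfccs = [compute_mfcc(sig, params) for sig in recording.channels.values()]
    stacked = concatenate_channels(mfccs)
    return to_model_input(stacked, channel_order=recording.positions)


def timeseries_to_model_input(recording: MultiChannelRecording) -> ModelInput:
    """Raw waveform baseline input: an (n_samples x n_channels) grid resized
    to the network shape. A single-channel recording is duplicated to two
    columns so the bilinear resize is defined."""
    grid = recording.as_array().T  # (samples, channels)
    if grid.shape[1] == 1:
        grid = np.repeat(grid, 2, axis=1)
    return to_model_input(grid, channel_order=recording.positions)
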