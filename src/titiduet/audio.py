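"""Audio I/O and the preprocessing chain applied to duet recordings.

The analysis chain mirrors the field workflow: stereo WAV files are split to
mono, downsampled to 44.1 kHz when recorded at a higher rate, high-pass
filtered at 80 Hz to strip wind/handling rumble below the monkeys' fundamental
(>100 Hz), and peak-normalized so the loudest sample of every file sits at
full scale.  All filters are zero-phase so that syllable onset times used by
the temporal features are not shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, resample_poly, sosfiltfilt

__all__ = [
    "AudioSignal",
    "load_audio",
    "save_audio",
    "to_mono",
    "resample",
    "bandpass_chain",
    "normalize_peak",
    "preprocess",
]

#: sampling rates accepted on ingest (field recorders used in the study)
INGEST_RATES = (44100, 48000, 96000)


class AudioFormatError(ValueError):
    """Raised for files that are not readable PCM WAV."""


@dataclass(frozen=True)
class AudioSignal:
    """A sampled waveform.

    samples are float64 in [-1, 1]; shape ``(n,)`` for mono or ``(n, 2)``
    for stereo.
    """

    samples: np.ndarray
    rate: int
    bit_depth: int = 16

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim not in (1, 2) or (s.ndim == 2 and s.shape[1] not in (1, 2)):
            raise ValueError("samples must be (n,) mono or (n, 2) stereo")
        if s.ndim == 2 and s.shape[1] == 1:
            s = s[:, 0]
        object.__setattr__(self, "samples", s)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def replace(self, samples: np.ndarray, rate: int | None = None) -> "AudioSignal":
        return AudioSignal(samples, self.rate if rate is None else rate, self.bit_depth)


def load_audio(path: str | Path) -> AudioSignal:
    """Read a PCM WAV file, scaling integer samples to [-1, 1].

    16-bit samples are divided by 2**15, 24-bit (delivered by scipy as
    left-justified int32) and 32-bit by 2**31, so full-scale negative maps to
    -1.0 regardless of bit depth.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, EOFError) as exc:  # non-PCM / truncated
        raise AudioFormatError(f"{path}: not a readable PCM WAV file ({exc})") from exc
    if data.dtype == np.int16:
        samples = data / 2.0**15
        depth = 16
    elif data.dtype == np.int32:
        samples = data / 2.0**31
        depth = 24
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
        depth = 8
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
        depth = 32
    else:
        raise AudioFormatError(f"{path}: unsupported sample format {data.dtype}")
    return AudioSignal(samples, int(rate), depth)


def save_audio(signal: AudioSignal, path: str | Path) -> None:
    """Write 16-bit PCM WAV; samples are clipped to [-1, 1] first."""
    s = np.clip(signal.samples, -1.0, 1.0)
    data = np.clip(np.round(s * 2.0**15), -(2**15), 2**15 - 1).astype(np.int16)
    wavfile.write(Path(path), signal.rate, data)


def to_mono(signal: AudioSignal, channel: str = "left") -> AudioSignal:
    """Reduce to one channel (``left`` | ``right`` | ``mix``).

    Mono input is returned unchanged.  ``mix`` averages the two channels, so
    a tone on one channel against silence on the other halves in amplitude.
    """
    if signal.channels == 1:
        return signal
    if channel == "left":
        out = signal.samples[:, 0]
    elif channel == "right":
        out = signal.samples[:, 1]
    elif channel == "mix":
        out = signal.samples.mean(axis=1)
    else:
        raise ValueError(f"channel must be left|right|mix, got {channel!r}")
    return signal.replace(out)


def resample(signal: AudioSignal, target_rate: int) -> AudioSignal:
    """Polyphase resampling with Kaiser-windowed anti-aliasing.

    Identity when the target equals the source rate.  The pipeline only
    downsamples (96 or 48 kHz recordings to 44.1 kHz) but upsampling works.
    """
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if target_rate == signal.rate:
        return signal
    frac = Fraction(target_rate, signal.rate)
    out = resample_poly(signal.samples, frac.numerator, frac.denominator,
                        axis=0, window=("kaiser", 8.0))
    return signal.replace(out, rate=target_rate)


def bandpass_chain(signal: AudioSignal, high_pass: float = 80.0,
                   low_pass: float | None = None) -> AudioSignal:
    """80 Hz high-pass and optional 2 kHz low-pass, zero phase.

    4th-order Butterworth sections applied forward-backward (sosfiltfilt),
    giving an 8th-order magnitude response and zero group delay.
    """
    nyq = signal.rate / 2.0
    for cutoff in (high_pass, low_pass):
        if cutoff is not None and not (0 < cutoff < nyq):
            raise ValueError(f"cutoff {cutoff} Hz outside (0, Nyquist={nyq}) Hz")
    out = signal.samples
    if high_pass is not None:
        sos = butter(4, high_pass, btype="highpass", fs=signal.rate, output="sos")
        out = sosfiltfilt(sos, out, axis=0)
    if low_pass is not None:
        sos = butter(4, low_pass, btype="lowpass", fs=signal.rate, output="sos")
        out = sosfiltfilt(sos, out, axis=0)
    return signal.replace(out)


def normalize_peak(signal: AudioSignal) -> AudioSignal:
    """Scale so the loudest peak sits exactly at full scale (|max| = 1)."""
    peak = np.max(np.abs(signal.samples))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero signal")
    return signal.replace(signal.samples / peak)


def preprocess(signal: AudioSignal, channel: str = "left",
               target_rate: int = 44100, high_pass: float = 80.0,
               low_pass: float | None = None,
               normalize: bool = True) -> AudioSignal:
    """Full conditioning chain: mono -> 44.1 kHz -> 80 Hz HP -> normalize."""
    out = to_mono(signal, channel)
    if out.rate > target_rate:
        out = resample(out, target_rate)
    if high_pass is not None or low_pass is not None:
        out = bandpass_chain(out, high_pass, low_pass)
    if normalize:
        out = normalize_peak(out)
    return out
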