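"""Power spectra of the combined (two-voice) duet signal.

The dominant frequency of a duet is read off the mean power spectrum of the
whole one-minute signal: squared-magnitude spectra of non-overlapping
2048-sample Hann windows are averaged and max-normalized, the five largest
local maxima inside the 80-2000 Hz analysis band are located, and the
largest of the five is the dominant frequency.  Cumulative band-energy
distributions and the frequency at which they reach one half ("halfway
frequency") provide a peak-free comparison of whole spectra across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .annotations import AnnotationTrack
from .audio import AudioSignal

__all__ = [
    "PowerSpectrum",
    "CumulativeSpectrum",
    "SpectralPeak",
    "mean_power_spectrum",
    "dominant_frequency",
    "find_peaks",
    "cumulative_distribution",
    "halfway_frequency",
    "group_mean_spectrum",
    "pair_bellow_spectrum",
]

WINDOW_LENGTH = 2048
DEFAULT_BAND = (80.0, 2000.0)


@dataclass(frozen=True)
class PowerSpectrum:
    """Relative power vs frequency on a uniform grid, max-normalized to 1."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise ValueError("frequencies and power must be equal-length 1-D")
        if np.any(p < 0):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)

    @property
    def bin_width(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def band(self, band: tuple[float, float]) -> "PowerSpectrum":
        lo, hi = band
        mask = (self.frequencies >= lo) & (self.frequencies <= hi)
        if not mask.any():
            raise ValueError(f"band {band} outside the frequency grid")
        return PowerSpectrum(self.frequencies[mask], self.power[mask])


@dataclass(frozen=True)
class CumulativeSpectrum:
    """Running fraction of band energy; non-decreasing from 0 to 1."""

    frequencies: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.cumulative, dtype=float)
        if np.any(np.diff(c) < -1e-12):
            raise ValueError("cumulative curve must be non-decreasing")
        if abs(c[0]) > 1e-9 or abs(c[-1] - 1.0) > 1e-9:
            raise ValueError("cumulative curve must run from 0 to 1")


@dataclass(frozen=True)
class SpectralPeak:
    frequency: float
    power: float
    rank: int


def mean_power_spectrum(signal: AudioSignal,
                        window_length: int = WINDOW_LENGTH) -> PowerSpectrum:
    """Average squared-magnitude spectrum over non-overlapping Hann windows.

    The trailing partial window is discarded; the result is max-normalized
    so the largest bin equals 1 ("relative amplitude").
    """
    if signal.channels != 1:
        raise ValueError("mean_power_spectrum expects a mono signal")
    if signal.n_samples < window_length:
        raise ValueError(
            f"signal of {signal.n_samples} samples is shorter than one "
            f"{window_length}-sample analysis window")
    freqs, power = welch(signal.samples, fs=signal.rate, window="hann",
                         nperseg=window_length, noverlap=0, detrend=False)
    peak = power.max()
    if peak > 0:
        power = power / peak
    return PowerSpectrum(freqs, power)


def find_peaks(spectrum: PowerSpectrum,
               band: tuple[float, float] = DEFAULT_BAND,
               n_peaks: int = 5) -> list[SpectralPeak]:
    """The ``n_peaks`` largest local maxima inside the band.

    A local maximum needs strictly smaller neighbors; a plateau is assigned
    to its lowest-frequency bin; power ties rank the lower frequency first.
    """
    sub = spectrum.band(band)
    p = sub.power
    candidates = []
    i = 0
    while i < len(p):
        j = i  # walk right across a plateau of equal bins
        while j + 1 < len(p) and p[j + 1] == p[i]:
            j += 1
        left_ok = i == 0 or p[i - 1] < p[i]
        right_ok = j == len(p) - 1 or p[j + 1] < p[i]
        if left_ok and right_ok and p[i] > 0:
            candidates.append(i)  # plateau credited to its lowest bin
        i = j + 1
    if not candidates:
        raise ValueError(f"no local maximum inside band {band}")
    candidates.sort(key=lambda i: (-p[i], sub.frequencies[i]))
    return [SpectralPeak(float(sub.frequencies[i]), float(p[i]), rank)
            for rank, i in enumerate(candidates[:n_peaks], start=1)]


def dominant_frequency(spectrum: PowerSpectrum,
                       band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Frequency of the largest of the five largest in-band peaks."""
    return find_peaks(spectrum, band, n_peaks=5)[0].frequency


def cumulative_distribution(spectrum: PowerSpectrum,
                            band: tuple[float, float] = DEFAULT_BAND,
                            ) -> CumulativeSpectrum:
    """Running sum of band power, normalized to 1 at the band top.

    The curve is anchored at 0 one bin below the first in-band frequency so
    it spans [0, 1] exactly.
    """
    sub = spectrum.band(band)
    total = sub.power.sum()
    if total <= 0:
        raise ValueError("zero energy inside the band")
    cum = np.concatenate([[0.0], np.cumsum(sub.power) / total])
    freqs = np.concatenate([[sub.frequencies[0] - sub.bin_width],
                            sub.frequencies])
    return CumulativeSpectrum(freqs, cum)


def halfway_frequency(cum: CumulativeSpectrum) -> float:
    """Frequency at which the cumulative energy fraction reaches one half.

    Each bin's mass is treated as spread uniformly over its width, so the
    curve is piecewise linear between bin upper edges: a single-bin step at
    f returns exactly f, and a flat spectrum returns the band midpoint.
    """
    f = np.asarray(cum.frequencies, dtype=float)
    c = np.asarray(cum.cumulative, dtype=float)
    df = f[1] - f[0]
    edges = f + df / 2.0
    return float(np.interp(0.5, c, edges))


def group_mean_spectrum(spectra: list[PowerSpectrum],
                        ) -> tuple[PowerSpectrum, np.ndarray]:
    """Per-bin mean spectrum and SEM across duets of one taxon.

    With a single spectrum the SEM is reported as zeros (undefined-as-zero).
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    grid = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != grid.shape or not np.allclose(s.frequencies, grid):
            raise ValueError("all spectra must share one frequency grid")
    stack = np.vstack([s.power for s in spectra])
    mean = stack.mean(axis=0)
    if len(spectra) == 1:
        sem = np.zeros_like(mean)
    else:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(spectra))
    return PowerSpectrum(grid, mean), sem


def pair_bellow_spectrum(signal: AudioSignal, track: AnnotationTrack,
                         bellow_voice: str,
                         window_length: int = WINDOW_LENGTH) -> PowerSpectrum:
    """Mean spectrum of one voice's bellows (partner pants included).

    Annotated bellow segments of the stated voice are cut from the mixed
    signal — together with whatever the partner was producing at the same
    time — concatenated, and analysed with :func:`mean_power_spectrum`.
    The dominant frequency of the result is the sex-comparison statistic.
    """
    events = [e for e in track
              if e.sex == bellow_voice and e.phrase_base == "bellow"]
    if not events:
        raise ValueError(f"no bellow events for voice {bellow_voice!r}")
    pieces = []
    for e in events:
        i0 = int(round(e.onset * signal.rate))
        i1 = int(round(e.offset * signal.rate))
        pieces.append(signal.samples[i0:i1])
    joined = np.concatenate(pieces)
    return mean_power_spectrum(AudioSignal(joined, signal.rate),
                               window_length=window_length)
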